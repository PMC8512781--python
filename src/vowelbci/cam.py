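"""Class-activation maps on the third batch-norm layer (BN_3).

The classifier head here is two fully connected layers, so the classic CAM
construction (which requires global average pooling feeding the classifier
directly) does not literally apply; a gradient-weighted generalization is
used instead. Because the fully connected head weighs every BN_3 grid cell
independently (there is no spatial weight sharing to justify averaging
gradients across cells), the attribution is computed element-wise: the map
is the rectified channel sum of gradient x activation,
``relu(sum_c dL/dA[p,q,c] * A[p,q,c])`` — the first-order contribution of
each cell to the class logit — bilinearly upsampled to the input image grid
and min-max scaled to 0-255. Constant maps scale to all zeros.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .cnn import BinaryCNN
from .ensemble import CNNeegClassifier

__all__ = ["CAMMap", "activation_map", "ensemble_activation_map", "render_cam"]


@dataclasses.dataclass
class CAMMap:
    """Frequency x electrode-pair activation grid scaled to [0, 255]."""

    values: np.ndarray
    target_class: str
    layer: str = "BN_3"
    source: str | int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _bilinear_resize(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize

    return resize(a, shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True)


def activation_map(
    model: BinaryCNN, image: np.ndarray, target_class: str, layer: str = "BN_3"
) -> CAMMap:
    """Gradient-weighted class-activation map for one image.

    ``image`` is a 2-D frequency x pair matrix (or the ``values`` of a
    spectral image). The output grid has the same axes as the input.
    """
    image = np.asarray(getattr(image, "values", image), dtype=np.float32)
    if image.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {image.shape}")
    classes = [str(c) for c in model.classes_]
    if str(target_class) not in classes:
        raise ValueError(f"class {target_class!r} unknown to this model (classes: {classes})")
    if layer not in model.layer_names_:
        raise ValueError(f"unknown layer {layer!r}; available: {model.layer_names_}")
    c = classes.index(str(target_class))
    x = image[None, :, :, None]

    # forward to the target layer, continue to the logits (caches populated),
    # then backpropagate the class logit down to the target layer's output.
    upto = model.layer_names_.index(layer) + 1
    act = model.network_.forward(x, train=False, upto=upto)
    logits = model.network_.forward(act, train=False, start=upto)
    dout = np.zeros_like(logits)
    dout[0, c] = 1.0
    grad = model.network_.backward(dout, downto=upto)
    # element-wise gradient x activation, rectified and channel-summed
    cam = np.maximum((act[0] * grad[0]).sum(axis=-1), 0.0)
    cam = _bilinear_resize(cam, image.shape)
    lo, hi = cam.min(), cam.max()
    values = np.zeros_like(cam) if hi == lo else (cam - lo) / (hi - lo) * 255.0
    return CAMMap(values=values, target_class=str(target_class), layer=layer)


def ensemble_activation_map(
    ensemble: CNNeegClassifier, image: np.ndarray, target_class: str, layer: str = "BN_3"
) -> CAMMap:
    """Average the CAMs of every binary model whose pair contains the class."""
    maps = [
        activation_map(est, image, target_class, layer)
        for pair, est in ensemble.models_.items()
        if str(target_class) in pair
    ]
    if not maps:
        raise ValueError(f"class {target_class!r} appears in no trained pair")
    values = np.mean([m.values for m in maps], axis=0)
    lo, hi = values.min(), values.max()
    values = np.zeros_like(values) if hi == lo else (values - lo) / (hi - lo) * 255.0
    return CAMMap(values=values, target_class=str(target_class), layer=layer)


def render_cam(
    cam: CAMMap,
    path: str | Path,
    freq_axis: np.ndarray | None = None,
    pair_labels: list[str] | None = None,
    raw_path: str | Path | None = None,
) -> Path:
    """Save a labelled heatmap figure (PNG) and optionally the raw grid as CSV."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    values = cam.values
    fig, ax = plt.subplots(figsize=(10, 4))
    im = ax.imshow(values, aspect="auto", origin="lower", cmap="jet", vmin=0, vmax=255)
    ax.set_xlabel("electrode pair")
    ax.set_ylabel("frequency (Hz)" if freq_axis is not None else "frequency bin")
    ax.set_title(f"class activation map, vowel /{cam.target_class}/ ({cam.layer})")
    if freq_axis is not None:
        ticks = np.linspace(0, len(freq_axis) - 1, min(9, len(freq_axis))).astype(int)
        ax.set_yticks(ticks)
        ax.set_yticklabels([f"{freq_axis[t]:.0f}" for t in ticks])
    if pair_labels is not None:
        step = max(1, len(pair_labels) // 12)
        ticks = np.arange(0, len(pair_labels), step)
        ax.set_xticks(ticks)
        ax.set_xticklabels([pair_labels[t] for t in ticks], rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="CAM value")
    fig.tight_layout()
    try:
        fig.savefig(path, dpi=150)
    finally:
        plt.close(fig)
    if raw_path is not None:
        np.savetxt(raw_path, values, delimiter=",")
    return path
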