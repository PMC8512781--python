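"""HDF5 checkpoints for trained binary models and OvO ensembles."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from ._nn import BatchNorm
from .cnn import BinaryCNN
from .ensemble import CNNeegClassifier

__all__ = ["load_binary", "load_ensemble", "save_binary", "save_ensemble"]


def _write_binary(group: h5py.Group, model: BinaryCNN) -> None:
    group.attrs["params"] = json.dumps(model.get_params())
    group.attrs["classes"] = [str(c) for c in model.classes_]
    group.attrs["input_shape"] = list(model.spec_.input_shape)
    for k, layer in enumerate(model.network_.layers):
        for j, p in enumerate(layer.params):
            group.create_dataset(f"layer{k:02d}_param{j}", data=p)
        if isinstance(layer, BatchNorm):
            group.create_dataset(f"layer{k:02d}_running_mean", data=layer.running_mean)
            group.create_dataset(f"layer{k:02d}_running_var", data=layer.running_var)


def _read_binary(group: h5py.Group) -> BinaryCNN:
    params = json.loads(group.attrs["params"])
    if params.get("input_shape") is not None:
        params["input_shape"] = tuple(params["input_shape"])
    model = BinaryCNN(**params)
    classes = [c if isinstance(c, str) else c.decode() for c in group.attrs["classes"]]
    shape = tuple(int(v) for v in group.attrs["input_shape"])
    # rebuild the network deterministically, then overwrite the weights
    X = np.zeros((4, *shape), dtype=np.float32)
    X[:2] += 1.0
    y = np.array([classes[0], classes[0], classes[1], classes[1]])
    probe = BinaryCNN(**{**params, "epochs": 0, "train_fraction": 1.0})
    probe.fit(X, y)
    model.__dict__.update(probe.__dict__)
    model.set_params(**params)
    for k, layer in enumerate(model.network_.layers):
        for j, p in enumerate(layer.params):
            p[...] = np.asarray(group[f"layer{k:02d}_param{j}"], dtype=p.dtype)
        if isinstance(layer, BatchNorm):
            layer.running_mean[...] = np.asarray(group[f"layer{k:02d}_running_mean"])
            layer.running_var[...] = np.asarray(group[f"layer{k:02d}_running_var"])
    model.classes_ = np.asarray(classes)
    return model


def save_binary(model: BinaryCNN, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        _write_binary(f.create_group("model"), model)
    return path


def load_binary(path: str | Path) -> BinaryCNN:
    with h5py.File(path, "r") as f:
        return _read_binary(f["model"])


def save_ensemble(ensemble: CNNeegClassifier, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["classes"] = [str(c) for c in ensemble.classes_]
        f.attrs["params"] = json.dumps(
            {k: v for k, v in ensemble.get_params().items() if k != "base_estimator"}
        )
        for (a, b), model in ensemble.models_.items():
            _write_binary(f.create_group(f"pair_{a}_{b}"), model)
    return path


def load_ensemble(path: str | Path) -> CNNeegClassifier:
    with h5py.File(path, "r") as f:
        params = json.loads(f.attrs["params"])
        ensemble = CNNeegClassifier(**params)
        ensemble.classes_ = np.asarray(
            [c if isinstance(c, str) else c.decode() for c in f.attrs["classes"]]
        )
        ensemble.models_ = {}
        ensemble.training_classes_ = {}
        for name in f:
            if not name.startswith("pair_"):
                continue
            _, a, b = name.split("_")
            ensemble.models_[(a, b)] = _read_binary(f[name])
            ensemble.training_classes_[(a, b)] = (a, b)
    return ensemble
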