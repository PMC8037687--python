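"""Persistence: cubes and datasets as HDF5, spectra as CSV, models as
NPZ weight archives with a JSON spec sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .nnmodels import BPNNClassifier, DCNNClassifier, TrainedModel, _mlp_shapes
from .preprocess import LabeledDataset
from .spectra import FrequencyGrid, Spectrum
from .synthetic import HyperCube

__all__ = [
    "save_cube",
    "load_cube",
    "save_dataset",
    "load_dataset",
    "save_spectrum_csv",
    "load_spectrum_csv",
    "save_model",
    "load_model",
    "save_history_csv",
]


def _grid_from_values(values: np.ndarray) -> FrequencyGrid:
    step = float(np.diff(values).mean())
    return FrequencyGrid(float(values[0]), float(values[-1]) + step / 4, step)


def save_cube(cube: HyperCube, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=cube.data, compression="gzip")
        fh.create_dataset("frequencies", data=cube.grid.values)
        fh.create_dataset("leaf_mask", data=cube.leaf_mask)
        fh.attrs["true_class"] = cube.true_class
        fh.attrs["seed"] = cube.seed


def load_cube(path) -> HyperCube:
    with h5py.File(path, "r") as fh:
        return HyperCube(
            data=fh["data"][...],
            grid=_grid_from_values(fh["frequencies"][...]),
            leaf_mask=fh["leaf_mask"][...].astype(bool),
            true_class=int(fh.attrs["true_class"]),
            seed=int(fh.attrs["seed"]),
        )


def save_dataset(dataset: LabeledDataset, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("spectra", data=dataset.spectra, compression="gzip")
        fh.create_dataset("labels", data=dataset.labels)
        fh.create_dataset("is_train", data=dataset.is_train)
        fh.create_dataset("frequencies", data=dataset.frequencies)


def load_dataset(path) -> LabeledDataset:
    with h5py.File(path, "r") as fh:
        return LabeledDataset(
            spectra=fh["spectra"][...],
            labels=fh["labels"][...],
            is_train=fh["is_train"][...].astype(bool),
            frequencies=fh["frequencies"][...],
        )


def save_spectrum_csv(spectrum: Spectrum, path) -> None:
    pd.DataFrame(
        {"frequency_THz": spectrum.frequencies, "absorbance": spectrum.absorbance}
    ).to_csv(path, index=False)


def load_spectrum_csv(path) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(df["frequency_THz"].to_numpy(), df["absorbance"].to_numpy())


def save_history_csv(model: TrainedModel, path) -> None:
    """Per-epoch loss/accuracy curves as CSV (one column per history key)."""
    history = {k: np.asarray(v).ravel() for k, v in model.history.items()}
    n = max((len(v) for v in history.values()), default=0)
    frame = pd.DataFrame(
        {k: np.pad(v.astype(float), (0, n - len(v)), constant_values=np.nan)
         for k, v in history.items()}
    )
    frame.insert(0, "epoch", np.arange(1, n + 1))
    frame.to_csv(path, index=False)


_WEIGHT_ATTRS = ("W", "b", "gamma", "beta", "run_mean", "run_var")


def _dcnn_weights(est: DCNNClassifier) -> list[np.ndarray]:
    out = []
    for layer in [*est._conv, *est._fc]:
        for attr in _WEIGHT_ATTRS:
            if hasattr(layer, attr):
                out.append(getattr(layer, attr))
    return out


def save_model(model: TrainedModel, path) -> None:
    """Single-archive weight store (.npz) + JSON spec sidecar (.json)."""
    path = Path(path)
    est = model.estimator
    meta = {
        "kind": type(est).__name__,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in est.get_params().items()},
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in model.spec.items()},
        "classes": [int(c) for c in est.classes_],
        "n_features_in": int(est.n_features_in_),
        "class_map": {str(k): v for k, v in model.class_map.items()},
    }
    arrays = {}
    if isinstance(est, DCNNClassifier):
        for i, arr in enumerate(_dcnn_weights(est)):
            arrays[f"w{i:03d}"] = arr
    elif isinstance(est, BPNNClassifier):
        arrays["coef_flat"] = est.coef_flat_
    else:
        raise TypeError(f"cannot serialize estimator of type {type(est).__name__}")
    for key, val in model.history.items():
        arrays[f"history_{key}"] = np.asarray(val)
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    blob = np.load(path.with_suffix(".npz"))
    params = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in meta["params"].items()}
    classes = np.asarray(meta["classes"])
    n_feat = meta["n_features_in"]
    if meta["kind"] == "DCNNClassifier":
        est = DCNNClassifier(**params)
        est._build(n_feat, len(classes), np.random.default_rng(0))
        weights = [blob[k] for k in sorted(blob.files) if k.startswith("w")]
        i = 0
        for layer in [*est._conv, *est._fc]:
            for attr in _WEIGHT_ATTRS:
                if hasattr(layer, attr):
                    setattr(layer, attr, weights[i])
                    i += 1
        est.history_ = {}
    elif meta["kind"] == "BPNNClassifier":
        est = BPNNClassifier(**params)
        est.coef_flat_ = blob["coef_flat"]
        width = n_feat if est.input_width is None else est.input_width
        est._shapes = _mlp_shapes([width, *est.hidden, len(classes)])
    else:
        raise TypeError(f"unknown model kind {meta['kind']!r}")
    est.classes_ = classes
    est.n_features_in_ = n_feat
    history = {k[len("history_"):]: blob[k] for k in blob.files
               if k.startswith("history_")}
    spec = {k: (tuple(v) if isinstance(v, list) else v)
            for k, v in meta["spec"].items()}
    return TrainedModel(est, spec, history,
                        {int(k): v for k, v in meta["class_map"].items()})
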