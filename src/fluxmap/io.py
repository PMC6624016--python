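"""Readers, writers, and the manifold model archive.

Traces travel as delimited text: the first row holds neuron names, one
row per frame, optionally a leading ``time`` column.  Behavior labels
are a single-column CSV with header ``behavior``.  Fitted manifolds are
stored as a zip archive of one JSON metadata file plus flat
little-endian binary arrays (shapes and dtypes listed in the metadata),
so the model can be read from any language without unpickling.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import EmbedConfig, Recording
from .manifold import BinSet, ManifoldModel
from .preprocess import zscore

__all__ = [
    "read_traces",
    "write_traces",
    "read_behaviors",
    "write_behaviors",
    "normalize_external_behavior",
    "save_model",
    "load_model",
]

_FIXED_DATE = (1980, 1, 1, 0, 0, 0)  # deterministic archive timestamps


def read_traces(path, frame_rate: Optional[float] = None, animal_id: str = "animal0") -> Recording:
    """Read a traces CSV/TSV into a :class:`Recording`.

    The first row gives neuron names; an optional ``time`` column (by
    that name) is dropped.  The frame rate comes from a
    ``# frame_rate = <x>`` comment line when present, else from the
    ``frame_rate`` argument (default 3.0).
    """
    meta_rate = None
    header = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "frame_rate" in line:
                    meta_rate = float(line.split("=")[1])
                continue
            header = line.rstrip("\n")
            break
    if header is None:
        raise ValueError(f"{path} has no header row")
    sep = "\t" if "\t" in header else ","
    names = [h.strip() for h in header.split(sep)]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate neuron columns in {path}")
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    if "time" in df.columns:
        df = df.drop(columns=["time"])
    if df.isna().any().any():
        raise ValueError(f"non-numeric or missing cells in {path}")
    try:
        activity = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
    rate = meta_rate if meta_rate is not None else (frame_rate or 3.0)
    return Recording(
        activity, [str(c) for c in df.columns], frame_rate=rate,
        animal_id=animal_id,
    )


def write_traces(rec: Recording, path) -> None:
    """Write a recording to CSV with a frame-rate comment header."""
    with open(path, "w") as fh:
        fh.write(f"# frame_rate = {rec.frame_rate}\n")
        pd.DataFrame(rec.activity, columns=rec.neuron_names).to_csv(
            fh, index=False, float_format="%.17g"
        )


def read_behaviors(
    path, n_frames: Optional[int] = None, vocab: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Read per-frame behavior labels (single ``behavior`` column).

    When ``n_frames`` is given, a length mismatch is an error; when
    ``vocab`` is given, unknown labels are an error.
    """
    df = pd.read_csv(path, comment="#")
    if "behavior" not in df.columns:
        raise ValueError(f"{path} lacks a 'behavior' column")
    labels = df["behavior"].astype(str).to_numpy()
    if n_frames is not None and labels.size != n_frames:
        raise ValueError(
            f"{labels.size} behavior labels for {n_frames} frames"
        )
    if vocab is not None:
        unknown = sorted(set(labels) - set(vocab))
        if unknown:
            raise ValueError(f"unknown behavior labels: {unknown}")
    return labels


def write_behaviors(labels, path) -> None:
    pd.DataFrame({"behavior": np.asarray(labels)}).to_csv(path, index=False)


def normalize_external_behavior(
    rec: Recording,
    reference_neuron: str,
    threshold_z: float = 0.0,
    labels: tuple = ("forward", "backward"),
) -> np.ndarray:
    """Two-state behavior labels from thresholding one reference neuron.

    The reference trace (canonically AVAL, the backward-locomotion
    command neuron) is z-scored; frames at or below ``threshold_z`` get
    ``labels[0]`` (forward locomotion), frames above get ``labels[1]``
    (backward).  Used to harmonize behavior annotation of external
    validation recordings.
    """
    if reference_neuron not in rec.neuron_names:
        raise ValueError(
            f"reference neuron {reference_neuron!r} not in recording"
        )
    z = zscore(rec.subset([reference_neuron])).activity[:, 0]
    return np.where(z <= threshold_z, labels[0], labels[1])


# ---------------------------------------------------------------------------
# model archive

_ARRAY_FIELDS = {
    "bins_alpha": ("int64", lambda m: m.bins.alpha),
    "bins_center": ("float64", lambda m: m.bins.center),
    "bins_sd": ("float64", lambda m: m.bins.sd),
    "mean_embedded": ("float64", lambda m: m.mean_embedded),
    "mean_activity": ("float64", lambda m: m.mean_activity),
    "behavior_dist": ("float64", lambda m: m.behavior_dist),
    "occupancy": ("int64", lambda m: m.occupancy),
    "flagged": ("uint8", lambda m: m.flagged),
    "visited": ("uint8", lambda m: m.visited),
    "theta": ("float64", lambda m: m.theta),
    "alpha": ("int64", lambda m: m.alpha),
    "assignments": ("int64", lambda m: m.assignments),
    "state_rec_ids": ("int64", lambda m: m.state_rec_ids),
}


def save_model(model: ManifoldModel, path) -> None:
    """Serialize a fitted manifold to a zip archive.

    The archive holds ``meta.json`` plus one raw little-endian binary
    file per array; the bin-level transition matrix is stored as
    coordinate triplets (rows, cols, vals).  Timestamps are fixed so
    identical models produce byte-identical archives.
    """
    arrays = {}
    meta_arrays = {}
    for name, (dtype, getter) in _ARRAY_FIELDS.items():
        arr = getter(model)
        if arr is None:
            continue
        arr = np.ascontiguousarray(arr, dtype=np.dtype(dtype).newbyteorder("<"))
        arrays[name] = arr
        meta_arrays[name] = {"shape": list(arr.shape), "dtype": dtype}
    bt = model.bin_transitions
    r, c = np.nonzero(bt)
    for name, arr, dtype in (
        ("bin_transitions_rows", r, "int64"),
        ("bin_transitions_cols", c, "int64"),
        ("bin_transitions_vals", bt[r, c], "float64"),
    ):
        arr = np.ascontiguousarray(arr, dtype=np.dtype(dtype).newbyteorder("<"))
        arrays[name] = arr
        meta_arrays[name] = {"shape": list(arr.shape), "dtype": dtype}

    meta = {
        "format_version": 1,
        "byte_order": "little",
        "model_neurons": list(model.model_neurons),
        "all_neurons": list(model.all_neurons),
        "embed": {"tau": model.embed_config.tau, "n_delays": model.embed_config.n_delays},
        "smooth_sigma": model.smooth_sigma,
        "min_count": model.min_count,
        "behavior_vocab": list(model.behavior_vocab),
        "n_bins": int(model.n_bins),
        "arrays": meta_arrays,
        "config": model.config,
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(
            zipfile.ZipInfo("meta.json", date_time=_FIXED_DATE),
            json.dumps(meta, sort_keys=True, indent=1),
        )
        for name in sorted(arrays):
            zf.writestr(
                zipfile.ZipInfo(f"{name}.bin", date_time=_FIXED_DATE),
                arrays[name].tobytes(),
            )


def load_model(path) -> ManifoldModel:
    """Load a manifold archive written by :func:`save_model`."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = {}
        for name, spec in meta["arrays"].items():
            raw = zf.read(f"{name}.bin")
            arr = np.frombuffer(
                raw, dtype=np.dtype(spec["dtype"]).newbyteorder("<")
            ).reshape(spec["shape"])
            arrays[name] = arr.copy()
    n_bins = meta["n_bins"]
    bt = np.zeros((n_bins, n_bins))
    bt[
        arrays["bin_transitions_rows"], arrays["bin_transitions_cols"]
    ] = arrays["bin_transitions_vals"]
    return ManifoldModel(
        bins=BinSet(
            alpha=arrays["bins_alpha"],
            center=arrays["bins_center"],
            sd=arrays["bins_sd"],
        ),
        mean_embedded=arrays["mean_embedded"],
        mean_activity=arrays["mean_activity"],
        behavior_dist=arrays["behavior_dist"],
        behavior_vocab=list(meta["behavior_vocab"]),
        occupancy=arrays["occupancy"],
        flagged=arrays["flagged"].astype(bool),
        bin_transitions=bt,
        visited=arrays["visited"].astype(bool),
        model_neurons=list(meta["model_neurons"]),
        all_neurons=list(meta["all_neurons"]),
        embed_config=EmbedConfig(**meta["embed"]),
        smooth_sigma=meta["smooth_sigma"],
        min_count=meta["min_count"],
        theta=arrays.get("theta"),
        alpha=arrays.get("alpha"),
        assignments=arrays.get("assignments"),
        state_rec_ids=arrays.get("state_rec_ids"),
        config=meta.get("config", {}),
    )
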