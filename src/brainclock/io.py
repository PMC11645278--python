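"""Readers and writers for manifests, time series, connectivity and models."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import ContractError
from .gcn import TrainedModel
from .hoi import OmegaMatrix
from .synthetic import MANIFEST_COLUMNS, RegionTimeSeries


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False, columns=list(MANIFEST_COLUMNS))


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ContractError(f"manifest missing columns: {sorted(missing)}")
    return df


def write_timeseries_tsv(ts: RegionTimeSeries, path) -> None:
    np.savetxt(path, ts.data, delimiter="\t", fmt="%.10g")


def read_timeseries_matrix(
    path,
    fmt: str | None = None,
    subject_id: str | None = None,
    sampling_interval: float = 2.0,
    modality: str = "fMRI",
    expected_regions: int | None = None,
) -> RegionTimeSeries:
    """Load one subject's T x R matrix from TSV or HDF5."""
    path = Path(path)
    if fmt is None:
        fmt = "HDF5" if path.suffix in {".h5", ".hdf5"} else "TSV"
    if fmt == "TSV":
        df = pd.read_csv(path, sep="\t", header=None)
        for c in df.columns:
            col = pd.to_numeric(df[c], errors="coerce")
            bad = col.isna() & df[c].notna()
            if bad.any():
                r = int(bad.idxmax())
                raise ContractError(f"non-numeric cell at row {r}, column {c} in {path}")
            df[c] = col
        data = df.to_numpy(dtype=float)
        sid = subject_id or path.stem
        ts = RegionTimeSeries(sid, data, sampling_interval, modality)
    elif fmt == "HDF5":
        with h5py.File(path, "r") as f:
            if subject_id is None:
                subject_id = next(iter(f.keys()))
            grp = f[subject_id]
            ts = RegionTimeSeries(
                subject_id,
                grp["data"][()],
                float(grp.attrs.get("sampling_interval", sampling_interval)),
                str(grp.attrs.get("modality", modality)),
            )
    else:
        raise ContractError(f"unknown format {fmt!r}")
    if expected_regions is not None and ts.n_regions != expected_regions:
        raise ContractError(
            f"{path}: expected {expected_regions} regions, found {ts.n_regions}"
        )
    return ts


def write_timeseries_h5(series: dict[str, RegionTimeSeries], path) -> None:
    with h5py.File(path, "w") as f:
        for sid, ts in series.items():
            grp = f.create_group(sid)
            grp.create_dataset("data", data=ts.data)
            grp.attrs["sampling_interval"] = ts.sampling_interval
            grp.attrs["modality"] = ts.modality


def read_timeseries_h5(path) -> dict[str, RegionTimeSeries]:
    out = {}
    with h5py.File(path, "r") as f:
        for sid in f:
            out[sid] = read_timeseries_matrix(path, fmt="HDF5", subject_id=sid)
    return out


def write_omega_tsv(m: OmegaMatrix, path) -> None:
    np.savetxt(path, m.values, delimiter="\t", fmt="%.12g")


def read_omega_tsv(path, subject_id: str | None = None, normalized=False) -> OmegaMatrix:
    vals = np.loadtxt(path, delimiter="\t")
    return OmegaMatrix(subject_id or Path(path).stem, vals, normalized=normalized)


def write_model_h5(model: TrainedModel, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("W0", "b0", "W1", "b1"):
            f.create_dataset(name, data=getattr(model, name))
        f.attrs.update(
            n_regions=model.n_regions, dropout_rate=model.dropout_rate,
            learning_rate=model.learning_rate, epochs=model.epochs, seed=model.seed,
        )
        f.create_dataset("training_log", data=np.asarray(model.training_log))


def read_model_h5(path) -> TrainedModel:
    with h5py.File(path, "r") as f:
        return TrainedModel(
            W0=f["W0"][()], b0=f["b0"][()], W1=f["W1"][()], b1=f["b1"][()],
            n_regions=int(f.attrs["n_regions"]),
            dropout_rate=float(f.attrs["dropout_rate"]),
            learning_rate=float(f.attrs["learning_rate"]),
            epochs=int(f.attrs["epochs"]),
            seed=int(f.attrs["seed"]),
            training_log=list(f["training_log"][()]),
        )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
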