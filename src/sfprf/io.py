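"""HDF5/CSV persistence for apertures, simulated datasets and fit tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import FMRIDataset
from .stimulus import ApertureSequence, FieldGrid

__all__ = [
    "save_apertures",
    "load_apertures",
    "save_dataset",
    "load_dataset",
]


def save_apertures(path, apertures: ApertureSequence, meta: dict | None = None):
    """Write an aperture sequence: /frames (T×H×W uint8), /annotations."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=apertures.frames, compression="gzip")
        f.create_dataset(
            "annotations",
            data=np.array(apertures.annotations, dtype="S32"),
        )
        f.attrs["tr_s"] = apertures.tr
        f.attrs["half_extent_deg"] = apertures.grid.half_extent
        f.attrs["resolution_deg"] = apertures.grid.resolution
        for k, v in (meta or {}).items():
            f.attrs[k] = v


def load_apertures(path) -> ApertureSequence:
    with h5py.File(path, "r") as f:
        grid = FieldGrid(
            half_extent=float(f.attrs["half_extent_deg"]),
            resolution=float(f.attrs["resolution_deg"]),
        )
        return ApertureSequence(
            grid=grid,
            frames=f["frames"][()],
            annotations=[a.decode() for a in f["annotations"][()]],
            tr=float(f.attrs["tr_s"]),
        )


def save_dataset(path, dataset: FMRIDataset, meta: dict | None = None):
    """Write /bold/{vertex}/{condition} run stacks plus the /truth table."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("bold")
        for vid, conds in dataset.bold.items():
            vg = g.create_group(str(vid))
            for cond, runs in conds.items():
                vg.create_dataset(cond, data=runs, compression="gzip")
        f.attrs["tr_s"] = dataset.tr
        f.attrs["run_labels"] = ",".join(dataset.run_labels)
        truth = dataset.truth.copy()
        for col in truth.columns:  # h5py cannot store object-dtype strings
            if truth[col].dtype == object:
                truth[col] = truth[col].astype("S32")
        f.create_dataset("truth", data=truth.to_records(index=False))
        for k, v in (meta or {}).items():
            f.attrs[k] = v
    dataset.truth.to_csv(path.with_suffix(".truth.csv"), index=False)


def load_dataset(path) -> FMRIDataset:
    with h5py.File(path, "r") as f:
        truth = pd.DataFrame(f["truth"][()])
        for col in truth.columns:
            if truth[col].dtype == object or truth[col].dtype.kind == "S":
                truth[col] = truth[col].str.decode("utf-8")
        bold = {}
        for vid in f["bold"]:
            bold[int(vid)] = {
                cond: f["bold"][vid][cond][()] for cond in f["bold"][vid]
            }
        return FMRIDataset(
            truth=truth,
            bold=bold,
            populations=[],
            run_labels=str(f.attrs["run_labels"]).split(","),
            tr=float(f.attrs["tr_s"]),
        )
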