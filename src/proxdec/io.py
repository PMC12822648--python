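"""File I/O: BIDS-style events TSV, voxel-metadata TSV, NIfTI runs.

Synthetic cohorts normally stay in memory; these helpers exist for
inspection and for the real-data entry point (4D NIfTI per run plus an
events TSV and a voxel-metadata TSV).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .simulate import SubjectData, VoxelTimeSeries

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "write_voxel_meta_tsv",
    "read_voxel_meta_tsv",
    "write_run_nifti",
    "load_run",
    "export_subject",
]

EVENT_COLUMNS = ["onset", "duration", "trial_type", "congruency", "split_id"]


def write_events_tsv(events: pd.DataFrame, path) -> None:
    cols = [c for c in EVENT_COLUMNS if c in events.columns]
    events[cols].to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col, default in [("congruency", "n/a"), ("split_id", -1),
                         ("shape", "n/a"), ("background", -1),
                         ("catch", False), ("run", 0)]:
        if col not in df.columns:
            df[col] = default
    return df


def write_voxel_meta_tsv(voxel_meta: pd.DataFrame, path) -> None:
    voxel_meta.to_csv(path, sep="\t", index=False)


def read_voxel_meta_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_run_nifti(ts: VoxelTimeSeries, path) -> None:
    """Write one run as a 4D NIfTI (x, y, z, time) using the voxel grid
    coordinates from the metadata table; unoccupied grid cells are zero."""
    meta = ts.voxel_meta
    dims = (
        int(meta["x"].max()) + 1,
        int(meta["y"].max()) + 1,
        int(meta["z"].max()) + 1,
        ts.data.shape[0],
    )
    vol = np.zeros(dims, dtype=np.float32)
    vol[meta["x"], meta["y"], meta["z"], :] = ts.data.T.astype(np.float32)
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header["pixdim"][4] = ts.tr_seconds
    nib.save(img, str(path))


def load_run(nifti_path, events_path, voxel_meta_path, tr_seconds: float | None = None):
    """Real-data entry point: one 4D run + events TSV + voxel metadata TSV.

    The metadata's grid coordinates select the voxels (in table order) from
    the volume.  Returns ``(VoxelTimeSeries, events)``.
    """
    img = nib.load(str(nifti_path))
    meta = read_voxel_meta_tsv(voxel_meta_path)
    data4d = np.asarray(img.dataobj)
    data = data4d[meta["x"], meta["y"], meta["z"], :].T.astype(float)
    if tr_seconds is None:
        tr_seconds = float(img.header["pixdim"][4]) or 1.0
    ts = VoxelTimeSeries(data=data, tr_seconds=tr_seconds, voxel_meta=meta)
    return ts, read_events_tsv(events_path)


def write_map_nifti(values: np.ndarray, voxel_meta: pd.DataFrame, path) -> None:
    """Write a per-voxel statistic or correlation map as a 3D NIfTI volume
    on the metadata grid (unoccupied cells are zero)."""
    dims = (int(voxel_meta["x"].max()) + 1, int(voxel_meta["y"].max()) + 1,
            int(voxel_meta["z"].max()) + 1)
    vol = np.zeros(dims, dtype=np.float32)
    vol[voxel_meta["x"], voxel_meta["y"], voxel_meta["z"]] = np.asarray(
        values, dtype=np.float32)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def export_subject(sd: SubjectData, out_dir, nifti: bool = False) -> None:
    """Write one simulated subject's runs as events TSVs (and optionally
    NIfTI volumes) under ``out_dir/<subject>/``."""
    base = Path(out_dir) / sd.subject
    base.mkdir(parents=True, exist_ok=True)
    write_voxel_meta_tsv(sd.voxel_meta, base / "voxel_meta.tsv")
    for kind, events, runs in [
        ("main", sd.design.main_runs, sd.main_runs),
        ("training", sd.design.training_runs, sd.training_runs),
        ("localizer", sd.design.localizer_runs, sd.localizer_runs),
    ]:
        for i, (ev, ts) in enumerate(zip(events, runs)):
            write_events_tsv(ev, base / f"task-{kind}_run-{i:02d}_events.tsv")
            if nifti:
                write_run_nifti(ts, base / f"task-{kind}_run-{i:02d}_bold.nii.gz")
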