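"""NIfTI-1 and events-table input/output."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BoldRun, VolumeGrid

EVENT_COLUMNS = ("onset", "duration", "trial_type")


def _grid_from_img(img, path) -> VolumeGrid:
    try:
        return VolumeGrid.from_affine(img.affine, img.shape[:3])
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def read_volume(path):
    """Read a 3D NIfTI volume; returns ``(data, grid)``."""
    path = Path(path)
    img = nib.load(path)
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {len(img.shape)}D")
    return np.asarray(img.get_fdata()), _grid_from_img(img, path)


def write_volume(data, grid: VolumeGrid, path) -> Path:
    """Write a 3D volume as NIfTI-1 with the grid's affine."""
    data = np.asarray(data)
    if data.shape != tuple(grid.shape):
        raise ValueError(f"data shape {data.shape} does not match grid {grid.shape}")
    path = Path(path)
    nib.save(nib.Nifti1Image(data.astype(np.float64), grid.affine), path)
    return path


def read_bold(path, tr: float | None = None) -> BoldRun:
    """Read a 4D NIfTI acquisition as a :class:`BoldRun`.

    The repetition time is taken from the NIfTI header unless overridden.
    """
    path = Path(path)
    img = nib.load(path)
    if len(img.shape) != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {len(img.shape)}D")
    grid = _grid_from_img(img, path)
    if tr is None:
        tr = float(img.header.get_zooms()[3])
        if tr <= 0:
            raise ValueError(f"{path}: no repetition time in the header; pass tr=")
    return BoldRun(grid=grid, tr=tr, data=np.asarray(img.get_fdata()))


def write_bold(run: BoldRun, path) -> Path:
    """Write a :class:`BoldRun` as 4D NIfTI-1 (TR recorded in the header)."""
    path = Path(path)
    img = nib.Nifti1Image(run.data.astype(np.float64), run.grid.affine)
    img.header.set_zooms((*run.grid.voxel_size, run.tr))
    nib.save(img, path)
    return path


def write_atlas(labels, grid: VolumeGrid, path) -> Path:
    """Write an integer label volume as NIfTI-1."""
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(labels).astype(np.int16), grid.affine), path)
    return path


def write_events(events: pd.DataFrame, path) -> Path:
    """Write a design table as tab-separated BIDS-style events."""
    missing = [c for c in (*EVENT_COLUMNS, "run") if c not in events.columns]
    if missing:
        raise ValueError(f"events table is missing columns {missing}")
    path = Path(path)
    events[["onset", "duration", "trial_type", "run"]].to_csv(path, sep="\t", index=False)
    return path


def read_events(path, conditions=None) -> pd.DataFrame:
    """Read and validate a tab-separated events table.

    The table needs columns ``onset, duration, trial_type`` (plus ``run``;
    a missing run column is treated as a single run 0). Rows are
    canonicalized (sorted by run, then onset). Overlapping blocks, negative
    onsets, and — when ``conditions`` is given — unknown condition labels are
    rejected with the offending row number.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "run" not in table.columns:
        table["run"] = 0
    for i, row in table.iterrows():
        if row["onset"] < 0:
            raise ValueError(f"{path}: negative onset at row {i}")
        if row["duration"] <= 0:
            raise ValueError(f"{path}: non-positive duration at row {i}")
        if conditions is not None and row["trial_type"] not in conditions:
            raise ValueError(
                f"{path}: unknown condition {row['trial_type']!r} at row {i}"
            )
    table = table.sort_values(["run", "onset"], ignore_index=True)
    for run_id, sub in table.groupby("run"):
        ends = (sub["onset"] + sub["duration"]).to_numpy()
        onsets = sub["onset"].to_numpy()
        overlap = np.nonzero(onsets[1:] < ends[:-1] - 1e-9)[0]
        if overlap.size:
            i = sub.index[overlap[0] + 1]
            raise ValueError(f"{path}: overlapping blocks in run {run_id} at row {i}")
    return table
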