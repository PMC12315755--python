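"""File I/O for the formats the pipeline touches.

NIfTI for volumes (via nibabel), TSV for tabular sidecars (motion
parameters, task events, eye-closure logs), JSON for configuration.  All
loaders validate against the session grid when one is supplied; nothing is
ever resampled.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BoldSeries, LabeledVolume, SiteConfig, VolumeGrid

__all__ = [
    "grid_from_nifti",
    "save_volume",
    "load_volume",
    "save_bold",
    "load_bold",
    "save_labeled_volume",
    "load_labeled_volume",
    "read_motion_tsv",
    "write_motion_tsv",
    "read_events_tsv",
    "write_events_tsv",
    "read_eye_closures_tsv",
    "write_eye_closures_tsv",
    "site_config_to_json",
    "site_config_from_json",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
EVENT_COLUMNS = ["onset", "duration", "trial_type"]
EYE_COLUMNS = ["onset", "duration"]


def grid_from_nifti(img: nib.Nifti1Image) -> VolumeGrid:
    shape = tuple(int(s) for s in img.shape[:3])
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(shape=shape, voxel_size_mm=zooms)


def save_volume(path, data: np.ndarray, grid: VolumeGrid) -> None:
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    img.header.set_zooms(grid.voxel_size_mm + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def load_volume(path, grid: VolumeGrid | None = None) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    file_grid = grid_from_nifti(img)
    if grid is not None:
        grid.check_same(file_grid, str(path))
    return np.asanyarray(img.dataobj), file_grid


def save_bold(path, bold: BoldSeries) -> None:
    save_volume(path, bold.data, bold.grid)


def load_bold(
    path,
    tr_s: float,
    kind: str,
    timestamps_s: np.ndarray | None = None,
    site: SiteConfig | None = None,
    grid: VolumeGrid | None = None,
) -> BoldSeries:
    data, file_grid = load_volume(path, grid)
    if timestamps_s is None:
        timestamps_s = np.arange(data.shape[3]) * tr_s
    return BoldSeries(
        grid=file_grid, data=data, tr_s=tr_s, timestamps_s=timestamps_s, kind=kind, site=site
    )


def save_labeled_volume(path, labeled: LabeledVolume, label_map_path=None) -> None:
    save_volume(path, labeled.labels.astype(np.int16), labeled.grid)
    if label_map_path is not None:
        Path(label_map_path).write_text(json.dumps(labeled.label_map, indent=1))


def load_labeled_volume(path, label_map: dict[str, int], grid: VolumeGrid | None = None) -> LabeledVolume:
    """Load and validate an integer segmentation volume.

    Raises if voxel values are not integers, if the grid disagrees with the
    session grid, or if any required label is absent (the error names the
    first missing label).
    """
    data, file_grid = load_volume(path, grid)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path}: segmentation voxels are not integer-valued")
        data = rounded.astype(np.int32)
    labeled = LabeledVolume(grid=file_grid, labels=data, label_map=dict(label_map))
    missing = labeled.validate_required()
    if missing:
        raise ValueError(f"{path}: missing required label(s): {', '.join(missing)}")
    return labeled


# ---------------------------------------------------------------------------
# TSV sidecars


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing TSV column(s): {', '.join(missing)}")
    return df[columns]


def _write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_motion_tsv(path) -> pd.DataFrame:
    """Six motion parameters per volume; rotations are in radians."""
    return _read_tsv(path, MOTION_COLUMNS)


def write_motion_tsv(path, motion: pd.DataFrame) -> None:
    _write_tsv(path, motion[MOTION_COLUMNS])


def read_events_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path, EVENT_COLUMNS)
    return df.astype({"onset": float, "duration": float})


def write_events_tsv(path, events: pd.DataFrame) -> None:
    _write_tsv(path, events[EVENT_COLUMNS])


def read_eye_closures_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, EYE_COLUMNS)


def write_eye_closures_tsv(path, closures: pd.DataFrame) -> None:
    _write_tsv(path, closures[EYE_COLUMNS])


# ---------------------------------------------------------------------------
# JSON config


def site_config_to_json(path, site: SiteConfig) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(site), indent=1))


def site_config_from_json(path) -> SiteConfig:
    return SiteConfig(**json.loads(Path(path).read_text()))
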