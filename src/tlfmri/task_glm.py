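"""Sparse-acquisition GLM: design matrix, per-voxel OLS, A-V contrast.

One design matrix per run: intercept, unconvolved auditory and visual
indicators (no HRF — sparse sampling precludes a time-series HRF model),
6 motion parameters and their squares, WM and CSF compartment signals, and
two indicators for the 2nd and 3rd volume of every acquisition cluster
that absorb T1-relaxation (non-steady-state) effects.  Runs are fit
independently and the Auditory - Visual contrast averaged across runs;
the block design makes this identical to a joint block-diagonal fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BoldSeries, VolumeGrid
from .schedule import AUDITORY, VISUAL, TrialSchedule

__all__ = ["DesignMatrix", "GlmFit", "ContrastMap", "build_design", "fit_glm",
           "contrast_auditory_minus_visual"]

MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_columns)
    column_names: list[str]
    dropped_columns: list[str] = field(default_factory=list)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.column_names.index(name)]

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.column_names)


@dataclass
class GlmFit:
    betas: np.ndarray  # (x, y, z, n_columns)
    column_names: list[str]
    resid_var: np.ndarray  # (x, y, z)

    def beta(self, name: str) -> np.ndarray:
        return self.betas[..., self.column_names.index(name)]


@dataclass
class ContrastMap:
    grid: VolumeGrid
    values: np.ndarray
    runs_used: int


def build_design(
    schedule: TrialSchedule,
    motion: pd.DataFrame | None,
    wm: np.ndarray | None,
    csf: np.ndarray | None,
) -> DesignMatrix:
    """Assemble the 19-column design for one run.

    Task and cluster-position columns are {0,1} indicators; nuisance
    columns (motion, squared motion, WM, CSF) are mean-centered so the
    intercept carries baseline.  Nuisance columns that are constant (e.g.
    all-zero motion) are dropped with a warning; the task, intercept and
    cluster-position columns are never dropped.
    """
    n = schedule.n_volumes
    cols: list[tuple[str, np.ndarray, bool]] = [("intercept", np.ones(n), False)]
    cols.append(("auditory", schedule.condition_indicator(AUDITORY), False))
    cols.append(("visual", schedule.condition_indicator(VISUAL), False))
    if motion is not None:
        if len(motion) != n:
            raise ValueError(f"motion table has {len(motion)} rows for {n} volumes")
        for c in MOTION_COLS:
            cols.append((c, motion[c].to_numpy(dtype=float), True))
        for c in MOTION_COLS:
            cols.append((f"{c}_sq", motion[c].to_numpy(dtype=float) ** 2, True))
    for name, sig in [("wm", wm), ("csf", csf)]:
        if sig is not None:
            sig = np.asarray(sig, dtype=float)
            if sig.shape != (n,):
                raise ValueError(f"{name} signal length {sig.shape} != {n} volumes")
            cols.append((name, sig, True))
    for pos in range(1, schedule.site.n_cluster_vols):
        cols.append((f"cluster_vol{pos + 1}", schedule.cluster_position_indicator(pos), False))

    names, arrays, dropped = [], [], []
    for name, arr, is_nuisance in cols:
        if is_nuisance:
            arr = arr - arr.mean()
            if np.max(np.abs(arr)) < 1e-12:
                dropped.append(name)
                continue
        names.append(name)
        arrays.append(arr)
    if dropped:
        warnings.warn(f"dropping degenerate design column(s): {', '.join(dropped)}")
    return DesignMatrix(matrix=np.column_stack(arrays), column_names=names, dropped_columns=dropped)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # columns whose removal restores full rank, reported for the error message
    bad = []
    base_rank = np.linalg.matrix_rank(X)
    for i, name in enumerate(names):
        reduced = np.delete(X, i, axis=1)
        if np.linalg.matrix_rank(reduced) == base_rank:
            bad.append(name)
    return bad


def fit_glm(bold: BoldSeries, design: DesignMatrix) -> GlmFit:
    """Per-voxel ordinary least squares on (smoothed) task data."""
    X = design.matrix
    n, p = X.shape
    if bold.n_volumes != n:
        raise ValueError(f"BOLD has {bold.n_volumes} volumes, design has {n} rows")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(_collinear_columns(X, design.column_names))
        )
    Y = bold.data.reshape(-1, n).T.astype(np.float64)  # (n, n_vox)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = max(n - p, 1)
    resid_var = (resid**2).sum(axis=0) / dof
    shape = bold.grid.shape
    return GlmFit(
        betas=beta.T.reshape(shape + (p,)),
        column_names=list(design.column_names),
        resid_var=resid_var.reshape(shape),
    )


def contrast_auditory_minus_visual(fits: list[GlmFit], grid: VolumeGrid) -> ContrastMap:
    """Voxelwise mean over runs of (beta_auditory - beta_visual).

    At least two usable runs are required for a participant-level
    contrast; fewer is a participant-level QC failure.
    """
    if len(fits) < 2:
        raise ValueError(f"contrast requires at least 2 runs, got {len(fits)}")
    maps = [f.beta("auditory") - f.beta("visual") for f in fits]
    return ContrastMap(grid=grid, values=np.mean(maps, axis=0), runs_used=len(fits))
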