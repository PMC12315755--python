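"""Coactivation-based extraction of MGN and LGN functional ROIs.

Within each thalamic search region, every voxel's (smoothed) task series
is partially correlated with the auditory- and visual-cortex reference
series, controlling compartment nuisance signals and the cluster-position
indicators.  The two coactivation maps are rank thresholded with a
size-adaptive fraction (32 / mean MGN-TSR voxels, 20 / mean LGN-TSR
voxels — deliberately arbitrary constants chosen to yield reasonably
sized fROIs, exposed in configuration), voxels surviving in both maps are
deleted from both, and the largest remaining contiguous cluster of the
modality-appropriate map becomes the fROI.  Advisory anatomical-
plausibility flags stand in for manual review.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BoldSeries, LabeledVolume, compartment_signal, dilate, erode, label_components
from .search_region import ThalamicSearchRegion

__all__ = [
    "FroiSet",
    "CoactivationResult",
    "partial_correlation",
    "residualize",
    "local_wm_series",
    "coactivation_nuisance",
    "coactivation_maps",
    "threshold_and_exclude",
    "largest_cluster",
    "qc_flags",
]

#: size-adaptive threshold numerators (target voxel counts per hemisphere)
THRESHOLD_TARGET = {"mgn": 32, "lgn": 20}


@dataclass
class FroiSet:
    """Left/right MGN and LGN binary masks plus QC flags."""

    mgn_L: np.ndarray
    mgn_R: np.ndarray
    lgn_L: np.ndarray
    lgn_R: np.ndarray
    qc: list[str] = field(default_factory=list)

    def mask(self, nucleus: str, hemisphere: str) -> np.ndarray:
        return getattr(self, f"{nucleus}_{hemisphere}")

    @property
    def sizes(self) -> dict[str, int]:
        return {
            name: int(getattr(self, name).sum())
            for name in ("mgn_L", "mgn_R", "lgn_L", "lgn_R")
        }


@dataclass
class CoactivationResult:
    tsr: ThalamicSearchRegion
    r_ac: np.ndarray  # 3D, NaN outside the TSR / at excluded voxels
    r_vc: np.ndarray
    kept_ac: np.ndarray | None = None
    kept_vc: np.ndarray | None = None
    threshold_fraction: float | None = None


# ---------------------------------------------------------------------------
# partial correlation


def residualize(y: np.ndarray, nuisance: np.ndarray | None) -> np.ndarray:
    """Residuals of columns of ``y`` after OLS on [1, nuisance]."""
    y = np.asarray(y, dtype=float)
    one_d = y.ndim == 1
    Y = y[:, None] if one_d else y
    n = Y.shape[0]
    Z = np.ones((n, 1))
    if nuisance is not None and np.size(nuisance):
        nuis = np.asarray(nuisance, dtype=float)
        if nuis.ndim == 1:
            nuis = nuis[:, None]
        Z = np.column_stack([Z, nuis])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("nuisance matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(Z, Y, rcond=None)
    resid = Y - Z @ beta
    return resid[:, 0] if one_d else resid


def partial_correlation(x: np.ndarray, y: np.ndarray, nuisance: np.ndarray | None = None) -> float:
    """Pearson correlation of x and y after projecting out [1, nuisance]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p = 0 if nuisance is None else (1 if np.ndim(nuisance) == 1 else np.shape(nuisance)[1])
    if x.shape[0] < p + 3:
        raise ValueError(f"need at least {p + 3} samples for {p} nuisance columns")
    rx = residualize(x, nuisance)
    ry = residualize(y, nuisance)
    sx = np.sqrt((rx**2).sum())
    sy = np.sqrt((ry**2).sum())
    if sx < 1e-12 * max(1.0, np.abs(x).max()) or sy < 1e-12 * max(1.0, np.abs(y).max()):
        raise ValueError("zero residual variance: signal is degenerate given the nuisance set")
    return float(np.clip((rx * ry).sum() / (sx * sy), -1.0, 1.0))


# ---------------------------------------------------------------------------
# nuisance bundle


def local_wm_series(
    bold: BoldSeries,
    labels: LabeledVolume,
    tsr_mask: np.ndarray,
    min_dist: int = 1,
    max_dist: int = 5,
    connectivity: int = 26,
) -> np.ndarray:
    """Mean unsmoothed series of WM between 1 and 5 voxels of the TSR.

    Distance is counted in iterative dilations.  An empty shell falls back
    to the global eroded-WM signal with a warning.
    """
    wm = labels.mask("white_matter")
    shell = dilate(tsr_mask, max_dist, connectivity=connectivity) & ~dilate(
        tsr_mask, min_dist - 1, connectivity=connectivity
    )
    sel = shell & wm
    if not sel.any():
        warnings.warn("no WM within 1-5 voxels of TSR; falling back to global WM signal")
        return compartment_signal(bold, labels, "white_matter")
    return bold.data[sel].mean(axis=0)


def coactivation_nuisance(
    bold_unsmoothed: BoldSeries,
    labels: LabeledVolume,
    tsr_mask: np.ndarray,
    cluster_vol2: np.ndarray,
    cluster_vol3: np.ndarray,
) -> np.ndarray:
    """Nuisance matrix for the coactivation partial correlations: WM, CSF,
    global gray matter (eroded-by-one GM, unsmoothed data), local WM, and
    the cluster-position indicators."""
    from .core import GRAY_MATTER_LABELS

    wm = compartment_signal(bold_unsmoothed, labels, "white_matter")
    csf = compartment_signal(bold_unsmoothed, labels, "csf")
    gm_mask = labels.union_mask(GRAY_MATTER_LABELS)
    gm_eroded = erode(gm_mask, 1)
    if not gm_eroded.any():
        warnings.warn("gray-matter mask vanished under erosion; using uneroded GM")
        gm_eroded = gm_mask
    gm = bold_unsmoothed.data[gm_eroded].mean(axis=0)
    lwm = local_wm_series(bold_unsmoothed, labels, tsr_mask)
    return np.column_stack([wm, csf, gm, lwm, cluster_vol2, cluster_vol3])


# ---------------------------------------------------------------------------
# coactivation maps


def _partial_corr_map(Y: np.ndarray, ref: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Partial correlation of each column of Y with ref; NaN where a
    voxel's residual variance vanishes."""
    Ry = residualize(Y, nuisance)
    rr = residualize(ref, nuisance)
    sr = np.sqrt((rr**2).sum())
    if sr < 1e-12 * max(1.0, np.abs(ref).max()):
        raise ValueError("reference series degenerate given the nuisance set")
    sy = np.sqrt((Ry**2).sum(axis=0))
    scale = np.abs(Y).max(axis=0)
    bad = sy < 1e-12 * np.maximum(1.0, scale)
    sy_safe = np.where(bad, 1.0, sy)
    r = (Ry * rr[:, None]).sum(axis=0) / (sy_safe * sr)
    r = np.clip(r, -1.0, 1.0)
    r[bad] = np.nan
    return r


def coactivation_maps(
    bold_smoothed: BoldSeries,
    tsr: ThalamicSearchRegion,
    ac_series: np.ndarray,
    vc_series: np.ndarray,
    nuisance: np.ndarray,
) -> CoactivationResult:
    """Per-voxel partial correlation of TSR series with the AC and VC
    references; degenerate voxels are excluded (NaN) with a warning."""
    Y = bold_smoothed.data[tsr.mask].T.astype(float)  # (t, n_vox)
    r_ac_v = _partial_corr_map(Y, ac_series, nuisance)
    r_vc_v = _partial_corr_map(Y, vc_series, nuisance)
    n_bad = int(np.isnan(r_ac_v).sum() + np.isnan(r_vc_v).sum())
    if n_bad:
        warnings.warn(f"{n_bad} degenerate TSR voxel correlations excluded")
    shape = tsr.mask.shape
    r_ac = np.full(shape, np.nan)
    r_vc = np.full(shape, np.nan)
    r_ac[tsr.mask] = r_ac_v
    r_vc[tsr.mask] = r_vc_v
    return CoactivationResult(tsr=tsr, r_ac=r_ac, r_vc=r_vc)


def _keep_top(r_map: np.ndarray, tsr_mask: np.ndarray, k: int) -> np.ndarray:
    vals = r_map[tsr_mask]
    finite = np.isfinite(vals)
    if k <= 0 or not finite.any():
        return np.zeros_like(tsr_mask)
    order = np.sort(vals[finite])[::-1]
    cut = order[min(k, order.size) - 1]
    keep = np.zeros_like(tsr_mask)
    keep[tsr_mask] = finite & (vals >= cut)
    return keep


def threshold_and_exclude(
    result: CoactivationResult,
    nucleus: str,
    mean_tsr_size: float,
    target: int | None = None,
) -> CoactivationResult:
    """Apply the size-adaptive rank threshold, then dual-map exclusion.

    The retained fraction is target / mean TSR size across hemispheres
    (capped at 1), and ceil(fraction * N) voxels are kept per map with
    boundary ties included.  Voxels kept in both the AC and VC maps are
    then removed from both to enforce modality specificity.
    """
    k_target = THRESHOLD_TARGET[nucleus] if target is None else target
    frac = min(1.0, k_target / mean_tsr_size)
    n = result.tsr.size
    k = int(np.ceil(frac * n))
    kept_ac = _keep_top(result.r_ac, result.tsr.mask, k)
    kept_vc = _keep_top(result.r_vc, result.tsr.mask, k)
    both = kept_ac & kept_vc
    result.kept_ac = kept_ac & ~both
    result.kept_vc = kept_vc & ~both
    result.threshold_fraction = frac
    return result


# ---------------------------------------------------------------------------
# cluster extraction and QC


def largest_cluster(mask: np.ndarray, tie_r_map: np.ndarray | None = None, connectivity: int = 26) -> np.ndarray:
    """Largest 26-connected component; ties broken by higher peak value in
    ``tie_r_map``, then by lexicographically smallest peak index."""
    if not mask.any():
        raise ValueError("no voxels survive thresholding (fROI failure, participant QC)")
    comp, n = label_components(mask, connectivity=connectivity)
    r = tie_r_map if tie_r_map is not None else np.zeros(mask.shape)
    best = None
    for cid in range(1, n + 1):
        cmask = comp == cid
        vals = np.where(cmask & np.isfinite(r), r, -np.inf)
        peak_flat = int(np.argmax(vals))
        key = (int(cmask.sum()), vals.ravel()[peak_flat], -peak_flat)
        if best is None or key > best[0]:
            best = (key, cmask)
    return best[1]


def _centroid(mask: np.ndarray) -> np.ndarray:
    return np.array(np.nonzero(mask), dtype=float).mean(axis=1)


def qc_flags(froi: FroiSet, asymmetry_log_ratio: float = np.log(3.0)) -> list[str]:
    """Advisory anatomical-plausibility flags.

    LGN_INFERIOR: LGN centroid below MGN centroid in the same hemisphere.
    LGN_MEDIAL: LGN centroid closer to the midline than MGN.
    ASYMMETRY: |ln(left size / right size)| exceeds ln 3 for a nucleus.
    FAILED_<mask>: a mask is missing or empty.  Exclusion is the caller's
    decision; the flags mirror criteria a human reviewer would apply.
    """
    flags: list[str] = []
    masks = {}
    for name in ("mgn_L", "mgn_R", "lgn_L", "lgn_R"):
        m = getattr(froi, name)
        if m is None or not np.asarray(m).any():
            flags.append(f"FAILED_{name}")
        else:
            masks[name] = np.asarray(m)
    if flags:
        return flags
    midline = (masks["mgn_L"].shape[0] - 1) / 2.0
    for hemi in ("L", "R"):
        c_mgn = _centroid(masks[f"mgn_{hemi}"])
        c_lgn = _centroid(masks[f"lgn_{hemi}"])
        if c_lgn[2] < c_mgn[2]:
            flags.append(f"LGN_INFERIOR_{hemi}")
        if abs(c_lgn[0] - midline) < abs(c_mgn[0] - midline):
            flags.append(f"LGN_MEDIAL_{hemi}")
    for nucleus in ("mgn", "lgn"):
        sl = masks[f"{nucleus}_L"].sum()
        sr = masks[f"{nucleus}_R"].sum()
        if abs(np.log(sl / sr)) > asymmetry_log_ratio:
            flags.append(f"ASYMMETRY_{nucleus.upper()}")
    return flags
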