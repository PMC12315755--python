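"""Selection of auditory- and visual-cortex clusters from the contrast map.

Per hemisphere, the search mask (Brodmann-area union dilated once) is rank
thresholded to its most extreme 10% of Auditory - Visual contrast values
(top tail for auditory cortex, bottom for visual), components smaller than
10 voxels are discarded, and the surviving component holding the greatest
|contrast| peak becomes the cluster from which the reference time series
is read: spatial mean per hemisphere, then the unweighted mean of the two
hemispheric series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BoldSeries, LabeledVolume, dilate, label_components
from .task_glm import ContrastMap

__all__ = [
    "CortexCluster",
    "make_cortex_search_mask",
    "select_cortex_cluster",
    "reference_series",
    "apriori_ac_vc_rois",
]

_MODALITY_LABELS = {"auditory": "ba41_42", "visual": "ba17_18"}


@dataclass
class CortexCluster:
    hemisphere: str  # "L" | "R"
    modality: str  # "auditory" | "visual"
    mask: np.ndarray
    peak_value: float
    size: int


def make_cortex_search_mask(
    labels: LabeledVolume, modality: str, connectivity: int = 26
) -> dict[str, np.ndarray]:
    """Per-hemisphere search masks: BA 41/42 (auditory) or BA 17/18
    (visual), dilated once in 3D and kept inside the brain."""
    if modality not in _MODALITY_LABELS:
        raise ValueError(f"modality must be 'auditory' or 'visual', got {modality!r}")
    base = _MODALITY_LABELS[modality]
    out = {}
    brain = labels.brain_mask
    for hemi in ("L", "R"):
        raw = labels.mask(f"{base}_{hemi}")
        if not raw.any():
            raise ValueError(f"empty cortex search region: {base}_{hemi}")
        out[hemi] = dilate(raw, 1, connectivity=connectivity) & brain
    return out


def _rank_threshold(values: np.ndarray, k: int, tail: str) -> np.ndarray:
    """Boolean keep-vector for the k most extreme values, ties included."""
    if tail == "top":
        cut = np.sort(values)[::-1][k - 1]
        return values >= cut
    if tail == "bottom":
        cut = np.sort(values)[k - 1]
        return values <= cut
    raise ValueError(f"tail must be 'top' or 'bottom', got {tail!r}")


def _peak_component(
    surviving: np.ndarray, comp_labels: np.ndarray, comp_ids: list[int], magnitude: np.ndarray
):
    """Pick the component with the greatest |peak|; ties -> larger
    component, then lexicographically smallest peak index."""
    best = None
    for cid in comp_ids:
        cmask = comp_labels == cid
        vals = np.where(cmask, magnitude, -np.inf)
        peak_flat = int(np.argmax(vals))
        peak = vals.ravel()[peak_flat]
        key = (peak, int(cmask.sum()), -peak_flat)
        if best is None or key > best[0]:
            best = (key, cmask, np.unravel_index(peak_flat, magnitude.shape))
    return best[1], best[2]


def select_cortex_cluster(
    contrast: ContrastMap,
    mask: np.ndarray,
    tail: str,
    hemisphere: str = "?",
    modality: str = "?",
    pct: float = 10.0,
    min_size: int = 10,
    connectivity: int = 26,
) -> CortexCluster:
    """Rank-threshold the contrast inside the search mask and return the
    surviving component with the greatest-magnitude peak.

    Exactly ceil(pct% * N) voxels are retained (boundary ties included);
    components below ``min_size`` are removed.  No surviving component is
    a participant-level QC failure and raises.
    """
    if not mask.any():
        raise ValueError("empty cortex search mask")
    values = contrast.values[mask]
    k = int(np.ceil(pct / 100.0 * values.size))
    keep_flat = _rank_threshold(values, k, tail)
    keep = np.zeros_like(mask)
    keep[mask] = keep_flat

    comp_labels, n_comp = label_components(keep, connectivity=connectivity)
    sizes = ndimage.sum_labels(keep, comp_labels, index=np.arange(1, n_comp + 1))
    survivors = [i + 1 for i, s in enumerate(sizes) if s >= min_size]
    if not survivors:
        raise ValueError(
            f"no {modality} cortex cluster of >= {min_size} voxels survives in "
            f"hemisphere {hemisphere} (participant-level QC failure)"
        )
    magnitude = np.abs(np.where(keep, contrast.values, 0.0))
    cmask, peak_idx = _peak_component(keep, comp_labels, survivors, magnitude)
    return CortexCluster(
        hemisphere=hemisphere,
        modality=modality,
        mask=cmask,
        peak_value=float(contrast.values[peak_idx]),
        size=int(cmask.sum()),
    )


def reference_series(
    bold: BoldSeries, cluster_L: CortexCluster, cluster_R: CortexCluster
) -> np.ndarray:
    """Cortical reference series: per-hemisphere spatial mean, then the
    unweighted mean of the two hemispheric series."""
    for cl in (cluster_L, cluster_R):
        if cl is None or not cl.mask.any():
            raise ValueError("both hemispheric clusters are required (QC failure)")
    left = bold.data[cluster_L.mask].mean(axis=0)
    right = bold.data[cluster_R.mask].mean(axis=0)
    return (left + right) / 2.0


def apriori_ac_vc_rois(labels: LabeledVolume, connectivity: int = 26) -> dict[str, np.ndarray]:
    """Anatomy-derived primary AC/VC ROIs, independent of the localizer.

    AC: transverse temporal gyrus dilated once.  VC: pericalcarine dilated
    once, restricted to gray matter, then dilated two more.  Keys are
    ``ac_L/ac_R/vc_L/vc_R``.
    """
    from .core import GRAY_MATTER_LABELS

    gm = labels.union_mask(GRAY_MATTER_LABELS)
    brain = labels.brain_mask
    out = {}
    for hemi in ("L", "R"):
        out[f"ac_{hemi}"] = dilate(labels.mask(f"transverse_temporal_{hemi}"), 1, connectivity) & brain
        vc = dilate(labels.mask(f"pericalcarine_{hemi}"), 1, connectivity) & gm
        out[f"vc_{hemi}"] = dilate(vc, 2, connectivity) & brain
    return out
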