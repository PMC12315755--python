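"""Shared domain types and low-level spatial operations.

Everything in one analysis lives on a single voxel grid in RAS orientation
(x: left->right, y: posterior->anterior, z: inferior->superior).  The
pipeline never resamples: images on a different grid are rejected, because
all mask algebra (dilation, erosion, slice trimming) is defined in voxel
units of the analysis grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "SiteConfig",
    "NYSPI",
    "SBU",
    "LabeledVolume",
    "BoldSeries",
    "REQUIRED_LABELS",
    "GRAY_MATTER_LABELS",
    "connectivity_structure",
    "dilate",
    "erode",
    "label_components",
    "fwhm_to_sigma",
    "smooth_gaussian",
    "compartment_signal",
]


# ---------------------------------------------------------------------------
# grids and site configuration


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel grid shared by every image in one analysis.

    Axis convention is fixed RAS: index 0 runs left->right, index 1
    posterior->anterior, index 2 inferior->superior.  ``voxel_size_mm``
    defaults to the 2 mm isotropic analysis resolution.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        """RAS affine with the grid origin at voxel (0,0,0)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff

    def check_same(self, other: "VolumeGrid", what: str = "image") -> None:
        if self.shape != other.shape or not np.allclose(self.voxel_size_mm, other.voxel_size_mm):
            raise ValueError(
                f"{what} grid {other.shape}@{other.voxel_size_mm} does not match "
                f"session grid {self.shape}@{self.voxel_size_mm}; the pipeline does not resample"
            )


@dataclass(frozen=True)
class SiteConfig:
    """Acquisition parameters of one scanning site.

    ``trial_dur_s`` must leave a non-negative gap once stimulation and the
    acquisition cluster are accounted for; the per-side gap itself is
    derived by :func:`tlfmri.schedule.calibrate_gap`.
    """

    name: str
    tr_s: float
    n_cluster_vols: int = 3
    stim_dur_s: float = 9.0
    trial_dur_s: float = 12.0
    n_aud_trials: int = 8
    n_vis_trials: int = 8
    fwhm_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")
        if self.trial_dur_s < self.stim_dur_s + self.n_cluster_vols * self.tr_s - 1e-9:
            raise ValueError(
                f"site {self.name!r}: trial duration {self.trial_dur_s} s cannot fit "
                f"{self.stim_dur_s} s stimulation plus a {self.n_cluster_vols}-volume cluster"
            )


#: Site presets used throughout: 3T scanners differing only in TR.
NYSPI = SiteConfig(name="nyspi", tr_s=0.85)
SBU = SiteConfig(name="sbu", tr_s=0.80)


# ---------------------------------------------------------------------------
# labeled anatomy

#: Label names every segmentation volume entering the pipeline must provide.
REQUIRED_LABELS: tuple[str, ...] = (
    "mgn_seed_L", "mgn_seed_R",
    "lgn_seed_L", "lgn_seed_R",
    "pulvinar_L", "pulvinar_R",
    "mediodorsal_L", "mediodorsal_R",
    "ba41_42_L", "ba41_42_R",
    "ba17_18_L", "ba17_18_R",
    "transverse_temporal_L", "transverse_temporal_R",
    "pericalcarine_L", "pericalcarine_R",
    "cortical_gm",
    "white_matter",
    "csf",
    "choroid_plexus",
    "putamen",
    "pallidum",
    "hippocampus",
    "parahippocampal_wm",
    "insular_wm",
    "brain",
)

#: Labels treated as cortical gray matter when a whole-GM mask is needed
#: (global gray-matter nuisance signal, a-priori VC construction).
GRAY_MATTER_LABELS: tuple[str, ...] = (
    "cortical_gm",
    "ba41_42_L", "ba41_42_R",
    "ba17_18_L", "ba17_18_R",
    "transverse_temporal_L", "transverse_temporal_R",
    "pericalcarine_L", "pericalcarine_R",
)


@dataclass
class LabeledVolume:
    """Integer-labeled segmentation on the analysis grid.

    One integer per voxel (0 = background / outside brain).  ``brain``
    labels intracranial voxels not claimed by any specific structure, so
    ``mask("brain")`` returns *all* labeled voxels.
    """

    grid: VolumeGrid
    labels: np.ndarray
    label_map: dict[str, int]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError(
                f"label array shape {self.labels.shape} does not match grid {self.grid.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-valued")
        if 0 in self.label_map.values():
            raise ValueError("label value 0 is reserved for background")

    def validate_required(self) -> list[str]:
        """Return required label names missing from the map or empty in the image."""
        present = set(np.unique(self.labels))
        missing = []
        for name in REQUIRED_LABELS:
            if name not in self.label_map or self.label_map[name] not in present:
                missing.append(name)
        return missing

    def mask(self, name: str) -> np.ndarray:
        """Binary mask of one named structure (``brain`` = every labeled voxel)."""
        if name == "brain":
            return self.labels != 0
        if name not in self.label_map:
            raise KeyError(f"label {name!r} not in label map")
        return self.labels == self.label_map[name]

    def union_mask(self, names) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        for name in names:
            out |= self.mask(name)
        return out

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != 0


# ---------------------------------------------------------------------------
# BOLD series


@dataclass
class BoldSeries:
    """4D BOLD data (x, y, z, t) with per-volume acquisition times.

    ``kind`` distinguishes clustered-sparse task runs (volumes arrive in
    consecutive triplets after each trial, timestamps non-uniform) from
    continuous resting-state runs (uniform TR).
    """

    grid: VolumeGrid
    data: np.ndarray
    tr_s: float
    timestamps_s: np.ndarray
    kind: str  # "task-sparse" | "rest-continuous"
    site: SiteConfig | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.data.shape[:3] != self.grid.shape:
            raise ValueError(
                f"BOLD spatial shape {self.data.shape[:3]} does not match grid {self.grid.shape}"
            )
        if self.data.shape[3] < 1:
            raise ValueError("BOLD series needs at least one volume")
        if self.timestamps_s.shape != (self.data.shape[3],):
            raise ValueError("one timestamp per volume required")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.kind not in ("task-sparse", "rest-continuous"):
            raise ValueError(f"unknown BOLD kind {self.kind!r}")
        if self.kind == "task-sparse":
            n_cluster = self.site.n_cluster_vols if self.site is not None else 3
            if self.n_volumes % n_cluster != 0:
                raise ValueError(
                    f"task-sparse run of {self.n_volumes} volumes is not a whole "
                    f"number of {n_cluster}-volume clusters"
                )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return replace(self, data=np.asarray(data))


# ---------------------------------------------------------------------------
# morphology

_CONN_TO_RANK = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int = 26) -> np.ndarray:
    """3x3x3 structuring element for 6-, 18- or 26-connected neighborhoods."""
    try:
        rank = _CONN_TO_RANK[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    return ndimage.generate_binary_structure(3, rank)


def dilate(mask: np.ndarray, iterations: int = 1, connectivity: int = 26) -> np.ndarray:
    """Binary dilation by ``iterations`` voxels (26-connected by default)."""
    if iterations == 0:
        return mask.astype(bool).copy()
    return ndimage.binary_dilation(
        mask, structure=connectivity_structure(connectivity), iterations=iterations
    )


def erode(mask: np.ndarray, iterations: int = 1, connectivity: int = 6) -> np.ndarray:
    """Binary erosion; 6-connected (face-adjacent cross) by default, the
    conservative choice for tissue-compartment shrinking."""
    if iterations == 0:
        return mask.astype(bool).copy()
    return ndimage.binary_erosion(
        mask, structure=connectivity_structure(connectivity), iterations=iterations
    )


def label_components(mask: np.ndarray, connectivity: int = 26):
    """Connected-component labeling; returns (label array, n_components)."""
    return ndimage.label(mask, structure=connectivity_structure(connectivity))


# ---------------------------------------------------------------------------
# smoothing

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    return fwhm_mm / _FWHM_FACTOR


def smooth_gaussian(bold: BoldSeries, fwhm_mm: float) -> BoldSeries:
    """Volume-wise isotropic Gaussian smoothing.

    The kernel width is specified as FWHM in millimetres and converted to a
    per-axis sigma in voxels using the grid's voxel size.  Smoothing is
    strictly spatial: the time axis is never filtered.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return bold.with_data(bold.data.copy())
    sigma_mm = fwhm_to_sigma(fwhm_mm)
    sigma_vox = tuple(sigma_mm / v for v in bold.grid.voxel_size_mm)
    out = ndimage.gaussian_filter(
        bold.data.astype(np.float64, copy=False),
        sigma=sigma_vox + (0.0,),
        mode="constant",
        cval=0.0,
    )
    return bold.with_data(out)


# ---------------------------------------------------------------------------
# compartment signals


def compartment_signal(
    bold: BoldSeries,
    labels: LabeledVolume,
    compartment: str,
    n_erosions_max: int = 3,
    connectivity: int = 6,
) -> np.ndarray:
    """Mean time series of a tissue compartment after iterative erosion.

    The compartment mask is eroded up to ``n_erosions_max`` times, but an
    erosion is only applied while it would leave at least two voxels.  The
    returned series is the spatial mean over the final mask, one value per
    volume.  Intended for *unsmoothed* data (smoothing would leak signal
    across compartment boundaries).
    """
    bold.grid.check_same(labels.grid, "label volume")
    mask = labels.mask(compartment)
    if not mask.any():
        raise ValueError(f"compartment {compartment!r} is empty")
    for _ in range(n_erosions_max):
        eroded = erode(mask, 1, connectivity=connectivity)
        if eroded.sum() >= 2:
            mask = eroded
        else:
            break
    return bold.data[mask].mean(axis=0)
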