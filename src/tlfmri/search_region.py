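"""Thalamic search regions (TSRs) for MGN and LGN.

The segmentation seed for each nucleus is dilated (MGN by three voxels,
LGN by one — segmentation LGN estimates run larger), voxels belonging to
surrounding structures are removed, the posterior-most two slices of the
resulting mask are trimmed to keep clear of midbrain, and MGN search
regions are additionally clipped to the inferior aspect of posterior
thalamus: nothing superior to the inferior-most pulvinar slice survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LabeledVolume, dilate

__all__ = ["ThalamicSearchRegion", "exclusion_union", "posterior_and_pulvinar_trim", "build_tsr"]

DEFAULT_DILATIONS = {"mgn": 3, "lgn": 1}

#: structure labels removed from TSRs without dilation
_EXCLUDE_RAW = ("cortical_gm", "parahippocampal_wm", "hippocampus")
#: structure labels dilated once before removal
_EXCLUDE_DILATED = (
    "mediodorsal_L", "mediodorsal_R",
    "insular_wm",
    "choroid_plexus",
    "pulvinar_L", "pulvinar_R",
    "putamen",
    "pallidum",
)


@dataclass
class ThalamicSearchRegion:
    hemisphere: str
    nucleus: str  # "mgn" | "lgn"
    mask: np.ndarray
    provenance: list[tuple[str, int]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return int(self.mask.sum())


def exclusion_union(labels: LabeledVolume, connectivity: int = 26) -> np.ndarray:
    """Union of surrounding-structure masks removed from every TSR."""
    out = np.zeros(labels.grid.shape, dtype=bool)
    for name in _EXCLUDE_RAW:
        out |= labels.mask(name)
    for name in _EXCLUDE_DILATED:
        m = labels.mask(name)
        if m.any():
            out |= dilate(m, 1, connectivity=connectivity)
    return out


def posterior_and_pulvinar_trim(
    tsr_mask: np.ndarray, nucleus: str, pulvinar_mask_bilateral: np.ndarray
) -> np.ndarray:
    """Remove the posterior-most two slices of the TSR; for MGN, also
    remove voxels strictly superior to the inferior-most pulvinar slice.

    "Posterior-most two slices" is evaluated on the slices the TSR itself
    occupies (the two smallest y indices present in the mask), and
    "superior to" is strict — the boundary slice is retained.
    """
    if not tsr_mask.any():
        raise ValueError("cannot trim an empty search region")
    out = tsr_mask.copy()
    ys = np.unique(np.nonzero(out)[1])
    for y in ys[:2]:
        out[:, y, :] = False
    if nucleus == "mgn":
        if not pulvinar_mask_bilateral.any():
            raise ValueError("pulvinar mask is empty; cannot apply inferior constraint")
        z_star = int(np.nonzero(pulvinar_mask_bilateral)[2].min())
        out[:, :, z_star + 1 :] = False
    if not out.any():
        raise ValueError(f"{nucleus} search region empty after trimming (QC failure)")
    return out


def build_tsr(
    labels: LabeledVolume,
    nucleus: str,
    hemisphere: str,
    dilations: int | None = None,
    connectivity: int = 26,
) -> ThalamicSearchRegion:
    """Construct one hemispheric search region from its segmentation seed."""
    if nucleus not in DEFAULT_DILATIONS:
        raise ValueError(f"nucleus must be 'mgn' or 'lgn', got {nucleus!r}")
    n_dil = DEFAULT_DILATIONS[nucleus] if dilations is None else dilations
    seed = labels.mask(f"{nucleus}_seed_{hemisphere}")
    if not seed.any():
        raise ValueError(f"empty seed label {nucleus}_seed_{hemisphere}")
    provenance = [("seed", int(seed.sum()))]

    mask = dilate(seed, n_dil, connectivity=connectivity) & labels.brain_mask
    provenance.append((f"dilated_x{n_dil}", int(mask.sum())))

    mask &= ~exclusion_union(labels, connectivity=connectivity)
    provenance.append(("exclusions_removed", int(mask.sum())))
    if not mask.any():
        raise ValueError(
            f"{nucleus}_{hemisphere} search region empty after exclusion removal (QC failure)"
        )

    pulvinar = labels.mask("pulvinar_L") | labels.mask("pulvinar_R")
    mask = posterior_and_pulvinar_trim(mask, nucleus, pulvinar)
    provenance.append(("trimmed", int(mask.sum())))
    return ThalamicSearchRegion(
        hemisphere=hemisphere, nucleus=nucleus, mask=mask, provenance=provenance
    )
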