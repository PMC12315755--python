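"""End-to-end orchestration: task runs -> fROIs -> resting connectivity.

The task stage smooths each run, fits the sparse GLM per run, averages
the Auditory - Visual contrast, selects cortical clusters, extracts the
AC/VC reference series from run-concatenated smoothed data, builds the
thalamic search regions, and extracts MGN/LGN fROIs from coactivation
maps.  The rest stage censors each run, post-processes survivors and
estimates ROI-pair connectivity using the fROIs and anatomy-derived
primary AC/VC ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cortex_select, froi_extract, rsfc, search_region, task_glm
from .censoring import (
    CensorConfig,
    RetentionReport,
    combine_censor,
    eye_closure_censor,
    gev_dv_threshold,
    lpf_fd,
    retention_rules,
)
from .core import BoldSeries, LabeledVolume, compartment_signal, smooth_gaussian
from .froi_extract import FroiSet
from .phantom import PhantomDataset
from .rsfc import RsfcConfig
from .schedule import TrialSchedule

__all__ = ["TaskResult", "run_task_pipeline", "run_rest_pipeline", "concat_task_runs"]


@dataclass
class TaskResult:
    froi: FroiSet
    contrast: task_glm.ContrastMap
    tsrs: dict[tuple[str, str], search_region.ThalamicSearchRegion]
    coactivation: dict[tuple[str, str], froi_extract.CoactivationResult]
    clusters: dict[tuple[str, str], cortex_select.CortexCluster]


def concat_task_runs(runs: list[BoldSeries], schedules: list[TrialSchedule]) -> BoldSeries:
    """Concatenate task runs along time, offsetting timestamps run by run."""
    data = np.concatenate([r.data for r in runs], axis=3)
    stamps = []
    offset = 0.0
    for r, s in zip(runs, schedules):
        stamps.append(r.timestamps_s + offset)
        offset += s.total_duration_s
    return BoldSeries(
        grid=runs[0].grid,
        data=data,
        tr_s=runs[0].tr_s,
        timestamps_s=np.concatenate(stamps),
        kind="task-sparse",
        site=runs[0].site,
    )


def run_task_pipeline(
    labels: LabeledVolume,
    task_runs: list[BoldSeries],
    schedules: list[TrialSchedule],
    motion: list[pd.DataFrame] | None = None,
    connectivity: int = 26,
) -> TaskResult:
    """Full localizer analysis for one participant."""
    site = schedules[0].site
    if motion is None:
        motion = [None] * len(task_runs)
    smoothed = [smooth_gaussian(r, site.fwhm_mm) for r in task_runs]

    fits = []
    for run, sm, sched, mot in zip(task_runs, smoothed, schedules, motion):
        wm = compartment_signal(run, labels, "white_matter")
        csf = compartment_signal(run, labels, "csf")
        design = task_glm.build_design(sched, mot, wm, csf)
        fits.append(task_glm.fit_glm(sm, design))
    contrast = task_glm.contrast_auditory_minus_visual(fits, labels.grid)

    clusters: dict[tuple[str, str], cortex_select.CortexCluster] = {}
    for modality, tail in (("auditory", "top"), ("visual", "bottom")):
        masks = cortex_select.make_cortex_search_mask(labels, modality, connectivity)
        for hemi in ("L", "R"):
            clusters[(modality, hemi)] = cortex_select.select_cortex_cluster(
                contrast, masks[hemi], tail, hemisphere=hemi, modality=modality,
                connectivity=connectivity,
            )

    sm_concat = concat_task_runs(smoothed, schedules)
    raw_concat = concat_task_runs(task_runs, schedules)
    ac_series = cortex_select.reference_series(
        sm_concat, clusters[("auditory", "L")], clusters[("auditory", "R")]
    )
    vc_series = cortex_select.reference_series(
        sm_concat, clusters[("visual", "L")], clusters[("visual", "R")]
    )
    vol2 = np.concatenate([s.cluster_position_indicator(1) for s in schedules])
    vol3 = np.concatenate([s.cluster_position_indicator(2) for s in schedules])

    tsrs = {
        (nuc, hemi): search_region.build_tsr(labels, nuc, hemi, connectivity=connectivity)
        for nuc in ("mgn", "lgn")
        for hemi in ("L", "R")
    }
    mean_sizes = {
        nuc: (tsrs[(nuc, "L")].size + tsrs[(nuc, "R")].size) / 2.0 for nuc in ("mgn", "lgn")
    }

    coact: dict[tuple[str, str], froi_extract.CoactivationResult] = {}
    froi_masks: dict[str, np.ndarray] = {}
    for (nuc, hemi), tsr in tsrs.items():
        nuis = froi_extract.coactivation_nuisance(raw_concat, labels, tsr.mask, vol2, vol3)
        result = froi_extract.coactivation_maps(sm_concat, tsr, ac_series, vc_series, nuis)
        result = froi_extract.threshold_and_exclude(result, nuc, mean_sizes[nuc])
        coact[(nuc, hemi)] = result
        kept = result.kept_ac if nuc == "mgn" else result.kept_vc
        r_map = result.r_ac if nuc == "mgn" else result.r_vc
        froi_masks[f"{nuc}_{hemi}"] = froi_extract.largest_cluster(
            kept, r_map, connectivity=connectivity
        )
    froi = FroiSet(**{k: froi_masks[k] for k in ("mgn_L", "mgn_R", "lgn_L", "lgn_R")})
    froi.qc = froi_extract.qc_flags(froi)
    return TaskResult(froi=froi, contrast=contrast, tsrs=tsrs, coactivation=coact, clusters=clusters)


def run_rest_pipeline(
    dataset: PhantomDataset,
    froi: FroiSet,
    rsfc_config: RsfcConfig = RsfcConfig(),
    censor_config: CensorConfig = CensorConfig(),
    participant: str = "sub-01",
    roi_source: str = "tl",
) -> tuple[pd.DataFrame, RetentionReport]:
    """Censor, post-process and estimate ROI-pair connectivity.

    Returns the run-level connectivity table (empty if the participant
    fails retention) and the retention report.
    """
    labels = dataset.labels
    brain = labels.brain_mask
    masks = []
    for run, mot, eyes in zip(dataset.rest_runs, dataset.rest_motion, dataset.eye_closures):
        fd = lpf_fd(mot, run.tr_s, censor_config)
        motion_censor = fd > censor_config.phi_f_mm
        _, _, dv_censor = gev_dv_threshold(run, brain, censor_config)
        eye = eye_closure_censor(eyes, run.timestamps_s, censor_config)
        masks.append(combine_censor(run.n_volumes, motion_censor, dv_censor, eye))
    report = retention_rules(masks, dataset.rest_runs[0].tr_s, censor_config)
    if not report.participant_valid:
        return pd.DataFrame(), report

    processed = [
        rsfc.postprocess_rest_run(run, labels, mot, mask, rsfc_config)
        for run, mot, mask, valid in zip(
            dataset.rest_runs, dataset.rest_motion, masks, report.run_valid
        )
        if valid
    ]
    thal = {name: froi.mask(*name.split("_")) for name in ("mgn_L", "mgn_R", "lgn_L", "lgn_R")}
    cortex = cortex_select.apriori_ac_vc_rois(labels)
    table = rsfc.roi_pair_connectivity(
        processed, thal, cortex, participant=participant, roi_source=roi_source,
        site=dataset.config.site.name,
    )
    return table, report
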