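"""Resting-state post-processing and functional-connectivity estimation.

Post-processing: mode-1000 normalization, linear detrend + mean centring,
censoring-aware band-pass (censored points linearly interpolated before
zero-phase Butterworth filtering, then re-censored), and edge trimming of
ceil(22 s / TR) volumes per end.  Connectivity: ROI-pair Pearson partial
correlations (the four hemispheric combinations averaged per run, runs
averaged per participant), selectivity contrasts with FDR correction,
benchmarking against alternative ROI sets, whole-brain seed maps, and the
Dice-Sorensen overlap coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import BoldSeries, LabeledVolume, compartment_signal
from .censoring import CensorMask
from .froi_extract import partial_correlation, residualize

__all__ = [
    "RsfcConfig",
    "ProcessedRestRun",
    "mode1000",
    "detrend_center",
    "bandpass_with_interpolation",
    "edge_trim_volumes",
    "rest_nuisance_matrix",
    "postprocess_rest_run",
    "roi_pair_connectivity",
    "participant_connectivity",
    "selectivity_contrasts",
    "benchmark_roi_sets",
    "seed_map",
    "dice",
]

ROI_PAIRS = ["mgn_ac", "mgn_vc", "lgn_ac", "lgn_vc"]


@dataclass(frozen=True)
class RsfcConfig:
    band_hz: tuple[float, float] = (0.009, 0.08)
    filter_order: int = 2
    edge_trim_s: float = 22.0
    mode_target: float = 1000.0

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ValueError("band must satisfy 0 < low < high")


# ---------------------------------------------------------------------------
# post-processing primitives


def mode1000(bold: BoldSeries, brain_mask: np.ndarray, target: float = 1000.0) -> BoldSeries:
    """Scale so the modal in-brain intensity equals ``target``.

    The mode is estimated by rounding in-brain values to the nearest
    integer and taking the most frequent (smallest wins a tie) — stable at
    scanner-scale intensities.
    """
    mode = _modal_intensity(bold.data[brain_mask])
    if mode <= 0:
        raise ValueError(f"non-positive modal intensity {mode}; data not suitable for mode scaling")
    return bold.with_data(bold.data * (target / mode))


def _modal_intensity(values: np.ndarray) -> int:
    """Most frequent nearest-integer value (smallest wins a tie)."""
    vals = np.rint(np.asarray(values, dtype=np.float32)).astype(np.int64).ravel()
    lo = vals.min()
    counts = np.bincount(vals - lo)
    return int(lo + np.argmax(counts))


def detrend_center(series: np.ndarray) -> np.ndarray:
    """Remove the OLS line (slope and mean) along the first axis."""
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to detrend")
    t = np.arange(n, dtype=float)
    t = (t - t.mean()) / t.std()
    flat = x.reshape(n, -1)
    slope = t @ flat / n
    out = flat - flat.mean(axis=0) - np.outer(t, slope)
    return out.reshape(x.shape)


def edge_trim_volumes(tr_s: float, edge_trim_s: float = 22.0) -> int:
    """Volumes discarded from each end after filtering: ceil(22 s / TR)."""
    return int(np.ceil(edge_trim_s / tr_s - 1e-12))


def bandpass_with_interpolation(
    series: np.ndarray,
    keep_mask: np.ndarray,
    tr_s: float,
    config: RsfcConfig = RsfcConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Censoring-aware zero-phase band-pass with edge trimming.

    Censored samples are replaced by linear interpolation between kept
    neighbours (edge gaps held at the nearest kept value) so the filter
    sees a continuous series; after forward-backward Butterworth
    filtering the interpolated samples are re-censored, and
    ceil(edge_trim_s / TR) volumes are dropped from each end.  Returns
    (trimmed series, trimmed keep mask).
    """
    x = np.asarray(series, dtype=float)
    keep = np.asarray(keep_mask, dtype=bool)
    n = x.shape[0]
    if keep.shape != (n,):
        raise ValueError("keep mask must have one entry per volume")
    if keep.sum() < 2:
        raise ValueError("fewer than 2 kept volumes; run is unusable")
    flat = x.reshape(n, -1)
    if not keep.all():
        # vectorized linear interpolation over censored samples: for each
        # gap sample find its kept neighbours once (shared across voxels)
        kept_idx = np.nonzero(keep)[0]
        gap_idx = np.nonzero(~keep)[0]
        right_pos = np.searchsorted(kept_idx, gap_idx)
        left = kept_idx[np.clip(right_pos - 1, 0, kept_idx.size - 1)]
        right = kept_idx[np.clip(right_pos, 0, kept_idx.size - 1)]
        denom = np.where(right > left, right - left, 1)
        w = np.clip((gap_idx - left) / denom, 0.0, 1.0)  # edge gaps -> nearest
        flat = flat.copy()
        flat[gap_idx] = (1.0 - w)[:, None] * flat[left] + w[:, None] * flat[right]
    fs = 1.0 / tr_s
    lo, hi = config.band_hz
    sos = sps.butter(
        config.filter_order,
        [lo / (fs / 2), min(hi / (fs / 2), 0.999)],
        btype="band",
        output="sos",
    )
    filt = sps.sosfiltfilt(sos, flat, axis=0)
    n_trim = edge_trim_volumes(tr_s, config.edge_trim_s)
    sl = slice(n_trim, n - n_trim)
    if sl.start >= n - n_trim:
        raise ValueError("run shorter than twice the edge trim")
    out = filt[sl].reshape((n - 2 * n_trim,) + x.shape[1:])
    return out, keep[sl].copy()


# ---------------------------------------------------------------------------
# per-run post-processing bundle


@dataclass
class ProcessedRestRun:
    """One resting run after normalization, filtering and trimming."""

    bold: BoldSeries  # trimmed, post-processed
    keep: np.ndarray  # per trimmed volume; censored/interpolated = False
    nuisance: np.ndarray  # (n_trimmed, n_regressors)
    brain_mask: np.ndarray


def _backward_diff(x: np.ndarray) -> np.ndarray:
    d = np.zeros_like(np.asarray(x, dtype=float))
    d[1:] = np.diff(np.asarray(x, dtype=float), axis=0)
    return d


def rest_nuisance_matrix(
    motion: pd.DataFrame,
    keep_mask: np.ndarray,
    tr_s: float,
    wm: np.ndarray,
    csf: np.ndarray,
    config: RsfcConfig = RsfcConfig(),
) -> np.ndarray:
    """Partial-correlation nuisance set: band-pass filtered motion
    parameters, their squares, their backward derivatives, the squares of
    the derivatives, and the WM and CSF signals with their derivatives.

    Motion is filtered with the same band-pass (censoring-aware) as the
    BOLD series, so the matrix rows align with the trimmed run; WM/CSF
    series are expected to come from post-processed data already trimmed.
    """
    mp = motion[["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]].to_numpy(float)
    mp_f, _ = bandpass_with_interpolation(mp, keep_mask, tr_s, config)
    d_mp = _backward_diff(mp_f)
    cols = [mp_f, mp_f**2, d_mp, d_mp**2]
    for sig in (wm, csf):
        sig = np.asarray(sig, dtype=float)
        cols.append(sig[:, None])
        cols.append(_backward_diff(sig)[:, None])
    return np.column_stack(cols)


def postprocess_rest_run(
    bold: BoldSeries,
    labels: LabeledVolume,
    motion: pd.DataFrame,
    censor: CensorMask,
    config: RsfcConfig = RsfcConfig(),
) -> ProcessedRestRun:
    """Full resting post-processing for one run.

    Mode-1000 normalize, detrend and centre in-brain voxel series, apply
    the censoring-aware band-pass, trim edges, and assemble the nuisance
    matrix (compartment signals are extracted from the post-processed
    data).
    """
    brain = labels.brain_mask
    M = bold.data[brain].T.astype(np.float64)  # (t, n_brain_vox)
    mode = _modal_intensity(M)
    if mode <= 0:
        raise ValueError(f"non-positive modal intensity {mode}")
    M *= config.mode_target / mode
    M = detrend_center(M)
    filt, keep_trim = bandpass_with_interpolation(M, censor.keep, bold.tr_s, config)
    n_trim_t = filt.shape[0]
    out = np.zeros(bold.grid.shape + (n_trim_t,), dtype=np.float32)
    out[brain] = filt.T
    n_trim = edge_trim_volumes(bold.tr_s, config.edge_trim_s)
    trimmed = BoldSeries(
        grid=bold.grid,
        data=out,
        tr_s=bold.tr_s,
        timestamps_s=bold.timestamps_s[n_trim : bold.n_volumes - n_trim],
        kind="rest-continuous",
        site=bold.site,
    )
    wm = compartment_signal(trimmed, labels, "white_matter")
    csf = compartment_signal(trimmed, labels, "csf")
    nuis = rest_nuisance_matrix(motion, censor.keep, bold.tr_s, wm, csf, config)
    return ProcessedRestRun(bold=trimmed, keep=keep_trim, nuisance=nuis, brain_mask=brain)


# ---------------------------------------------------------------------------
# connectivity


def _roi_series(run: ProcessedRestRun, mask: np.ndarray, name: str) -> np.ndarray:
    if not mask.any():
        raise ValueError(f"ROI {name!r} is empty")
    series = run.bold.data[mask].mean(axis=0)
    if np.ptp(series[run.keep]) < 1e-12:
        raise ValueError(f"ROI {name!r} series is degenerate on retained volumes")
    return series


def roi_pair_connectivity(
    runs: list[ProcessedRestRun],
    thalamic_masks: dict[str, np.ndarray],
    cortex_masks: dict[str, np.ndarray],
    participant: str = "sub-01",
    roi_source: str = "tl",
    site: str = "",
) -> pd.DataFrame:
    """Run-level ROI-pair partial correlations.

    For each pair (e.g. MGN-AC) the four hemispheric combinations
    (L-L, L-R, R-L, R-R) are estimated on retained volumes and averaged
    into a single run-level value.  Returns tidy rows
    (participant, run, pair, roi_source, site, value).
    """
    rows = []
    for i_run, run in enumerate(runs):
        kept = run.keep
        nuis = run.nuisance[kept]
        series = {}
        for name, mask in {**thalamic_masks, **cortex_masks}.items():
            series[name] = _roi_series(run, mask, name)[kept]
        for pair in ROI_PAIRS:
            thal, ctx = pair.split("_")
            combos = [
                partial_correlation(series[f"{thal}_{h1}"], series[f"{ctx}_{h2}"], nuis)
                for h1 in ("L", "R")
                for h2 in ("L", "R")
            ]
            rows.append(
                {
                    "participant": participant,
                    "run": i_run,
                    "pair": pair,
                    "roi_source": roi_source,
                    "site": site,
                    "value": float(np.mean(combos)),
                }
            )
    return pd.DataFrame(rows)


def participant_connectivity(table: pd.DataFrame) -> pd.DataFrame:
    """Average run-level values into participant-level values (raw r)."""
    return (
        table.groupby(["participant", "pair", "roi_source"], as_index=False)["value"]
        .mean()
    )


def selectivity_contrasts(participant_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Within-participant selectivity differences with one-tailed tests.

    The four contrasts (MGN-AC > MGN-VC, MGN-AC > LGN-AC, LGN-VC > LGN-AC,
    LGN-VC > MGN-VC) are tested with one-sample one-tailed t-tests and
    Benjamini-Hochberg corrected across the four.
    """
    wide = participant_table.pivot_table(index="participant", columns="pair", values="value")
    contrasts = {
        "mgn_ac_gt_mgn_vc": wide["mgn_ac"] - wide["mgn_vc"],
        "mgn_ac_gt_lgn_ac": wide["mgn_ac"] - wide["lgn_ac"],
        "lgn_vc_gt_lgn_ac": wide["lgn_vc"] - wide["lgn_ac"],
        "lgn_vc_gt_mgn_vc": wide["lgn_vc"] - wide["mgn_vc"],
    }
    if len(wide) < 2:
        raise ValueError("at least 2 participants required for group tests")
    rows = []
    for name, diff in contrasts.items():
        d = diff.to_numpy(dtype=float)
        if np.ptp(d) < 1e-15:
            raise ValueError(f"zero variance in contrast {name}")
        t, p = stats.ttest_1samp(d, 0.0, alternative="greater")
        rows.append({"contrast": name, "mean_diff": d.mean(), "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    reject, p_fdr, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["p_fdr"] = p_fdr
    out["significant"] = reject
    return out


def benchmark_roi_sets(
    participant_table: pd.DataFrame,
    primary_source: str = "tl",
    alt_sources: list[str] | None = None,
) -> pd.DataFrame:
    """Per-participant (primary - alternative) connectivity differences for
    MGN-AC and LGN-VC, with two-tailed one-sample t-tests per alternative."""
    sources = sorted(participant_table["roi_source"].unique())
    if alt_sources is None:
        alt_sources = [s for s in sources if s != primary_source]
    rows = []
    for pair in ("mgn_ac", "lgn_vc"):
        sub = participant_table[participant_table["pair"] == pair]
        primary = sub[sub["roi_source"] == primary_source].set_index("participant")["value"]
        for alt in alt_sources:
            other = sub[sub["roi_source"] == alt].set_index("participant")["value"]
            if set(primary.index) != set(other.index):
                raise ValueError(
                    f"participant mismatch between {primary_source!r} and {alt!r} for {pair}"
                )
            diff = (primary - other.reindex(primary.index)).to_numpy(dtype=float)
            if np.ptp(diff) < 1e-15:
                t, p = np.nan, 1.0 if np.allclose(diff, 0) else np.nan
            else:
                t, p = stats.ttest_1samp(diff, 0.0)
            rows.append(
                {
                    "pair": pair,
                    "alternative": alt,
                    "mean_diff": float(diff.mean()),
                    "t": float(t) if np.isfinite(np.asarray(t, dtype=float)) else np.nan,
                    "p": float(p),
                    "n": diff.size,
                }
            )
    return pd.DataFrame(rows)


def seed_map(
    runs: list[ProcessedRestRun],
    seed_mask_L: np.ndarray,
    seed_mask_R: np.ndarray,
) -> np.ndarray:
    """Whole-brain seed partial-correlation map (smoothed, post-processed
    runs): per hemisphere and run, each in-brain voxel's partial
    correlation with the seed series; runs averaged, then hemispheres."""
    hemi_maps = []
    for seed_mask, name in ((seed_mask_L, "seed_L"), (seed_mask_R, "seed_R")):
        run_maps = []
        for run in runs:
            kept = run.keep
            nuis = run.nuisance[kept]
            seed = _roi_series(run, seed_mask, name)[kept]
            Y = run.bold.data[run.brain_mask].T[kept]
            Ry = residualize(Y, nuis)
            rs = residualize(seed, nuis)
            num = Ry.T @ rs
            den = np.sqrt((Ry**2).sum(axis=0)) * np.sqrt((rs**2).sum())
            r = np.zeros(den.shape)
            good = den > 1e-12
            r[good] = np.clip(num[good] / den[good], -1, 1)
            vol = np.zeros(run.brain_mask.shape)
            vol[run.brain_mask] = r
            run_maps.append(vol)
        hemi_maps.append(np.mean(run_maps, axis=0))
    return np.mean(hemi_maps, axis=0)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice-Sorensen coefficient 2|A∩B| / (|A|+|B|); 0 when both empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (a & b).sum() / denom)
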