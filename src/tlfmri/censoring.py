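"""Resting-state volume censoring and retention rules.

Three censoring signals — low-pass-filtered framewise displacement
(LPF-FD) against a study-wide threshold, run-wise GEV-DV (generalized
extreme value fit to the low-pass-filtered temporal-derivative RMS over
brain voxels), and eye-closure intervals — are combined by union, after
which contiguity rules discard short surviving segments, short runs, and
under-sampled participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .core import BoldSeries

__all__ = [
    "CensorConfig",
    "CensorMask",
    "lpf_fd",
    "gev_dv_threshold",
    "eye_closure_censor",
    "combine_censor",
    "retention_rules",
    "RetentionReport",
]

MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass(frozen=True)
class CensorConfig:
    """Censoring thresholds; defaults are the study-wide optimized values."""

    phi_f_mm: float = 0.07587  # LPF-FD threshold
    d_g: float = 3.105  # GEV-DV multiplier, arbitrary units
    mp_lpf_cutoff_hz: float = 0.2  # low-pass cutoff for motion/DV traces
    rot_radius_mm: float = 50.0  # rotation -> arc displacement radius
    eye_close_min_s: float = 3.0
    eye_gap_max_s: float = 30.0
    min_segment_s: float = 8.0
    min_run_s: float = 90.0
    min_participant_s: float = 300.0
    min_runs: int = 2

    def __post_init__(self) -> None:
        for name in ("phi_f_mm", "d_g", "mp_lpf_cutoff_hz", "rot_radius_mm",
                     "eye_close_min_s", "eye_gap_max_s", "min_segment_s",
                     "min_run_s", "min_participant_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CensorMask:
    keep: np.ndarray  # per-volume bool
    reasons: list[set]  # per-volume reason set, empty where kept

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def retained_seconds(self, tr_s: float) -> float:
        return self.n_kept * tr_s


def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float, axis: int = 0) -> np.ndarray:
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        warnings.warn(
            f"low-pass cutoff {cutoff_hz} Hz is at or above Nyquist {nyq} Hz; skipping filter"
        )
        return x
    sos = sps.butter(2, cutoff_hz / nyq, btype="low", output="sos")
    return sps.sosfiltfilt(sos, x, axis=axis)


def lpf_fd(motion: pd.DataFrame, tr_s: float, config: CensorConfig = CensorConfig()) -> np.ndarray:
    """Low-pass-filtered framewise displacement per volume (mm).

    Each of the six motion parameters is zero-phase low-pass filtered,
    rotations (radians) are converted to arc length on a 50 mm sphere,
    and FD is the sum of absolute backward differences, 0 at the first
    volume.
    """
    mp = motion[MOTION_COLS].to_numpy(dtype=float)
    if mp.shape[0] < 8:
        raise ValueError("need at least 8 volumes for LPF-FD")
    filtered = _lowpass(mp, 1.0 / tr_s, config.mp_lpf_cutoff_hz, axis=0)
    filtered = filtered.copy()
    filtered[:, 3:] *= config.rot_radius_mm
    fd = np.zeros(mp.shape[0])
    fd[1:] = np.abs(np.diff(filtered, axis=0)).sum(axis=1)
    return fd


def gev_dv_threshold(
    bold: BoldSeries,
    brain_mask: np.ndarray,
    config: CensorConfig = CensorConfig(),
) -> tuple[float, np.ndarray, np.ndarray]:
    """Run-wise GEV-DV threshold; returns (threshold, DV series, censored).

    DV_t is the RMS over brain voxels of the backward temporal difference
    of low-pass-filtered voxel series (0 at the first volume).  A
    generalized extreme value distribution is fit to the run's DV values
    and the threshold set at location + d_G * scale; a failed fit falls
    back to median + d_G * IQR with a warning.
    """
    n_t = bold.n_volumes
    if n_t < 30:
        raise ValueError("need at least 30 volumes for a stable GEV fit")
    # float32 is ample precision for an RMS summary over ~10^4 voxels
    Y = np.ascontiguousarray(bold.data[brain_mask], dtype=np.float32)  # (n_vox, t)
    Yf = _lowpass(Y, 1.0 / bold.tr_s, config.mp_lpf_cutoff_hz, axis=1)
    dv = np.zeros(n_t)
    diffs = np.diff(Yf, axis=1)
    dv[1:] = np.sqrt((diffs.astype(np.float64) ** 2).mean(axis=0))
    vals = dv[1:]
    if np.ptp(vals) < 1e-12:
        # constant data: nothing fluctuates, nothing censored
        threshold = float(vals.max() if vals.size else 0.0)
        return threshold, dv, np.zeros(n_t, dtype=bool)
    try:
        c, loc, scale = stats.genextreme.fit(vals)
        if not (np.isfinite(loc) and np.isfinite(scale) and scale > 0):
            raise RuntimeError("non-finite GEV parameters")
        threshold = float(loc + config.d_g * scale)
    except Exception:
        warnings.warn("GEV fit failed; falling back to median + d_G * IQR")
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        threshold = float(med + config.d_g * (q3 - q1))
    censored = dv > threshold
    return threshold, dv, censored


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def eye_closure_censor(
    closures: pd.DataFrame,
    timestamps_s: np.ndarray,
    config: CensorConfig = CensorConfig(),
) -> np.ndarray:
    """Censor volumes during eye closures longer than 3 s, and volumes
    between two such closures separated by less than 30 s.

    Overlapping logged intervals are merged before the duration rule is
    applied; the between-closure rule only considers closures that are
    themselves censorable.
    """
    timestamps = np.asarray(timestamps_s, dtype=float)
    censor = np.zeros(timestamps.size, dtype=bool)
    if closures is None or len(closures) == 0:
        return censor
    merged = _merge_intervals(
        [(float(r.onset), float(r.onset) + float(r.duration)) for r in closures.itertuples()]
    )
    long_closures = [(a, b) for a, b in merged if (b - a) > config.eye_close_min_s]
    for a, b in long_closures:
        censor |= (timestamps >= a) & (timestamps <= b)
    for (_, end_prev), (start_next, _) in zip(long_closures, long_closures[1:]):
        if start_next - end_prev < config.eye_gap_max_s:
            censor |= (timestamps > end_prev) & (timestamps < start_next)
    return censor


def combine_censor(
    n_volumes: int,
    motion_censor: np.ndarray | None = None,
    dv_censor: np.ndarray | None = None,
    eye_censor: np.ndarray | None = None,
) -> CensorMask:
    """Union of the censoring signals; reasons recorded per volume."""
    reasons = [set() for _ in range(n_volumes)]
    keep = np.ones(n_volumes, dtype=bool)
    for name, mask in (("motion", motion_censor), ("dv", dv_censor), ("eyes", eye_censor)):
        if mask is None:
            continue
        mask = np.asarray(mask, dtype=bool)
        keep &= ~mask
        for i in np.nonzero(mask)[0]:
            reasons[i].add(name)
    return CensorMask(keep=keep, reasons=reasons)


def _kept_segments(keep: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of kept volumes as (start, stop) half-open pairs."""
    segs = []
    in_seg = False
    for i, k in enumerate(keep):
        if k and not in_seg:
            start, in_seg = i, True
        elif not k and in_seg:
            segs.append((start, i))
            in_seg = False
    if in_seg:
        segs.append((start, keep.size))
    return segs


@dataclass
class RetentionReport:
    run_valid: list[bool]
    run_retained_s: list[float]
    participant_valid: bool
    total_retained_s: float


def retention_rules(
    masks: list[CensorMask], tr_s: float, config: CensorConfig = CensorConfig()
) -> RetentionReport:
    """Apply contiguity / run / participant retention rules (in place).

    Kept segments shorter than 8 s are discarded (a segment of exactly 8 s
    is kept); a run retaining under 90 s is invalid; a participant with
    fewer than 2 valid runs or under 300 s total is invalid.
    """
    run_valid, run_secs = [], []
    for mask in masks:
        for start, stop in _kept_segments(mask.keep):
            if (stop - start) * tr_s < config.min_segment_s - 1e-9:
                mask.keep[start:stop] = False
                for i in range(start, stop):
                    mask.reasons[i].add("contiguity")
        secs = mask.retained_seconds(tr_s)
        run_secs.append(secs)
        run_valid.append(secs >= config.min_run_s - 1e-9)
    total = sum(s for s, v in zip(run_secs, run_valid) if v)
    participant_valid = (
        sum(run_valid) >= config.min_runs and total >= config.min_participant_s - 1e-9
    )
    return RetentionReport(
        run_valid=run_valid,
        run_retained_s=run_secs,
        participant_valid=participant_valid,
        total_retained_s=total,
    )
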