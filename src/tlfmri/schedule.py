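"""Clustered-sparse task schedule construction.

A task run is one 12-second fixation trial followed by sixteen 12-second
stimulus trials (8 auditory, 8 visual) in seeded pseudorandom order.  Each
trial is gap / 9 s stimulation / gap / an acquisition cluster of
``n_cluster_vols`` volumes, with the two gaps calibrated so the trial lasts
exactly ``trial_dur_s``.  Auditory stimulation itself is nine 900 ms music
segments each followed by 100 ms of silence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SiteConfig

__all__ = [
    "Trial",
    "TrialSchedule",
    "calibrate_gap",
    "build_run_schedule",
    "schedule_events",
    "schedule_from_events",
    "sequence_audio_trial",
    "normalize_segments",
]

FIXATION = "fixation"
AUDITORY = "auditory"
VISUAL = "visual"


def calibrate_gap(
    tr_s: float, n_cluster_vols: int, stim_dur_s: float, trial_dur_s: float
) -> float:
    """Per-side gap (seconds) that brings one trial to ``trial_dur_s``.

    The trial layout is gap + stimulation + gap + cluster, so each gap is
    half of whatever time the stimulation and acquisition cluster leave
    over.  Negative leftover means the site configuration is infeasible.
    """
    gap = (trial_dur_s - stim_dur_s - n_cluster_vols * tr_s) / 2.0
    if gap < -1e-9:
        raise ValueError(
            f"infeasible site timing: {stim_dur_s} s stimulation + "
            f"{n_cluster_vols}x{tr_s} s cluster exceed the {trial_dur_s} s trial"
        )
    return max(gap, 0.0)


@dataclass(frozen=True)
class Trial:
    index: int
    trial_type: str
    onset_s: float
    gap_s: float
    stim_dur_s: float
    cluster_volume_indices: tuple[int, ...]

    @property
    def cluster_onset_s(self) -> float:
        return self.onset_s + 2.0 * self.gap_s + self.stim_dur_s


@dataclass
class TrialSchedule:
    site: SiteConfig
    trials: list[Trial]
    seed: int | None = None

    @property
    def n_volumes(self) -> int:
        return sum(len(t.cluster_volume_indices) for t in self.trials)

    @property
    def total_duration_s(self) -> float:
        return len(self.trials) * self.site.trial_dur_s

    def volume_timestamps(self) -> np.ndarray:
        """Acquisition start time of every volume, in run seconds."""
        times = np.empty(self.n_volumes)
        for t in self.trials:
            for k, v in enumerate(t.cluster_volume_indices):
                times[v] = t.cluster_onset_s + k * self.site.tr_s
        return times

    def condition_indicator(self, trial_type: str) -> np.ndarray:
        """Per-volume {0,1} indicator: 1 on every cluster volume following a
        trial of the given type."""
        ind = np.zeros(self.n_volumes)
        for t in self.trials:
            if t.trial_type == trial_type:
                ind[list(t.cluster_volume_indices)] = 1.0
        return ind

    def cluster_position_indicator(self, position: int) -> np.ndarray:
        """Indicator of the ``position``-th volume (0-based) of every cluster."""
        ind = np.zeros(self.n_volumes)
        for t in self.trials:
            ind[t.cluster_volume_indices[position]] = 1.0
        return ind


def _max_run_length(types: list[str]) -> int:
    best = run = 0
    prev = None
    for t in types:
        run = run + 1 if t == prev else 1
        prev = t
        best = max(best, run)
    return best


def build_run_schedule(
    site: SiteConfig, seed: int | None = None, max_consecutive: int = 3
) -> TrialSchedule:
    """Assemble one run: fixation first, then a seeded pseudorandom order of
    auditory/visual trials with at most ``max_consecutive`` same-type trials
    in a row.  Every trial, fixation included, is followed by one
    acquisition cluster."""
    rng = np.random.default_rng(seed)
    gap = calibrate_gap(site.tr_s, site.n_cluster_vols, site.stim_dur_s, site.trial_dur_s)
    stim_types = [AUDITORY] * site.n_aud_trials + [VISUAL] * site.n_vis_trials
    order = list(stim_types)
    while True:
        rng.shuffle(order)
        if _max_run_length(order) <= max_consecutive:
            break
    trials = []
    n = site.n_cluster_vols
    for i, trial_type in enumerate([FIXATION] + order):
        trials.append(
            Trial(
                index=i,
                trial_type=trial_type,
                onset_s=i * site.trial_dur_s,
                gap_s=gap,
                stim_dur_s=site.stim_dur_s,
                cluster_volume_indices=tuple(range(i * n, (i + 1) * n)),
            )
        )
    return TrialSchedule(site=site, trials=trials, seed=seed)


def schedule_events(schedule: TrialSchedule) -> pd.DataFrame:
    """Events table (onset, duration, trial_type), one row per trial."""
    return pd.DataFrame(
        {
            "onset": [t.onset_s for t in schedule.trials],
            "duration": [schedule.site.trial_dur_s] * len(schedule.trials),
            "trial_type": [t.trial_type for t in schedule.trials],
        }
    )


def schedule_from_events(events: pd.DataFrame, site: SiteConfig) -> TrialSchedule:
    """Rebuild a schedule from an events table (inverse of schedule_events)."""
    gap = calibrate_gap(site.tr_s, site.n_cluster_vols, site.stim_dur_s, site.trial_dur_s)
    n = site.n_cluster_vols
    trials = []
    for i, row in enumerate(events.itertuples(index=False)):
        trials.append(
            Trial(
                index=i,
                trial_type=row.trial_type,
                onset_s=float(row.onset),
                gap_s=gap,
                stim_dur_s=site.stim_dur_s,
                cluster_volume_indices=tuple(range(i * n, (i + 1) * n)),
            )
        )
    return TrialSchedule(site=site, trials=trials)


# ---------------------------------------------------------------------------
# auditory stimulus sequencing


def sequence_audio_trial(
    segment_pool,
    seed: int | None = None,
    n_segments: int = 9,
    segment_dur_s: float = 0.9,
    gap_dur_s: float = 0.1,
) -> list[tuple[object, float]]:
    """Order the music segments of one auditory trial.

    Draws ``n_segments`` segments from the pool without replacement and
    pairs each with its trailing silence, totalling
    ``n_segments * (segment_dur_s + gap_dur_s)`` seconds (9 s by default).
    """
    pool = list(segment_pool)
    if len(pool) < n_segments:
        raise ValueError(
            f"segment pool has {len(pool)} segments; {n_segments} needed per trial"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_segments, replace=False)
    return [(pool[i], gap_dur_s) for i in chosen]


def normalize_segments(waveforms) -> list[np.ndarray]:
    """Rescale sampled waveforms to a common mean absolute amplitude.

    Each segment is scaled so its mean |amplitude| equals the grand mean
    of the pool, preventing loudness jumps between consecutive segments.
    """
    waves = [np.asarray(w, dtype=float) for w in waveforms]
    if not waves:
        raise ValueError("no waveforms supplied")
    means = np.array([np.abs(w).mean() for w in waves])
    if np.any(means == 0):
        raise ValueError("all-zero waveform cannot be amplitude-normalized")
    target = means.mean()
    return [w * (target / m) for w, m in zip(waves, means)]
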