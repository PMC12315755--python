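"""Synthetic phantom: anatomy, task BOLD, resting BOLD, motion, eye logs.

The phantom emulates the statistical structure the analysis assumes, on a
small analysis grid, so every downstream stage can be exercised and
verified without external data:

* a labeled anatomy with implanted "truth" MGN and LGN nuclei, with the
  truth LGN superior and lateral to the truth MGN in each hemisphere, and
  FreeSurfer-style seed labels offset from truth by a 1-voxel jitter to
  emulate segmentation-prior error;
* clustered-sparse task runs in which only the acquisition-cluster volumes
  exist, with condition-locked amplitudes (auditory structures respond on
  auditory-trial clusters, visual on visual) and per-cluster-position
  T1-relaxation offsets — no hemodynamic convolution, matching the
  unconvolved task regressors of the sparse design;
* continuous resting-state runs built from band-limited (0.009-0.08 Hz)
  latent sources: truth MGN shares the auditory-cortex source at a target
  correlation ``rest_coupling_r`` and truth LGN the visual-cortex source,
  cross-pairs are uncoupled, and WM/CSF/global confound sources are mixed
  into all tissue;
* motion traces (smooth drift plus injected displacement spikes sized to
  trip the LPF-FD threshold) and eye-closure logs whose durations straddle
  the 3 s censoring rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    NYSPI,
    BoldSeries,
    LabeledVolume,
    SiteConfig,
    VolumeGrid,
)
from .froi_extract import FroiSet
from .schedule import AUDITORY, VISUAL, TrialSchedule, build_run_schedule

__all__ = [
    "PhantomConfig",
    "PhantomDataset",
    "generate_anatomy",
    "generate_task_run",
    "generate_rest_run",
    "generate_motion",
    "generate_eye_closures",
    "generate_dataset",
    "write_phantom_bids",
]

_CANONICAL_SHAPE = (40, 48, 36)

#: structures whose task response is locked to auditory trials
AUDITORY_TASK_LABELS = ("ba41_42_L", "ba41_42_R", "transverse_temporal_L", "transverse_temporal_R")
#: structures whose task response is locked to visual trials
VISUAL_TASK_LABELS = ("ba17_18_L", "ba17_18_R", "pericalcarine_L", "pericalcarine_R")


@dataclass
class PhantomConfig:
    """Knobs of the synthetic dataset; defaults are the study conditions.

    Amplitudes are in scanner units on a baseline of 1000 (so
    ``task_amplitude_pct=2`` is a 2% signal change and mode-1000
    normalization is near-identity).  ``t1_offsets`` are additive fractions
    of baseline for cluster volumes 1..n, emulating incomplete T1 recovery
    during clustered-sparse acquisition.
    """

    grid: VolumeGrid = field(default_factory=lambda: VolumeGrid(_CANONICAL_SHAPE))
    site: SiteConfig = NYSPI
    mgn_size: int = 20
    lgn_size: int = 30
    baseline: float = 1000.0
    task_amplitude_pct: float = 2.0
    t1_offsets: tuple[float, ...] = (0.05, 0.02, 0.0)
    noise_sd: float = 5.0
    task_drift_amplitude: float = 2.0
    rest_coupling_r: float = 0.4
    rest_struct_sd: float = 10.0
    rest_compartment_sd: float = 10.0
    rest_global_sd: float = 1.5
    rest_confound_mix: float = 1.0
    rest_band_hz: tuple[float, float] = (0.009, 0.08)
    n_task_runs: int = 4
    n_rest_runs: int = 4
    rest_run_dur_s: float = 458.0
    seed_jitter_vox: int = 1
    motion_drift_mm: float = 0.01
    motion_spike_rate_per_min: float = 0.5
    motion_spike_mm: float = 1.0
    eye_closure_rate_per_min: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rest_coupling_r < 1.0):
            raise ValueError("rest_coupling_r must be in [0, 1)")
        if self.task_amplitude_pct < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise SD must be non-negative")
        if len(self.t1_offsets) != self.site.n_cluster_vols:
            raise ValueError("one T1 offset per cluster volume required")


@dataclass
class PhantomDataset:
    """Everything one synthetic participant provides to the pipeline."""

    config: PhantomConfig
    labels: LabeledVolume
    truth_froi: FroiSet
    task_runs: list[BoldSeries]
    task_schedules: list[TrialSchedule]
    task_motion: list[pd.DataFrame]
    rest_runs: list[BoldSeries]
    rest_motion: list[pd.DataFrame]
    rest_spike_volumes: list[np.ndarray]
    eye_closures: list[pd.DataFrame]


# ---------------------------------------------------------------------------
# anatomy


def _scaled(coord, shape) -> np.ndarray:
    return np.asarray(coord, dtype=float) * (np.asarray(shape) / np.asarray(_CANONICAL_SHAPE))


def _ball_mask(shape, center, n_voxels: int) -> np.ndarray:
    """The ``n_voxels`` grid points nearest ``center`` (ties lexicographic)."""
    center = np.asarray(center, dtype=float)
    r = int(np.ceil(n_voxels ** (1 / 3))) + 2
    lo = np.maximum(np.floor(center).astype(int) - r, 0)
    hi = np.minimum(np.floor(center).astype(int) + r + 1, shape)
    xs, ys, zs = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    pts = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)
    d2 = ((pts - center) ** 2).sum(axis=1)
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], d2))
    chosen = pts[order[:n_voxels]]
    mask = np.zeros(shape, dtype=bool)
    mask[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True
    return mask


def _box_mask(shape, x0, x1, y0, y1, z0, z1) -> np.ndarray:
    """Inclusive box in canonical coordinates, scaled to ``shape``."""
    sx, sy, sz = np.asarray(shape) / np.asarray(_CANONICAL_SHAPE)
    mask = np.zeros(shape, dtype=bool)
    mask[
        int(round(x0 * sx)) : int(round(x1 * sx)) + 1,
        int(round(y0 * sy)) : int(round(y1 * sy)) + 1,
        int(round(z0 * sz)) : int(round(z1 * sz)) + 1,
    ] = True
    return mask


def _ellipsoid_mask(shape, center, semi) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    d = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return d <= 1.0


def _mirror_x(mask: np.ndarray) -> np.ndarray:
    return mask[::-1, :, :].copy()


def _shift(mask: np.ndarray, vec) -> np.ndarray:
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, v in enumerate(vec):
        v = int(v)
        n = mask.shape[ax]
        if v >= 0:
            src[ax], dst[ax] = slice(0, n - v), slice(v, n)
        else:
            src[ax], dst[ax] = slice(-v, n), slice(0, n + v)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def generate_anatomy(config: PhantomConfig) -> tuple[LabeledVolume, FroiSet]:
    """Build the labeled phantom anatomy and the ground-truth nuclei.

    Geometry guarantees, per hemisphere: truth LGN centroid superior and
    lateral to truth MGN; the pulvinar label superior/posterior to the
    geniculi; exclusion structures adjacent to (but clear of) the truth
    nuclei; and seed labels displaced from truth by ``seed_jitter_vox``.
    The LGN jitter always contains a posterior unit component so that the
    single-voxel LGN search-region dilation followed by the posterior
    two-slice trim cannot cut truth voxels out of the search region; the
    MGN jitter direction is unrestricted (its 3-voxel dilation has slack).
    """
    shape = config.grid.shape
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))

    brain = _ellipsoid_mask(shape, _scaled((19.5, 23.5, 17.5), shape), _scaled((17, 21, 15), shape))

    # right-hemisphere truth nuclei; left is the x mirror
    truth_mgn_R = _ball_mask(shape, _scaled((25, 20, 14), shape), config.mgn_size)
    truth_lgn_R = _ball_mask(shape, _scaled((29, 20, 17), shape), config.lgn_size)
    truth_mgn_L = _mirror_x(truth_mgn_R)
    truth_lgn_L = _mirror_x(truth_lgn_R)

    j = config.seed_jitter_vox
    if j == 0:
        jit_mgn_L = jit_mgn_R = jit_lgn_L = jit_lgn_R = (0, 0, 0)
    else:
        axes = [(j, 0, 0), (-j, 0, 0), (0, j, 0), (0, -j, 0), (0, 0, j), (0, 0, -j)]
        jit_mgn_L = axes[rng.integers(len(axes))]
        jit_mgn_R = axes[rng.integers(len(axes))]
        jit_lgn_L = (int(rng.integers(-1, 2)) * j, -j, 0)
        jit_lgn_R = (int(rng.integers(-1, 2)) * j, -j, 0)

    structures: dict[str, np.ndarray] = {
        "mgn_seed_L": _shift(truth_mgn_L, jit_mgn_L),
        "mgn_seed_R": _shift(truth_mgn_R, jit_mgn_R),
        "lgn_seed_L": _shift(truth_lgn_L, jit_lgn_L),
        "lgn_seed_R": _shift(truth_lgn_R, jit_lgn_R),
        "pulvinar_R": _box_mask(shape, 23, 27, 14, 17, 19, 22),
        "mediodorsal_R": _box_mask(shape, 23, 26, 24, 27, 17, 20),
        "ba41_42_R": _box_mask(shape, 33, 36, 16, 28, 10, 16) & brain,
        "ba17_18_R": _box_mask(shape, 21, 30, 4, 7, 10, 20) & brain,
        "transverse_temporal_R": _box_mask(shape, 33, 35, 29, 32, 12, 16) & brain,
        "pericalcarine_R": _box_mask(shape, 21, 25, 8, 10, 13, 18) & brain,
        "csf": _box_mask(shape, 17, 22, 22, 30, 16, 22),
        "choroid_plexus": _box_mask(shape, 18, 21, 12, 15, 16, 19),
        "cortical_gm": _box_mask(shape, 10, 29, 38, 44, 10, 24) & brain,
    }
    # bilateral lateral shells: pallidum / putamen / insular WM stacked
    # laterally, anterior to the geniculi
    for name, (x0, x1) in [("pallidum", (27, 28)), ("putamen", (29, 30)), ("insular_wm", (31, 32))]:
        m = _box_mask(shape, x0, x1, 26, 31, 13, 17) & brain
        structures[name] = m | _mirror_x(m)
    hip = _box_mask(shape, 26, 30, 12, 16, 8, 11) & brain
    structures["hippocampus"] = hip | _mirror_x(hip)
    para = _box_mask(shape, 24, 27, 13, 16, 5, 7) & brain
    structures["parahippocampal_wm"] = para | _mirror_x(para)
    for name in ["pulvinar", "mediodorsal", "ba41_42", "ba17_18", "transverse_temporal", "pericalcarine"]:
        structures[f"{name}_L"] = _mirror_x(structures[f"{name}_R"])

    # collision check: labeled structures must be pairwise disjoint, and
    # the truth nuclei may overlap nothing but their own (jittered) seed
    occupancy = np.zeros(shape, dtype=np.int16)
    for _, m in structures.items():
        occupancy += m
    if occupancy.max() > 1:
        clash = occupancy > 1
        offenders = sorted(n for n, m in structures.items() if (m & clash).any())
        raise ValueError(f"phantom structures collide: {', '.join(offenders)}")
    truths = {
        "truth_mgn_L": (truth_mgn_L, "mgn_seed_L"), "truth_mgn_R": (truth_mgn_R, "mgn_seed_R"),
        "truth_lgn_L": (truth_lgn_L, "lgn_seed_L"), "truth_lgn_R": (truth_lgn_R, "lgn_seed_R"),
    }
    for tname, (tmask, own_seed) in truths.items():
        for sname, smask in structures.items():
            if sname != own_seed and (tmask & smask).any():
                raise ValueError(f"phantom structures collide: {tname}, {sname}")
    if (truth_mgn_L & truth_lgn_L).any() or (truth_mgn_R & truth_lgn_R).any():
        raise ValueError("phantom structures collide: truth MGN, truth LGN")

    # truth voxels never become white matter (the WM compartment signal
    # must stay free of implanted source signal); unlabeled truth voxels
    # fall into the generic "brain" filler label
    truth_any = truth_mgn_L | truth_mgn_R | truth_lgn_L | truth_lgn_R
    structures["white_matter"] = (
        _box_mask(shape, 6, 33, 10, 36, 6, 28) & brain & ~(occupancy > 0) & ~truth_any
    )
    assigned = (occupancy > 0) | structures["white_matter"]
    structures["brain"] = brain & ~assigned

    label_map = {name: i + 1 for i, name in enumerate(sorted(structures))}
    labels = np.zeros(shape, dtype=np.int16)
    for name, mask in structures.items():
        labels[mask] = label_map[name]
    labeled = LabeledVolume(grid=config.grid, labels=labels, label_map=label_map)
    missing = labeled.validate_required()
    if missing:
        raise ValueError(f"phantom anatomy lost required label(s): {', '.join(missing)}")

    truth = FroiSet(
        mgn_L=truth_mgn_L, mgn_R=truth_mgn_R, lgn_L=truth_lgn_L, lgn_R=truth_lgn_R
    )
    return labeled, truth


# ---------------------------------------------------------------------------
# task BOLD


def generate_task_run(
    labels: LabeledVolume,
    truth: FroiSet,
    schedule: TrialSchedule,
    config: PhantomConfig,
    rng: np.random.Generator,
) -> BoldSeries:
    """Synthesize the acquisition-cluster volumes of one task run.

    voxel = baseline * (1 + a*c(t) + t1_offset(position)) + drift + noise,
    where ``a`` is the task amplitude for structures matching the trial's
    condition and ``c(t)`` is 1 on every volume of the cluster following
    that trial.
    """
    shape = labels.grid.shape
    n_vols = schedule.n_volumes
    brain = labels.brain_mask
    amp = config.baseline * config.task_amplitude_pct / 100.0

    aud_ind = schedule.condition_indicator(AUDITORY)
    vis_ind = schedule.condition_indicator(VISUAL)
    t1 = np.zeros(n_vols)
    for pos, off in enumerate(config.t1_offsets):
        t1 += off * schedule.cluster_position_indicator(pos)

    timestamps = schedule.volume_timestamps()
    drift = config.task_drift_amplitude * np.sin(
        2 * np.pi * 0.005 * timestamps + rng.uniform(0, 2 * np.pi)
    )

    aud_mask = labels.union_mask(AUDITORY_TASK_LABELS) | truth.mgn_L | truth.mgn_R
    vis_mask = labels.union_mask(VISUAL_TASK_LABELS) | truth.lgn_L | truth.lgn_R

    data = np.zeros(shape + (n_vols,), dtype=np.float64)
    base = config.baseline * (1.0 + t1) + drift
    data[brain] = base
    data[aud_mask] += amp * aud_ind
    data[vis_mask] += amp * vis_ind
    if config.noise_sd > 0:
        data[brain] += rng.normal(0.0, config.noise_sd, size=(int(brain.sum()), n_vols))
    return BoldSeries(
        grid=labels.grid, data=data, tr_s=schedule.site.tr_s,
        timestamps_s=timestamps, kind="task-sparse", site=schedule.site,
    )


# ---------------------------------------------------------------------------
# resting-state BOLD


def _bandlimited(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float], k: int = 1) -> np.ndarray:
    """k unit-variance band-limited series, shape (k, n)."""
    nyq = fs / 2.0
    lo, hi = band
    sos = sps.butter(2, [lo / nyq, min(hi / nyq, 0.99)], btype="band", output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal((k, n)), axis=1)
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_rest_run(
    labels: LabeledVolume,
    truth: FroiSet,
    config: PhantomConfig,
    rng: np.random.Generator,
) -> BoldSeries:
    """Continuous resting run with seeded thalamocortical covariance.

    Each structure carries an independent band-limited latent source,
    except: auditory-cortex labels share one source, visual-cortex labels
    another; truth MGN mixes the auditory-cortex source at correlation
    ``rest_coupling_r`` and truth LGN the visual-cortex source; the
    cross-pairings have zero latent coupling.  WM, CSF and a global source
    are mixed into all tissue voxels as confounds; white noise on top.
    """
    fs = 1.0 / config.site.tr_s
    n_vols = int(round(config.rest_run_dur_s / config.site.tr_s))
    r = config.rest_coupling_r

    s_ac, s_vc, u_mgn, u_lgn, g, w, c = _bandlimited(rng, n_vols, fs, config.rest_band_hz, k=7)
    mgn_latent = r * s_ac + np.sqrt(1 - r * r) * u_mgn
    lgn_latent = r * s_vc + np.sqrt(1 - r * r) * u_lgn

    brain = labels.brain_mask
    shape = labels.grid.shape
    sources: list[tuple[np.ndarray, np.ndarray, float]] = [
        (labels.union_mask(AUDITORY_TASK_LABELS), s_ac, config.rest_struct_sd),
        (labels.union_mask(VISUAL_TASK_LABELS), s_vc, config.rest_struct_sd),
        (truth.mgn_L | truth.mgn_R, mgn_latent, config.rest_struct_sd),
        (truth.lgn_L | truth.lgn_R, lgn_latent, config.rest_struct_sd),
        (labels.mask("white_matter"), w, config.rest_compartment_sd),
        (labels.mask("csf"), c, config.rest_compartment_sd),
    ]
    # independent latent per remaining anatomical structure; the generic
    # "brain" filler deliberately gets none — a shared filler source would
    # induce spurious connectivity between any two ROIs that pick up
    # filler voxels (dilated cortex ROIs, fROI halo voxels)
    other = [
        "pulvinar_L", "pulvinar_R", "mediodorsal_L", "mediodorsal_R",
        "putamen", "pallidum", "hippocampus", "parahippocampal_wm",
        "insular_wm", "choroid_plexus", "cortical_gm",
        "mgn_seed_L", "mgn_seed_R", "lgn_seed_L", "lgn_seed_R",
    ]
    # truth voxels carry only their coupled latent: exclude them from the
    # source masks of whatever label they happen to sit in (seed / filler)
    truth_any = truth.mgn_L | truth.mgn_R | truth.lgn_L | truth.lgn_R
    indep = _bandlimited(rng, n_vols, fs, config.rest_band_hz, k=len(other))
    for name, series in zip(other, indep):
        sources.append((labels.mask(name) & ~truth_any, series, config.rest_struct_sd))

    data = np.zeros(shape + (n_vols,), dtype=np.float32)
    confound = (
        config.rest_global_sd * g
        + config.rest_confound_mix * w
        + config.rest_confound_mix * c
    )
    data[brain] = (config.baseline + confound).astype(np.float32)
    for mask, series, sd in sources:
        m = mask & brain
        if m.any():
            data[m] += (sd * series).astype(np.float32)
    if config.noise_sd > 0:
        data[brain] += rng.normal(0.0, config.noise_sd, size=(int(brain.sum()), n_vols)).astype(
            np.float32
        )
    return BoldSeries(
        grid=labels.grid, data=data, tr_s=config.site.tr_s,
        timestamps_s=np.arange(n_vols) * config.site.tr_s,
        kind="rest-continuous", site=config.site,
    )


# ---------------------------------------------------------------------------
# motion and eyes


def generate_motion(
    config: PhantomConfig,
    n_volumes: int,
    tr_s: float,
    rng: np.random.Generator,
    with_spikes: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Motion-parameter table plus the injected spike volume indices.

    Smooth low-amplitude drift (low-pass filtered noise) on all six
    parameters, with Poisson-placed single-volume displacement spikes on a
    random translation axis.  Spike magnitude defaults to 1 mm so the
    low-pass-filtered framewise displacement clears the 0.07587 mm
    threshold only around spikes.
    """
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    fs = 1.0 / tr_s
    motion = np.zeros((n_volumes, 6))
    if config.motion_drift_mm > 0 and n_volumes > 18:
        sos = sps.butter(2, min(0.03 / (fs / 2), 0.9), btype="low", output="sos")
        drift = sps.sosfiltfilt(sos, rng.standard_normal((6, n_volumes)), axis=1)
        sd = drift.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        drift /= sd
        scale = np.array([config.motion_drift_mm] * 3 + [config.motion_drift_mm / 50.0] * 3)
        motion = (drift * scale[:, None]).T
    spikes = np.array([], dtype=int)
    if with_spikes and config.motion_spike_rate_per_min > 0:
        dur_min = n_volumes * tr_s / 60.0
        n_spikes = rng.poisson(config.motion_spike_rate_per_min * dur_min)
        if n_spikes > 0 and n_volumes > 8:
            spikes = np.sort(
                rng.choice(np.arange(4, n_volumes - 4), size=min(n_spikes, n_volumes // 10), replace=False)
            )
            for v in spikes:
                motion[v, rng.integers(0, 3)] += config.motion_spike_mm
    return pd.DataFrame(motion, columns=cols), spikes


def generate_eye_closures(
    config: PhantomConfig, run_dur_s: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Eye-closure intervals with durations straddling the 3 s rule."""
    onsets, durations = [], []
    t = float(rng.exponential(60.0 / max(config.eye_closure_rate_per_min, 1e-9)))
    while t < run_dur_s - 10.0 and config.eye_closure_rate_per_min > 0:
        dur = float(rng.uniform(1.0, 2.5)) if rng.random() < 0.5 else float(rng.uniform(3.5, 8.0))
        onsets.append(round(t, 3))
        durations.append(round(min(dur, run_dur_s - t), 3))
        t += dur + float(rng.exponential(60.0 / config.eye_closure_rate_per_min))
    return pd.DataFrame({"onset": onsets, "duration": durations})


# ---------------------------------------------------------------------------
# whole dataset


def generate_dataset(
    config: PhantomConfig, include_task: bool = True, include_rest: bool = True
) -> PhantomDataset:
    """One synthetic participant, fully reproducible from (config, seed).

    ``include_task`` / ``include_rest`` skip generating the corresponding
    runs when an analysis only needs one modality; the data produced for
    either modality is identical regardless of the flags.
    """
    labels, truth = generate_anatomy(config)
    task_runs, task_schedules, task_motion = [], [], []
    for i in range(config.n_task_runs if include_task else 0):
        sched = build_run_schedule(config.site, seed=int(np.random.SeedSequence([config.seed, 7, i]).generate_state(1)[0] % (2**31)))
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11, i]))
        task_runs.append(generate_task_run(labels, truth, sched, config, rng))
        mot, _ = generate_motion(config, sched.n_volumes, config.site.tr_s, rng, with_spikes=False)
        task_schedules.append(sched)
        task_motion.append(mot)
    rest_runs, rest_motion, rest_spikes, eyes = [], [], [], []
    for i in range(config.n_rest_runs if include_rest else 0):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13, i]))
        run = generate_rest_run(labels, truth, config, rng)
        mot, spk = generate_motion(config, run.n_volumes, config.site.tr_s, rng)
        rest_runs.append(run)
        rest_motion.append(mot)
        rest_spikes.append(spk)
        eyes.append(generate_eye_closures(config, config.rest_run_dur_s, rng))
    return PhantomDataset(
        config=config, labels=labels, truth_froi=truth,
        task_runs=task_runs, task_schedules=task_schedules, task_motion=task_motion,
        rest_runs=rest_runs, rest_motion=rest_motion, rest_spike_volumes=rest_spikes,
        eye_closures=eyes,
    )


def write_phantom_bids(dataset: PhantomDataset, out_dir, subject: str = "01") -> None:
    """Write a BIDS-flavored directory tree for one phantom participant."""
    import json
    from pathlib import Path

    from . import io as tio
    from .schedule import schedule_events

    base = Path(out_dir) / f"sub-{subject}" / "ses-01"
    anat = base / "anat"
    func = base / "func"
    anat.mkdir(parents=True, exist_ok=True)
    func.mkdir(parents=True, exist_ok=True)
    tio.save_labeled_volume(
        anat / f"sub-{subject}_ses-01_dseg.nii.gz",
        dataset.labels,
        anat / f"sub-{subject}_ses-01_dseg.json",
    )
    for i, (run, sched, mot) in enumerate(
        zip(dataset.task_runs, dataset.task_schedules, dataset.task_motion), start=1
    ):
        stem = f"sub-{subject}_ses-01_task-tl_run-{i:02d}"
        tio.save_bold(func / f"{stem}_bold.nii.gz", run)
        tio.write_events_tsv(func / f"{stem}_events.tsv", schedule_events(sched))
        tio.write_motion_tsv(func / f"{stem}_motion.tsv", mot)
    for i, (run, mot, eye) in enumerate(
        zip(dataset.rest_runs, dataset.rest_motion, dataset.eye_closures), start=1
    ):
        stem = f"sub-{subject}_ses-01_task-rest_run-{i:02d}"
        tio.save_bold(func / f"{stem}_bold.nii.gz", run)
        tio.write_motion_tsv(func / f"{stem}_motion.tsv", mot)
        tio.write_eye_closures_tsv(func / f"{stem}_eyeclosure.tsv", eye)
    tio.site_config_to_json(base / "site.json", dataset.config.site)


def load_phantom_bids(out_dir, subject: str = "01") -> PhantomDataset:
    """Reload a participant written by :func:`write_phantom_bids`."""
    import json
    from pathlib import Path

    from . import io as tio
    from .schedule import schedule_from_events

    base = Path(out_dir) / f"sub-{subject}" / "ses-01"
    site = tio.site_config_from_json(base / "site.json")
    anat = base / "anat"
    func = base / "func"
    label_map = json.loads((anat / f"sub-{subject}_ses-01_dseg.json").read_text())
    labels = tio.load_labeled_volume(anat / f"sub-{subject}_ses-01_dseg.nii.gz", label_map)
    config = PhantomConfig(grid=labels.grid, site=site)

    task_runs, task_schedules, task_motion = [], [], []
    for ev_path in sorted(func.glob(f"sub-{subject}_ses-01_task-tl_run-*_events.tsv")):
        stem = ev_path.name[: -len("_events.tsv")]
        sched = schedule_from_events(tio.read_events_tsv(ev_path), site)
        task_schedules.append(sched)
        task_runs.append(
            tio.load_bold(
                func / f"{stem}_bold.nii.gz", site.tr_s, "task-sparse",
                timestamps_s=sched.volume_timestamps(), site=site, grid=labels.grid,
            )
        )
        task_motion.append(tio.read_motion_tsv(func / f"{stem}_motion.tsv"))
    rest_runs, rest_motion, eyes = [], [], []
    for mot_path in sorted(func.glob(f"sub-{subject}_ses-01_task-rest_run-*_motion.tsv")):
        stem = mot_path.name[: -len("_motion.tsv")]
        rest_runs.append(
            tio.load_bold(
                func / f"{stem}_bold.nii.gz", site.tr_s, "rest-continuous",
                site=site, grid=labels.grid,
            )
        )
        rest_motion.append(tio.read_motion_tsv(mot_path))
        eyes.append(tio.read_eye_closures_tsv(func / f"{stem}_eyeclosure.tsv"))
    empty = np.zeros(labels.grid.shape, dtype=bool)
    return PhantomDataset(
        config=config, labels=labels,
        truth_froi=FroiSet(empty, empty.copy(), empty.copy(), empty.copy()),
        task_runs=task_runs, task_schedules=task_schedules, task_motion=task_motion,
        rest_runs=rest_runs, rest_motion=rest_motion,
        rest_spike_volumes=[np.array([], dtype=int)] * len(rest_runs),
        eye_closures=eyes,
    )
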