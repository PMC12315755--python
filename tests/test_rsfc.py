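"""Resting-state post-processing and connectivity estimation."""

import numpy as np
import pandas as pd
import pytest

from tlfmri.core import BoldSeries, VolumeGrid
from tlfmri.rsfc import (
    ProcessedRestRun,
    bandpass_with_interpolation,
    benchmark_roi_sets,
    detrend_center,
    dice,
    edge_trim_volumes,
    mode1000,
    roi_pair_connectivity,
    seed_map,
    selectivity_contrasts,
)


def _rest_bold(data, tr=0.85):
    return BoldSeries(
        grid=VolumeGrid(data.shape[:3]), data=data, tr_s=tr,
        timestamps_s=np.arange(data.shape[3]) * tr, kind="rest-continuous",
    )


# ---------------------------------------------------------------------------
# mode-1000 normalization


def test_mode1000_constant_and_scaling():
    brain = np.ones((4, 4, 4), dtype=bool)
    out = mode1000(_rest_bold(np.full((4, 4, 4, 3), 500.0)), brain)
    np.testing.assert_allclose(out.data, 1000.0)
    out2 = mode1000(_rest_bold(np.full((4, 4, 4, 3), 2000.0)), brain)
    np.testing.assert_allclose(out2.data, 1000.0)  # scale 0.5


def test_mode1000_matches_histogram_oracle():
    rng = np.random.default_rng(0)
    vals = np.r_[np.full(300, 830.0), rng.integers(500, 1500, 700).astype(float)]
    rng.shuffle(vals)
    data = vals.reshape(10, 10, 10, 1)
    brain = np.ones((10, 10, 10), dtype=bool)
    ints, counts = np.unique(np.rint(vals).astype(int), return_counts=True)
    oracle_mode = ints[np.argmax(counts)]
    out = mode1000(_rest_bold(data), brain)
    np.testing.assert_allclose(out.data, data * (1000.0 / oracle_mode))


def test_mode1000_nonpositive_mode_errors():
    with pytest.raises(ValueError):
        mode1000(_rest_bold(np.zeros((4, 4, 4, 2))), np.ones((4, 4, 4), bool))


# ---------------------------------------------------------------------------
# detrending


def test_detrend_removes_lines_and_recovers_signal():
    n = 200
    t = np.arange(n, dtype=float)
    np.testing.assert_allclose(detrend_center(3.0 + 0.5 * t), 0.0, atol=1e-9)
    np.testing.assert_allclose(detrend_center(np.full(n, 7.0)), 0.0, atol=1e-12)
    sine = np.sin(2 * np.pi * 7 * t / n)
    mixed = 2.0 - 0.3 * t + sine
    # the sinusoid is recovered up to its own tiny trend/mean projection
    resid = detrend_center(mixed) - detrend_center(sine)
    assert np.abs(resid).max() < 1e-10


# ---------------------------------------------------------------------------
# band-pass with interpolation


@pytest.mark.parametrize("tr, n_trim", [(0.85, 26), (0.80, 28)])
def test_edge_trim_volume_counts(tr, n_trim):
    """22 s of edge trim: 26 volumes at TR 0.85, 28 at TR 0.80."""
    assert edge_trim_volumes(tr, 22.0) == n_trim


def _attenuation(freq_hz, tr=0.8, n=2400):
    """Gain of the band-pass at one frequency, measured in the central
    half of the trimmed output (clear of residual edge transients)."""
    t = np.arange(n) * tr
    x = np.sin(2 * np.pi * freq_hz * t)
    out, _ = bandpass_with_interpolation(x, np.ones(n, bool), tr)
    mid = out[out.shape[0] // 4 : 3 * out.shape[0] // 4]
    return np.abs(mid).max()


def test_bandpass_frequency_response():
    assert _attenuation(0.04) == pytest.approx(1.0, abs=0.05)  # passband
    assert _attenuation(0.5) < 0.10  # above the band
    assert _attenuation(0.004) < 0.10  # below the band


def test_bandpass_zero_phase_peak_preserved():
    tr = 0.8
    n = 600
    x = np.exp(-0.5 * ((np.arange(n) - 300) / 12.0) ** 2)  # symmetric pulse
    out, _ = bandpass_with_interpolation(x, np.ones(n, bool), tr)
    n_trim = edge_trim_volumes(tr)
    assert np.argmax(out) + n_trim == 300


def test_bandpass_interpolation_recensors_and_errors():
    tr = 0.8
    n = 400
    rng = np.random.default_rng(1)
    x = rng.normal(size=n)
    keep = np.ones(n, bool)
    keep[100:110] = False
    out, keep_trim = bandpass_with_interpolation(x, keep, tr)
    n_trim = edge_trim_volumes(tr)
    assert out.shape[0] == n - 2 * n_trim
    np.testing.assert_array_equal(keep_trim, keep[n_trim : n - n_trim])
    with pytest.raises(ValueError):
        bandpass_with_interpolation(x, np.zeros(n, bool), tr)


def test_bandpass_interpolation_bridges_gap_linearly():
    """The filter input over a censored gap is the linear bridge between
    the neighbouring kept samples (checked via a pure low-freq signal)."""
    tr = 0.8
    n = 800
    t = np.arange(n) * tr
    x = np.sin(2 * np.pi * 0.02 * t)
    keep = np.ones(n, bool)
    keep[400:403] = False
    corrupted = x.copy()
    corrupted[400:403] = 99.0  # censored values must not matter
    out_a, _ = bandpass_with_interpolation(corrupted, keep, tr)
    bridge = x.copy()
    bridge[400:403] = np.interp([400, 401, 402], [399, 403], [x[399], x[403]])
    out_b, _ = bandpass_with_interpolation(bridge, np.ones(n, bool), tr)
    np.testing.assert_allclose(out_a, out_b, atol=1e-9)


# ---------------------------------------------------------------------------
# dice


def test_dice_formula():
    a = np.zeros((5, 5, 5), bool)
    b = np.zeros((5, 5, 5), bool)
    a[:2, :2, :2] = True
    assert dice(a, a) == 1.0
    assert dice(a, b) == 0.0  # one empty
    assert dice(b, b) == 0.0  # both empty, by convention
    a = np.zeros(60, bool).reshape(4, 3, 5)
    b = np.zeros(60, bool).reshape(4, 3, 5)
    a.flat[:10] = True
    b.flat[:30] = True
    assert dice(a, b) == pytest.approx(2 * 10 / (10 + 30))


# ---------------------------------------------------------------------------
# connectivity tables and statistics


def _processed_run(rng, n_t=120, shape=(6, 6, 2), seed_signal=None):
    data = rng.normal(size=shape + (n_t,))
    if seed_signal is not None:
        data[2, 2, 0] += seed_signal
        data[3, 3, 1] += seed_signal
    bold = _rest_bold(data, tr=0.8)
    return ProcessedRestRun(
        bold=bold,
        keep=np.ones(n_t, bool),
        nuisance=rng.normal(size=(n_t, 3)),
        brain_mask=np.ones(shape, bool),
    )


def test_roi_pair_identical_masks_give_unity():
    rng = np.random.default_rng(2)
    run = _processed_run(rng)
    m = np.zeros((6, 6, 2), bool)
    m[1:3, 1:3, 0] = True
    masks = {"mgn_L": m, "mgn_R": m, "lgn_L": m, "lgn_R": m}
    cortex = {"ac_L": m, "ac_R": m, "vc_L": m, "vc_R": m}
    table = roi_pair_connectivity([run], masks, cortex)
    assert set(table["pair"]) == {"mgn_ac", "mgn_vc", "lgn_ac", "lgn_vc"}
    np.testing.assert_allclose(table["value"], 1.0, atol=1e-9)


def test_roi_pair_empty_roi_errors():
    rng = np.random.default_rng(3)
    run = _processed_run(rng)
    m = np.zeros((6, 6, 2), bool)
    m[1, 1, 0] = True
    empty = np.zeros((6, 6, 2), bool)
    with pytest.raises(ValueError, match="mgn_L"):
        roi_pair_connectivity(
            [run],
            {"mgn_L": empty, "mgn_R": m, "lgn_L": m, "lgn_R": m},
            {"ac_L": m, "ac_R": m, "vc_L": m, "vc_R": m},
        )


def _participant_table(values_by_pair, n=8, source="tl", jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        for pair, v in values_by_pair.items():
            rows.append(
                {"participant": f"p{i}", "pair": pair, "roi_source": source,
                 "value": v + jitter * rng.normal()}
            )
    return pd.DataFrame(rows)


def test_selectivity_contrasts_and_fdr():
    table = _participant_table(
        {"mgn_ac": 0.4, "mgn_vc": 0.0, "lgn_ac": 0.0, "lgn_vc": 0.4}, jitter=0.05
    )
    out = selectivity_contrasts(table)
    assert set(out["contrast"]) == {
        "mgn_ac_gt_mgn_vc", "mgn_ac_gt_lgn_ac", "lgn_vc_gt_lgn_ac", "lgn_vc_gt_mgn_vc",
    }
    assert (out["mean_diff"] > 0.2).all()
    assert out["significant"].all()
    # Benjamini-Hochberg step-up oracle on the returned p-values
    p = np.sort(out["p"].to_numpy())
    m = len(p)
    passed = p <= 0.05 * (np.arange(1, m + 1) / m)
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    assert out["significant"].sum() == (k if k else 0) or (out["p_fdr"] <= 0.05).sum() == out["significant"].sum()


def test_one_sample_t_matches_textbook_formula():
    vals = np.array([0.1, 0.3, 0.2, 0.25, 0.15])
    rows = []
    for i, v in enumerate(vals):
        rows += [
            {"participant": f"p{i}", "pair": "mgn_ac", "roi_source": "tl", "value": v},
            {"participant": f"p{i}", "pair": "mgn_vc", "roi_source": "tl", "value": 0.0},
            {"participant": f"p{i}", "pair": "lgn_ac", "roi_source": "tl", "value": 0.0},
            {"participant": f"p{i}", "pair": "lgn_vc", "roi_source": "tl", "value": v / 2},
        ]
    out = selectivity_contrasts(pd.DataFrame(rows))
    t_row = out[out["contrast"] == "mgn_ac_gt_mgn_vc"].iloc[0]
    expected_t = vals.mean() / (vals.std(ddof=1) / np.sqrt(len(vals)))
    assert t_row["t"] == pytest.approx(expected_t, abs=1e-10)


def test_benjamini_hochberg_all_pass_case():
    """p = (.01, .02, .03, .04) with m = 4 all pass at alpha = .05."""
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], alpha=0.05, method="fdr_bh")
    # independent step-up oracle
    p = np.array([0.01, 0.02, 0.03, 0.04])
    crit = 0.05 * np.arange(1, 5) / 4
    k = np.max(np.nonzero(p <= crit)[0]) + 1
    assert k == 4
    assert reject.all()


def test_benchmark_roi_sets():
    tl = _participant_table({"mgn_ac": 0.4, "mgn_vc": 0.0, "lgn_ac": 0.0, "lgn_vc": 0.4})
    same = tl.assign(roi_source="alt")
    out = benchmark_roi_sets(pd.concat([tl, same]), "tl", ["alt"])
    assert (out["mean_diff"] == 0.0).all()
    worse = _participant_table(
        {"mgn_ac": 0.25, "mgn_vc": 0.0, "lgn_ac": 0.0, "lgn_vc": 0.25},
        source="shifted", jitter=0.03, seed=5,
    )
    out2 = benchmark_roi_sets(pd.concat([tl, worse]), "tl", ["shifted"])
    assert (out2["mean_diff"] > 0.1).all()
    missing = worse[worse["participant"] != "p0"]
    with pytest.raises(ValueError, match="mismatch"):
        benchmark_roi_sets(pd.concat([tl, missing]), "tl", ["shifted"])


def test_seed_map_high_inside_seed():
    rng = np.random.default_rng(4)
    sig = rng.normal(size=200)
    run = _processed_run(rng, n_t=200, seed_signal=5.0 * sig)
    seed_l = np.zeros((6, 6, 2), bool)
    seed_l[2, 2, 0] = True
    seed_r = np.zeros((6, 6, 2), bool)
    seed_r[3, 3, 1] = True
    m = seed_map([run], seed_l, seed_r)
    assert m[2, 2, 0] > 0.6  # averaged with the other hemisphere's map
    assert abs(m[0, 0, 0]) < 0.4
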