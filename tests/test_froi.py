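"""Partial correlation, coactivation thresholding, cluster extraction, QC."""

import numpy as np
import pytest

from tlfmri.core import BoldSeries, VolumeGrid
from tlfmri.froi_extract import (
    CoactivationResult,
    FroiSet,
    coactivation_maps,
    largest_cluster,
    local_wm_series,
    partial_correlation,
    qc_flags,
    threshold_and_exclude,
)
from tlfmri.search_region import ThalamicSearchRegion

from conftest import make_minimal_labels


# ---------------------------------------------------------------------------
# partial correlation


def test_partial_correlation_self_is_one():
    x = np.random.default_rng(0).normal(size=30)
    assert partial_correlation(x, x) == pytest.approx(1.0)


def test_partial_correlation_without_nuisance_is_pearson():
    from scipy import stats

    rng = np.random.default_rng(1)
    x, y = rng.normal(size=(2, 40))
    assert partial_correlation(x, y) == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)


def test_partial_correlation_matches_residual_oracle():
    """200 random instances: matches Pearson correlation of explicit OLS
    residuals to 1e-12."""
    rng = np.random.default_rng(2)
    for _ in range(200):
        n = 50
        Z = rng.normal(size=(n, 3))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        r = partial_correlation(x, y, Z)
        Z1 = np.column_stack([np.ones(n), Z])
        H = Z1 @ np.linalg.solve(Z1.T @ Z1, Z1.T)
        rx, ry = x - H @ x, y - H @ y
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(oracle, abs=1e-12)


def test_partial_correlation_degenerate_and_short():
    x = np.random.default_rng(3).normal(size=30)
    with pytest.raises(ValueError, match="degenerate"):
        partial_correlation(x, x.copy(), nuisance=x[:, None])  # nuisance contains x
    with pytest.raises(ValueError, match="samples"):
        partial_correlation(np.ones(4), np.ones(4), np.random.default_rng(0).normal(size=(4, 3)))


# ---------------------------------------------------------------------------
# coactivation maps


def _tsr_from(mask, nucleus="mgn", hemi="L"):
    return ThalamicSearchRegion(hemisphere=hemi, nucleus=nucleus, mask=mask)


def _task_bold(data, tr=0.85):
    return BoldSeries(
        grid=VolumeGrid(data.shape[:3]), data=data, tr_s=tr,
        timestamps_s=np.arange(data.shape[3], dtype=float), kind="rest-continuous",
    )


def test_coactivation_maps_identify_reference_signal():
    rng = np.random.default_rng(4)
    n_t = 60
    ac = rng.normal(size=n_t)
    vc = rng.normal(size=n_t)
    data = rng.normal(0, 0.01, size=(8, 8, 3, n_t))
    tsr_mask = np.zeros((8, 8, 3), dtype=bool)
    tsr_mask[2:6, 2:6, 1] = True
    data[3, 3, 1] += ac
    data[4, 4, 1] += vc
    res = coactivation_maps(_task_bold(data), _tsr_from(tsr_mask), ac, vc,
                            nuisance=rng.normal(size=(n_t, 2)))
    assert res.r_ac[3, 3, 1] > 0.99
    assert res.r_vc[4, 4, 1] > 0.99
    assert abs(res.r_ac[4, 4, 1]) < 0.5
    assert np.isnan(res.r_ac[0, 0, 0])  # outside the TSR


def test_coactivation_maps_invariant_to_common_permutation():
    rng = np.random.default_rng(5)
    n_t = 40
    ac = rng.normal(size=n_t)
    vc = rng.normal(size=n_t)
    data = rng.normal(size=(6, 6, 3, n_t))
    nuis = rng.normal(size=(n_t, 2))
    tsr_mask = np.zeros((6, 6, 3), dtype=bool)
    tsr_mask[1:5, 1:5, 1] = True
    perm = rng.permutation(n_t)
    a = coactivation_maps(_task_bold(data), _tsr_from(tsr_mask), ac, vc, nuis)
    b = coactivation_maps(
        _task_bold(data[..., perm]), _tsr_from(tsr_mask), ac[perm], vc[perm], nuis[perm]
    )
    np.testing.assert_allclose(a.r_ac[tsr_mask], b.r_ac[tsr_mask], atol=1e-10)
    np.testing.assert_allclose(a.r_vc[tsr_mask], b.r_vc[tsr_mask], atol=1e-10)


def test_coactivation_degenerate_voxel_excluded():
    rng = np.random.default_rng(6)
    n_t = 40
    ac = rng.normal(size=n_t)
    data = rng.normal(size=(5, 5, 3, n_t))
    tsr_mask = np.zeros((5, 5, 3), dtype=bool)
    tsr_mask[1:4, 1:4, 1] = True
    data[2, 2, 1] = 0.0  # constant voxel -> zero residual variance
    with pytest.warns(UserWarning, match="degenerate"):
        res = coactivation_maps(_task_bold(data), _tsr_from(tsr_mask), ac, ac.copy(), None)
    assert np.isnan(res.r_ac[2, 2, 1])


# ---------------------------------------------------------------------------
# local WM shell


def test_local_wm_shell_oracle():
    from tlfmri.core import LabeledVolume, dilate

    labeled = make_minimal_labels((20, 20, 20))
    lbl = labeled.labels.copy()
    wm_id = labeled.label_map["white_matter"]
    lbl[lbl == wm_id] = labeled.label_map["brain"]
    tsr_mask = np.zeros((20, 20, 20), dtype=bool)
    tsr_mask[9:11, 9:11, 9:11] = True
    # one WM voxel inside the 1..5 shell, one exactly 6 dilations away
    lbl[12, 10, 10] = wm_id  # 2 voxels from the TSR
    lbl[16, 10, 10] = wm_id  # 6 voxels from the TSR (excluded)
    labeled = LabeledVolume(labeled.grid, lbl, labeled.label_map)
    data = np.zeros((20, 20, 20, 3))
    data[12, 10, 10] = [1.0, 2.0, 3.0]
    data[16, 10, 10] = 99.0
    sig = local_wm_series(_task_bold(data), labeled, tsr_mask)
    np.testing.assert_allclose(sig, [1.0, 2.0, 3.0])
    # adjacent WM (distance exactly 1) is included
    lbl2 = lbl.copy()
    lbl2[11, 10, 10] = wm_id
    labeled2 = LabeledVolume(labeled.grid, lbl2, labeled.label_map)
    data[11, 10, 10] = [3.0, 4.0, 5.0]
    sig2 = local_wm_series(_task_bold(data), labeled2, tsr_mask)
    np.testing.assert_allclose(sig2, [2.0, 3.0, 4.0])  # mean of the two shell voxels


def test_local_wm_falls_back_to_global():
    labeled = make_minimal_labels((16, 16, 16))
    tsr_mask = np.zeros((16, 16, 16), dtype=bool)
    tsr_mask[14, 14, 14] = True  # more than 5 voxels from the single WM voxel
    data = np.random.default_rng(0).normal(size=(16, 16, 16, 3))
    wm_vox = tuple(np.argwhere(labeled.mask("white_matter"))[0])
    with pytest.warns(UserWarning, match="global WM"):
        sig = local_wm_series(_task_bold(data), labeled, tsr_mask)
    np.testing.assert_allclose(sig, data[wm_vox])


# ---------------------------------------------------------------------------
# thresholding and dual exclusion


def _coact_result(r_ac, r_vc, tsr_mask, nucleus="mgn"):
    return CoactivationResult(tsr=_tsr_from(tsr_mask, nucleus=nucleus), r_ac=r_ac, r_vc=r_vc)


def test_threshold_fraction_arithmetic():
    """TSRs of 64 voxels per hemisphere with target 32 keep exactly half."""
    shape = (10, 10, 4)
    tsr_mask = np.zeros(shape, dtype=bool)
    tsr_mask[1:9, 1:9, 1] = True  # 64 voxels
    rng = np.random.default_rng(7)
    r_ac = np.full(shape, np.nan)
    r_vc = np.full(shape, np.nan)
    # anti-aligned maps: the AC-top half is the VC-bottom half, so the two
    # kept sets are spatially disjoint and dual exclusion removes nothing
    vals = rng.permutation(64) / 64.0
    r_ac[tsr_mask] = vals
    r_vc[tsr_mask] = -vals
    res = threshold_and_exclude(_coact_result(r_ac, r_vc, tsr_mask), "mgn", 64.0)
    assert res.threshold_fraction == pytest.approx(0.5)
    assert res.kept_ac.sum() == 32
    assert res.kept_vc.sum() == 32
    # sort-and-cut oracle: kept values are exactly the 32 largest
    kept_vals = np.sort(r_ac[res.kept_ac])
    oracle = np.sort(np.sort(r_ac[tsr_mask])[::-1][:32])
    np.testing.assert_allclose(kept_vals, oracle)


def test_dual_exclusion_removes_shared_voxels():
    shape = (6, 6, 3)
    tsr_mask = np.zeros(shape, dtype=bool)
    tsr_mask[1:5, 1:5, 1] = True
    r = np.full(shape, np.nan)
    r[tsr_mask] = np.linspace(0, 1, 16)
    # identical maps: every kept voxel is shared -> both empty after
    res = threshold_and_exclude(_coact_result(r, r.copy(), tsr_mask), "lgn", 32.0)
    assert res.kept_ac.sum() == 0 and res.kept_vc.sum() == 0
    # spatially disjoint kept maps: unchanged by exclusion
    vals = np.arange(16, dtype=float)
    r2 = np.full(shape, np.nan)
    r2[tsr_mask] = vals
    r3 = np.full(shape, np.nan)
    r3[tsr_mask] = vals[::-1]
    res2 = threshold_and_exclude(_coact_result(r2, r3, tsr_mask), "lgn", 40.0)
    # fraction 0.5 -> top 8 of each; anti-aligned maps keep opposite halves
    assert res2.kept_ac.sum() == 8 and res2.kept_vc.sum() == 8
    assert not (res2.kept_ac & res2.kept_vc).any()


def test_threshold_fraction_caps_at_one():
    shape = (5, 5, 3)
    tsr_mask = np.zeros(shape, dtype=bool)
    tsr_mask[1:4, 1:4, 1] = True
    r_ac = np.where(tsr_mask, 0.5, np.nan)
    r_vc = np.where(tsr_mask, -0.5, np.nan)
    res = threshold_and_exclude(_coact_result(r_ac, r_vc, tsr_mask), "mgn", 9.0)
    assert res.threshold_fraction == 1.0


# ---------------------------------------------------------------------------
# largest cluster


def _flood_fill_components(mask):
    """Brute-force 26-connected components."""
    visited = np.zeros_like(mask)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if visited[start]:
            continue
        stack, comp = [start], []
        visited[start] = True
        while stack:
            x, y, z = stack.pop()
            comp.append((x, y, z))
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        n = (x + dx, y + dy, z + dz)
                        if all(0 <= n[i] < mask.shape[i] for i in range(3)) and mask[n] and not visited[n]:
                            visited[n] = True
                            stack.append(n)
        comps.append(set(comp))
    return comps


def test_largest_cluster_matches_flood_fill():
    rng = np.random.default_rng(8)
    for _ in range(10):
        mask = rng.random((10, 10, 10)) < 0.08
        if not mask.any():
            continue
        comps = _flood_fill_components(mask)
        best = max(comps, key=len)
        got = largest_cluster(mask)
        if sum(len(c) == len(best) for c in comps) == 1:  # unique size winner
            assert {tuple(v) for v in np.argwhere(got)} == best


def test_largest_cluster_sizes_and_ties():
    mask = np.zeros((12, 6, 6), dtype=bool)
    mask[1:2, 1:6, 1] = True  # 5 voxels
    mask[5:6, 1:5, 1:3] = True  # 7... adjust: 4x2 = 8
    got = largest_cluster(mask)
    assert got.sum() == 8
    # equal sizes: peak coactivation decides
    tie = np.zeros((12, 6, 6), dtype=bool)
    tie[1, 1:6, 1] = True
    tie[8, 1:6, 1] = True
    r = np.zeros(tie.shape)
    r[1, 2, 1] = 0.8
    r[8, 2, 1] = 0.6
    got_tie = largest_cluster(tie, r)
    assert got_tie[1, 2, 1] and not got_tie[8, 2, 1]
    with pytest.raises(ValueError, match="QC"):
        largest_cluster(np.zeros((4, 4, 4), dtype=bool))


def test_single_voxel_cluster():
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[2, 2, 2] = True
    np.testing.assert_array_equal(largest_cluster(mask), mask)


# ---------------------------------------------------------------------------
# QC flags


def _ball(shape, center, r=1):
    out = np.zeros(shape, dtype=bool)
    x, y, z = center
    out[x - r : x + r + 1, y - r : y + r + 1, z - r : z + r + 1] = True
    return out


def test_qc_flags_clean_geometry():
    shape = (30, 20, 20)
    froi = FroiSet(
        mgn_L=_ball(shape, (10, 10, 8)), mgn_R=_ball(shape, (19, 10, 8)),
        lgn_L=_ball(shape, (6, 10, 12)), lgn_R=_ball(shape, (23, 10, 12)),
    )
    assert qc_flags(froi) == []


def test_qc_flags_inferior_and_medial():
    shape = (30, 20, 20)
    froi = FroiSet(
        mgn_L=_ball(shape, (6, 10, 12)), mgn_R=_ball(shape, (23, 10, 12)),
        lgn_L=_ball(shape, (10, 10, 8)), lgn_R=_ball(shape, (19, 10, 8)),
    )
    flags = qc_flags(froi)
    assert "LGN_INFERIOR_L" in flags and "LGN_INFERIOR_R" in flags
    assert "LGN_MEDIAL_L" in flags and "LGN_MEDIAL_R" in flags


def test_qc_flags_asymmetry():
    shape = (30, 20, 20)
    big = np.zeros(shape, dtype=bool)
    big[8:12, 8:13, 6:9] = True  # 60 voxels
    small = np.zeros(shape, dtype=bool)
    small[19:24, 9:10, 7:9] = True  # 10 voxels
    froi = FroiSet(
        mgn_L=big, mgn_R=small,
        lgn_L=_ball(shape, (6, 10, 12)), lgn_R=_ball(shape, (23, 10, 12)),
    )
    assert "ASYMMETRY_MGN" in qc_flags(froi)


def test_qc_flags_missing_mask():
    shape = (10, 10, 10)
    froi = FroiSet(
        mgn_L=np.zeros(shape, dtype=bool), mgn_R=_ball(shape, (5, 5, 5)),
        lgn_L=_ball(shape, (2, 5, 7)), lgn_R=_ball(shape, (7, 5, 7)),
    )
    assert "FAILED_mgn_L" in qc_flags(froi)
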