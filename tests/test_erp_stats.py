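"""Repeated-measures ANOVA, extent filtering and cluster-permutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orfi_eeg import erp_stats

from .oracles import rm_anova_2x3_oracle


# ---------------------------------------------------------------------------
# rmANOVA
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(20))
def test_anova_matches_textbook_oracle(seed):
    """F, GG epsilon and GG-corrected p agree with loop-based sums of squares."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 12))
    y = rng.normal(size=(n, 2, 3)) + rng.normal(size=(n, 1, 1))
    maps = erp_stats.pointwise_rm_anova(y[..., None])
    oracle = rm_anova_2x3_oracle(y)
    for eff in ("main_condition", "main_trial", "interaction"):
        assert maps[eff].F[0] == pytest.approx(oracle[eff]["F"], abs=1e-8)
        assert maps[eff].epsilon[0] == pytest.approx(oracle[eff]["epsilon"], abs=1e-8)
        assert maps[eff].p_gg[0] == pytest.approx(oracle[eff]["p_gg"], abs=1e-8)


def test_anova_matches_pingouin():
    """Cross-check against an established implementation on one dataset."""
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(42)
    n = 10
    y = rng.normal(size=(n, 2, 3))
    maps = erp_stats.pointwise_rm_anova(y[..., None])
    rows = [
        dict(subject=s, cond=f"c{i}", trial=f"t{j}", dv=y[s, i, j])
        for s in range(n) for i in range(2) for j in range(3)
    ]
    df = pingouin.rm_anova(
        data=pd.DataFrame(rows), dv="dv", within=["cond", "trial"], subject="subject",
        detailed=True,
    )
    by_name = {"cond": "main_condition", "trial": "main_trial", "cond * trial": "interaction"}
    for _, row in df.iterrows():
        eff = by_name[row["Source"]]
        assert maps[eff].F[0] == pytest.approx(row["F"], rel=1e-6)
        if not np.isnan(row["eps"]):
            assert maps[eff].epsilon[0] == pytest.approx(row["eps"], rel=1e-6)


def test_anova_detects_pure_condition_effect():
    rng = np.random.default_rng(0)
    y = rng.normal(scale=0.01, size=(12, 2, 3))
    y[:, 0, :] += 1.0  # constant condition offset
    maps = erp_stats.pointwise_rm_anova(y[..., None])
    assert maps["main_condition"].p[0] < 1e-6
    assert maps["interaction"].p[0] > 0.01


def test_interaction_p_uniform_under_condition_shift():
    """A pure condition shift must not inflate the interaction test."""
    rng = np.random.default_rng(1)
    ps = []
    for _ in range(200):
        y = rng.normal(size=(8, 2, 3))
        y[:, 0, :] += 1.0
        maps = erp_stats.pointwise_rm_anova(y[..., None])
        ps.append(maps["interaction"].p_uncorrected[0])
    # KS test against uniform at a lenient level
    assert stats.kstest(ps, "uniform").pvalue > 0.001


def test_anova_invariant_to_subject_order():
    rng = np.random.default_rng(2)
    y = rng.normal(size=(9, 2, 3, 4))
    m1 = erp_stats.pointwise_rm_anova(y)
    m2 = erp_stats.pointwise_rm_anova(y[::-1])
    for eff in m1:
        np.testing.assert_allclose(m1[eff].F, m2[eff].F, rtol=1e-10)
        np.testing.assert_allclose(m1[eff].p, m2[eff].p, rtol=1e-8)


def test_anova_input_validation():
    with pytest.raises(ValueError):
        erp_stats.pointwise_rm_anova(np.zeros((2, 2, 3, 1)))  # too few subjects
    with pytest.raises(ValueError):
        erp_stats.pointwise_rm_anova(np.zeros((5, 3, 2, 1)))  # wrong factor shape
    bad = np.random.default_rng(0).normal(size=(5, 2, 3, 1))
    bad[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        erp_stats.pointwise_rm_anova(bad)


def test_rt_anova_reports():
    rng = np.random.default_rng(3)
    y = 470 + rng.normal(scale=20, size=(22, 2, 3))
    y[:, 0, 1] -= 12  # faster after SIMI in condition "identical"
    rep = erp_stats.rt_rm_anova(y)
    assert set(rep["omnibus"]) == {"main_condition", "main_trial", "interaction"}
    for eff in rep["omnibus"].values():
        assert 0 <= eff["partial_eta_sq"] <= 1
    ph = rep["posthoc"]
    assert len(ph) == 6
    # Bonferroni: adjusted p = raw p times the number of comparisons (capped)
    np.testing.assert_allclose(
        ph["p_bonferroni"], np.minimum(1.0, ph["p"] * 6), rtol=1e-12
    )


def test_rt_anova_zero_effect_when_cells_equal():
    y = np.tile(np.random.default_rng(4).normal(size=(10, 1, 1)), (1, 2, 3))
    rep = erp_stats.rt_rm_anova(y)
    for eff in rep["omnibus"].values():
        assert eff["F"] == pytest.approx(0.0, abs=1e-18)
        assert eff["partial_eta_sq"] == pytest.approx(0.0, abs=1e-18)


def test_eta_squared_matches_ss_decomposition():
    rng = np.random.default_rng(5)
    y = rng.normal(size=(8, 2, 3))
    rep = erp_stats.rt_rm_anova(y)
    oracle = rm_anova_2x3_oracle(y)
    for eff, o in oracle.items():
        df1, df2 = o["df"]
        # reconstruct SS ratio from the oracle's F and dfs:
        # eta2 = SS_eff/(SS_eff+SS_err) = F*df1/(F*df1+df2)
        eta = o["F"] * df1 / (o["F"] * df1 + df2)
        assert rep["omnibus"][eff]["partial_eta_sq"] == pytest.approx(eta, abs=1e-10)


# ---------------------------------------------------------------------------
# extent filter
# ---------------------------------------------------------------------------


def _chain_adjacency(n):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


def _stat_from_p(p):
    shape = p.shape
    one = np.ones(shape)
    return erp_stats.StatMap(
        "interaction", one, p, p, p, one, one, np.zeros(shape, bool), (2.0, 10.0)
    )


def test_extent_filter_keeps_qualifying_patch():
    p = np.ones((10, 100))
    p[2:8, 30:55] = 0.001  # 6 contiguous electrodes x 25 ms
    mask = erp_stats.extent_filter(_stat_from_p(p), _chain_adjacency(10)).mask
    assert mask[2:8, 30:55].all()
    assert mask.sum() == 6 * 25


@pytest.mark.parametrize(
    "elec_slice,t_slice",
    [
        (slice(2, 8), slice(30, 45)),  # 15 ms only -> too short
        (slice(2, 6), slice(30, 55)),  # 4 electrodes -> too few
    ],
)
def test_extent_filter_removes_undersized_patches(elec_slice, t_slice):
    p = np.ones((10, 100))
    p[elec_slice, t_slice] = 0.001
    mask = erp_stats.extent_filter(_stat_from_p(p), _chain_adjacency(10)).mask
    assert not mask.any()


def test_extent_filter_requires_contiguity():
    """Five significant electrodes that are not mutually contiguous are dropped."""
    p = np.ones((10, 100))
    p[[0, 2, 4, 6, 8], 30:55] = 0.001  # alternating -> all isolated in a chain graph
    mask = erp_stats.extent_filter(_stat_from_p(p), _chain_adjacency(10)).mask
    assert not mask.any()


def test_extent_filter_monotone_in_thresholds():
    rng = np.random.default_rng(6)
    p = rng.uniform(size=(12, 200)) ** 3
    adj = _chain_adjacency(12)
    strict = erp_stats.extent_filter(_stat_from_p(p), adj, alpha=0.01, min_ms=20, min_electrodes=5)
    for kwargs in (
        dict(alpha=0.05, min_ms=20, min_electrodes=5),
        dict(alpha=0.01, min_ms=10, min_electrodes=5),
        dict(alpha=0.01, min_ms=20, min_electrodes=3),
    ):
        loose = erp_stats.extent_filter(_stat_from_p(p), adj, **kwargs)
        assert (loose.mask | strict.mask).sum() == loose.mask.sum()  # strict ⊆ loose


# ---------------------------------------------------------------------------
# cluster time courses and permutation test
# ---------------------------------------------------------------------------


def test_cluster_timecourse_is_member_mean(montage):
    rng = np.random.default_rng(7)
    erp = rng.normal(size=(montage.n_channels, 50))
    for name, labels in montage.cluster_sets.items():
        tc = erp_stats.cluster_timecourse(erp, montage, name)
        manual = np.mean([erp[montage.labels.index(lab)] for lab in labels], axis=0)
        np.testing.assert_allclose(tc, manual, rtol=1e-12)
    # shifting one member by +5 µV shifts the mean by +1 µV
    erp2 = erp.copy()
    erp2[montage.index("AFz")] += 5.0
    np.testing.assert_allclose(
        erp_stats.cluster_timecourse(erp2, montage, "frontal"),
        erp_stats.cluster_timecourse(erp, montage, "frontal") + 1.0,
        rtol=1e-12,
    )


def test_identical_series_give_no_clusters():
    rng = np.random.default_rng(8)
    a = rng.normal(size=(10, 80))
    res = erp_stats.paired_t_cluster_perm(a, a.copy(), n_perm=200, seed=0)
    assert res.clusters == []
    np.testing.assert_array_equal(res.t_obs, 0)


def test_boxcar_effect_recovered():
    """A strong 100 ms effect yields one significant cluster covering >= 80% of it."""
    rng = np.random.default_rng(9)
    n, t = 20, 400
    hits = 0
    for run in range(20):
        noise = rng.normal(size=(n, t))
        b = rng.normal(size=(n, t))
        a = b + noise * 0.2
        a[:, 150:250] += 2.0 * rng.normal(1.0, 0.5, size=(n, 1)).clip(0.2)
        res = erp_stats.paired_t_cluster_perm(a, b, n_perm=300, seed=run)
        sig = res.significant
        if len(sig) >= 1:
            cover = max(
                (min(c.end, 249) - max(c.start, 150) + 1) / 100 for c in sig
            )
            if cover >= 0.8:
                hits += 1
    assert hits >= 18


def test_cluster_p_symmetric_under_label_swap():
    rng = np.random.default_rng(10)
    a = rng.normal(size=(12, 150))
    b = rng.normal(size=(12, 150)) + 0.3
    r1 = erp_stats.paired_t_cluster_perm(a, b, n_perm=400, seed=5)
    r2 = erp_stats.paired_t_cluster_perm(b, a, n_perm=400, seed=5)
    assert [c.size for c in r1.clusters] == [c.size for c in r2.clusters]
    np.testing.assert_allclose(
        [c.p_corrected for c in r1.clusters], [c.p_corrected for c in r2.clusters]
    )
    np.testing.assert_allclose(r1.t_obs, -r2.t_obs, atol=1e-10)


def test_max_run_lengths_vectorized():
    rng = np.random.default_rng(11)
    sup = rng.random((50, 120)) < 0.3
    got = erp_stats.max_run_lengths(sup)
    for i, row in enumerate(sup):
        best = cur = 0
        for v in row:
            cur = cur + 1 if v else 0
            best = max(best, cur)
        assert got[i] == best


def test_nd_cluster_engine_agrees_with_1d_on_same_data():
    """The N-D engine with 1-D maps reproduces the temporal test's clusters."""
    rng = np.random.default_rng(12)
    a = rng.normal(size=(15, 100))
    b = rng.normal(size=(15, 100))
    a[:, 40:60] += 1.0
    r1 = erp_stats.paired_t_cluster_perm(a, b, n_perm=500, seed=3)
    r2 = erp_stats.sign_flip_cluster_nd(a - b, n_perm=500, seed=3)
    assert sorted(c.size for c in r1.clusters) == sorted(c.size for c in r2.clusters)
    np.testing.assert_allclose(r1.t_obs, r2.t_obs, rtol=1e-10)
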