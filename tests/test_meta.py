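import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcmeta.meta import (
    StudyEffect,
    adjusted_effect,
    asin_sqrt_transform,
    bh_fdr,
    feature_eligible,
    hedges_g,
    meta_analyse,
    pool_random_effects,
)


class TestAsinSqrt:
    @pytest.mark.parametrize("p,expected", [
        (0.0, 0.0),
        (1.0, math.pi / 2),
        (0.25, math.pi / 6),
    ])
    def test_closed_form(self, p, expected):
        assert asin_sqrt_transform(p) == pytest.approx(expected, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            asin_sqrt_transform(1.1)
        with pytest.raises(ValueError):
            asin_sqrt_transform(-0.01)

    def test_clips_tiny_overshoot(self):
        assert asin_sqrt_transform(1 + 1e-13) == pytest.approx(math.pi / 2)


class TestHedgesG:
    def test_hand_computation(self):
        # s_pooled = 1, d = (2-5)/1 = -3, J = 1 - 3/15 = 0.8, g = -2.4
        e = hedges_g([1, 2, 3], [4, 5, 6])
        assert e.g == pytest.approx(-2.4)
        d, df, n1, n2 = -3.0, 4, 3, 3
        var_expected = 0.8**2 * ((n1 + n2) / (n1 * n2) + d**2 / (2 * df))
        assert e.var_g == pytest.approx(var_expected)

    def test_identical_groups_zero(self):
        e = hedges_g([1, 2, 3, 4], [1, 2, 3, 4])
        assert e.g == 0.0
        assert not e.degenerate

    def test_antisymmetry(self, rng):
        x1 = rng.normal(0, 1, 30)
        x2 = rng.normal(0.5, 1.2, 25)
        a = hedges_g(x1, x2)
        b = hedges_g(x2, x1)
        assert a.g == pytest.approx(-b.g)
        assert a.var_g == pytest.approx(b.var_g)

    def test_degenerate_constant_groups(self):
        e = hedges_g([2, 2, 2], [2, 2, 2])
        assert e.degenerate
        assert e.g == 0.0
        assert e.var_g > 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=1000))
    def test_scale_equivariance(self, scale, seed):
        r = np.random.default_rng(seed)
        x1, x2 = r.normal(0, 1, 10), r.normal(1, 1, 12)
        a, b = hedges_g(x1, x2), hedges_g(scale * x1, scale * x2)
        assert b.g == pytest.approx(a.g, rel=1e-9)
        assert b.var_g == pytest.approx(a.var_g, rel=1e-9)


class TestEligibility:
    def test_study_count_rule(self):
        sizes = {("c1", "g1"): 50, ("c1", "g2"): 50,
                 ("c2", "g1"): 50, ("c2", "g2"): 50}
        presence = {k: 30 for k in sizes}
        assert not feature_eligible(presence, sizes)  # only 2 cohorts

    def test_passing_fixture(self):
        sizes = {(c, g): 50 for c in "abc" for g in ("g1", "g2")}
        presence = {k: 0 for k in sizes}
        presence[("a", "g1")] = 6  # 12% prevalence, 6 positives
        assert feature_eligible(presence, sizes)

    def test_five_sample_rule(self):
        sizes = {(c, g): 30 for c in "abc" for g in ("g1", "g2")}
        presence = {k: 4 for k in sizes}  # 13% prevalence but < 5 positives
        assert not feature_eligible(presence, sizes)


def _mk_effects(gs, vs):
    return [StudyEffect(f"c{i}", 50, 50, 0, 0, 1, 1, g, v)
            for i, (g, v) in enumerate(zip(gs, vs))]


class TestPooling:
    def test_homogeneous_pair(self):
        r = pool_random_effects(_mk_effects([0.5, 0.5], [0.02, 0.02]))
        assert r.g_pooled == pytest.approx(0.5)
        assert r.tau2 == pytest.approx(0.0, abs=1e-10)
        assert r.i2 == 0.0

    def test_inverse_variance_oracle_at_zero_tau2(self):
        # low scatter -> Q < k-1 -> Paule-Mandel tau2 = 0 exactly, so the
        # pooled estimate must equal the brute-force inverse-variance mean
        gs = [0.30, 0.31, 0.29, 0.305]
        vs = [0.02, 0.04, 0.03, 0.05]
        r = pool_random_effects(_mk_effects(gs, vs), tau2_method="PM")
        assert r.tau2 == 0.0
        w = [1 / v for v in vs]
        expected = sum(wi * gi for wi, gi in zip(w, gs)) / sum(w)
        assert r.g_pooled == pytest.approx(expected, rel=1e-12)

    def test_matches_metafor_reference(self):
        # values frozen from R metafor rma(yi, vi, method=..., test="knha")
        gs = [0.2, 0.5, 0.1, 0.6, 0.35]
        vs = [0.02, 0.03, 0.025, 0.04, 0.03]
        r = pool_random_effects(_mk_effects(gs, vs), tau2_method="REML")
        assert r.tau2 == pytest.approx(0.0113726120, abs=5e-6)
        assert r.g_pooled == pytest.approx(0.3251322794, abs=1e-5)
        assert r.ci_low == pytest.approx(0.0753481083, abs=1e-4)
        assert r.ci_high == pytest.approx(0.5749164504, abs=1e-4)
        assert r.p == pytest.approx(0.02247723502, rel=1e-3)
        pm = pool_random_effects(_mk_effects(gs, vs), tau2_method="PM")
        assert pm.tau2 == pytest.approx(0.0125392850, abs=5e-5)
        assert pm.g_pooled == pytest.approx(0.3258141635, abs=1e-4)
        # I^2 from the Q-based definition: 100 * (Q - (k-1)) / Q
        Q = 5.7224770642  # metafor QE for this fixture
        assert r.i2 == pytest.approx(100 * (Q - 4) / Q, abs=0.01)

    def test_reml_and_pm_agree_on_homogeneous_variances(self, rng):
        gs = rng.normal(0.4, 0.25, 8)
        vs = np.full(8, 0.03)
        a = pool_random_effects(_mk_effects(gs, vs), tau2_method="REML")
        b = pool_random_effects(_mk_effects(gs, vs), tau2_method="PM")
        assert a.tau2 == pytest.approx(b.tau2, rel=0.10)

    def test_single_study_flagged(self):
        r = pool_random_effects(_mk_effects([0.4], [0.02]))
        assert r.k == 1 and not r.pooled
        assert r.ci_low < 0.4 < r.ci_high

    def test_ci_contains_estimate(self, rng):
        gs = rng.normal(0, 0.5, 6)
        vs = rng.uniform(0.01, 0.05, 6)
        r = pool_random_effects(_mk_effects(gs, vs))
        assert r.ci_low <= r.g_pooled <= r.ci_high
        assert 0 <= r.i2 <= 100 and r.tau2 >= 0


class TestAdjustedEffect:
    def test_confound_absorbed(self, rng):
        n = 200
        age = rng.normal(60, 10, n)
        is_case = (rng.random(n) < 0.5).astype(float)
        y = 0.02 * age + rng.normal(0, 0.1, n)  # abundance driven by age only
        eff = adjusted_effect(y, is_case, age[:, None])
        assert abs(eff.g) < 0.05

    def test_orthogonal_covariates_match_unadjusted(self, rng):
        n = 400
        is_case = np.repeat([1.0, 0.0], n // 2)
        cov = np.tile([1.0, -1.0], n // 2)[:, None]  # balanced within class
        y = 0.3 * is_case + rng.normal(0, 0.2, n)
        eff = adjusted_effect(y, is_case, cov)
        raw = y[is_case == 1].mean() - y[is_case == 0].mean()
        assert eff.g == pytest.approx(raw, abs=0.03)

    def test_normal_equations_oracle(self):
        # 12-sample fixture solved directly via the normal equations
        y = np.array([0.1, 0.4, 0.2, 0.5, 0.3, 0.6, 0.15, 0.45, 0.2, 0.55, 0.1, 0.5])
        is_case = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        age = np.array([50, 52, 60, 61, 70, 72, 55, 56, 65, 64, 58, 59], dtype=float)
        X = np.column_stack([np.ones(12), is_case, age])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        eff = adjusted_effect(y, is_case, age[:, None], min_complete=5)
        assert eff.g == pytest.approx(beta[1], rel=1e-10)

    def test_rank_deficient_skipped(self):
        y = np.arange(12, dtype=float)
        is_case = np.repeat([1.0, 0.0], 6)
        assert adjusted_effect(y, is_case, is_case[:, None], min_complete=5) is None


class TestBhFdr:
    def test_single_pvalue(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computation(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_sm, atol=1e-12)

    def test_monotone_in_sorted_p(self, rng):
        p = np.sort(rng.uniform(0, 1, 50))
        q = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-15)


def test_meta_analyse_q_at_least_p(small_profile):
    group_of = {s: j % 2 for j, s in enumerate(small_profile.sample_ids)}
    records = meta_analyse([small_profile], lambda s: group_of[s],
                           apply_eligibility=False)
    for r in records:
        assert r.q >= r.p - 1e-12
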