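import math

import numpy as np
import pytest

from crcmeta.io import SignatureSet
from crcmeta.signatures import (
    cardiometabolic_rank,
    disease_signature_meta,
    jaccard_similarity,
    overlap_fraction,
    partial_spearman,
)


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard_similarity({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert jaccard_similarity({"a"}, {"b"}) == 0.0

    def test_hand_value(self):
        assert jaccard_similarity({"x", "y"}, {"y", "z"}) == pytest.approx(1 / 3)

    def test_symmetry_and_identity(self, rng):
        universe = [f"f{i}" for i in range(30)]
        a = set(rng.choice(universe, 10, replace=False))
        b = set(rng.choice(universe, 12, replace=False))
        assert jaccard_similarity(a, b) == jaccard_similarity(b, a)
        assert (jaccard_similarity(a, b) == 1.0) == (a == b)

    def test_both_empty_defined_zero(self):
        assert jaccard_similarity(set(), set()) == 0.0

    def test_accepts_signature_sets(self):
        a = SignatureSet("a", {"x", "y"})
        b = SignatureSet("b", {"y"})
        assert jaccard_similarity(a, b) == pytest.approx(0.5)


class TestOverlapFraction:
    def test_reference_superset(self):
        assert overlap_fraction({"a", "b"}, {"a", "b", "c"}) == 1.0

    def test_no_overlap(self):
        assert overlap_fraction({"a"}, {"b"}) == 0.0

    def test_three_of_twelve(self):
        sig = {f"f{i}" for i in range(12)}
        ref = {"f0", "f1", "f2"}
        assert overlap_fraction(sig, ref) == pytest.approx(0.25)

    def test_empty_signature_undefined(self):
        assert math.isnan(overlap_fraction(set(), {"a"}))

    def test_complement_identity(self):
        universe = {f"f{i}" for i in range(20)}
        sig = {f"f{i}" for i in range(7)}
        ref = {f"f{i}" for i in range(3, 11)}
        total = overlap_fraction(sig, ref) + overlap_fraction(sig, universe - ref)
        assert total == pytest.approx(1.0)


class TestPartialSpearman:
    def test_monotone_limit(self):
        x = np.arange(20, dtype=float)
        y = np.exp(x / 5)  # monotone transform
        assert partial_spearman(x, y) == pytest.approx(1.0)

    def test_self_adjustment(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        rho = partial_spearman(x, y, covariates=x[:, None])
        assert abs(rho) < 0.25  # x residualized on itself carries no signal

    def test_matches_pingouin(self, rng):
        # pingouin rank-transforms the covariate as well; feed it ranked to
        # compare the same estimand
        import pandas as pd
        import pingouin as pg
        from scipy.stats import rankdata

        x = rng.normal(size=20)
        z = rng.normal(size=20)
        y = 0.5 * x + 0.8 * z + rng.normal(size=20)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        expected = pg.partial_corr(df, x="x", y="y", covar="z",
                                   method="spearman")["r"].iloc[0]
        got = partial_spearman(x, y, rankdata(z)[:, None])
        assert got == pytest.approx(expected, abs=1e-9)

    def test_direct_residual_formula(self, rng):
        from scipy.stats import rankdata

        x = rng.normal(size=20)
        z = rng.normal(size=(20, 1))
        y = x + z[:, 0] + rng.normal(size=20)
        rx, ry = rankdata(x), rankdata(y)
        design = np.column_stack([np.ones(20), z])
        H = design @ np.linalg.inv(design.T @ design) @ design.T
        ex, ey = rx - H @ rx, ry - H @ ry
        expected = (ex @ ey) / (np.linalg.norm(ex) * np.linalg.norm(ey))
        assert partial_spearman(x, y, z) == pytest.approx(expected, abs=1e-12)

    def test_constant_variable_undefined(self):
        assert math.isnan(partial_spearman(np.ones(10), np.arange(10.0)))


class TestCardiometabolicRank:
    def test_perfect_tracker_selected_with_max_rank(self, rng):
        n, p = 60, 8
        risk = rng.normal(size=n)
        A = rng.normal(size=(n, p))
        A[:, 0] = risk  # feature 0 tracks every index
        indices = np.column_stack([risk + 0.01 * rng.normal(size=n),
                                   2 * risk + 0.01 * rng.normal(size=n)])
        cats = {"bp": "cardio", "lipids": "metabolic"}
        scores = cardiometabolic_rank(A, [f"f{i}" for i in range(p)],
                                      indices, cats)
        assert scores[0].rank == max(s.rank for s in scores)
        assert scores[0].selected

    def test_null_selects_about_quarter(self, rng):
        n, p = 80, 200
        A = rng.normal(size=(n, p))
        indices = rng.normal(size=(n, 3))
        cats = {"i1": "a", "i2": "a", "i3": "b"}
        scores = cardiometabolic_rank(A, [f"f{i}" for i in range(p)],
                                      indices, cats)
        frac = np.mean([s.selected for s in scores])
        assert 0.15 <= frac <= 0.35  # quartile rule

    def test_invariant_to_monotone_index_transform(self, rng):
        n, p = 40, 10
        A = rng.normal(size=(n, p))
        indices = rng.normal(size=(n, 2))
        cats = {"u": "a", "v": "b"}
        fids = [f"f{i}" for i in range(p)]
        base = cardiometabolic_rank(A, fids, indices, cats)
        warped = np.column_stack([np.exp(indices[:, 0]), indices[:, 1] ** 3])
        alt = cardiometabolic_rank(A, fids, warped, cats)
        for s, t in zip(base, alt):
            assert s.rank == pytest.approx(t.rank, abs=1e-12)


class TestDiseaseSignatureMeta:
    def _cohorts(self, rng, n_cohorts=4, effect_features=(), present_in=None):
        from crcmeta.io import CohortProfile

        profiles, disease, country = [], {}, {}
        fids = [f"f{i}" for i in range(30)]
        for c in range(n_cohorts):
            n = 60
            sids = [f"c{c}_s{j}" for j in range(n)]
            raw = rng.gamma(1.0, size=(30, n))
            labels = np.r_[np.ones(n // 2), np.zeros(n // 2)]
            for f in effect_features:
                i = fids.index(f)
                if present_in is not None and c not in present_in:
                    raw[i] = 0.0
                else:
                    raw[i, labels == 1] *= 6.0
            ab = raw / max(raw.sum(axis=0).max(), 1e-9)
            profiles.append(CohortProfile(f"c{c}", fids, sids, ab))
            for j, s in enumerate(sids):
                disease[s] = int(labels[j])
                country[s] = ["IT", "CZ"][j % 2] if c % 2 == 0 else "US"
        return profiles, disease, country

    def test_planted_effect_recovered(self, rng):
        profiles, disease, country = self._cohorts(rng, effect_features=["f3"])
        sig = disease_signature_meta(profiles, disease.get, country.get)
        assert "f3" in sig.members

    def test_min_datasets_rule(self, rng):
        profiles, disease, country = self._cohorts(
            rng, effect_features=["f3"], present_in={0, 1})
        sig = disease_signature_meta(profiles, disease.get, country.get,
                                     min_datasets=3)
        assert "f3" not in sig.members

    def test_null_signature_small(self, rng):
        profiles, disease, country = self._cohorts(rng)
        sig = disease_signature_meta(profiles, disease.get, country.get)
        assert len(sig.members) <= 0.15 * 30
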