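import numpy as np
import pytest

from crcmeta.io import MsaSet
from crcmeta.simulate import generate_msa
from crcmeta.strains import (
    binary_entropy,
    collinearity_prune,
    dedup_by_ani_clusters,
    one_hot_encode,
    prevalence_filter,
    select_positions,
    strain_feature_pipeline,
    strain_permanova,
)


class TestBinaryEntropy:
    @pytest.mark.parametrize("p,expected", [(0.5, 1.0), (0.0, 0.0), (1.0, 0.0)])
    def test_known_values(self, p, expected):
        assert binary_entropy(p) == pytest.approx(expected)

    def test_threshold_boundary(self):
        assert binary_entropy(0.11) == pytest.approx(0.4999, abs=5e-4)
        assert binary_entropy(0.11) < 0.5
        assert binary_entropy(0.89) == pytest.approx(binary_entropy(0.11))
        assert binary_entropy(0.15) > 0.5


class TestSelectPositions:
    def test_invariant_and_balanced_columns(self):
        msa = MsaSet("x", ["a", "b", "c", "d"],
                     ["AAGA", "AAGC", "ATGA", "ATGC"])
        # col1: invariant; col2: 50/50 A/T; col3: invariant; col4: 50/50 A/C
        positions, stats = select_positions(msa)
        assert positions == [2, 4]
        assert stats[2] == (0.5, 1.0)

    def test_entropy_cutoff(self):
        # 89/11 -> H ~= 0.4999 excluded; 85/15 -> H ~= 0.61 included
        seqs_89 = ["A"] * 89 + ["C"] * 11
        seqs_85 = ["A"] * 85 + ["C"] * 15
        msa = MsaSet("x", [f"s{i}" for i in range(100)],
                     [a + b for a, b in zip(seqs_89, seqs_85)])
        positions, _ = select_positions(msa)
        assert positions == [2]

    def test_gap_counts_as_symbol_and_n_ignored(self):
        msa = MsaSet("x", ["a", "b", "c", "d"],
                     ["-N", "-N", "AN", "AN"])
        positions, stats = select_positions(msa)
        assert positions == [1]  # 50/50 gap vs A
        assert 2 not in stats  # all-N column dropped


class TestOneHot:
    def test_symbol_encoding(self):
        msa = MsaSet("sgb", ["a", "b", "c"], ["A", "-", "N"])
        mat = one_hot_encode(msa, [1])
        assert mat.feature_ids == [("sgb", 1, s) for s in ("A", "C", "G", "T", "gap")]
        np.testing.assert_array_equal(mat.values[0], [1, 0, 0, 0, 0])
        np.testing.assert_array_equal(mat.values[1], [0, 0, 0, 0, 1])
        np.testing.assert_array_equal(mat.values[2], [0, 0, 0, 0, 0])

    def test_conservation(self, rng):
        msa, _ = generate_msa(15, 60, n_clades=3, divergence=0.05,
                              gap_rate=0.05, seed=6)
        positions, _ = select_positions(msa)
        mat = one_hot_encode(msa, positions)
        arr = msa.to_array()
        for i in range(15):
            non_n = sum(arr[i, p - 1] != "N" for p in positions)
            assert mat.values[i].sum() == non_n


from crcmeta.strains import StrainFeatureMatrix


def _matrix(cols):
    vals = np.array(cols).T
    return StrainFeatureMatrix(
        feature_ids=[("x", i + 1, "A") for i in range(vals.shape[1])],
        sample_ids=[f"s{i}" for i in range(vals.shape[0])],
        values=vals,
    )


class TestPrevalenceFilter:

    def test_boundaries_inclusive(self):
        n = 10
        all_ones = [1] * n
        half = [1] * 5 + [0] * 5
        at20 = [1] * 2 + [0] * 8
        at10 = [1] * 1 + [0] * 9
        mat = _matrix([all_ones, half, at20, at10])
        out = prevalence_filter(mat)
        kept = [f[1] for f in out.feature_ids]
        assert kept == [2, 3]  # 50% and exactly 20% kept; 100% and 10% removed


class TestCollinearityPrune:
    def test_duplicate_removed(self):
        col = [1, 0, 1, 0, 1, 0]
        mat = _matrix([col, col])
        out = collinearity_prune(mat)
        assert out.n_features == 1

    def test_anticorrelated_one_hot_pair(self):
        # complementary one-hot features at a 50/50 biallelic site: r = -1
        a = [1, 0, 1, 0]
        b = [0, 1, 0, 1]
        mat = _matrix([a, b])
        out = collinearity_prune(mat)
        assert out.n_features == 1
        assert out.feature_ids[0][1] == 1  # first occurrence kept

    def test_orthogonal_kept(self):
        a = [1, 1, 0, 0]
        b = [1, 0, 1, 0]  # phi = 0
        mat = _matrix([a, b])
        assert collinearity_prune(mat).n_features == 2

    def test_constant_dropped(self):
        mat = _matrix([[1, 1, 1, 1], [1, 0, 1, 0]])
        out = collinearity_prune(mat)
        assert out.n_features == 1
        assert out.values.var(axis=0).min() > 0


class TestAniDedup:
    def test_min_gap_duplicate_collapsed(self):
        # columns 1 and 2 induce the same sample split (a,b | c,d) but
        # column 2 does it with gaps; samples differ at only 2/40 sites so
        # they form a single cluster at threshold 0.05
        base = "A" * 38
        seqs = ["AG" + base, "AG" + base, "C-" + base, "C-" + base]
        msa = MsaSet("x", list("abcd"), seqs)
        kept = dedup_by_ani_clusters([1, 2], msa, ani_threshold=0.05)
        assert kept == [1]

    def test_distinct_partitions_all_kept(self):
        # pos1 splits a,b | c,d while pos2 splits a,c | b,d: different
        # partitions, both informative, both kept
        base = "A" * 38
        seqs = ["AG" + base, "AC" + base, "CG" + base, "CC" + base]
        msa = MsaSet("x", list("abcd"), seqs)
        assert dedup_by_ani_clusters([1, 2], msa, ani_threshold=0.05) == [1, 2]

    def test_singleton_clusters_pass_through(self):
        # mutually distant samples give only singleton clusters -> no
        # within-cluster information, positions returned unchanged
        msa = MsaSet("x", list("ab"), ["AACC", "CCAA"])
        assert dedup_by_ani_clusters([1, 2, 3], msa) == [1, 2, 3]

    def test_pipeline_switch_passthrough(self):
        msa, _ = generate_msa(12, 40, n_clades=3, divergence=0.02, seed=9)
        with_dedup = strain_feature_pipeline(msa, ani_dedup=True)
        without = strain_feature_pipeline(msa, ani_dedup=False)
        assert without.n_features >= with_dedup.n_features


class TestPipelineAndPermanova:
    def test_funnel_monotone(self):
        msa, _ = generate_msa(30, 120, n_clades=4, divergence=0.03,
                              gap_rate=0.03, seed=10)
        mat = strain_feature_pipeline(msa)
        funnel = mat.provenance["funnel"]
        counts = [n for _, n in funnel]
        assert counts == sorted(counts, reverse=True)

    def test_clade_aligned_labels_reject(self):
        msa, truth = generate_msa(60, 200, n_clades=4, divergence=0.01,
                                  gap_rate=0.02, seed=11)
        mat = strain_feature_pipeline(msa)
        clade = np.array([truth["clade_of"][s] for s in mat.sample_ids])
        res = strain_permanova(mat, (clade >= 2).astype(int), n_perm=199, seed=0)
        assert res.p <= 0.01

    def test_single_block_equals_unblocked(self):
        msa, truth = generate_msa(24, 80, n_clades=2, divergence=0.08,
                                  gap_rate=0.0, seed=12)
        mat = strain_feature_pipeline(msa, ani_dedup=False)
        labels = np.array([truth["clade_of"][s] for s in mat.sample_ids])
        a = strain_permanova(mat, labels, blocks=None, n_perm=99, seed=5)
        b = strain_permanova(mat, labels, blocks=np.zeros(len(labels)), n_perm=99, seed=5)
        assert a.pseudo_f == pytest.approx(b.pseudo_f)
        assert a.p == pytest.approx(b.p)
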