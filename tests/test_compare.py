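import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sitepart.compare import (
    branch_ratio,
    matrix_difference,
    matrix_distance,
    mix_branch_lengths,
    noise_analysis,
    random_partition,
)
from sitepart.substitution import ExchangeabilityMatrix, matrix_from_pairs
from sitepart.trees import PhyloTree


class TestMatrixDistance:
    def test_identity(self):
        R = ExchangeabilityMatrix.random(seed=0)
        assert matrix_distance(R, R) == 0.0

    def test_single_pair_difference(self):
        a = np.ones(190)
        b = a.copy()
        b[37] += 0.3
        assert matrix_distance(
            ExchangeabilityMatrix.from_pairs(a), ExchangeabilityMatrix.from_pairs(b)
        ) == pytest.approx(0.3)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000), st.integers(0, 10_000), st.integers(0, 10_000))
    def test_metric_axioms(self, s1, s2, s3):
        A = ExchangeabilityMatrix.random(seed=s1)
        B = ExchangeabilityMatrix.random(seed=s2)
        C = ExchangeabilityMatrix.random(seed=s3)
        dab = matrix_distance(A, B)
        assert dab >= 0
        assert dab == pytest.approx(matrix_distance(B, A))
        assert dab <= matrix_distance(A, C) + matrix_distance(C, B) + 1e-12


class TestMatrixDifference:
    def test_reconstructs_b_from_a(self):
        A = ExchangeabilityMatrix.random(seed=1)
        B = ExchangeabilityMatrix.random(seed=2)
        table = matrix_difference(A, B)
        assert len(table) == 190
        recon = matrix_from_pairs((table["a"] - table["difference"]).to_numpy())
        assert recon == pytest.approx(B.matrix)


class TestRandomPartition:
    def test_exact_published_sizes(self):
        part = random_partition(3580, (1750, 1025, 805), seed=0)
        assert part.sizes.tolist() == [1750, 1025, 805]

    def test_uniform_over_splits(self):
        """n=4 into (2,2): the three distinct splits appear uniformly."""
        from scipy.stats import chisquare

        counts = {}
        for seed in range(3000):
            labels = random_partition(4, (2, 2), seed=seed).labels
            key = tuple(np.nonzero(labels == labels[0])[0])
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        assert chisquare(list(counts.values())).pvalue > 0.01

    def test_single_group(self):
        part = random_partition(10, (10,), seed=1)
        assert np.all(part.labels == 1)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            random_partition(10, (4, 4), seed=0)

    def test_deterministic_given_seed(self):
        a = random_partition(50, (30, 20), seed=7).labels
        b = random_partition(50, (30, 20), seed=7).labels
        assert np.array_equal(a, b)


def _chain(lengths):
    # 3-leaf star: branches indexed by leaf
    newick = f"(a:{lengths[0]},b:{lengths[1]},c:{lengths[2]});"
    return PhyloTree.from_newick(newick)


class TestBranchRatio:
    def test_identical_trees_all_zero(self):
        t = _chain([0.1, 0.2, 0.3])
        assert all(v == pytest.approx(0.0) for v in branch_ratio(t, t).values())

    def test_doubled_tree_all_one(self):
        t = _chain([0.1, 0.2, 0.3])
        assert all(
            v == pytest.approx(1.0) for v in branch_ratio(t.rescaled(2.0), t).values()
        )

    def test_hand_example(self):
        ref = _chain([0.1, 0.1, 0.6])
        obs = _chain([0.1, 0.2, 0.3])
        ratios = {min(k): v for k, v in branch_ratio(obs, ref).items()}
        assert ratios["a"] == pytest.approx(0.0)
        assert ratios["b"] == pytest.approx(1.0)
        assert ratios["c"] == pytest.approx(-0.5)

    def test_zero_reference_branch_flagged_nan(self):
        ref = _chain([0.0, 0.2, 0.3])
        obs = _chain([0.1, 0.2, 0.3])
        ratios = {min(k): v for k, v in branch_ratio(obs, ref).items()}
        assert np.isnan(ratios["a"])

    def test_topology_mismatch_rejected(self):
        a = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        b = PhyloTree.from_newick("((a:1,c:1):1,(b:1,d:1):1);")
        with pytest.raises(ValueError, match="topology"):
            branch_ratio(a, b)


class TestMixBranchLengths:
    def test_equal_trees_fixed_point(self):
        t = _chain([0.1, 0.2, 0.3])
        mixed = mix_branch_lengths([t, t.copy()], [0.4, 0.6])
        assert mixed.branch_map() == pytest.approx(t.branch_map())

    def test_degenerate_weights_select_first_tree(self):
        a = _chain([0.1, 0.2, 0.3])
        b = _chain([0.5, 0.5, 0.5])
        mixed = mix_branch_lengths([a, b], [1.0, 0.0])
        assert mixed.branch_map() == pytest.approx(a.branch_map())

    def test_hand_mean(self):
        a = _chain([0.1, 0.1, 0.1])
        b = _chain([0.3, 0.3, 0.3])
        mixed = mix_branch_lengths([a, b], [0.5, 0.5])
        assert all(v == pytest.approx(0.2) for v in mixed.branch_map().values())

    def test_weights_must_sum_to_one(self):
        t = _chain([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="sum"):
            mix_branch_lengths([t, t], [0.5, 0.6])


class TestNoiseAnalysisContract:
    def test_single_replicate_rejected(self):
        from sitepart.alignment import Alignment
        from sitepart.clustering import ClusterAssignment

        msa = Alignment.from_sequences(["a", "b"], ["AR", "AR"])
        tree = PhyloTree.from_newick("(a:0.1,b:0.1);")
        assignment = ClusterAssignment(np.array([1, 2]), np.zeros((2, 1)), 0.0)
        with pytest.raises(ValueError, match="S >= 2"):
            noise_analysis(msa, tree, assignment, ExchangeabilityMatrix.flat(), S=1)

    def test_bonferroni_is_capped_product(self):
        from sitepart.compare import NoiseAnalysisResult

        res = NoiseAnalysisResult(
            observed_distance=np.array([1.0, 1.0]),
            random_distances=np.ones((5, 2)),
            t_statistic=np.zeros(2),
            p_value=np.array([0.04, 0.7]),
            p_bonferroni=np.minimum(1.0, np.array([0.04, 0.7]) * 2),
            S=5,
        )
        assert res.p_bonferroni.tolist() == [0.08, 1.0]
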