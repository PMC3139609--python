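import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asra.data_model import ValidationError
from asra.rankprod import (
    RankLists,
    call_differential,
    estimate_pfp,
    pairwise_difference_lists,
    rank_product,
)
from asra.synthetic import PlantConfig, generate_training
from conftest import make_matrix


def _toy_matrix(n1, n2, genes=4, seed=0):
    rng = np.random.default_rng(seed)
    return make_matrix(
        rng.normal(8, 1, size=(genes, n1 + n2)),
        conditions=["c1"] * n1 + ["c2"] * n2,
    )


class TestPairwiseLists:
    @pytest.mark.parametrize("n1,n2,k", [(3, 3, 9), (3, 2, 6), (1, 1, 1)])
    def test_list_count_is_n1_times_n2(self, n1, n2, k):
        r = pairwise_difference_lists(_toy_matrix(n1, n2), "c1", "c2")
        assert r.K == k

    def test_ranks_order_by_decreasing_difference(self):
        m = make_matrix([[10.0, 5.0], [4.0, 3.0]], conditions=["c1", "c2"])
        r = pairwise_difference_lists(m, "c1", "c2")  # diffs (5, 1)
        assert list(r.ranks_up[0]) == [1, 2]
        assert list(r.ranks_down[0]) == [2, 1]

    def test_each_list_is_a_permutation_and_directions_mirror(self):
        r = pairwise_difference_lists(_toy_matrix(3, 2, genes=7), "c1", "c2")
        G = r.G
        for k in range(r.K):
            assert sorted(r.ranks_up[k]) == list(range(1, G + 1))
            # without ties up- and down-ranks of a list are reverses
            np.testing.assert_array_equal(r.ranks_down[k], G + 1 - r.ranks_up[k])

    def test_unknown_label_errors(self):
        with pytest.raises(ValidationError):
            pairwise_difference_lists(_toy_matrix(2, 2), "c1", "nope")


class TestRankProduct:
    def test_unanimous_top_gene_has_rp_one(self):
        r = RankLists(["a", "b"], np.array([[1, 2], [1, 2]]), np.array([[2, 1], [2, 1]]))
        assert rank_product(r, "up")[0] == pytest.approx(1.0)

    def test_geometric_mean_formula(self):
        r = RankLists(["a", "b"], np.array([[2, 1], [3, 1]]), np.array([[1, 2], [1, 3]]))
        assert rank_product(r, "up")[0] == pytest.approx(math.sqrt(6))

    def test_matches_bruteforce_on_toy_instance(self):
        m = _toy_matrix(2, 1, genes=4, seed=5)
        r = pairwise_difference_lists(m, "c1", "c2")
        rp = rank_product(r, "up")
        # independent brute-force: explicit per-gene product over lists
        for g in range(4):
            prod = 1.0
            for k in range(r.K):
                prod *= r.ranks_up[k, g]
            assert rp[g] == pytest.approx(prod ** (1.0 / r.K))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform_of_differences(self, seed):
        """Ranks (hence RP) depend only on the ordering of the differences."""
        rng = np.random.default_rng(seed)
        vals = rng.normal(8, 1, size=(6, 4))
        m1 = make_matrix(vals, conditions=["c1", "c1", "c2", "c2"])
        # strictly increasing transform of the values preserves per-list
        # difference ordering only if applied to differences; emulate by an
        # affine map of the whole matrix (monotone, difference-order preserving)
        m2 = make_matrix(2.5 * vals + 1.0, conditions=["c1", "c1", "c2", "c2"])
        r1 = pairwise_difference_lists(m1, "c1", "c2")
        r2 = pairwise_difference_lists(m2, "c1", "c2")
        np.testing.assert_array_equal(r1.ranks_up, r2.ranks_up)
        np.testing.assert_allclose(rank_product(r1, "up"), rank_product(r2, "up"))


def _enumerate_pfp_oracle(ranks_up, rp_obs):
    """Independent exhaustive enumeration of the permutation null (test-local)."""
    K, G = ranks_up.shape
    null = []
    for combo in itertools.product(itertools.permutations(range(1, G + 1)), repeat=K):
        for g in range(G):
            prod = 1.0
            for k in range(K):
                prod *= combo[k][g]
            null.append(prod ** (1.0 / K))
    n_rounds = math.factorial(G) ** K
    pfp = []
    for g in range(G):
        count = sum(1 for v in null if v <= rp_obs[g] + 1e-12)
        rho = sum(1 for h in range(G) if rp_obs[h] < rp_obs[g]) + (
            1 + sum(1 for h in range(G) if h != g and rp_obs[h] == rp_obs[g]) / 2.0
        )
        pfp.append(count / n_rounds / rho)
    return np.array(pfp)


class TestPfp:
    @pytest.mark.parametrize("n1,n2,genes,seed", [(1, 1, 3, 0), (2, 1, 3, 4), (1, 2, 4, 9)])
    def test_exhaustive_mode_equals_enumeration_oracle(self, n1, n2, genes, seed):
        m = _toy_matrix(n1, n2, genes=genes, seed=seed)
        r = pairwise_difference_lists(m, "c1", "c2")
        rp = rank_product(r, "up")
        ours = estimate_pfp(r, rp, exhaustive=True)
        oracle = _enumerate_pfp_oracle(r.ranks_up, rp)
        np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_observed_below_every_null_gives_zero(self):
        r = RankLists(["a", "b", "c"], np.array([[1, 2, 3]]), np.array([[3, 2, 1]]))
        pfp = estimate_pfp(r, np.array([0.5, 2.0, 3.0]), B=10, seed=0)
        assert pfp[0] == 0.0

    def test_expected_counts_nondecreasing_in_rank_product(self):
        m = _toy_matrix(3, 3, genes=40, seed=2)
        r = pairwise_difference_lists(m, "c1", "c2")
        rp = rank_product(r, "up")
        pfp = estimate_pfp(r, rp, B=30, seed=1)
        from scipy.stats import rankdata

        expected = pfp * rankdata(rp, method="average")
        order = np.argsort(rp)
        assert (np.diff(expected[order]) >= -1e-9).all()

    def test_same_seed_reproduces_bitwise(self):
        m = _toy_matrix(3, 2, genes=30, seed=3)
        r = pairwise_difference_lists(m, "c1", "c2")
        rp = rank_product(r, "up")
        a = estimate_pfp(r, rp, B=20, seed=42)
        b = estimate_pfp(r, rp, B=20, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_invalid_permutation_count_errors(self):
        m = _toy_matrix(2, 2, genes=5)
        r = pairwise_difference_lists(m, "c1", "c2")
        with pytest.raises(ValidationError):
            estimate_pfp(r, rank_product(r, "up"), B=0, seed=0)


class TestCallDifferential:
    def test_null_data_false_positive_fraction_near_nominal(self):
        """With the independent-per-list null on a no-effect design the
        fraction of pfp<=0.05 calls sits within 3x of the cutoff."""
        cfg = PlantConfig(
            n_genes=1000, n_asra_up=0, n_asra_down=0, n_exclusive=0, n_absent_any=0,
            n_a_up=0, n_a_down=0, n_b_up=0, n_b_down=0, n_a_up_b_down=0, n_a_down_b_up=0,
            seed=8,
        )
        x, _ = generate_training(cfg)
        d = call_differential(x, "ASYM", "SYM", cutoff=0.05, B=100, seed=1,
                              null="independent-lists")
        frac = (d.sig_up.sum() + d.sig_down.sum()) / (2 * cfg.n_genes)
        assert frac <= 0.15

    def test_planted_up_gene_recovered(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(8, 0.15, size=(300, 6))
        vals[0, :3] += 3.0
        m = make_matrix(vals, conditions=["c1"] * 3 + ["c2"] * 3)
        d = call_differential(m, "c1", "c2", cutoff=0.05, B=50, seed=2)
        assert d.sig_up[0] and not d.sig_down[0]
        assert d.fc[0] == pytest.approx(3.0, abs=0.5)

    def test_zero_cutoff_calls_nothing(self):
        m = _toy_matrix(3, 3, genes=50, seed=6)
        d = call_differential(m, "c1", "c2", cutoff=0.0, B=20, seed=0)
        assert not d.sig_up.any() and not d.sig_down.any()

    @pytest.mark.parametrize("null", ["within-array", "independent-lists"])
    def test_directions_never_both_significant(self, null):
        m = _toy_matrix(3, 2, genes=100, seed=4)
        d = call_differential(m, "c1", "c2", cutoff=0.5, B=30, seed=5, null=null)
        assert not (d.sig_up & d.sig_down).any()

    def test_fc_sign_agrees_with_significant_direction(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(8, 0.15, size=(200, 6))
        vals[0, :3] += 2.5
        vals[1, 3:] += 2.5
        m = make_matrix(vals, conditions=["c1"] * 3 + ["c2"] * 3)
        d = call_differential(m, "c1", "c2", cutoff=0.05, B=50, seed=0)
        assert d.sig_up[0] and d.fc[0] > 0
        assert d.sig_down[1] and d.fc[1] < 0

    def test_results_frame_round_trip(self, tmp_path):
        m = _toy_matrix(2, 2, genes=20, seed=1)
        d = call_differential(m, "c1", "c2", B=10, seed=0)
        d.write_tsv(tmp_path / "rp.tsv")
        import pandas as pd

        back = pd.read_csv(tmp_path / "rp.tsv", sep="\t", index_col=0)
        assert list(back.columns) == ["rp_up", "pfp_up", "rp_down", "pfp_down", "fc", "sig_up", "sig_down"]
        np.testing.assert_allclose(back["rp_up"].to_numpy(), d.rp_up, rtol=1e-5)
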