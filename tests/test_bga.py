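import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asra.bga import (
    ASYMMETRIC_LABEL,
    SYMMETRIC_LABEL,
    BGAModel,
    DegenerateModelError,
    bga_fit,
    classify,
    coa,
    merge_symmetric_labels,
    project,
    separation_distance,
    separation_pvalue,
)
from asra.data_model import ExpressionMatrix, ValidationError
from conftest import make_matrix


def _random_nonneg(shape, seed):
    rng = np.random.default_rng(seed)
    return rng.uniform(0.5, 10, size=shape)


class TestCoa:
    def test_diagonal_two_by_two_hand_solution(self):
        out = coa(np.array([[2.0, 0.0], [0.0, 2.0]]))
        assert out.n_axes == 1
        assert out.eigenvalues[0] == pytest.approx(1.0)
        np.testing.assert_allclose(np.abs(out.row_coords[:, 0]), [1.0, 1.0], atol=1e-12)
        assert out.row_coords[0, 0] * out.row_coords[1, 0] < 0

    def test_proportional_columns_have_zero_inertia(self):
        out = coa(np.array([[1.0, 2.0], [3.0, 6.0], [2.0, 4.0]]))
        assert out.total_inertia == pytest.approx(0.0, abs=1e-12)
        assert out.n_axes == 0

    def test_eigenvalues_sum_to_chi_square_inertia(self):
        m = _random_nonneg((6, 4), seed=0)
        out = coa(m)
        # independent inertia formula: sum (p_ij - r_i c_j)^2 / (r_i c_j)
        P = m / m.sum()
        r, c = P.sum(1), P.sum(0)
        inertia = ((P - np.outer(r, c)) ** 2 / np.outer(r, c)).sum()
        assert out.eigenvalues.sum() == pytest.approx(inertia, rel=1e-10)
        assert out.total_inertia == pytest.approx(inertia, rel=1e-10)

    def test_eigenvalues_nonnegative_nonincreasing_and_centered(self):
        out = coa(_random_nonneg((5, 5), seed=3))
        assert (out.eigenvalues >= 0).all()
        assert (np.diff(out.eigenvalues) <= 1e-12).all()
        for ax in range(out.n_axes):
            assert out.row_masses @ out.row_coords[:, ax] == pytest.approx(0, abs=1e-8)
            assert out.col_masses @ out.col_coords[:, ax] == pytest.approx(0, abs=1e-8)

    def test_barycentric_relation(self):
        m = _random_nonneg((7, 3), seed=5)
        out = coa(m)
        P = m / m.sum()
        profiles = P / P.sum(0, keepdims=True)  # column profiles
        np.testing.assert_allclose(
            profiles.T @ out.row_standard, out.col_coords, atol=1e-10
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_eigendecomposition_oracle(self, seed):
        """COA axes equal an independent eigen-decomposition of S^T S."""
        rng = np.random.default_rng(seed)
        m = rng.uniform(0.1, 5, size=rng.integers(2, 7, size=2))
        out = coa(m)
        P = m / m.sum()
        r, c = P.sum(1), P.sum(0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        evals, evecs = np.linalg.eigh(S.T @ S)
        evals = np.sort(evals)[::-1]
        np.testing.assert_allclose(out.eigenvalues, evals[: out.n_axes], atol=1e-8)
        for ax in range(out.n_axes):
            v = evecs[:, np.argsort(np.linalg.eigh(S.T @ S)[0])[::-1][ax]]
            col = v / np.sqrt(c) * np.sqrt(evals[ax])
            match_direct = np.allclose(out.col_coords[:, ax], col, atol=1e-8)
            match_flipped = np.allclose(out.col_coords[:, ax], -col, atol=1e-8)
            assert match_direct or match_flipped

    def test_negative_entry_error_mentions_shift(self):
        with pytest.raises(ValidationError, match="shift"):
            coa(np.array([[1.0, -0.1], [2.0, 3.0]]))

    def test_zero_margin_error(self):
        with pytest.raises(ValidationError, match="margin"):
            coa(np.array([[0.0, 0.0], [2.0, 3.0]]))


class TestBgaFit:
    def test_two_groups_yield_single_axis_model(self, toy_two_group):
        model = bga_fit(toy_two_group, reference="B")
        assert model.eigenvalue > 0 and not model.degenerate
        assert model.group_centroids["B"] > model.boundary > model.group_centroids["A"]

    def test_label_swap_negates_loadings_but_not_classifications(self, toy_two_group):
        m1 = bga_fit(toy_two_group, reference="B")
        m2 = bga_fit(toy_two_group, reference="A")
        np.testing.assert_allclose(m1.gene_loadings, -m2.gene_loadings, atol=1e-10)
        assert m1.group_centroids["A"] == pytest.approx(-m2.group_centroids["A"])
        c1 = project(m1, toy_two_group)
        labels1 = classify(m1, c1)
        labels2 = classify(m2, project(m2, toy_two_group))
        # sides swap with the reference, so the induced partition is identical
        assert (labels1 == labels2.map(
            {SYMMETRIC_LABEL: ASYMMETRIC_LABEL, ASYMMETRIC_LABEL: SYMMETRIC_LABEL}
        )).all()

    def test_identical_group_means_flagged_degenerate(self):
        vals = np.tile(np.array([[4.0], [6.0], [8.0]]), (1, 4))
        m = make_matrix(vals, conditions=["A", "A", "B", "B"])
        model = bga_fit(m)
        assert model.degenerate
        with pytest.raises(DegenerateModelError):
            project(model, m)

    def test_wrong_group_count_errors(self, toy_two_group):
        groups = pd.Series(["A", "B", "C", "A", "B"], index=toy_two_group.sample_ids)
        with pytest.raises(ValidationError, match="2 groups"):
            bga_fit(toy_two_group, groups=groups)

    def test_sample_order_and_duplicate_weighting_invariance(self, toy_two_group):
        m1 = bga_fit(toy_two_group, reference="B")
        shuffled = ExpressionMatrix(
            values=toy_two_group.values[["s4", "s1", "s5", "s3", "s2"]],
            conditions=toy_two_group.conditions[["s4", "s1", "s5", "s3", "s2"]],
        )
        m2 = bga_fit(shuffled, reference="B")
        np.testing.assert_allclose(m1.gene_loadings, m2.gene_loadings, atol=1e-12)
        # duplicating a whole group's samples leaves the group means unchanged
        dup = ExpressionMatrix(
            values=pd.concat(
                [toy_two_group.values, toy_two_group.values[["s4", "s5"]].rename(
                    columns={"s4": "s4b", "s5": "s5b"})], axis=1
            ),
            conditions=pd.concat(
                [toy_two_group.conditions, pd.Series({"s4b": "B", "s5b": "B"})]
            ),
        )
        m3 = bga_fit(dup, reference="B")
        np.testing.assert_allclose(m1.gene_loadings, m3.gene_loadings, atol=1e-12)


class TestProjection:
    def test_training_samples_fall_on_their_group_sides(self, toy_two_group):
        model = bga_fit(toy_two_group, reference="B")
        coords = project(model, toy_two_group)
        assert (coords[["s1", "s2", "s3"]] < model.boundary).all()
        assert (coords[["s4", "s5"]] > model.boundary).all()

    def test_group_mean_profile_projects_onto_centroid(self, toy_two_group):
        model = bga_fit(toy_two_group, reference="B")
        mean_a = toy_two_group.values[["s1", "s2", "s3"]].mean(axis=1)
        sample = ExpressionMatrix(values=mean_a.to_frame("mA"))
        coord = project(model, sample)["mA"]
        assert coord == pytest.approx(model.group_centroids["A"], abs=1e-10)

    def test_missing_genes_trigger_refit_on_common_subset(self, toy_two_group):
        model = bga_fit(toy_two_group, reference="B")
        partial = toy_two_group.subset_genes(toy_two_group.gene_ids[:4])
        coords = project(model, partial)
        assert np.isfinite(coords).all() and len(coords) == 5

    def test_model_save_load_round_trip(self, toy_two_group, tmp_path):
        model = bga_fit(toy_two_group, reference="B")
        model.save(tmp_path / "model.json")
        back = BGAModel.load(tmp_path / "model.json")
        np.testing.assert_allclose(back.gene_loadings, model.gene_loadings)
        assert back.group_centroids == pytest.approx(model.group_centroids)
        np.testing.assert_allclose(
            project(back, toy_two_group), project(model, toy_two_group)
        )


class TestClassify:
    def test_centroids_classify_to_their_fields(self, toy_two_group):
        model = bga_fit(toy_two_group, reference="B")
        labels = classify(
            model,
            pd.Series(
                {"sym": model.group_centroids["B"], "asym": model.group_centroids["A"]}
            ),
        )
        assert labels["sym"] == SYMMETRIC_LABEL
        assert labels["asym"] == ASYMMETRIC_LABEL

    def test_boundary_tie_labels_symmetric(self, toy_two_group):
        model = bga_fit(toy_two_group, reference="B")
        labels = classify(model, pd.Series({"tie": model.boundary}))
        assert labels["tie"] == SYMMETRIC_LABEL


class TestSeparationStats:
    def test_identical_groups_give_t0_p1(self):
        t, p = separation_pvalue([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_closed_form_pooled_t(self):
        # means 2 and 8, each group variance 1, pooled se = sqrt(2/3)
        t, p = separation_pvalue([1.0, 2.0, 3.0], [7.0, 8.0, 9.0])
        t_expected = (2 - 8) / np.sqrt(1.0 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_expected)  # -7.348469...
        assert p == pytest.approx(2 * stats.t.sf(abs(t_expected), df=4), rel=1e-12)

    def test_three_vs_five_uses_six_degrees_of_freedom(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 3), rng.normal(1, 1, 5)
        t, p = separation_pvalue(a, b)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=6), rel=1e-12)

    def test_zero_variance_edge_cases(self):
        _, p_equal = separation_pvalue([2.0, 2.0], [2.0, 2.0])
        assert p_equal == 1.0
        _, p_diff = separation_pvalue([2.0, 2.0], [3.0, 3.0])
        assert p_diff == 0.0

    def test_separation_distance_orientation(self):
        coords = pd.Series({"a1": -1.0, "a2": -3.0, "b1": 2.0, "b2": 4.0})
        groups = pd.Series({"a1": "ASYM", "a2": "ASYM", "b1": "SYM", "b2": "SYM"})
        assert separation_distance(coords, groups, "ASYM", "SYM") == pytest.approx(5.0)
        assert separation_distance(coords, groups, "SYM", "ASYM") == pytest.approx(-5.0)
        with pytest.raises(ValidationError):
            separation_distance(coords, groups, "ASYM", "nope")

    def test_equal_group_means_give_zero_distance(self):
        coords = pd.Series({"a": 1.0, "b": 3.0, "c": 2.0, "d": 2.0})
        groups = pd.Series({"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        assert separation_distance(coords, groups, "g1", "g2") == pytest.approx(0.0)


def test_merge_symmetric_labels_collapses_both_sym_states():
    cond = pd.Series(["ASYM", "SYM", "p53SYM"], index=["a", "b", "c"])
    merged = merge_symmetric_labels(cond)
    assert list(merged) == ["ASYM", "SYM", "SYM"]
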