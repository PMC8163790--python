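"""Rank tests, BH adjustment, fold changes, LASSO/PCA/classifier tools."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from proteotype.config import PipelineConfig
from proteotype.differential import (
    Contrast,
    benjamini_hochberg,
    cv_logistic_cstat,
    fold_change,
    lasso_select,
    mann_whitney,
    optional_t_test,
    pca_project,
    run_contrast,
    sex_contrast,
    strain_contrast,
)
from proteotype.io import ConcentrationMatrix, ValidationError, annotations_to_frame


def exact_mww_oracle(a, b):
    """Brute-force two-sided p: enumerate every group labeling of the pooled
    midranked values and count U statistics at least as extreme (distance
    from the null mean) as observed."""
    a, b = list(a), list(b)
    n_a = len(a)
    pooled = np.asarray(a + b, float)
    ranks = stats.rankdata(pooled)
    center = n_a * len(b) / 2.0
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    dev = abs(u_obs - center)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0
        total += 1
        hits += abs(u - center) >= dev - 1e-9
    return hits / total


class TestMannWhitney:
    def test_fully_separated_three_vs_three(self):
        # only the 2 extreme labelings out of C(6,3)=20 are as extreme
        _, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_fully_separated_five_vs_five(self):
        _, p = mann_whitney([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2 / 252, abs=1e-9)

    def test_constant_values_give_p_one(self):
        _, p = mann_whitney([7, 7, 7], [7, 7])
        assert p == 1.0

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_exact_path_matches_enumeration_oracle(self, data):
        n_a = data.draw(st.integers(2, 8))
        n_b = data.draw(st.integers(2, min(8, 10 - n_a)))
        # small integer support to force ties
        a = data.draw(st.lists(st.integers(0, 5), min_size=n_a, max_size=n_a))
        b = data.draw(st.lists(st.integers(0, 5), min_size=n_b, max_size=n_b))
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(exact_mww_oracle(a, b), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_exact_path_matches_scipy_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 7), rng.integers(2, 7)
        vals = rng.permutation(20)[: n_a + n_b].astype(float)
        a, b = vals[:n_a], vals[n_a:]
        _, p = mann_whitney(a, b)
        expected = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(expected.pvalue, abs=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 40), rng.normal(1, 1, 40)
        _, p = mann_whitney(a, b)
        expected = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(expected.pvalue, rel=1e-6)


class TestBenjaminiHochberg:
    def test_hand_applied_step_up(self):
        adj = benjamini_hochberg([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(adj, [0.02, 0.04, 0.04, 0.02])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.3]), [0.3])

    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.05] * 10), [0.05] * 10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.2])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_statsmodels_and_exceeds_raw(self, p_values):
        adj = benjamini_hochberg(p_values)
        expected = multipletests(p_values, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, expected, atol=1e-12)
        assert (adj >= np.asarray(p_values) - 1e-15).all()

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=15),
        st.data(),
    )
    def test_monotone_in_each_raw_p(self, p_values, data):
        i = data.draw(st.integers(0, len(p_values) - 1))
        bumped = list(p_values)
        bumped[i] = min(1.0, bumped[i] + data.draw(st.floats(0.0, 0.5)))
        before = benjamini_hochberg(p_values)
        after = benjamini_hochberg(bumped)
        assert (after >= before - 1e-12).all()


class TestFoldChange:
    def test_simple_doubling(self):
        fc = fold_change([2, 2], [4, 4])
        assert fc.fc == pytest.approx(2.0)
        assert fc.log_fc == pytest.approx(1.0)

    def test_equal_means_give_unit_fold(self):
        fc = fold_change([3, 5], [4, 4])
        assert fc.fc == pytest.approx(1.0)
        assert fc.log_fc == pytest.approx(0.0)

    def test_zero_mean_in_knockout_is_ablated(self):
        fc = fold_change([5, 5], [0, 0])
        assert fc.is_ablated
        assert fc.log_fc == -math.inf

    def test_both_zero_undefined(self):
        assert fold_change([0, 0], [0, 0]).status == "undefined"


def _make_matrix(rng, n_a=19, n_b=19, n_proteins=30, shift_protein=0, log2fc=2.0, cv=0.05):
    samples = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    base = 10.0 ** rng.uniform(0, 3, n_proteins)
    truth = np.tile(base, (n_a + n_b, 1))
    truth[n_a:, shift_protein] *= 2.0**log2fc
    sigma = math.sqrt(math.log1p(cv**2))
    obs = truth * rng.lognormal(-sigma**2 / 2, sigma, truth.shape)
    values = pd.DataFrame(obs, index=samples, columns=[f"P{j}" for j in range(n_proteins)])
    flags = pd.DataFrame("in_range", index=values.index, columns=values.columns)
    return ConcentrationMatrix(values, flags), samples[:n_a], samples[n_a:]


class TestRunContrast:
    def test_planted_fourfold_shift_detected_without_false_calls(self):
        hits = clean = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            matrix, a, b = _make_matrix(rng)
            contrast = Contrast("t", tuple(a), tuple(b), 0.05, 2.0, True)
            res = run_contrast(matrix, contrast)
            called = set(res.loc[res.significant, "protein_id"])
            hits += called >= {"P0"}
            clean += called <= {"P0"}
        assert hits >= 19
        assert clean >= 19

    def test_empty_matrix_gives_empty_result(self):
        values = pd.DataFrame(
            index=["A0", "A1", "B0", "B1"], columns=[], dtype=float
        )
        matrix = ConcentrationMatrix(values, values.astype(object))
        res = run_contrast(
            matrix, Contrast("t", ("A0", "A1"), ("B0", "B1"))
        )
        assert res.empty

    def test_ablated_protein_significant_with_sentinel(self):
        rng = np.random.default_rng(3)
        matrix, a, b = _make_matrix(rng, n_a=6, n_b=6)
        # knockouts read at blank level, censored below LLOQ
        matrix.values.loc[b, "P0"] = 0.01
        matrix.flags.loc[b, "P0"] = "below_lloq"
        res = run_contrast(matrix, Contrast("t", tuple(a), tuple(b)))
        row = res.set_index("protein_id").loc["P0"]
        assert row["ablated"]
        assert row["significant"]
        assert row["log2_fc"] == -math.inf

    def test_protein_missing_in_half_a_group_excluded(self):
        rng = np.random.default_rng(4)
        matrix, a, b = _make_matrix(rng, n_a=4, n_b=4, n_proteins=3)
        matrix.values.loc[a[:3], "P1"] = np.nan
        matrix.flags.loc[a[:3], "P1"] = "missing"
        res = run_contrast(matrix, Contrast("t", tuple(a), tuple(b)))
        assert "P1" not in set(res["protein_id"])

    def test_contrast_builders_resolve_groups(self, small_dataset):
        ann = annotations_to_frame(small_dataset.annotations)
        cfg = PipelineConfig()
        sc = sex_contrast(ann, cfg)
        assert len(sc.group_a) == len(sc.group_b) == len(ann) // 2
        kc = strain_contrast(ann, "KO01", cfg)
        assert len(kc.group_b) == 6
        assert kc.use_adjusted_p


class TestWelch:
    def test_identical_groups(self):
        t, p = optional_t_test([1, 2, 3], [1, 2, 3])
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_distinct_means_guarded(self):
        t, p = optional_t_test([0, 0, 0], [1, 1, 1])
        assert p == 0.0

    def test_textbook_value(self):
        t, _ = optional_t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.224744871, abs=1e-8)


class TestLassoSelect:
    def _data(self, rng, n=30, n_null=50, separate=True):
        y = np.array([0, 1] * (n // 2))
        x = pd.DataFrame(
            10.0 ** rng.normal(2, 0.3, (n, n_null + 1)),
            columns=[f"P{j}" for j in range(n_null + 1)],
        )
        if separate:
            x["P0"] = 10.0 ** (2 + y + rng.normal(0, 0.05, n))
        return x, y

    def test_perfect_separator_always_selected(self):
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            x, y = self._data(rng)
            assert "P0" in lasso_select(x, y, seed=seed)

    def test_pure_noise_selects_little(self):
        empties = 0
        for seed in range(12):
            rng = np.random.default_rng(300 + seed)
            x, y = self._data(rng, n=6, n_null=10, separate=False)
            empties += len(lasso_select(x, y, seed=seed)) <= 1
        assert empties >= 7

    def test_duplicate_feature_grows_selection_by_at_most_one(self):
        rng = np.random.default_rng(5)
        x, y = self._data(rng)
        base = lasso_select(x, y, seed=0)
        x2 = x.copy()
        x2["P0_dup"] = x["P0"]
        dup = lasso_select(x2, y, seed=0)
        assert len(dup) <= len(base) + 1

    def test_single_class_rejected(self):
        rng = np.random.default_rng(6)
        x, _ = self._data(rng, n=6)
        with pytest.raises(ValidationError):
            lasso_select(x, np.zeros(6, dtype=int), seed=0)


class TestPca:
    def test_anticorrelated_pair_loads_entirely_on_pc1(self):
        x = np.linspace(1, 2, 20)
        values = pd.DataFrame({"A": 10.0**x, "B": 10.0 ** (3 - x)})
        _, var = pca_project(values)
        assert var[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_noise_splits_variance_evenly(self):
        rng = np.random.default_rng(7)
        values = pd.DataFrame(10.0 ** rng.normal(1, 0.2, (100, 2)), columns=["A", "B"])
        _, var = pca_project(values)
        assert var[0] == pytest.approx(0.5, abs=0.05)
        assert var[1] == pytest.approx(0.5, abs=0.05)

    def test_scores_match_eigendecomposition_oracle_up_to_sign(self):
        rng = np.random.default_rng(8)
        values = pd.DataFrame(10.0 ** rng.normal(1, 0.3, (5, 4)))
        values.columns = [f"P{j}" for j in range(4)]
        scores, _ = pca_project(values, n_components=2)
        x = np.log10(values.to_numpy())
        z = (x - x.mean(0)) / x.std(0)
        cov = z.T @ z / len(z)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        expected = z @ evecs[:, order[:2]]
        for k in range(2):
            dots = np.abs(
                [np.dot(scores.iloc[:, k], expected[:, k])]
            ) / (np.linalg.norm(scores.iloc[:, k]) * np.linalg.norm(expected[:, k]))
            assert dots[0] == pytest.approx(1.0, abs=1e-8)

    def test_constant_protein_dropped(self):
        values = pd.DataFrame(
            {"A": [1.0, 2, 3, 4], "B": [5.0, 5, 5, 5], "C": [2.0, 1, 4, 3]}
        )
        scores, _ = pca_project(values)
        assert scores.shape[1] == 2


class TestCvLogisticCstat:
    def test_perfectly_separable_labels_score_one(self):
        rng = np.random.default_rng(9)
        y = np.array([0, 1] * 20)
        x = pd.DataFrame({"P0": 10.0 ** (1 + y + rng.normal(0, 0.01, 40))})
        report = cv_logistic_cstat(x, y, k=5, seed=0)
        assert report.mean_c_statistic == pytest.approx(1.0)

    def test_permuted_labels_score_near_chance(self):
        means = []
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            x = pd.DataFrame(10.0 ** rng.normal(1, 0.3, (100, 3)), columns=list("abc"))
            y = rng.permutation([0, 1] * 50)
            means.append(cv_logistic_cstat(x, y, k=5, seed=seed).mean_c_statistic)
        assert np.mean(means) == pytest.approx(0.5, abs=0.1)

    def test_k_larger_than_class_rejected(self):
        x = pd.DataFrame({"a": np.arange(6.0) + 1})
        with pytest.raises(ValidationError):
            cv_logistic_cstat(x, [0, 0, 0, 1, 1, 1], k=5, seed=0)
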