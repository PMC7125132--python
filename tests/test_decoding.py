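"""Lagged decoding: design construction, AUC oracles, nulls, odds ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from metahistory import (
    GeneratorConfig,
    build_lagged_design,
    cross_validated_auc,
    empirical_null,
    group_significance,
    odds_ratios,
    phi_correlation,
    conditional_probabilities,
    simulate_experiment,
    zero_lag_weights,
)
from metahistory.decoding import DecodingResult, LaggedDesign, atanh_phi
from metahistory.exceptions import ConstantColumnError
from tests.conftest import auc_by_pair_enumeration, toy_table


class TestLaggedDesign:
    def test_five_trial_toy_alignment(self):
        table = toy_table(
            prospective=[1, 0, 1, 1, 0],
            awareness=[1, 1, 0, 0, 1],
            confidence=[0, 1, 1, 0, 0],
        )
        design = build_lagged_design(table, "s01", 1)
        assert len(design) == 4
        # row 0 pairs features of trial 1 with the target of trial 2
        g = table.subject("s01")
        np.testing.assert_array_equal(
            design.features[0],
            g.loc[0, ["correct", "awareness", "confidence"]].to_numpy(),
        )
        assert design.target[0] == g.loc[1, "prospective"]
        np.testing.assert_array_equal(design.target, [0, 1, 1, 0])

    def test_lag4_row_count(self, default_experiment):
        design = build_lagged_design(default_experiment, "s01", 4)
        assert len(design) == 600 - 4

    def test_constant_features_pass_through(self):
        table = toy_table(
            prospective=[0, 1] * 10, awareness=[1] * 20, confidence=[0] * 20
        )
        design = build_lagged_design(table, "s01", 1)
        assert np.ptp(design.features[:, 1]) == 0
        cv = cross_validated_auc(design, n_splits=5, seed=0)
        assert np.all((cv.fold_aucs >= 0) & (cv.fold_aucs <= 1))

    def test_bad_lag_rejected(self, small_experiment):
        with pytest.raises(ValueError):
            build_lagged_design(small_experiment, "s01", 0)
        with pytest.raises(ValueError):
            build_lagged_design(small_experiment, "s01", 5)

    def test_within_block_drops_boundary_pairs(self, small_experiment):
        full = build_lagged_design(small_experiment, "s01", 2)
        within = build_lagged_design(small_experiment, "s01", 2, within_block=True)
        n_blocks = small_experiment.subject("s01")["block"].nunique()
        assert len(full) - len(within) == 2 * (n_blocks - 1)


class TestAUCOracle:
    def test_worked_example(self):
        """AUC 0.75 = 3 concordant pairs out of 4 for the textbook vectors."""
        y = [0, 0, 1, 1]
        s = [0.1, 0.4, 0.35, 0.8]
        assert auc_by_pair_enumeration(y, s) == 0.75
        assert roc_auc_score(y, s) == 0.75

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.floats(0, 1)), min_size=4,
                    max_size=50))
    def test_pair_enumeration_matches_roc(self, pairs):
        y = np.array([p[0] for p in pairs])
        s = np.array([p[1] for p in pairs])
        if len(np.unique(y)) < 2:
            return
        assert roc_auc_score(y, s) == pytest.approx(
            auc_by_pair_enumeration(y, s), abs=1e-12
        )

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.floats(0, 1)), min_size=4,
                    max_size=30))
    def test_target_inversion_antisymmetry(self, pairs):
        """For fixed scores, inverting the target maps AUC to 1 - AUC."""
        y = np.array([p[0] for p in pairs])
        s = np.array([p[1] for p in pairs])
        if len(np.unique(y)) < 2:
            return
        assert roc_auc_score(1 - y, s) == pytest.approx(
            1 - roc_auc_score(y, s), abs=1e-12
        )

    def test_fold_aucs_match_pair_enumeration(self, small_experiment):
        """Each fold's AUC equals exhaustive concordant-pair counting."""
        design = build_lagged_design(small_experiment, "s01", 1)
        small = LaggedDesign(1, design.features[:50], design.target[:50], "s01")
        cv = cross_validated_auc(small, n_splits=20, seed=3, record_folds=True)
        for auc, y, s in zip(cv.fold_aucs, cv.fold_targets, cv.fold_scores):
            assert auc == pytest.approx(auc_by_pair_enumeration(y, s), abs=1e-12)


class TestCrossValidation:
    def test_independent_target_scores_at_chance(self):
        rng = np.random.default_rng(0)
        design = LaggedDesign(
            1, rng.integers(0, 2, (600, 3)), rng.integers(0, 2, 600), "x"
        )
        cv = cross_validated_auc(design, n_splits=50, seed=1)
        assert cv.mean_auc == pytest.approx(0.5, abs=0.04)

    def test_deterministic_copy_is_perfectly_decodable(self):
        rng = np.random.default_rng(1)
        conf = rng.integers(0, 2, 200)
        X = np.column_stack([rng.integers(0, 2, 200), rng.integers(0, 2, 200), conf])
        design = LaggedDesign(1, X, conf.copy(), "x")
        cv = cross_validated_auc(design, n_splits=20, seed=2)
        assert cv.mean_auc == pytest.approx(1.0, abs=1e-9)

    def test_single_class_design_rejected(self):
        design = LaggedDesign(1, np.zeros((10, 3), dtype=int), np.ones(10, dtype=int),
                              "x")
        with pytest.raises(ValueError):
            cross_validated_auc(design, n_splits=2, seed=0)

    def test_seeded_reproducibility(self, small_experiment):
        design = build_lagged_design(small_experiment, "s02", 1)
        a = cross_validated_auc(design, n_splits=10, seed=7)
        b = cross_validated_auc(design, n_splits=10, seed=7)
        np.testing.assert_array_equal(a.fold_aucs, b.fold_aucs)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)


class TestEmpiricalNull:
    def test_null_centres_on_chance(self, small_experiment):
        design = build_lagged_design(small_experiment, "s01", 1)
        null = empirical_null(design, n_permutations=30, n_splits=30, seed=4)
        assert null.mean() == pytest.approx(0.5, abs=0.02)

    def test_null_destroys_perfect_association(self):
        rng = np.random.default_rng(3)
        conf = rng.integers(0, 2, 300)
        X = np.column_stack([rng.integers(0, 2, 300), rng.integers(0, 2, 300), conf])
        design = LaggedDesign(1, X, conf.copy(), "x")
        null = empirical_null(design, n_permutations=20, n_splits=20, seed=5)
        assert null.mean() == pytest.approx(0.5, abs=0.03)

    def test_different_seeds_same_centre(self, small_experiment):
        design = build_lagged_design(small_experiment, "s01", 1)
        a = empirical_null(design, n_permutations=15, n_splits=15, seed=10)
        b = empirical_null(design, n_permutations=15, n_splits=15, seed=11)
        assert not np.array_equal(a, b)
        assert abs(a.mean() - b.mean()) < 0.03


def _result(subject, lag, mean_auc, chance, coef=None):
    n = 10
    return DecodingResult(
        subject=subject,
        lag=lag,
        fold_aucs=np.full(n, mean_auc),
        coefficients=np.tile(coef if coef is not None else np.zeros(3), (n, 1)),
        intercepts=np.zeros(n),
        null_aucs=np.full(n, chance),
    )


class TestGroupSignificance:
    def test_all_zero_differences_give_p_one(self):
        results = [_result(f"s{i}", 1, 0.5, 0.5) for i in range(10)]
        table = group_significance(results, n_resamples=500, seed=0)
        assert table.loc[0, "p"] == 1.0

    def test_consistent_positive_shift_is_significant(self):
        """15 subjects all +0.2 above chance: exhaustive sign-flip
        enumeration gives p = 2/2^15; resampling hits the +1 floor."""
        results = [_result(f"s{i}", 1, 0.7, 0.5) for i in range(15)]
        n_resamples = 2000
        table = group_significance(results, n_resamples=n_resamples, seed=1)
        # exhaustive enumeration oracle: only the two all-same-sign
        # assignments reach |mean| >= 0.2
        exhaustive_p = 2 / 2**15
        assert exhaustive_p < 1 / (1 + n_resamples)
        assert table.loc[0, "p"] <= 2 / (1 + n_resamples)

    def test_bonferroni_multiplies_by_lag_count(self):
        rng = np.random.default_rng(2)
        results = [
            _result(f"s{i}", lag, 0.5 + rng.normal(0, 0.05), 0.5)
            for i in range(6)
            for lag in (1, 2, 3, 4)
        ]
        table = group_significance(results, n_resamples=500, seed=3)
        for _, row in table.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, 4 * row["p"]))

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            group_significance([_result("s1", 1, 0.6, 0.5)], n_resamples=10, seed=0)


class TestOddsRatios:
    def test_zero_coefficients_give_unit_odds(self):
        results = [_result(f"s{i}", 1, 0.5, 0.5, coef=np.zeros(3)) for i in range(5)]
        table = odds_ratios(results, seed=0)
        assert np.allclose(table["odds_ratio"], 1.0)

    def test_known_coefficient_exponentiates(self):
        coef = np.array([0.0, 0.0, math.log(3.0)])
        results = [_result(f"s{i}", 1, 0.6, 0.5, coef=coef) for i in range(5)]
        table = odds_ratios(results, seed=0)
        conf_rows = table[table["feature"] == "confidence"]
        assert np.allclose(conf_rows["odds_ratio"], 3.0)
        assert np.allclose(conf_rows["mean_or"], 3.0)

    def test_independent_feature_or_near_one(self):
        """Decoding a generator whose only lag-1 weight is on confidence:
        the unweighted features' odds ratios stay near 1 and the
        confidence odds ratio recovers ~3."""
        beta = zero_lag_weights()
        beta[1]["confidence"] = math.log(3.0)
        cfg = GeneratorConfig(n_subjects=6, beta=beta, seed=17)
        table = simulate_experiment(cfg)
        results = []
        for s in table.subjects:
            design = build_lagged_design(table, s, 1)
            cv = cross_validated_auc(design, n_splits=20, seed=hash(s) % 2**31)
            results.append(
                DecodingResult(s, 1, cv.fold_aucs, cv.coefficients, cv.intercepts,
                               np.array([0.5]))
            )
        ors = odds_ratios(results, seed=1)
        summary = ors.drop_duplicates(["lag", "feature"])
        by_feature = summary.set_index("feature")["mean_or"]
        assert by_feature["confidence"] == pytest.approx(3.0, rel=0.25)
        assert by_feature["correct"] == pytest.approx(1.0, abs=0.25)
        assert by_feature["awareness"] == pytest.approx(1.0, abs=0.25)


class TestPhi:
    def test_identical_vectors(self):
        x = np.array([0, 1, 1, 0, 1])
        assert phi_correlation(x, x) == pytest.approx(1.0)

    def test_closed_form_2x2(self):
        """Counts a=30, b=20, c=20, d=30 give (ad-bc)/sqrt(margins) = 0.2."""
        x = np.repeat([1, 1, 0, 0], [30, 20, 20, 30])
        y = np.repeat([1, 0, 1, 0], [30, 20, 20, 30])
        assert phi_correlation(x, y) == pytest.approx(0.2)

    def test_constant_vector_raises(self):
        with pytest.raises(ConstantColumnError):
            phi_correlation(np.ones(10), np.array([0, 1] * 5))

    def test_atanh_transform(self):
        assert atanh_phi(0.0) == 0.0
        assert atanh_phi(0.2) == pytest.approx(math.atanh(0.2))

    @settings(max_examples=100, derandomize=True)
    @given(st.tuples(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30),
                     st.integers(1, 30)))
    def test_matches_contingency_formula(self, counts):
        a, b, c, d = counts
        x = np.repeat([1, 1, 0, 0], [a, b, c, d])
        y = np.repeat([1, 0, 1, 0], [a, b, c, d])
        expected = (a * d - b * c) / math.sqrt(
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert phi_correlation(x, y) == pytest.approx(expected, abs=1e-12)


class TestConditionalProbabilities:
    def test_deterministic_confidence_rule(self):
        """prospective_t = confidence_{t-1} pins the conditional grid at 0/1."""
        rng = np.random.default_rng(4)
        conf = rng.integers(0, 2, 101)
        table = toy_table(
            prospective=[0] + list(conf[:-1]),
            confidence=list(conf),
            awareness=list(rng.integers(0, 2, 101)),
        )
        grid = conditional_probabilities(table)
        filled = grid[grid["n"] > 0]
        high = filled[filled["conf"] == 1]
        low = filled[filled["conf"] == 0]
        assert (high["p_high"] == 1.0).all()
        assert (low["p_high"] == 0.0).all()

    def test_independent_history_flat_grid(self):
        cfg = GeneratorConfig(n_subjects=3, beta=zero_lag_weights(), seed=23)
        table = simulate_experiment(cfg)
        grid = conditional_probabilities(table)
        marginal = table.data["prospective"].mean()
        filled = grid[grid["n"] >= 20]
        assert np.allclose(filled["p_high"], marginal, atol=0.15)

    def test_awareness_only_effect_varies_only_with_awareness(self):
        beta = zero_lag_weights()
        beta[1]["awareness"] = 1.5
        cfg = GeneratorConfig(n_subjects=8, beta=beta, seed=29)
        table = simulate_experiment(cfg)
        grid = conditional_probabilities(table)
        means = grid.groupby(["correct", "aware", "conf"])["p_high"].mean()
        aware_effect = means.groupby("aware").mean()
        conf_effect = means.groupby("conf").mean()
        corr_effect = means.groupby("correct").mean()
        assert aware_effect[1] - aware_effect[0] > 0.2
        assert abs(conf_effect[1] - conf_effect[0]) < 0.05
        assert abs(corr_effect[1] - corr_effect[0]) < 0.05

    def test_missing_cells_reported_not_imputed(self):
        table = toy_table(
            prospective=[0, 1] * 10, awareness=[1] * 20, confidence=[1] * 20
        )
        grid = conditional_probabilities(table)
        assert len(grid) == 8
        missing = grid[grid["n"] == 0]
        assert missing["p_high"].isna().all()
        # every trial is correct, aware and confident: one filled cell
        assert len(missing) == 7
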