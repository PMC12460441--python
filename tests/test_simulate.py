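"""Generator contracts: prevalence, determinism, missingness mechanisms,
difference features and the stratified split with its rejection rule."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from woerisk import (
    Cohort,
    CohortSpec,
    ConfigurationError,
    VariableSpec,
    derive_difference_features,
    generate_cohort,
    inject_missingness,
    make_study_cohort,
    reject_bad_split,
    stratified_split,
)


def null_spec(n, intercept=0.0, seed=0):
    return CohortSpec(
        n_subjects=n, intercept=intercept, seed=seed,
        variables=(VariableSpec(name="x", vartype="continuous"),),
    )


@pytest.mark.parametrize("intercept", [0.0, -2.0])
def test_prevalence_matches_logistic_of_intercept(intercept):
    n = 10000
    cohort = generate_cohort(null_spec(n, intercept=intercept, seed=4))
    p = expit(intercept)
    se = np.sqrt(p * (1 - p) / n)
    assert abs(cohort.outcome.mean() - p) < 3 * se


def test_generation_is_deterministic():
    a = generate_cohort(null_spec(500, seed=9))
    b = generate_cohort(null_spec(500, seed=9))
    pd.testing.assert_frame_equal(a.features, b.features)
    assert np.array_equal(a.outcome, b.outcome)
    assert np.array_equal(a.truth.log_odds, b.truth.log_odds)


def test_truth_log_odds_reproduce_outcome_rates():
    spec = CohortSpec(
        n_subjects=40000, seed=2,
        variables=(VariableSpec(name="b", vartype="binary", informative=True,
                                effect=(-1.0, 1.0)),),
    )
    cohort = generate_cohort(spec)
    for lo in np.unique(cohort.truth.log_odds):
        sel = cohort.truth.log_odds == lo
        assert abs(cohort.outcome[sel].mean() - expit(lo)) < 0.02


def test_variable_spec_invariants():
    with pytest.raises(ConfigurationError):
        VariableSpec(name="x", vartype="continuous", informative=True)  # no effect
    with pytest.raises(ConfigurationError):
        VariableSpec(name="x", vartype="categorical", n_categories=1)
    with pytest.raises(ConfigurationError):
        CohortSpec(n_subjects=10, missing_rate=1.0,
                   variables=(VariableSpec(name="x", vartype="continuous"),))


class TestMissingness:
    def test_rate_zero_is_identity(self, small_cohort):
        out = inject_missingness(small_cohort, 0.0, "MCAR", seed=1)
        pd.testing.assert_frame_equal(out.features, small_cohort.features)

    def test_mcar_rate_at_study_dimensions(self):
        spec = CohortSpec(
            n_subjects=155, seed=3,
            variables=tuple(VariableSpec(name=f"v{j}", vartype="continuous")
                            for j in range(135)),
        )
        cohort = inject_missingness(generate_cohort(spec), 0.35, "MCAR", seed=5)
        assert 0.34 <= cohort.missing_fraction() <= 0.36

    def test_mar_on_outcome_direction(self):
        spec = null_spec(10000, seed=6)
        cohort = inject_missingness(generate_cohort(spec), 0.3,
                                    "MAR-on-outcome", seed=7, mar_factor=2.0)
        miss = cohort.features["x"].isna().to_numpy()
        r1 = miss[cohort.outcome == 1].mean()
        r0 = miss[cohort.outcome == 0].mean()
        assert r1 > r0
        assert abs(miss.mean() - 0.3) < 0.02
        # outcome itself is never masked
        assert not np.isnan(cohort.outcome).any()

    def test_invalid_rate_rejected(self, small_cohort):
        with pytest.raises(ConfigurationError):
            inject_missingness(small_cohort, 1.0, "MCAR", seed=0)


class TestDifferenceFeatures:
    @staticmethod
    def cohort(values: dict, timepoints: dict):
        specs = [VariableSpec(name=k, vartype="continuous", measure="CRT",
                              timepoint=timepoints[k]) for k in values]
        df = pd.DataFrame(values, dtype=float)
        return Cohort(df, np.zeros(len(df), dtype=int), specs)

    def test_baseline_minus_later(self):
        c = self.cohort({"CRT b": [10.0], "CRT a": [12.0]},
                        {"CRT b": "baseline", "CRT a": "acute"})
        out = derive_difference_features(c)
        assert out.features["CRT Difference Baseline Acute"].iloc[0] == -2.0

    def test_missing_operand_propagates(self):
        c = self.cohort({"CRT b": [np.nan, 10.0], "CRT a": [12.0, np.nan]},
                        {"CRT b": "baseline", "CRT a": "acute"})
        out = derive_difference_features(c)
        assert out.features["CRT Difference Baseline Acute"].isna().all()

    def test_one_column_per_later_timepoint(self):
        c = self.cohort(
            {"b": [1.0], "a": [2.0], "s": [3.0], "r": [4.0]},
            {"b": "baseline", "a": "acute", "s": "asymptomatic", "r": "rtp"},
        )
        out = derive_difference_features(c)
        added = [n for n in out.features.columns if "Difference" in n]
        assert sorted(added) == [
            "CRT Difference Baseline Acute",
            "CRT Difference Baseline Asymptomatic",
            "CRT Difference Baseline RTP",
        ]
        assert out.features["CRT Difference Baseline RTP"].iloc[0] == -3.0

    def test_later_without_baseline_skipped_with_warning(self, caplog):
        c = self.cohort({"CRT a": [12.0]}, {"CRT a": "acute"})
        with caplog.at_level(logging.WARNING):
            out = derive_difference_features(c)
        assert out.features.shape[1] == 1
        assert any("without a baseline" in r.message for r in caplog.records)


class TestStratifiedSplit:
    @staticmethod
    def cohort_with_outcome(y):
        y = np.asarray(y)
        df = pd.DataFrame({"x": np.arange(len(y), dtype=float)})
        return Cohort(df, y, [VariableSpec(name="x", vartype="continuous")])

    def test_study_split_counts(self):
        y = np.r_[np.ones(120, dtype=int), np.zeros(74, dtype=int)]
        train, test = stratified_split(self.cohort_with_outcome(y), 0.2, seed=0)
        assert (test.outcome.sum(), (1 - test.outcome).sum()) == (24, 15)
        assert (train.outcome.sum(), (1 - train.outcome).sum()) == (96, 59)

    def test_round_half_up_per_class(self):
        # 5 per class at fraction 0.5: round-half-up gives 3 test subjects each
        y = np.r_[np.ones(5, dtype=int), np.zeros(5, dtype=int)]
        train, test = stratified_split(self.cohort_with_outcome(y), 0.5, seed=1)
        assert test.outcome.sum() == 3 and (1 - test.outcome).sum() == 3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("frac", [0.2, 0.33, 0.5])
    def test_split_disjoint_exhaustive_and_proportionate(self, seed, frac):
        rng = np.random.default_rng(seed)
        y = rng.binomial(1, 0.6, size=163)
        cohort = self.cohort_with_outcome(y)
        train, test = stratified_split(cohort, frac, seed=seed)
        assert train.n_subjects + test.n_subjects == cohort.n_subjects
        joined = np.sort(np.r_[train.features["x"], test.features["x"]])
        assert np.array_equal(joined, np.arange(len(y), dtype=float))
        for cls in (0, 1):
            n_cls = (y == cls).sum()
            got = (test.outcome == cls).sum()
            assert abs(got - frac * n_cls) <= 0.5 + 1e-9

    def test_deterministic_given_seed(self, small_cohort):
        a = stratified_split(small_cohort, 0.25, seed=5)
        b = stratified_split(small_cohort, 0.25, seed=5)
        pd.testing.assert_frame_equal(a[1].features, b[1].features)

    def test_tiny_class_rejected(self):
        y = np.r_[np.ones(10, dtype=int), np.zeros(1, dtype=int)]
        with pytest.raises(ConfigurationError):
            stratified_split(self.cohort_with_outcome(y), 0.2, seed=0)


class TestRejectBadSplit:
    @staticmethod
    def pair(train_cats, test_cats):
        spec = [VariableSpec(name="sport", vartype="categorical", n_categories=4)]
        mk = lambda cats: Cohort(pd.DataFrame({"sport": cats}),
                                 np.zeros(len(cats), dtype=int), spec)
        return mk(train_cats), mk(test_cats)

    def test_novel_test_category_rejected(self):
        train, test = self.pair(["Soccer", "Rowing"], ["Tennis"])
        assert reject_bad_split(train, test) is True

    def test_covered_categories_accepted(self):
        train, test = self.pair(["Soccer", "Rowing", "Tennis"], ["Tennis"])
        assert reject_bad_split(train, test) is False

    def test_continuous_only_vacuous(self, small_cohort):
        train, test = stratified_split(small_cohort.drop_variables(
            ["cat_inf", "cat_noise"]), 0.2, seed=0)
        assert reject_bad_split(train, test) is False


def test_study_cohort_shape_and_missingness():
    cohort = make_study_cohort(seed=2)
    assert cohort.features.shape == (194, 135)
    assert 0.2 < cohort.missing_fraction() < 0.45
    kinds = {v.vartype for v in cohort.dictionary}
    assert kinds == {"continuous", "categorical", "binary"}
    # derived differences present and never re-differenced
    diffs = [v for v in cohort.dictionary if "Difference" in v.name]
    assert len(diffs) == 54
    assert all(v.measure is None for v in diffs)
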