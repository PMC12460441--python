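"""Regularization path, AICc selection, L2 refit and prediction semantics,
with statsmodels as the independent penalized/unpenalized oracle."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit

from woerisk import (
    PipelineConfig,
    RiskModel,
    WoETable,
    aicc,
    fit_benchmark_raw,
    fit_l1_path,
    fit_l2,
    fit_pipeline,
    generate_cohort,
    lambda_max,
    recovery_spec,
    select_model,
    stratified_split,
)
from woerisk.binning import BinningScheme
from woerisk.metrics import roc_auc
from woerisk.model import ModelPath, PathPoint, log_likelihood


@pytest.fixture(scope="module")
def design():
    rng = np.random.default_rng(21)
    n, p = 600, 8
    X = rng.normal(size=(n, p))
    beta = np.r_[1.0, -1.0, 0.8, np.zeros(p - 3)]
    y = rng.binomial(1, expit(X @ beta))
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(p)]), y


class TestAicc:
    def test_stated_closed_form(self):
        assert aicc(-50.0, 5, 100) == pytest.approx(100 + 10 + 60 / 94, abs=1e-12)

    def test_zero_parameters(self):
        assert aicc(-50.0, 0, 100) == pytest.approx(100.0)

    def test_large_n_limit_is_plain_aic(self):
        assert aicc(-50.0, 5, 10**8) == pytest.approx(110.0, abs=1e-5)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            aicc(-50.0, 5, 6)


class TestL1Path:
    def test_lambda_max_point_is_null_model(self, design):
        X, y = design
        path = fit_l1_path(X, y, grid_size=20)
        top = path.points[0]
        assert top.lam == pytest.approx(lambda_max(X.to_numpy(), y))
        assert np.all(top.coefs == 0.0)
        assert top.intercept == pytest.approx(logit(y.mean()), abs=1e-12)
        assert top.k == 1

    def test_coefficients_activate_just_below_lambda_max(self, design):
        X, y = design
        path = fit_l1_path(X, y, grid_size=40)
        assert np.any(path.points[1].coefs != 0.0)

    def test_loglik_weakly_increases_as_lambda_decreases(self, design):
        X, y = design
        path = fit_l1_path(X, y, grid_size=30)
        lls = [p.loglik for p in path.points]
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_matches_statsmodels_penalized_fit(self, design):
        """Mid-path point vs an independent L1-penalized optimizer."""
        X, y = design
        path = fit_l1_path(X, y, grid_size=30, tol=1e-9, max_iter=5000)
        pt = path.points[12]
        Xi = sm.add_constant(X.to_numpy())
        alpha = np.r_[0.0, np.full(X.shape[1], pt.lam)]
        res = sm.Logit(y, Xi).fit_regularized(method="l1", alpha=alpha, disp=0,
                                              acc=1e-12, maxiter=2000)
        assert res.params[1:] == pytest.approx(pt.coefs, abs=2e-4)
        assert res.params[0] == pytest.approx(pt.intercept, abs=2e-4)

    def test_incomplete_design_rejected(self, design):
        X, y = design
        X = X.copy()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_l1_path(X, y)


class TestSelect:
    def test_argmin_and_sparser_tie_break(self):
        mk = lambda lam, coefs, crit: PathPoint(
            lam=lam, intercept=0.0, coefs=np.array(coefs), loglik=-10.0,
            k=int(np.count_nonzero(coefs)) + 1, aicc=crit)
        path = ModelPath(columns=["a", "b"], n=100, points=[
            mk(1.0, [0.0, 0.0], 30.0),
            mk(0.5, [1.0, 0.0], 25.0),
            mk(0.1, [1.0, 1.0], 25.0),
        ])
        assert select_model(path) == ["a"]

    def test_permutation_null_selects_almost_nothing(self):
        """Labels permuted after the WoE transform (the path's input is a
        fixed complete matrix): AICc keeps almost no variable on average."""
        from woerisk.woe import WoEEncoder

        cohort = generate_cohort(recovery_spec(n_subjects=2000, seed=31))
        X = WoEEncoder().fit_transform(cohort.features, cohort.outcome)
        counts = []
        for seed in range(32, 37):
            y = np.random.default_rng(seed).permutation(cohort.outcome)
            path = fit_l1_path(X, y, grid_size=50)
            counts.append(len(select_model(path)))
        assert np.mean(counts) <= 4.0


class TestL2:
    def test_duplicated_columns_get_equal_coefficients(self, design):
        X, y = design
        Xd = pd.concat([X[["x0"]], X[["x0"]].rename(columns={"x0": "x0b"})], axis=1)
        intercept, coefs = fit_l2(Xd, y, l2_strength=1.0)
        assert np.isfinite(coefs).all()
        assert coefs[0] == pytest.approx(coefs[1], abs=1e-5)

    def test_vanishing_penalty_approaches_mle(self, design):
        X, y = design
        Xs = X.iloc[:, :3]
        _, coefs = fit_l2(Xs, y, l2_strength=1e-10)
        res = sm.Logit(y, sm.add_constant(Xs.to_numpy())).fit(disp=0)
        assert coefs == pytest.approx(res.params[1:], abs=1e-5)

    def test_empty_selection_gives_prevalence_model(self, design):
        _, y = design
        intercept, coefs = fit_l2(np.empty((len(y), 0)), y)
        assert coefs.size == 0
        assert expit(intercept) == pytest.approx(y.mean(), abs=1e-12)


def toy_model():
    """Hand-built two-variable model with known WoE tables."""
    mk = lambda name, w_lo, w_hi: WoETable(
        scheme=BinningScheme(variable=name, kind="continuous", edges=(0.0,)),
        n1=(8, 2), n0=(2, 8), woe=(w_lo, w_hi), iv=1.0, smoothing=0.0)
    return RiskModel(
        variables=["a", "b"], intercept=-0.5, coefficients=np.array([1.0, 2.0]),
        l2_strength=0.01,
        woe_tables={"a": mk("a", -1.0, 1.0), "b": mk("b", -0.5, 0.5)},
        train_means={"a": 0.0, "b": 0.0},
    )


class TestPredict:
    def test_probability_is_logistic_of_logit(self):
        model = toy_model()
        frame = pd.DataFrame({"a": [-1.0, 1.0], "b": [1.0, -1.0]})
        z, p = model.predict(frame)
        assert p == pytest.approx(expit(z), abs=1e-15)
        # a=-1 -> woe -1, b=1 -> woe 0.5: logit = -0.5 - 1 + 1 = -0.5
        assert z[0] == pytest.approx(-0.5)

    def test_neutral_record_scores_sigma_w0(self):
        model = toy_model()
        # missing values hit no fitted missing bin -> WoE 0 for both variables
        z, p = model.predict(pd.DataFrame({"a": [np.nan], "b": [np.nan]}))
        assert z[0] == pytest.approx(model.intercept)
        assert p[0] == pytest.approx(expit(model.intercept))

    def test_zero_logit_is_half(self):
        model = toy_model()
        model.intercept = 0.0
        z, p = model.predict(pd.DataFrame({"a": [np.nan], "b": [np.nan]}))
        assert (z[0], p[0]) == (0.0, 0.5)

    def test_one_bin_move_changes_logit_by_w_delta_woe(self):
        model = toy_model()
        lo = model.predict(pd.DataFrame({"a": [-1.0], "b": [-1.0]}))[0][0]
        hi = model.predict(pd.DataFrame({"a": [1.0], "b": [-1.0]}))[0][0]
        assert hi - lo == pytest.approx(1.0 * (1.0 - (-1.0)), abs=1e-12)

    def test_unknown_variables_reported(self):
        model = toy_model()
        with pytest.raises(KeyError, match="b"):
            model.predict(pd.DataFrame({"a": [0.0]}))

    def test_serialization_round_trip(self, small_fit, small_cohort, tmp_path):
        path = tmp_path / "model.json"
        small_fit.model.to_json(path)
        clone = RiskModel.from_json(path)
        np.testing.assert_array_equal(
            clone.decision_function(small_cohort.features),
            small_fit.model.decision_function(small_cohort.features))


class TestPipelineRecovery:
    def test_informative_variables_precede_noise_on_path(self):
        """Entry order along the path: informative variables activate at
        larger penalties than noise variables on average."""
        cohort = generate_cohort(recovery_spec(n_subjects=2000, n_variables=20,
                                               n_informative=4, seed=55))
        fit = fit_pipeline(cohort, PipelineConfig(grid_size=60))
        entry = {}
        for i, pt in enumerate(fit.path.points):
            for v, w in zip(fit.path.columns, pt.coefs):
                if w != 0 and v not in entry:
                    entry[v] = i
        informative = cohort.truth.informative
        inf_entry = np.mean([entry.get(v, len(fit.path.points)) for v in informative])
        noise_entry = np.mean([entry.get(v, len(fit.path.points))
                               for v in fit.path.columns if v not in informative])
        assert inf_entry < noise_entry

    def test_independent_woe_coefficients_near_one(self):
        """Naive-Bayes correspondence: with independent informative variables
        of modest strength the logistic weights on WoE columns concentrate
        near 1 (non-collapsibility inflates them as effects grow)."""
        cohort = generate_cohort(recovery_spec(n_subjects=8000, n_variables=4,
                                               n_informative=4,
                                               effect_size=0.5, seed=77))
        fit = fit_pipeline(cohort, PipelineConfig(),
                           variables=list(cohort.truth.informative),
                           skip_selection=True)
        assert fit.model.coefficients == pytest.approx(np.ones(4), abs=0.25)


@pytest.fixture(scope="module")
def raw():
    rng = np.random.default_rng(41)
    n = 300
    df = pd.DataFrame({
        "num": rng.normal(size=n),
        "cat": rng.choice(["a", "b", "c"], size=n).astype(object),
        "flat": np.ones(n),
    })
    df.loc[:49, "num"] = np.nan
    y = rng.binomial(1, expit(df["num"].fillna(0) * 1.5))
    return df, y


class TestBenchmark:
    def test_design_matrix_semantics(self, raw):
        df, y = raw
        model = fit_benchmark_raw(df, y, kinds={"cat": "categorical"},
                                  grid_size=20)
        X = model.design(df)
        # 3 indicator columns + standardized numeric; zero-variance dropped
        assert [c for c in X.columns if c.startswith("cat=")] == \
            ["cat=a", "cat=b", "cat=c"]
        assert "flat" not in X.columns
        assert X["num"].mean() == pytest.approx(0.0, abs=1e-12)
        assert X["num"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)
        # imputation at the training mean -> standardized missing rows are 0
        assert X.loc[:49, "num"].unique() == pytest.approx([0.0])

    def test_benchmark_predicts_on_new_rows(self, raw):
        df, y = raw
        model = fit_benchmark_raw(df, y, kinds={"cat": "categorical"},
                                  grid_size=20)
        new = pd.DataFrame({"num": [np.nan, 2.0], "cat": ["b", "z"],
                            "flat": [1.0, 1.0]})
        z, p = model.predict(new)
        assert np.isfinite(z).all()
        assert p == pytest.approx(expit(z))


def test_full_pipeline_beats_chance_on_held_out_data(small_cohort, fast_config):
    train, test = stratified_split(small_cohort, 0.3, seed=2)
    fit = fit_pipeline(train, fast_config)
    auc = roc_auc(fit.model.decision_function(test.features), test.outcome)
    bayes = roc_auc(test.truth.log_odds, test.outcome)
    assert 0.6 < auc <= bayes + 0.05
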