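"""Penalized logistic risk modelling on WoE-transformed variables.

The model approximates the log-odds of injury as a weighted sum of the
per-variable weights of evidence,

    logit(x) = w0 + Σ_i w_i · WoE_i(x_i),        P(Y=1|x) = σ(logit(x)),

fitted in three stages: an L1-regularization path over a log-spaced λ grid
(the L1 penalty zeroes coefficients, performing variable selection), model
choice by the corrected Akaike Information Criterion along the path, and an
L2-regularized refit of the selected variables that tempers collinearity
among correlated predictors.  With mutually independent predictors the WoE
coefficients concentrate near 1, the naive-Bayes correspondence.

The per-λ penalized optimizations are delegated to scikit-learn (saga for
L1, lbfgs for L2) with the intercept left unpenalized; λ_max, the analytic
null fit, path bookkeeping, AICc and selection live here.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit as logit_fn
from sklearn.linear_model import LogisticRegression

from .woe import WoEEncoder, WoETable, woe_apply

logger = logging.getLogger(__name__)


def log_likelihood(intercept: float, coefs: np.ndarray, X: np.ndarray,
                   y: np.ndarray) -> float:
    """Unpenalized Bernoulli log-likelihood at the given coefficients."""
    z = intercept + X @ coefs
    # log σ(z) and log σ(-z), numerically stable
    return float(-(np.logaddexp(0.0, -z) * y + np.logaddexp(0.0, z) * (1 - y)).sum())


def aicc(loglik: float, k: int, n: int) -> float:
    """Corrected AIC: −2·loglik + 2k + 2k(k+1)/(n−k−1).

    ``k`` counts all fitted parameters including the intercept.  Requires
    n > k + 1, where the small-sample correction is defined.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest λ at which every non-intercept coefficient is exactly zero:
    the max absolute score-function entry at the prevalence-only null fit."""
    ybar = y.mean()
    return float(np.abs(X.T @ (y - ybar)).max())


@dataclass(frozen=True)
class PathPoint:
    lam: float
    intercept: float
    coefs: np.ndarray
    loglik: float
    k: int  # active coefficients, intercept included
    aicc: float
    converged: bool = True


@dataclass
class ModelPath:
    """L1 regularization path: one penalized fit per λ, λ decreasing."""

    columns: list
    n: int
    points: list

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([p.lam for p in self.points])

    def active_set(self, point: PathPoint) -> list:
        return [c for c, w in zip(self.columns, point.coefs) if w != 0.0]


def fit_l1_path(X, y, grid_size: int = 100, lambda_min_ratio: float = 1e-3,
                tol: float = 1e-7, max_iter: int = 1000,
                random_state: int = 0) -> ModelPath:
    """Fit the L1-penalized logistic path on a complete design matrix.

    The grid is log-spaced from λ_max down to λ_max·lambda_min_ratio.  The
    λ_max point is the analytic null optimum (zero coefficients, intercept at
    the prevalence log-odds); subsequent points are warm-started saga fits of
    the objective −loglik + λ·Σ|w_i| with the intercept unpenalized.
    Non-convergence within ``max_iter`` is recorded on the point and warned
    about — the usual symptom of quasi-separation at small λ, where the
    iteration cap bounds the coefficients.
    """
    columns = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(X.shape[1])]
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.isnan(Xa).any():
        raise ValueError("design matrix must be complete (WoE-transformed)")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    n, p = Xa.shape
    lam_max = lambda_max(Xa, y)
    grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, grid_size)
    ybar = y.mean()
    null_intercept = float(logit_fn(ybar))
    null_ll = log_likelihood(null_intercept, np.zeros(p), Xa, y)

    points = []
    clf = LogisticRegression(l1_ratio=1.0, solver="saga", warm_start=True,
                             tol=tol, max_iter=max_iter, random_state=random_state)
    for lam in grid:
        if lam >= lam_max:
            coefs = np.zeros(p)
            pt = PathPoint(lam=float(lam), intercept=null_intercept, coefs=coefs,
                           loglik=null_ll, k=1, aicc=aicc(null_ll, 1, n))
            points.append(pt)
            continue
        clf.C = 1.0 / lam
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # we flag non-convergence ourselves
            clf.fit(Xa, y)
        converged = int(np.max(clf.n_iter_)) < max_iter
        coefs = clf.coef_[0].copy()
        intercept = float(clf.intercept_[0])
        ll = log_likelihood(intercept, coefs, Xa, y)
        k = int(np.count_nonzero(coefs)) + 1
        crit = aicc(ll, k, n) if n > k + 1 else math.inf
        points.append(PathPoint(lam=float(lam), intercept=intercept, coefs=coefs,
                                loglik=ll, k=k, aicc=crit, converged=converged))
    n_capped = sum(not p.converged for p in points)
    if n_capped:
        logger.warning(
            "%d/%d path fits hit max_iter=%d (expected under quasi-separation "
            "at small lambda; coefficients are capped by the iteration bound)",
            n_capped, len(points), max_iter)
    return ModelPath(columns=columns, n=n, points=points)


def select_model(path: ModelPath) -> list:
    """Active variable set of the AICc-minimizing path point; ties (to within
    1e-9) broken toward the sparser model."""
    if not path.points:
        raise ValueError("empty path")
    best = path.points[0]
    for pt in path.points[1:]:
        if pt.aicc < best.aicc - 1e-9 or (abs(pt.aicc - best.aicc) <= 1e-9 and pt.k < best.k):
            best = pt
    return path.active_set(best)


def fit_l2(X, y, l2_strength: Optional[float] = None, tol: float = 1e-8,
           max_iter: int = 5000):
    """L2-penalized logistic fit of the objective −loglik + (α/2)·‖w‖².

    α defaults to 1/n_train — a light ridge whose role is a unique optimum
    under collinearity (duplicated columns receive equal coefficients), not
    shrinkage.  Returns ``(intercept, coefficient array)``; an empty design
    yields the prevalence-only model.
    """
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if Xa.ndim != 2 or Xa.shape[1] == 0:
        return float(logit_fn(y.mean())), np.zeros(0)
    alpha = 1.0 / n if l2_strength is None else float(l2_strength)
    clf = LogisticRegression(C=1.0 / alpha, solver="lbfgs", tol=tol,
                             max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xa, y)
    return float(clf.intercept_[0]), clf.coef_[0].copy()


@dataclass
class RiskModel:
    """Fitted scoring pipeline: selected variables, their WoE tables, the L2
    coefficients and the training WoE means (the SHAP baseline).  The
    serialized form alone reproduces every prediction bit-for-bit."""

    variables: list
    intercept: float
    coefficients: np.ndarray
    l2_strength: float
    woe_tables: dict  # name -> WoETable
    train_means: dict  # name -> training mean of the WoE column

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.variables):
            raise ValueError("coefficient count must equal selected-variable count")

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        missing = [v for v in self.variables if v not in features.columns]
        if missing:
            raise KeyError(f"record lacks model variables: {missing}")
        data = {v: woe_apply(self.woe_tables[v], features[v].to_numpy())
                for v in self.variables}
        return pd.DataFrame(data, index=features.index)

    def decision_function(self, features: pd.DataFrame) -> np.ndarray:
        Xw = self.transform(features)
        return self.intercept + Xw.to_numpy() @ self.coefficients

    def predict(self, features: pd.DataFrame):
        """Per-subject ``(logit, probability)``; probability = σ(logit)."""
        z = self.decision_function(features)
        return z, expit(z)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        return expit(self.decision_function(features))

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "intercept": self.intercept,
            "coefficients": [float(c) for c in self.coefficients],
            "l2_strength": self.l2_strength,
            "woe_tables": {v: t.to_dict() for v, t in self.woe_tables.items()},
            "train_means": {v: float(m) for v, m in self.train_means.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(
            variables=list(d["variables"]),
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            l2_strength=float(d["l2_strength"]),
            woe_tables={v: WoETable.from_dict(t) for v, t in d["woe_tables"].items()},
            train_means={v: float(m) for v, m in d["train_means"].items()},
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def predict(model: RiskModel, features: pd.DataFrame):
    """Module-level alias for :meth:`RiskModel.predict`."""
    return model.predict(features)


# ---------------------------------------------------------------------------
# raw-variable benchmark


@dataclass
class BenchmarkModel:
    """Mean-imputed / one-hot / standardized logistic benchmark fitted through
    the same L1 → AICc → L2 pipeline on the original variables."""

    columns: list  # engineered design columns
    means: dict
    stds: dict
    categorical_levels: dict  # source column -> training levels
    selected: list
    intercept: float
    coefficients: np.ndarray

    def design(self, features: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col, levels in self.categorical_levels.items():
            vals = features[col]
            for lev in levels:
                out[f"{col}={lev}"] = (vals == lev).astype(float)
        for col in self.means:
            v = pd.to_numeric(features[col], errors="coerce")
            v = v.fillna(self.means[col])
            out[col] = (v - self.means[col]) / self.stds[col]
        return pd.DataFrame(out, index=features.index)[self.columns]

    def predict(self, features: pd.DataFrame):
        X = self.design(features)[self.selected].to_numpy()
        z = self.intercept + X @ self.coefficients
        return z, expit(z)


def fit_benchmark_raw(features: pd.DataFrame, y, kinds: dict,
                      grid_size: int = 100, l2_strength: Optional[float] = None,
                      random_state: int = 0) -> BenchmarkModel:
    """Benchmark on the original variables: training-mean imputation for
    numeric columns, one-hot encoding (one indicator per training level,
    missing rows all-zero) for categoricals, standardization to zero mean and
    unit variance, then the L1-path → AICc → L2 pipeline.  Zero-variance
    columns are dropped with a warning.
    """
    y = np.asarray(y)
    means, stds, cat_levels, cols = {}, {}, {}, []
    design = {}
    for col in features.columns:
        if kinds.get(col) == "categorical":
            levels = sorted(set(features[col].dropna()), key=str)
            cat_levels[col] = levels
            for lev in levels:
                name = f"{col}={lev}"
                design[name] = (features[col] == lev).astype(float)
                cols.append(name)
        else:
            v = pd.to_numeric(features[col], errors="coerce")
            m = float(v.mean())
            v = v.fillna(m)
            sd = float(v.std(ddof=0))
            if sd == 0.0 or not math.isfinite(sd):
                logger.warning("benchmark: dropping zero-variance column %r", col)
                continue
            means[col], stds[col] = m, sd
            design[col] = (v - m) / sd
            cols.append(col)
    X = pd.DataFrame(design, index=features.index)[cols]
    path = fit_l1_path(X, y, grid_size=grid_size, random_state=random_state)
    selected = select_model(path)
    intercept, coefs = fit_l2(X[selected], y, l2_strength=l2_strength)
    return BenchmarkModel(columns=cols, means=means, stds=stds,
                          categorical_levels=cat_levels, selected=selected,
                          intercept=intercept, coefficients=coefs)
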