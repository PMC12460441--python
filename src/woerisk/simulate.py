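"""Synthetic cohort generation for the post-concussion MSK-injury risk pipeline.

Real athlete data behind this kind of study are not publicly deposited, so the
package ships a generator that reproduces the *statistical structure* the
analysis assumes: mixed continuous/categorical/binary predictors observed at a
pre-injury baseline and three post-injury timepoints (acute, asymptomatic,
return-to-play), baseline-minus-timepoint difference features, correlated
variable blocks, a binary outcome drawn from a piecewise-constant
(bin-structured) log-odds model, and configurable missingness.  Because the
generating log-odds are recorded per subject, every downstream stage can be
tested against a known Bayes-optimal score.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

logger = logging.getLogger(__name__)

TIMEPOINTS = ("baseline", "acute", "asymptomatic", "rtp", "static")
VARTYPES = ("continuous", "categorical", "binary")
MECHANISMS = ("MCAR", "MAR-on-outcome")

#: display labels used when naming derived difference columns
_TP_LABEL = {"acute": "Acute", "asymptomatic": "Asymptomatic", "rtp": "RTP"}


class ConfigurationError(ValueError):
    """Raised when a cohort specification violates its invariants."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of a single predictor.

    Parameters
    ----------
    name
        Unique column name.
    vartype
        ``continuous``, ``categorical`` or ``binary``.
    timepoint
        When the measure is taken; ``static`` for demographics/history.
    measure
        Base measure identifier shared across timepoints (defaults to
        ``name``); used to pair baseline and later-timepoint columns when
        deriving difference features.  ``None`` marks derived columns that
        must never be differenced again.
    n_categories
        Number of levels (categorical only), at least 2.
    category_probs
        Optional level probabilities (categorical only).
    informative
        Whether the variable enters the generating log-odds.
    effect
        Per-latent-bin log-odds offsets.  For continuous variables the latent
        bins are equal-probability slices of the marginal; for categorical
        variables one offset per level; for binary variables offsets for the
        levels 0 and 1.
    correlation_block
        Continuous variables sharing a block label are drawn with a common
        Gaussian factor (equicorrelation within the block).
    """

    name: str
    vartype: str
    timepoint: str = "static"
    measure: Optional[str] = "__same_as_name__"
    n_categories: Optional[int] = None
    category_probs: Optional[tuple] = None
    informative: bool = False
    effect: Optional[tuple] = None
    correlation_block: Optional[str] = None

    def __post_init__(self):
        if self.vartype not in VARTYPES:
            raise ConfigurationError(f"{self.name}: unknown vartype {self.vartype!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ConfigurationError(f"{self.name}: unknown timepoint {self.timepoint!r}")
        if self.measure == "__same_as_name__":
            object.__setattr__(self, "measure", self.name)
        if self.effect is not None:
            object.__setattr__(self, "effect", tuple(float(e) for e in self.effect))
        if self.category_probs is not None:
            object.__setattr__(self, "category_probs", tuple(float(p) for p in self.category_probs))
        if self.informative != (self.effect is not None and len(self.effect) > 0):
            raise ConfigurationError(
                f"{self.name}: effect list must be non-empty iff informative"
            )
        if self.vartype == "categorical":
            if self.n_categories is None or self.n_categories < 2:
                raise ConfigurationError(f"{self.name}: categorical needs n_categories >= 2")
            if self.informative and len(self.effect) != self.n_categories:
                raise ConfigurationError(
                    f"{self.name}: effect length must equal n_categories"
                )
            if self.category_probs is not None and len(self.category_probs) != self.n_categories:
                raise ConfigurationError(f"{self.name}: category_probs length mismatch")
        elif self.n_categories is not None:
            raise ConfigurationError(f"{self.name}: n_categories only valid for categorical")
        if self.vartype == "binary" and self.informative and len(self.effect) != 2:
            raise ConfigurationError(f"{self.name}: binary effect must have length 2")
        if self.vartype == "continuous" and self.informative and len(self.effect) < 2:
            raise ConfigurationError(f"{self.name}: continuous effect needs >= 2 latent bins")

    @property
    def categories(self) -> tuple:
        return tuple(f"c{j + 1}" for j in range(self.n_categories or 0))


@dataclass(frozen=True)
class CohortSpec:
    """Full generating model for a synthetic cohort."""

    n_subjects: int
    variables: tuple
    intercept: float = 0.0
    missing_rate: float = 0.0
    missing_mechanism: str = "MCAR"
    mar_factor: float = 2.0
    block_correlation: float = 0.6
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ConfigurationError("variable names must be unique")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.missing_mechanism not in MECHANISMS:
            raise ConfigurationError(
                f"missing_mechanism must be one of {MECHANISMS}"
            )
        if not (0.0 <= self.block_correlation < 1.0):
            raise ConfigurationError("block_correlation must lie in [0, 1)")


@dataclass(frozen=True)
class Truth:
    """Generating-model record: per-subject log-odds and the informative set."""

    log_odds: np.ndarray
    informative: tuple

    def subset(self, idx: np.ndarray) -> "Truth":
        return Truth(self.log_odds[idx], self.informative)


@dataclass
class Cohort:
    """Feature table (NaN = missing), binary outcome, dictionary, and truth."""

    features: pd.DataFrame
    outcome: np.ndarray
    dictionary: list
    truth: Optional[Truth] = None

    def __post_init__(self):
        self.outcome = np.asarray(self.outcome, dtype=int)
        if len(self.outcome) != len(self.features):
            raise ConfigurationError("outcome length must equal feature row count")

    @property
    def n_subjects(self) -> int:
        return len(self.features)

    @property
    def variable_names(self) -> list:
        return [v.name for v in self.dictionary]

    def spec_for(self, name: str) -> VariableSpec:
        for v in self.dictionary:
            if v.name == name:
                return v
        raise KeyError(name)

    def subset(self, idx: np.ndarray) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(
            self.features.iloc[idx].reset_index(drop=True),
            self.outcome[idx],
            list(self.dictionary),
            self.truth.subset(idx) if self.truth is not None else None,
        )

    def drop_variables(self, names: Sequence[str]) -> "Cohort":
        names = set(names)
        keep = [v for v in self.dictionary if v.name not in names]
        return Cohort(
            self.features[[v.name for v in keep]].copy(),
            self.outcome.copy(),
            keep,
            self.truth,
        )

    def missing_fraction(self) -> float:
        return float(self.features.isna().to_numpy().mean())


def _latent_bin_offsets(x: np.ndarray, effect: Sequence[float]) -> np.ndarray:
    """Piecewise-constant log-odds contribution over equal-probability slices
    of the standard-normal marginal."""
    m = len(effect)
    cuts = norm.ppf(np.arange(1, m) / m)
    idx = np.searchsorted(cuts, x, side="left")
    return np.asarray(effect, dtype=float)[idx]


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a complete cohort from the bin-structured logistic model.

    Outcomes are Bernoulli draws of the logistic of ``intercept`` plus the
    summed per-variable latent-bin offsets; the generating log-odds and the
    informative-variable set are recorded in ``cohort.truth``.  Deterministic
    given ``spec.seed``.  If ``spec.missing_rate > 0``, missingness is
    injected afterwards (the truth record refers to the complete data).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    if spec.intercept == 0.0 or any(v.informative for v in spec.variables):
        pass  # always valid: intercept alone fixes prevalence at expit(intercept)

    block_factors: dict = {}
    rho = spec.block_correlation
    columns = {}
    log_odds = np.full(n, float(spec.intercept))

    for v in spec.variables:
        if v.vartype == "continuous":
            eps = rng.standard_normal(n)
            if v.correlation_block is not None:
                if v.correlation_block not in block_factors:
                    block_factors[v.correlation_block] = rng.standard_normal(n)
                z = block_factors[v.correlation_block]
                x = math.sqrt(rho) * z + math.sqrt(1.0 - rho) * eps
            else:
                x = eps
            columns[v.name] = x
            if v.informative:
                log_odds += _latent_bin_offsets(x, v.effect)
        elif v.vartype == "binary":
            x = rng.binomial(1, 0.5, size=n).astype(float)
            columns[v.name] = x
            if v.informative:
                eff = np.asarray(v.effect)
                log_odds += eff[x.astype(int)]
        else:  # categorical
            probs = v.category_probs
            idx = rng.choice(v.n_categories, size=n, p=probs)
            columns[v.name] = pd.Categorical.from_codes(idx, categories=list(v.categories)).astype(object)
            if v.informative:
                eff = np.asarray(v.effect)
                log_odds += eff[idx]

    outcome = rng.binomial(1, expit(log_odds))
    features = pd.DataFrame(columns, index=range(n))
    cohort = Cohort(features, outcome, list(spec.variables),
                    Truth(log_odds, tuple(v.name for v in spec.variables if v.informative)))
    if spec.missing_rate > 0:
        cohort = inject_missingness(
            cohort, spec.missing_rate, spec.missing_mechanism,
            seed=int(rng.integers(2**31 - 1)), mar_factor=spec.mar_factor,
        )
    return cohort


def _solve_group_rates(rate: float, n1: int, n0: int, factor: float) -> tuple:
    """Per-group missing rates whose pooled mean is `rate` and whose odds
    differ by `factor` (event group more often missing when factor > 1)."""
    if n1 == 0 or n0 == 0:
        return rate, rate

    def pooled(logit0: float) -> float:
        r0 = expit(logit0)
        r1 = expit(logit0 + math.log(factor))
        return (n1 * r1 + n0 * r0) / (n1 + n0) - rate

    lo = brentq(pooled, -30.0, 30.0)
    return float(expit(lo + math.log(factor))), float(expit(lo))


def inject_missingness(cohort: Cohort, rate: float, mechanism: str = "MCAR",
                       seed: int = 0, mar_factor: float = 2.0) -> Cohort:
    """Mask feature cells (never the outcome).

    MCAR masks every cell independently with probability ``rate``.
    MAR-on-outcome uses per-group rates whose odds differ by ``mar_factor``
    (event group more often missing) while the pooled expected rate stays at
    ``rate``.  A column is never left entirely missing: one original value is
    restored if masking would empty it.
    """
    if not (0.0 <= rate < 1.0):
        raise ConfigurationError("missing rate must lie in [0, 1)")
    if rate == 0.0:
        return cohort
    if mechanism not in MECHANISMS:
        raise ConfigurationError(f"unknown missing mechanism {mechanism!r}")
    rng = np.random.default_rng(seed)
    y = cohort.outcome
    n, p = cohort.features.shape
    if mechanism == "MCAR":
        cell_rate = np.full(n, rate)
    else:
        r1, r0 = _solve_group_rates(rate, int(y.sum()), int((1 - y).sum()), mar_factor)
        cell_rate = np.where(y == 1, r1, r0)
    mask = rng.random((n, p)) < cell_rate[:, None]
    # keep at least one observed value per column
    for j in np.where(mask.all(axis=0))[0]:
        mask[rng.integers(n), j] = False
    features = cohort.features.copy()
    for j, col in enumerate(features.columns):
        features.loc[mask[:, j], col] = np.nan
    return Cohort(features, y.copy(), list(cohort.dictionary), cohort.truth)


def derive_difference_features(cohort: Cohort) -> Cohort:
    """Append baseline-minus-later-timepoint difference columns.

    For every continuous measure observed at baseline and at least one later
    timepoint, a column ``"<measure> Difference Baseline <Timepoint>"`` is
    added, computed as baseline value minus later value (missing whenever
    either operand is missing).  Measures seen at a later timepoint without a
    baseline are skipped with a warning.  Derived columns carry
    ``measure=None`` so they are never differenced again.
    """
    by_measure: dict = {}
    for v in cohort.dictionary:
        if v.measure is not None and v.vartype == "continuous":
            by_measure.setdefault(v.measure, {})[v.timepoint] = v

    features = cohort.features.copy()
    dictionary = list(cohort.dictionary)
    for measure, tps in by_measure.items():
        later = [tp for tp in ("acute", "asymptomatic", "rtp") if tp in tps]
        if not later:
            continue
        if "baseline" not in tps:
            logger.warning(
                "measure %r observed at %s without a baseline; difference skipped",
                measure, later,
            )
            continue
        base = features[tps["baseline"].name]
        for tp in later:
            name = f"{measure} Difference Baseline {_TP_LABEL[tp]}"
            features[name] = base - features[tps[tp].name]
            dictionary.append(VariableSpec(
                name=name, vartype="continuous", timepoint=tp, measure=None,
            ))
    return Cohort(features, cohort.outcome.copy(), dictionary, cohort.truth)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(cohort: Cohort, test_fraction: float, seed: int = 0):
    """Outcome-stratified train/test split.

    Per outcome class, ``round_half_up(test_fraction * class_size)`` subjects
    go to the test set, so prevalence is matched between the partitions; the
    split is disjoint, exhaustive and deterministic given ``seed``.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ConfigurationError("test_fraction must lie strictly in (0, 1)")
    y = cohort.outcome
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in (0, 1):
        members = np.where(y == cls)[0]
        if len(members) < 2:
            raise ConfigurationError(
                f"outcome class {cls} has fewer than 2 members; cannot stratify"
            )
        n_test = _round_half_up(test_fraction * len(members))
        chosen = rng.permutation(members)[:n_test]
        test_idx.append(chosen)
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(cohort.n_subjects), test_idx)
    return cohort.subset(train_idx), cohort.subset(test_idx)


def reject_bad_split(train: Cohort, test: Cohort) -> bool:
    """True iff some categorical variable has a test-only category.

    Such splits leave the training-fitted binning with no evidence for the
    novel category and are rejected by the stability protocol.
    """
    for v in train.dictionary:
        if v.vartype != "categorical":
            continue
        tr = set(train.features[v.name].dropna())
        te = set(test.features[v.name].dropna())
        if te - tr:
            return True
    return False


# ---------------------------------------------------------------------------
# Ready-made generating specs

_STUDY_MEASURES = [
    # (measure, correlated-with-its-own-timepoints?)
    "Symptom Count", "Symptom Severity", "BESS", "Tandem Gait Single",
    "Tandem Gait Dual", "SAC", "ImPACT Verbal Memory", "ImPACT Visual Memory",
    "ImPACT Motor Speed", "ImPACT Reaction Time", "TMT-A", "TMT-B",
    "K-D", "Near Point Convergence", "CRT", "BSI-18", "HADS", "SWLS",
]

# measure/timepoint pairs carrying true signal, with per-tercile log-odds offsets
_STUDY_EFFECTS = {
    ("CRT", "baseline"): (-0.6, 0.0, 0.6),
    ("CRT", "acute"): (-0.6, 0.0, 0.6),
    ("BESS", "baseline"): (-0.5, 0.0, 0.5),
    ("ImPACT Reaction Time", "acute"): (-0.6, 0.0, 0.6),
    ("TMT-A", "acute"): (-0.5, 0.0, 0.5),
    ("K-D", "baseline"): (-0.5, 0.0, 0.5),
    ("SWLS", "baseline"): (0.6, 0.0, -0.6),
    ("ImPACT Motor Speed", "rtp"): (-0.5, 0.0, 0.5),
}


def study_spec(n_subjects: int = 194, missing_rate: float = 0.35,
               seed: int = 0) -> CohortSpec:
    """Generating spec mirroring the study's shape.

    18 measures at four timepoints (72 continuous columns; difference
    derivation later adds 54 more), plus 9 static demographic/history
    variables — 135 predictors in total.  Ten variables are informative
    (eight measure/timepoint combinations, sport, and time lost), the
    intercept puts prevalence near the study's 120/194, timepoints of a
    measure form a correlation block, and 35% of cells are missing at random
    by default.
    """
    variables = []
    for m in _STUDY_MEASURES:
        for tp in ("baseline", "acute", "asymptomatic", "rtp"):
            eff = _STUDY_EFFECTS.get((m, tp))
            variables.append(VariableSpec(
                name=f"{m} {_TP_LABEL.get(tp, 'Baseline')}",
                vartype="continuous", timepoint=tp, measure=m,
                informative=eff is not None, effect=eff,
                correlation_block=m,
            ))
    # sport roster: uneven sizes, heterogeneous injury rates
    sport_probs = (0.15, 0.12, 0.12, 0.10, 0.10, 0.10, 0.09, 0.08, 0.08, 0.06)
    sport_eff = (0.8, 0.4, 0.3, 0.0, 0.0, -0.2, -0.3, -0.5, 0.3, -0.6)
    variables.append(VariableSpec(
        name="Sport", vartype="categorical", timepoint="static", n_categories=10,
        category_probs=sport_probs, informative=True, effect=sport_eff,
    ))
    variables.append(VariableSpec(
        name="Time Lost", vartype="continuous", timepoint="static",
        measure=None, informative=True, effect=(0.8, 0.0, -0.4),
    ))
    variables.append(VariableSpec(name="Prior MSK Count", vartype="continuous",
                                  timepoint="static", measure=None))
    for nm in ("Sex", "Prior Concussion", "Anxiety History", "ADHD History",
               "Depression History", "Learning Disability History"):
        variables.append(VariableSpec(name=nm, vartype="binary", timepoint="static"))
    return CohortSpec(
        n_subjects=n_subjects, variables=tuple(variables), intercept=0.35,
        missing_rate=missing_rate, missing_mechanism="MCAR", seed=seed,
    )


def make_study_cohort(n_subjects: int = 194, missing_rate: float = 0.35,
                      seed: int = 0) -> Cohort:
    """Generate the default 135-predictor study-shaped cohort.

    Differences are derived from the complete data before missingness is
    injected into the base columns, so a difference is missing exactly when
    one of its operands is.
    """
    spec = study_spec(n_subjects=n_subjects, missing_rate=0.0, seed=seed)
    cohort = derive_difference_features(generate_cohort(spec))
    if missing_rate > 0:
        cohort = inject_missingness(cohort, missing_rate, "MCAR", seed=seed + 1)
    return cohort


def recovery_spec(n_subjects: int = 4000, n_variables: int = 40,
                  n_informative: int = 8, effect_size: float = 1.0,
                  seed: int = 0) -> CohortSpec:
    """Independent-variable spec for selection-recovery studies: the first
    ``n_informative`` continuous variables carry tercile offsets
    ``(-effect_size, 0, +effect_size)``; the rest are noise."""
    variables = []
    for j in range(n_variables):
        informative = j < n_informative
        variables.append(VariableSpec(
            name=f"v{j:02d}", vartype="continuous", timepoint="static",
            measure=None, informative=informative,
            effect=(-effect_size, 0.0, effect_size) if informative else None,
        ))
    return CohortSpec(n_subjects=n_subjects, variables=tuple(variables), seed=seed)
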