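"""End-to-end fitting: WoE encoding → L1 path → AICc selection → L2 refit.

This is the single entry point every consumer (CLI, stability protocol,
tests) goes through, so that "the methodology" always means the same
sequence of training-set-only operations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import ModelPath, RiskModel, fit_l1_path, fit_l2, select_model
from .simulate import Cohort
from .woe import WoEEncoder

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the whole pipeline, serializable and hashable.

    Binning: at most ``max_bins`` regular bins (a missing bin comes on top)
    merged from ``max_prebins`` quantile pre-bins, each holding at least
    ``min_bin_fraction`` of training subjects, with Laplace pseudo-count
    ``smoothing``.  Path: ``grid_size`` log-spaced penalties down to
    ``lambda_min_ratio``·λ_max.  ``l2_strength`` of None means 1/n_train.
    """

    max_prebins: int = 20
    max_bins: int = 5
    min_bin_fraction: float = 0.05
    smoothing: float = 0.5
    grid_size: int = 100
    lambda_min_ratio: float = 1e-3
    l2_strength: Optional[float] = None
    test_fraction: float = 0.2
    n_runs: int = 20
    target_fpr: float = 1.0 / 15.0
    n_calibration_bins: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie strictly in (0, 1)")
        if self.max_bins < 1 or self.max_prebins < 2:
            raise ValueError("max_bins >= 1 and max_prebins >= 2 required")
        if not (0.0 <= self.min_bin_fraction < 1.0):
            raise ValueError("min_bin_fraction must lie in [0, 1)")
        if self.smoothing < 0:
            raise ValueError("smoothing must be non-negative")
        if self.grid_size < 2 or not (0.0 < self.lambda_min_ratio < 1.0):
            raise ValueError("invalid path-grid parameters")
        if not (0.0 <= self.target_fpr <= 1.0):
            raise ValueError("target_fpr must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class FitResult:
    """Fitted model plus the artifacts a reviewer wants to audit."""

    model: RiskModel
    encoder: WoEEncoder
    path: ModelPath
    selected: list


def _kinds(cohort: Cohort) -> dict:
    return {v.name: v.vartype for v in cohort.dictionary}


def fit_pipeline(train: Cohort, config: PipelineConfig = PipelineConfig(),
                 variables: Optional[Sequence[str]] = None,
                 skip_selection: bool = False) -> FitResult:
    """Run the full training-set methodology on a cohort.

    ``variables`` restricts the candidate set (default: every dictionary
    variable); ``skip_selection`` fits the L2 model directly on that set,
    which is how fixed-variable refits are expressed.
    """
    t0 = time.perf_counter()
    y = train.outcome
    names = list(variables) if variables is not None else train.variable_names
    features = train.features[names]
    encoder = WoEEncoder(
        max_prebins=config.max_prebins, max_bins=config.max_bins,
        min_bin_fraction=config.min_bin_fraction, smoothing=config.smoothing,
    )
    X = encoder.fit_transform(features, y, kinds=_kinds(train))
    if skip_selection:
        selected = names
        path = ModelPath(columns=names, n=len(y), points=[])
    else:
        path = fit_l1_path(X, y, grid_size=config.grid_size,
                           lambda_min_ratio=config.lambda_min_ratio,
                           random_state=config.seed)
        selected = select_model(path)
    intercept, coefs = fit_l2(X[selected], y, l2_strength=config.l2_strength)
    model = RiskModel(
        variables=list(selected), intercept=intercept, coefficients=coefs,
        l2_strength=(1.0 / len(y)) if config.l2_strength is None else config.l2_strength,
        woe_tables={v: encoder.tables_[v] for v in selected},
        train_means={v: float(encoder.train_means_[v]) for v in selected},
    )
    logger.info("pipeline fit: n=%d, candidates=%d, selected=%d, %.2fs",
                len(y), len(names), len(selected), time.perf_counter() - t0)
    return FitResult(model=model, encoder=encoder, path=path, selected=list(selected))
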