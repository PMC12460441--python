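"""Split-stability protocol: the whole methodology repeated over random
stratified train/test splits.

Each run draws a fresh stratified split, rejects it if any categorical level
appears only in the test set (the training-fitted binning would have no
evidence for it), refits WoE tables, the L1 path, AICc selection and the L2
model on the training half alone, and evaluates on the held-out half.  The
report aggregates AUC mean ± sd, per-variable selection frequency and the
count of distinct variables ever selected.  Fixed-variable refits and the
group-variable ablation reuse the same per-run split seeds so comparisons
are paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import roc_auc
from .pipeline import FitResult, PipelineConfig, fit_pipeline
from .simulate import Cohort, reject_bad_split, stratified_split

logger = logging.getLogger(__name__)

_MAX_REJECTIONS = 1000


@dataclass
class StabilityRun:
    run: int
    split_seed: int
    n_rejected: int
    selected: list
    n_selected: int
    test_auc: float


@dataclass
class StabilityReport:
    runs: list
    auc_mean: float
    auc_sd: float
    selection_frequency: dict
    n_distinct_selected: int

    def per_run_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "run": r.run, "split_seed": r.split_seed,
            "n_rejected": r.n_rejected, "n_selected": r.n_selected,
            "test_auc": r.test_auc, "selected": ";".join(r.selected),
        } for r in self.runs])

    def to_dict(self) -> dict:
        return {
            "auc_mean": self.auc_mean, "auc_sd": self.auc_sd,
            "n_distinct_selected": self.n_distinct_selected,
            "selection_frequency": self.selection_frequency,
            "runs": self.per_run_frame().to_dict(orient="records"),
        }


def _accepted_split(cohort: Cohort, test_fraction: float, master_seed: int,
                    run: int):
    """Draw stratified splits until one passes the rejection rule; seeds are
    master + 1000·run + attempt, so runs are independent and reruns exact."""
    for attempt in range(_MAX_REJECTIONS):
        seed = master_seed + 1000 * run + attempt
        train, test = stratified_split(cohort, test_fraction, seed=seed)
        if not reject_bad_split(train, test):
            return train, test, seed, attempt
    raise RuntimeError(
        f"run {run}: {_MAX_REJECTIONS} consecutive splits rejected — a "
        "categorical level is too rare to ever appear in training"
    )


def run_stability(cohort: Cohort, config: PipelineConfig = PipelineConfig(),
                  n_runs: Optional[int] = None, master_seed: Optional[int] = None,
                  variables: Optional[Sequence[str]] = None,
                  skip_selection: bool = False) -> StabilityReport:
    """Repeat split → fit → evaluate ``n_runs`` times and aggregate.

    ``variables``/``skip_selection`` are forwarded to the pipeline, giving
    the fixed-variable variant of the protocol.  Deterministic given
    ``master_seed`` (default: ``config.seed``).
    """
    n_runs = config.n_runs if n_runs is None else n_runs
    master_seed = config.seed if master_seed is None else master_seed
    runs = []
    for r in range(n_runs):
        train, test, seed, n_rej = _accepted_split(
            cohort, config.test_fraction, master_seed, r)
        fit = fit_pipeline(train, config, variables=variables,
                           skip_selection=skip_selection)
        logits = fit.model.decision_function(test.features)
        auc = roc_auc(logits, test.outcome)
        runs.append(StabilityRun(run=r, split_seed=seed, n_rejected=n_rej,
                                 selected=list(fit.selected),
                                 n_selected=len(fit.selected),
                                 test_auc=float(auc)))
    aucs = np.array([r.test_auc for r in runs])
    all_selected = sorted({v for r in runs for v in r.selected})
    freq = {v: float(np.mean([v in r.selected for r in runs])) for v in all_selected}
    return StabilityReport(
        runs=runs,
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        selection_frequency=freq,
        n_distinct_selected=len(all_selected),
    )


def refit_fixed_variables(cohort: Cohort, variables: Sequence[str],
                          config: PipelineConfig = PipelineConfig(),
                          n_runs: Optional[int] = None,
                          master_seed: Optional[int] = None) -> StabilityReport:
    """Skip selection and refit WoE + L2 on a fixed variable set per split.

    The split seeds match :func:`run_stability` under the same master seed,
    mirroring the paired fixed-set versus adaptive-selection comparison.
    """
    if not variables:
        raise ValueError("variable set must be non-empty")
    known = set(cohort.variable_names)
    unknown = [v for v in variables if v not in known]
    if unknown:
        raise KeyError(f"variables absent from the dictionary: {unknown}")
    return run_stability(cohort, config, n_runs=n_runs, master_seed=master_seed,
                         variables=variables, skip_selection=True)


def sport_breakdown_and_ablation(cohort: Cohort, group_variable: str,
                                 ablate: Optional[Sequence[str]] = None,
                                 config: PipelineConfig = PipelineConfig(),
                                 n_runs: Optional[int] = None,
                                 master_seed: Optional[int] = None) -> dict:
    """Per-group test AUC across the stability runs, plus an ablated rerun.

    For every level of ``group_variable`` the test-set AUC is computed within
    the group on each run where both outcome classes occur (otherwise that
    run contributes nothing and the level may end up ``undefined``).
    ``ablate`` lists the variables to drop (default: the group variable
    itself); an empty list reproduces the base protocol exactly.
    """
    if cohort.spec_for(group_variable).vartype != "categorical":
        raise ValueError(f"{group_variable!r} must be categorical")
    n_runs = config.n_runs if n_runs is None else n_runs
    master_seed = config.seed if master_seed is None else master_seed
    per_group: dict = {}
    for r in range(n_runs):
        train, test, _, _ = _accepted_split(cohort, config.test_fraction,
                                            master_seed, r)
        fit = fit_pipeline(train, config)
        logits = fit.model.decision_function(test.features)
        groups = test.features[group_variable]
        for g in pd.unique(groups.dropna()):
            sel = (groups == g).to_numpy()
            y = test.outcome[sel]
            if y.sum() == 0 or y.sum() == len(y):
                continue  # AUC undefined within this run
            per_group.setdefault(g, []).append(float(roc_auc(logits[sel], y)))
    breakdown = {
        str(g): {"auc_mean": float(np.mean(v)), "n_runs_defined": len(v)}
        for g, v in sorted(per_group.items(), key=lambda kv: str(kv[0]))
    }
    ablate = [group_variable] if ablate is None else list(ablate)
    ablated_cohort = cohort.drop_variables(ablate) if ablate else cohort
    ablation = run_stability(ablated_cohort, config, n_runs=n_runs,
                             master_seed=master_seed)
    return {"per_group": breakdown, "ablated_variables": ablate,
            "ablation": ablation}
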