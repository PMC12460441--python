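"""Linear SHAP attribution for the WoE logistic model.

For a linear model on WoE features the exact Shapley contribution of
variable i to a subject's log-odds is

    φ_i = w_i · (WoE_i(x_i) − mean WoE_i),

with the mean taken over the *training* sample; the base value
w0 + Σ_i w_i·mean-WoE_i plus the contributions reconstructs the subject's
logit exactly (local accuracy).  Variable importance is the training-set mean
of |φ_i|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import RiskModel

logger = logging.getLogger(__name__)


@dataclass
class Explanations:
    """Per-subject, per-variable contributions on the log-odds scale."""

    phi: pd.DataFrame  # rows: subjects, columns: model variables
    base_value: float
    logits: np.ndarray

    def reconstruction_error(self) -> float:
        """max |base + Σφ − logit| over subjects (local-accuracy residual)."""
        return float(np.abs(self.base_value + self.phi.sum(axis=1).to_numpy()
                            - self.logits).max())

    def to_long_frame(self) -> pd.DataFrame:
        long = self.phi.reset_index(names="subject").melt(
            id_vars="subject", var_name="variable", value_name="contribution")
        return long.sort_values(["subject", "variable"]).reset_index(drop=True)


def shap_contributions(model: RiskModel, X_woe: pd.DataFrame) -> Explanations:
    """φ_i = w_i·(WoE_i − training mean WoE_i) for every subject and selected
    variable of ``X_woe`` (a WoE-transformed matrix over the model's
    variables, e.g. ``model.transform(raw)``)."""
    means = np.array([model.train_means[v] for v in model.variables])
    w = model.coefficients
    Xa = X_woe[model.variables].to_numpy(dtype=float)
    phi = (Xa - means) * w
    base = float(model.intercept + w @ means)
    logits = model.intercept + Xa @ w
    return Explanations(
        phi=pd.DataFrame(phi, columns=model.variables, index=X_woe.index),
        base_value=base, logits=logits,
    )


def explain_subjects(model: RiskModel, features: pd.DataFrame) -> Explanations:
    """Convenience wrapper: transform raw records, then attribute."""
    return shap_contributions(model, model.transform(features))


def rank_importance(explanations: Explanations, top_k: int | None = None) -> pd.DataFrame:
    """Mean |φ_i| across subjects, sorted descending, with 1-based ranks.

    Explanations should come from the training set, matching the convention
    that importance summarizes the fitted model's behaviour on the data it
    was fitted to.
    """
    imp = explanations.phi.abs().mean(axis=0).sort_values(ascending=False)
    out = pd.DataFrame({
        "variable": imp.index,
        "mean_abs_shap": imp.to_numpy(),
        "rank": np.arange(1, len(imp) + 1),
    }).reset_index(drop=True)
    if top_k is not None:
        if top_k > len(out):
            logger.warning("top_k=%d exceeds variable count %d; returning all",
                           top_k, len(out))
        out = out.head(top_k)
    return out
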