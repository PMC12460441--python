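"""Weight-of-evidence value assignment and the cohort-level encoder.

The WoE of a bin is the log-ratio of the bin's share of events to its share
of non-events,

    woe_b = ln[ ((n1_b + s) / (N1 + s·B)) / ((n0_b + s) / (N0 + s·B)) ],

with Laplace pseudo-count s over the B bins, so positive values carry
evidence *for* the event.  The information value of a variable is
IV = Σ_b (p1_b − p0_b)·woe_b on the smoothed shares.  Missing values occupy
their own bin and receive a WoE like any other bin, which is how the pipeline
imputes — no missing entries survive the transform.  All tables are fitted on
the training split only and serialize losslessly to JSON for exact
re-application.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .binning import BinningScheme, optimize_bins, prebin

MISSING_LABEL = "(missing)"


@dataclass(frozen=True)
class WoETable:
    """Per-bin counts, WoE values and the information value for one variable.

    Bin order is: regular bins in scheme order, then the missing bin (if the
    scheme has one).  ``woe`` is finite for every bin whenever
    ``smoothing > 0``.
    """

    scheme: BinningScheme
    n1: tuple  # events per bin
    n0: tuple  # non-events per bin
    woe: tuple
    iv: float
    smoothing: float

    @property
    def n_bins(self) -> int:
        return len(self.woe)

    @property
    def totals(self) -> tuple:
        return (int(sum(self.n1)), int(sum(self.n0)))

    def to_dict(self) -> dict:
        s = self.scheme
        return {
            "variable": s.variable,
            "kind": s.kind,
            "edges": list(s.edges),
            "groups": [list(g) for g in s.groups],
            "has_missing_bin": s.has_missing_bin,
            "n1": list(self.n1),
            "n0": list(self.n0),
            "woe": list(self.woe),
            "iv": self.iv,
            "smoothing": self.smoothing,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WoETable":
        scheme = BinningScheme(
            variable=d["variable"], kind=d["kind"], edges=tuple(d["edges"]),
            groups=tuple(tuple(g) for g in d["groups"]),
            has_missing_bin=d["has_missing_bin"],
        )
        return cls(scheme=scheme, n1=tuple(d["n1"]), n0=tuple(d["n0"]),
                   woe=tuple(d["woe"]), iv=float(d["iv"]),
                   smoothing=float(d["smoothing"]))


def compute_woe(scheme: BinningScheme, values, outcome,
                smoothing: float = 0.5) -> WoETable:
    """Count events/non-events per bin of ``scheme`` and assign WoE values.

    Must be called on the same training sample the scheme was fitted on.
    Raises if either outcome class is absent (the log-ratio is undefined).
    """
    y = np.asarray(outcome)
    N1, N0 = int(y.sum()), int((1 - y).sum())
    if N1 == 0 or N0 == 0:
        raise ValueError("WoE undefined: one outcome class is empty")
    idx = scheme.assign(values)
    if (idx == -1).any():
        raise ValueError(f"{scheme.variable}: unseen category during fit")
    nb = scheme.n_regular_bins + (1 if scheme.has_missing_bin else 0)
    if scheme.has_missing_bin is False and (idx == scheme.n_regular_bins).any():
        raise ValueError(f"{scheme.variable}: missing values but no missing bin")
    n1 = np.bincount(idx, weights=y, minlength=nb).astype(int)[:nb]
    n0 = np.bincount(idx, weights=1 - y, minlength=nb).astype(int)[:nb]
    s, B = smoothing, nb
    woe, iv = [], 0.0
    for b in range(nb):
        p1 = (n1[b] + s) / (N1 + s * B)
        p0 = (n0[b] + s) / (N0 + s * B)
        w = math.log(p1 / p0)
        woe.append(w)
        iv += (p1 - p0) * w
    return WoETable(scheme=scheme, n1=tuple(int(v) for v in n1),
                    n0=tuple(int(v) for v in n0), woe=tuple(woe),
                    iv=float(iv), smoothing=float(smoothing))


def woe_apply(table: WoETable, values) -> np.ndarray:
    """Replace each value by its bin's WoE.

    Total by construction: missing values get the missing bin's WoE (0 when
    no missing bin was fitted), out-of-range continuous values fall into the
    nearest edge bin, and categories unseen in training get 0 (neutral
    evidence).
    """
    idx = table.scheme.assign(values)
    woe = np.asarray(table.woe, dtype=float)
    out = np.zeros(len(idx), dtype=float)
    regular = idx >= 0
    if table.scheme.has_missing_bin:
        out[regular] = woe[idx[regular]]
    else:
        is_missing = idx == table.scheme.n_regular_bins
        sel = regular & ~is_missing
        out[sel] = woe[idx[sel]]
    return out


def fit_variable(values, outcome, kind: str = "continuous", variable: str = "",
                 max_prebins: int = 20, max_bins: int = 5,
                 min_bin_fraction: float = 0.05, smoothing: float = 0.5) -> WoETable:
    """Pre-bin, optimize and assign WoE for a single variable."""
    pb = prebin(values, outcome, max_prebins=max_prebins, kind=kind)
    scheme = optimize_bins(pb, variable=variable, max_bins=max_bins,
                           min_bin_fraction=min_bin_fraction, smoothing=smoothing)
    return compute_woe(scheme, values, outcome, smoothing=smoothing)


class WoEEncoder:
    """Fit per-variable IV-optimal WoE tables on training data and transform
    any conforming feature table onto the common evidence scale.

    The transform never produces missing entries; training-column means are
    retained for SHAP baselines.
    """

    def __init__(self, max_prebins: int = 20, max_bins: int = 5,
                 min_bin_fraction: float = 0.05, smoothing: float = 0.5):
        self.max_prebins = max_prebins
        self.max_bins = max_bins
        self.min_bin_fraction = min_bin_fraction
        self.smoothing = smoothing
        self.tables_: dict = {}
        self.train_means_: Optional[pd.Series] = None
        self.iv_: Optional[pd.Series] = None

    def fit(self, features: pd.DataFrame, outcome, kinds: Optional[dict] = None):
        """``kinds`` maps column name -> 'continuous'|'categorical'|'binary'
        (binary treated as continuous); unlisted columns default by dtype."""
        kinds = kinds or {}
        self.tables_ = {}
        for col in features.columns:
            kind = kinds.get(col)
            if kind is None:
                kind = "categorical" if features[col].dtype == object else "continuous"
            elif kind == "binary":
                kind = "continuous"
            self.tables_[col] = fit_variable(
                features[col].to_numpy(), outcome, kind=kind, variable=col,
                max_prebins=self.max_prebins, max_bins=self.max_bins,
                min_bin_fraction=self.min_bin_fraction, smoothing=self.smoothing,
            )
        transformed = self.transform(features)
        self.train_means_ = transformed.mean(axis=0)
        self.iv_ = pd.Series({c: t.iv for c, t in self.tables_.items()})
        return self

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        if not self.tables_:
            raise RuntimeError("encoder not fitted")
        data = {col: woe_apply(t, features[col].to_numpy())
                for col, t in self.tables_.items()}
        return pd.DataFrame(data, index=features.index)

    def fit_transform(self, features: pd.DataFrame, outcome,
                      kinds: Optional[dict] = None) -> pd.DataFrame:
        return self.fit(features, outcome, kinds=kinds).transform(features)

    def to_dict(self) -> dict:
        return {
            "params": {
                "max_prebins": self.max_prebins, "max_bins": self.max_bins,
                "min_bin_fraction": self.min_bin_fraction,
                "smoothing": self.smoothing,
            },
            "columns": list(self.tables_),  # survives sorted-key serialization
            "tables": {c: t.to_dict() for c, t in self.tables_.items()},
            "train_means": {} if self.train_means_ is None
            else {k: float(v) for k, v in self.train_means_.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WoEEncoder":
        enc = cls(**d["params"])
        order = d.get("columns", list(d["tables"]))
        enc.tables_ = {c: WoETable.from_dict(d["tables"][c]) for c in order}
        if d.get("train_means"):
            enc.train_means_ = pd.Series(d["train_means"])
        return enc

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "WoEEncoder":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
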