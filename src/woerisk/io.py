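"""Data-dictionary-driven CSV ingestion and cohort serialization.

The on-disk contract is deliberately boring: comma-separated UTF-8 with a
header row, empty cell = missing, plus a YAML (or JSON) data dictionary that
declares every column's type, timepoint and role.  Exactly one column is the
outcome; undeclared columns are an error unless explicitly listed under
``ignore``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .simulate import Cohort, VariableSpec

logger = logging.getLogger(__name__)


@dataclass
class DataDictionary:
    """Typed schema of a cohort CSV: predictors, the outcome column, and
    columns to ignore (ids, notes)."""

    variables: list  # list[VariableSpec]
    outcome: str
    ignore: list = field(default_factory=list)
    allowed_categories: dict = field(default_factory=dict)  # name -> list

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in dictionary")
        if self.outcome in names:
            raise ValueError("outcome must not also be declared as a predictor")

    @property
    def predictor_names(self) -> list:
        return [v.name for v in self.variables]

    def to_dict(self) -> dict:
        out = {
            "outcome": self.outcome,
            "ignore": list(self.ignore),
            "variables": [],
        }
        for v in self.variables:
            entry = {"name": v.name, "vartype": v.vartype, "timepoint": v.timepoint}
            if v.measure != v.name:
                entry["measure"] = v.measure
            if v.name in self.allowed_categories:
                entry["categories"] = list(self.allowed_categories[v.name])
            out["variables"].append(entry)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "DataDictionary":
        variables, allowed = [], {}
        for entry in d["variables"]:
            variables.append(VariableSpec(
                name=entry["name"], vartype=entry["vartype"],
                timepoint=entry.get("timepoint", "static"),
                measure=entry.get("measure", entry["name"]),
                n_categories=(len(entry["categories"])
                              if entry.get("categories") and entry["vartype"] == "categorical"
                              else (2 if entry["vartype"] == "categorical" else None)),
            ))
            if entry.get("categories"):
                allowed[entry["name"]] = list(entry["categories"])
        return cls(variables=variables, outcome=d["outcome"],
                   ignore=list(d.get("ignore", [])), allowed_categories=allowed)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DataDictionary":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_cohort(cls, cohort: Cohort, outcome: str = "outcome") -> "DataDictionary":
        allowed = {}
        for v in cohort.dictionary:
            if v.vartype == "categorical":
                allowed[v.name] = sorted(set(cohort.features[v.name].dropna()), key=str)
        return cls(variables=list(cohort.dictionary), outcome=outcome,
                   allowed_categories=allowed)


def load_table(csv_path, dictionary: "DataDictionary | str | Path") -> Cohort:
    """Read a cohort CSV against its dictionary.

    Empty cells become missing markers (never zeros); every CSV column must
    be declared as predictor, outcome or ignored; the outcome must be a
    complete 0/1 column.  Categorical values outside the declared set are
    kept as their own category with a warning.
    """
    if not isinstance(dictionary, DataDictionary):
        dictionary = DataDictionary.from_yaml(dictionary)
    raw = pd.read_csv(csv_path)
    declared = set(dictionary.predictor_names) | {dictionary.outcome} | set(dictionary.ignore)
    undeclared = [c for c in raw.columns if c not in declared]
    if undeclared:
        raise ValueError(f"undeclared columns in {csv_path}: {undeclared}")
    missing_cols = [c for c in dictionary.predictor_names + [dictionary.outcome]
                    if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"columns declared but absent from {csv_path}: {missing_cols}")
    if raw[dictionary.outcome].isna().any():
        raise ValueError("outcome column has missing values")
    outcome = raw[dictionary.outcome].astype(int).to_numpy()
    if not set(np.unique(outcome)) <= {0, 1}:
        raise ValueError("outcome must be binary 0/1")

    cols = {}
    for v in dictionary.variables:
        col = raw[v.name]
        if v.vartype == "categorical":
            vals = col.astype(object).where(col.notna(), np.nan)
            allowed = dictionary.allowed_categories.get(v.name)
            if allowed is not None:
                novel = sorted(set(vals.dropna()) - set(allowed), key=str)
                if novel:
                    logger.warning("%s: values outside the declared categories "
                                   "retained as their own levels: %s", v.name, novel)
            cols[v.name] = vals
        else:
            cols[v.name] = pd.to_numeric(col, errors="raise").astype(float)
    features = pd.DataFrame(cols)[dictionary.predictor_names]
    cohort = Cohort(features, outcome, list(dictionary.variables))
    logger.info("loaded %s: %d rows, %d predictors, %.1f%% cells missing",
                csv_path, cohort.n_subjects, features.shape[1],
                100 * cohort.missing_fraction())
    return cohort


def write_cohort(cohort: Cohort, out_dir, outcome_name: str = "outcome",
                 stem: str = "cohort") -> dict:
    """Write ``<stem>.csv`` (empty cell = missing), ``<stem>.dictionary.yaml``
    and, when a truth record exists, ``<stem>.truth.csv``.  Returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = cohort.features.copy()
    table[outcome_name] = cohort.outcome
    csv_path = out_dir / f"{stem}.csv"
    table.to_csv(csv_path, index=False)
    dict_path = out_dir / f"{stem}.dictionary.yaml"
    DataDictionary.from_cohort(cohort, outcome=outcome_name).to_yaml(dict_path)
    paths = {"csv": csv_path, "dictionary": dict_path}
    if cohort.truth is not None:
        truth_path = out_dir / f"{stem}.truth.csv"
        pd.DataFrame({"log_odds": cohort.truth.log_odds}).to_csv(truth_path, index=False)
        paths["truth"] = truth_path
    return paths
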