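"""Information-value-optimal supervised binning.

Continuous variables are pre-cut at empirical quantiles (rank-based, so the
scheme is invariant under strictly monotone transforms); categorical levels
are ordered by training event rate so that groups of adjacent levels behave
like ordinal segments.  An exact dynamic program then merges contiguous
pre-bins into at most ``max_bins`` final bins maximizing total information
value, subject to a minimum bin-occupancy fraction.  Missing values always
form their own bin and never participate in the merge.

Because Laplace smoothing ties each bin's contribution to the total number of
bins B, per-segment IV terms are only additive at fixed B; the DP therefore
runs once per exact segment count and takes the best feasible count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreBins:
    """Ordered fine partition of one variable, with per-pre-bin outcome counts.

    For continuous variables ``edges`` holds the upper cut value of every
    pre-bin except the last (cuts are actual data values; a value v belongs to
    the first pre-bin whose edge satisfies v <= edge).  For categorical
    variables ``categories`` lists the levels in ascending training event-rate
    order and ``edges`` is unused.
    """

    kind: str  # "continuous" | "categorical"
    n1: np.ndarray  # events per pre-bin
    n0: np.ndarray  # non-events per pre-bin
    edges: tuple = ()
    categories: tuple = ()
    n1_missing: int = 0
    n0_missing: int = 0

    @property
    def n_prebins(self) -> int:
        return len(self.n1)

    @property
    def has_missing(self) -> bool:
        return (self.n1_missing + self.n0_missing) > 0

    @property
    def totals(self) -> tuple:
        return (int(self.n1.sum()) + self.n1_missing,
                int(self.n0.sum()) + self.n0_missing)


@dataclass(frozen=True)
class BinningScheme:
    """Final bin definitions for one variable.

    ``edges`` are strictly increasing interior cut-points (continuous);
    ``groups`` maps each categorical level to exactly one group of adjacent
    (event-rate-ordered) levels.  ``has_missing_bin`` records whether missing
    training values were present and hence occupy a dedicated bin.
    """

    variable: str
    kind: str
    edges: tuple = ()
    groups: tuple = ()  # tuple of tuples of category labels
    has_missing_bin: bool = False

    def __post_init__(self):
        if self.kind == "continuous":
            e = np.asarray(self.edges, dtype=float)
            if e.size and not np.all(np.diff(e) > 0):
                raise ValueError(f"{self.variable}: edges must be strictly increasing")
        else:
            flat = [c for g in self.groups for c in g]
            if len(flat) != len(set(flat)):
                raise ValueError(f"{self.variable}: category mapped to multiple groups")

    @property
    def n_regular_bins(self) -> int:
        if self.kind == "continuous":
            return len(self.edges) + 1
        return len(self.groups)

    def assign(self, values) -> np.ndarray:
        """Bin index per value; missing -> index ``n_regular_bins`` (the
        missing bin) whether or not one was fitted (callers decide the
        fallback WoE).  Out-of-range continuous values land in the nearest
        edge bin; unseen categories get index -1."""
        if self.kind == "continuous":
            v = np.asarray(values, dtype=float)
            idx = np.searchsorted(np.asarray(self.edges, dtype=float), v, side="left")
            idx = np.where(np.isnan(v), self.n_regular_bins, idx)
            return idx.astype(int)
        lookup = {c: i for i, g in enumerate(self.groups) for c in g}
        out = np.empty(len(values), dtype=int)
        for i, val in enumerate(np.asarray(values, dtype=object)):
            if val is None or (isinstance(val, float) and math.isnan(val)):
                out[i] = self.n_regular_bins
            else:
                out[i] = lookup.get(val, -1)
        return out


def _clean_xy(values, outcome):
    y = np.asarray(outcome)
    if len(np.asarray(values, dtype=object)) != len(y):
        raise ValueError("values and outcome must have the same length")
    return y


def prebin(values, outcome, max_prebins: int = 20, kind: str = "continuous") -> PreBins:
    """Cut one variable into at most ``max_prebins`` non-empty pre-bins.

    Continuous: cut values are lower-interpolated empirical quantiles (actual
    data values), deduplicated, so equal values always share a pre-bin and the
    partition depends on ranks only.  Categorical: levels ordered by event
    rate (ties broken by label).  Missing values are set aside with their own
    counts; an all-missing variable yields zero pre-bins.
    """
    y = _clean_xy(values, outcome)
    if max_prebins < 2:
        raise ValueError("max_prebins must be >= 2")
    if kind == "categorical":
        vals = np.asarray(values, dtype=object)
        miss = np.array([v is None or (isinstance(v, float) and math.isnan(v)) for v in vals])
        obs, yo = vals[~miss], y[~miss]
        stats = {}
        for v, yy in zip(obs, yo):
            n1, n0 = stats.get(v, (0, 0))
            stats[v] = (n1 + int(yy), n0 + int(1 - yy))
        order = sorted(stats, key=lambda c: (stats[c][0] / (stats[c][0] + stats[c][1]), str(c)))
        n1 = np.array([stats[c][0] for c in order], dtype=int)
        n0 = np.array([stats[c][1] for c in order], dtype=int)
        return PreBins(kind="categorical", n1=n1, n0=n0, categories=tuple(order),
                       n1_missing=int(y[miss].sum()), n0_missing=int((1 - y[miss]).sum()))

    v = np.asarray(values, dtype=float)
    miss = np.isnan(v)
    obs, yo = v[~miss], y[~miss]
    if obs.size == 0:
        return PreBins(kind="continuous", n1=np.array([], dtype=int),
                       n0=np.array([], dtype=int),
                       n1_missing=int(y[miss].sum()), n0_missing=int((1 - y[miss]).sum()))
    qs = np.arange(1, max_prebins) / max_prebins
    edges = np.unique(np.quantile(obs, qs, method="lower"))
    edges = edges[edges < obs.max()]  # last bin must be non-empty
    idx = np.searchsorted(edges, obs, side="left")
    nb = len(edges) + 1
    n1 = np.bincount(idx, weights=yo, minlength=nb).astype(int)
    n0 = np.bincount(idx, weights=1 - yo, minlength=nb).astype(int)
    return PreBins(kind="continuous", n1=n1, n0=n0, edges=tuple(float(e) for e in edges),
                   n1_missing=int(y[miss].sum()), n0_missing=int((1 - y[miss]).sum()))


def _iv_term(n1: float, n0: float, N1: int, N0: int, s: float, B: int) -> float:
    p1 = (n1 + s) / (N1 + s * B)
    p0 = (n0 + s) / (N0 + s * B)
    return (p1 - p0) * math.log(p1 / p0)


def _segment_iv(prebins: PreBins, cuts: Sequence[int], smoothing: float) -> float:
    """Total IV (including the missing bin) of the segmentation whose segments
    end after pre-bin indices in ``cuts`` plus the final segment."""
    N1, N0 = prebins.totals
    if N1 == 0 or N0 == 0:
        raise ValueError("both outcome classes are required to score a segmentation")
    bounds = [(-1, *cuts, prebins.n_prebins - 1)[i:i + 2]
              for i in range(len(cuts) + 1)]
    B = len(bounds) + (1 if prebins.has_missing else 0)
    iv = 0.0
    for lo, hi in bounds:
        iv += _iv_term(prebins.n1[lo + 1:hi + 1].sum(), prebins.n0[lo + 1:hi + 1].sum(),
                       N1, N0, smoothing, B)
    if prebins.has_missing:
        iv += _iv_term(prebins.n1_missing, prebins.n0_missing, N1, N0, smoothing, B)
    return iv


def optimize_bins(prebins: PreBins, variable: str = "", max_bins: int = 5,
                  min_bin_fraction: float = 0.05, smoothing: float = 0.5) -> BinningScheme:
    """Exact IV-maximizing contiguous merge of pre-bins.

    Runs a dynamic program once per candidate final bin count B (smoothing
    couples per-bin IV terms through B, so terms are additive only at fixed
    B), enforcing that every regular bin holds at least
    ``min_bin_fraction`` of the training subjects; the best feasible
    segmentation over all B <= max_bins is returned.  When no multi-bin
    segmentation is feasible the variable collapses to a single bin (logged),
    never an error.
    """
    P = prebins.n_prebins
    N1, N0 = prebins.totals
    n_total = N1 + N0
    if P == 0:
        return BinningScheme(variable=variable, kind=prebins.kind,
                             has_missing_bin=prebins.has_missing)
    counts = prebins.n1 + prebins.n0
    csum = np.concatenate([[0], np.cumsum(counts)])
    c1 = np.concatenate([[0], np.cumsum(prebins.n1)])
    c0 = np.concatenate([[0], np.cumsum(prebins.n0)])
    min_count = max(1, math.ceil(min_bin_fraction * n_total))

    best_iv, best_cuts = -math.inf, None
    for B in range(1, min(max_bins, P) + 1):
        B_tot = B + (1 if prebins.has_missing else 0)

        def term(i: int, j: int) -> float:  # pre-bins i..j inclusive
            return _iv_term(c1[j + 1] - c1[i], c0[j + 1] - c0[i], N1, N0, smoothing, B_tot)

        def ok(i: int, j: int) -> bool:
            return csum[j + 1] - csum[i] >= min_count

        # dp[b][j]: best IV of first j+1 pre-bins split into b segments
        dp = np.full((B + 1, P), -math.inf)
        back = np.full((B + 1, P), -1, dtype=int)
        for j in range(P):
            if ok(0, j):
                dp[1][j] = term(0, j)
        for b in range(2, B + 1):
            for j in range(b - 1, P):
                for i in range(b - 1, j + 1):  # segment is i..j
                    if dp[b - 1][i - 1] == -math.inf or not ok(i, j):
                        continue
                    cand = dp[b - 1][i - 1] + term(i, j)
                    if cand > dp[b][j]:
                        dp[b][j] = cand
                        back[b][j] = i
        total = dp[B][P - 1]
        if total == -math.inf:
            continue
        if prebins.has_missing:
            total += _iv_term(prebins.n1_missing, prebins.n0_missing, N1, N0,
                              smoothing, B_tot)
        # ties broken toward fewer bins (strict improvement required)
        if total > best_iv + 1e-12:
            cuts = []
            b, j = B, P - 1
            while b > 1:
                i = back[b][j]
                cuts.append(i - 1)
                j, b = i - 1, b - 1
            best_iv, best_cuts = total, sorted(cuts)

    if best_cuts is None:
        logger.warning("%s: min_bin_fraction %.3f unsatisfiable; using a single bin",
                       variable, min_bin_fraction)
        best_cuts = []

    if prebins.kind == "continuous":
        edges = tuple(prebins.edges[i] for i in best_cuts)
        return BinningScheme(variable=variable, kind="continuous", edges=edges,
                             has_missing_bin=prebins.has_missing)
    bounds = [-1, *best_cuts, P - 1]
    groups = tuple(tuple(prebins.categories[bounds[k] + 1:bounds[k + 1] + 1])
                   for k in range(len(bounds) - 1))
    return BinningScheme(variable=variable, kind="categorical", groups=groups,
                         has_missing_bin=prebins.has_missing)
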