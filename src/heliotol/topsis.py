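"""Entropy-weight TOPSIS evaluation of the tolerance decision matrix.

Two classical MCDM building blocks, paired the standard way:

*Entropy weights.* Each criterion column is min-max normalised (cost
criteria reversed), turned into a probability distribution over
alternatives, and scored by its Shannon entropy ``e_j`` on a [0, 1]
scale; the weight is proportional to ``1 - e_j``, so a criterion on
which alternatives barely differ carries almost no weight.

*TOPSIS.* Columns are vector-normalised (``x / ||x||_2``), weighted, and
each alternative is scored by its relative closeness
``CI = D- / (D+ + D-)`` to the positive/negative ideal points. CI is in
[0, 1]; higher is closer to the per-criterion best.

Criterion directions are explicit: ``benefit`` (larger is better, the
default for every tolerance coefficient) or ``cost``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BENEFIT = "benefit"
COST = "cost"


class DegenerateWeightsError(ValueError):
    """Every criterion is constant: entropy weights are undefined."""


@dataclass(frozen=True)
class WeightVector:
    """Entropy weights with the audit intermediates retained."""

    weights: pd.Series = field(repr=False)     # per criterion, sums to 1
    entropy: pd.Series = field(repr=False)     # e_j in [0, 1]
    proportions: pd.DataFrame = field(repr=False)  # p_ij per alternative x criterion

    def __post_init__(self):
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-12):
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class TopsisResult:
    """Closeness coefficients and ideal-point distances per alternative."""

    table: pd.DataFrame = field(repr=False)  # index alternative; d_plus, d_minus, ci, rank
    directions: Mapping[str, str] = field(default_factory=dict)

    @property
    def ci(self) -> pd.Series:
        return self.table["ci"]

    @property
    def ranks(self) -> pd.Series:
        return self.table["rank"]


def _resolve_directions(columns: Sequence[str],
                        directions: Mapping[str, str] | str | None) -> dict[str, str]:
    if directions is None:
        return {c: BENEFIT for c in columns}
    if isinstance(directions, str):
        if directions not in (BENEFIT, COST):
            raise ValueError(f"direction must be {BENEFIT!r} or {COST!r}")
        return {c: directions for c in columns}
    out = {}
    for c in columns:
        d = directions.get(c, BENEFIT)
        if d not in (BENEFIT, COST):
            raise ValueError(f"direction for {c!r} must be {BENEFIT!r} or {COST!r}")
        out[c] = d
    return out


def entropy_weights(X: pd.DataFrame,
                    directions: Mapping[str, str] | str | None = None) -> WeightVector:
    """Objective criterion weights from the entropy of each column.

    Min-max normalises each column (reversed for cost criteria), forms
    ``p_ij = x'_ij / sum_i x'_ij``, computes
    ``e_j = -(1/ln n) * sum_i p_ij ln p_ij`` with ``0 ln 0 := 0``, and
    sets ``w_j = (1 - e_j) / sum_k (1 - e_k)``. A constant column gets
    ``e_j = 1`` hence weight 0 (with a warning); if every column is
    constant the weights are undefined and an error is raised.
    """
    X = pd.DataFrame(X).astype(float)
    n = len(X)
    if n < 2:
        raise ValueError("entropy weights need at least 2 alternatives")
    dirs = _resolve_directions(list(X.columns), directions)

    norm = pd.DataFrame(index=X.index, columns=X.columns, dtype=float)
    constant = {}
    for c in X.columns:
        col = X[c].to_numpy()
        lo, hi = col.min(), col.max()
        if hi == lo:
            constant[c] = True
            norm[c] = 0.0
            continue
        constant[c] = False
        x = (col - lo) / (hi - lo)
        if dirs[c] == COST:
            x = 1.0 - x
        norm[c] = x

    if all(constant.values()):
        raise DegenerateWeightsError(
            "all criteria are constant across alternatives; entropy weights undefined"
        )
    if any(constant.values()):
        warnings.warn(
            f"constant criterion column(s) {sorted(c for c in constant if constant[c])} "
            f"receive zero entropy weight",
            stacklevel=2,
        )

    e = pd.Series(index=X.columns, dtype=float)
    p = pd.DataFrame(index=X.index, columns=X.columns, dtype=float)
    for c in X.columns:
        if constant[c]:
            e[c] = 1.0
            p[c] = np.nan
            continue
        col = norm[c].to_numpy()
        s = col.sum()
        if s == 0:  # all alternatives at the worst value after reversal
            e[c] = 1.0
            p[c] = np.nan
            continue
        pj = col / s
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(pj > 0, pj * np.log(pj), 0.0)
        e[c] = -plogp.sum() / np.log(n)
        p[c] = pj

    d = 1.0 - e
    w = d / d.sum()
    return WeightVector(weights=w, entropy=e, proportions=p)


def topsis_ci(X: pd.DataFrame,
              weights: WeightVector | pd.Series | Mapping[str, float],
              directions: Mapping[str, str] | str | None = None) -> TopsisResult:
    """Closeness coefficients to the ideal solutions.

    Vector-normalises each column, applies the weights, takes the
    per-column max (benefit) / min (cost) as the positive ideal and the
    reverse as the negative ideal, and scores each alternative by
    ``CI = D- / (D+ + D-)`` with Euclidean distances. Alternatives are
    ranked by descending CI (competition ranking: ties share the
    smallest rank).
    """
    X = pd.DataFrame(X).astype(float)
    if isinstance(weights, WeightVector):
        w = weights.weights.reindex(X.columns)
    else:
        w = pd.Series(weights, dtype=float).reindex(X.columns)
    if w.isna().any():
        raise ValueError("weights missing for some criteria")
    dirs = _resolve_directions(list(X.columns), directions)

    M = X.to_numpy()
    norms = np.sqrt((M * M).sum(axis=0))
    if np.any(norms == 0):
        bad = [c for c, nz in zip(X.columns, norms) if nz == 0]
        raise ZeroDivisionError(f"zero column norm for criteria {bad}; cannot normalise")
    V = (M / norms) * w.to_numpy()

    is_benefit = np.array([dirs[c] == BENEFIT for c in X.columns])
    pos = np.where(is_benefit, V.max(axis=0), V.min(axis=0))
    neg = np.where(is_benefit, V.min(axis=0), V.max(axis=0))

    d_plus = np.sqrt(((V - pos) ** 2).sum(axis=1))
    d_minus = np.sqrt(((V - neg) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    ci = np.empty(len(X))
    degenerate = denom == 0
    if degenerate.any():
        warnings.warn("identical alternatives: CI defined as 0.5", stacklevel=2)
    ci[degenerate] = 0.5
    ci[~degenerate] = d_minus[~degenerate] / denom[~degenerate]

    out = pd.DataFrame(
        {"d_plus": d_plus, "d_minus": d_minus, "ci": ci}, index=X.index
    )
    out["rank"] = rank_descending(out["ci"])
    return TopsisResult(table=out, directions=dirs)


def rank_descending(ci: pd.Series) -> pd.Series:
    """Competition ranks (1 = highest CI; ties share the minimum rank)."""
    return ci.rank(ascending=False, method="min").astype(int)
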