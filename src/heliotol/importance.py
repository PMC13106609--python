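"""Out-of-bag permutation importance for trait ranking.

A bootstrap ensemble of regression trees is fit to predict a response
(aboveground fresh weight) from the other traits. The importance of a
predictor is the classical %IncMSE: the mean, over trees, of the percent
increase in that tree's out-of-bag mean squared error when the
predictor's values are shuffled among the out-of-bag samples. The
ensemble members are standard CART regressors; the bootstrap, the
out-of-bag bookkeeping and the permutation scoring are done here so
that every random draw is seeded and auditable.

Significance comes from a response-permutation null: the whole
importance computation is repeated on shuffled responses and
``p = (1 + #{null >= observed}) / (n_null + 1)`` per predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor


@dataclass(frozen=True)
class ImportanceResult:
    """Per-predictor %IncMSE, optional permutation p-values, and settings."""

    table: pd.DataFrame = field(repr=False)  # index predictor; inc_mse_percent, [p, stars]
    n_trees: int = 0
    seed: int | None = None

    @property
    def ranking(self) -> list[str]:
        return list(self.table.sort_values("inc_mse_percent", ascending=False).index)


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, mtry: int,
                rng: np.random.Generator):
    """Bootstrap ensemble; returns (trees, oob_masks)."""
    n = len(y)
    trees, oobs = [], []
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n)
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        tree = DecisionTreeRegressor(
            max_features=mtry,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        oobs.append(oob)
    return trees, oobs


def _oob_inc_mse(trees, oobs, X: np.ndarray, y: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Mean percent OOB-MSE increase per predictor over trees."""
    p = X.shape[1]
    deltas = np.zeros(p)
    counts = np.zeros(p)
    for tree, oob in zip(trees, oobs):
        if oob.sum() < 2:
            continue
        Xo, yo = X[oob], y[oob]
        base = float(np.mean((tree.predict(Xo) - yo) ** 2))
        if base == 0:
            continue
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            mse = float(np.mean((tree.predict(Xp) - yo) ** 2))
            deltas[j] += 100.0 * (mse - base) / base
            counts[j] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, deltas / np.maximum(counts, 1), 0.0)
    return out


def permutation_importance(features: pd.DataFrame, response: pd.Series,
                           n_trees: int = 500, seed: int = 0,
                           mtry: int | None = None) -> ImportanceResult:
    """%IncMSE permutation importance of each feature column.

    Defaults follow regression-forest convention: 500 trees and
    ``mtry = ceil(p / 3)`` candidate features per split. Deterministic
    given ``seed``.
    """
    X = pd.DataFrame(features).astype(float)
    y = pd.Series(response).astype(float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if len(X) < 10:
        raise ValueError("need at least 10 observations")
    if y.std() == 0:
        raise ValueError("constant response: model degenerate")
    if mtry is None:
        mtry = max(1, math.ceil(X.shape[1] / 3))

    rng = np.random.default_rng(seed)
    Xv, yv = X.to_numpy(), y.to_numpy()
    trees, oobs = _fit_forest(Xv, yv, n_trees, mtry, rng)
    inc = _oob_inc_mse(trees, oobs, Xv, yv, rng)
    table = pd.DataFrame({"inc_mse_percent": inc}, index=list(X.columns))
    table.index.name = "predictor"
    return ImportanceResult(table=table, n_trees=n_trees, seed=seed)


def importance_significance(features: pd.DataFrame, response: pd.Series,
                            n_null: int = 99, n_trees: int = 500,
                            seed: int = 0,
                            mtry: int | None = None) -> ImportanceResult:
    """Permutation-null p-values attached to the %IncMSE importances.

    The null distribution of each predictor's importance is obtained by
    refitting the whole ensemble on ``n_null`` random permutations of
    the response. The smallest attainable p is ``1/(n_null + 1)``, so at
    least 19 null refits are required to resolve p < 0.05.
    """
    if n_null < 19:
        raise ValueError("n_null must be >= 19 to resolve p < 0.05")
    obs = permutation_importance(features, response, n_trees=n_trees,
                                 seed=seed, mtry=mtry)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    y = pd.Series(response).astype(float).to_numpy()
    exceed = np.zeros(len(obs.table))
    for b in range(n_null):
        y_perm = rng.permutation(y)
        null = permutation_importance(
            features, pd.Series(y_perm, index=features.index),
            n_trees=n_trees, seed=int(rng.integers(0, 2**31 - 1)), mtry=mtry,
        )
        exceed += (
            null.table["inc_mse_percent"].to_numpy()
            >= obs.table["inc_mse_percent"].to_numpy() - 1e-12
        )
    p = (1 + exceed) / (n_null + 1)
    table = obs.table.copy()
    table["p"] = p
    # permutation p-values are discrete with floor 1/(n_null+1), so the
    # conventional cutoffs are inclusive
    table["stars"] = ["**" if v <= 0.01 else "*" if v <= 0.05 else "" for v in p]
    return ImportanceResult(table=table, n_trees=n_trees, seed=seed)
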