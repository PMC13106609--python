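"""Trait associations: Pearson correlation matrix and Mantel tests.

The Pearson matrix is computed across genotypes on replicate-mean trait
values (pooled control + stress rows by default, or per treatment).
Mantel tests relate pairwise genotype distance matrices: each single
trait's Euclidean distance matrix (on z-scored values) is tested against
a focal trait's matrix — typically aboveground fresh weight or net
photosynthetic rate, the two hubs of the trait network — by permuting
genotype labels of one matrix. Mantel r is classed as weak (< 0.2),
moderate ([0.2, 0.4)) or strong (>= 0.4).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

STRENGTH_WEAK = "weak"
STRENGTH_MODERATE = "moderate"
STRENGTH_STRONG = "strong"


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    strength: str
    seed: int | None = None


def pearson_matrix(data: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p over the columns of ``data``.

    ``data`` is an observation x trait table (e.g. genotype means,
    optionally stacked over treatments). p-values come from the exact
    t-transform of r with n - 2 degrees of freedom. A zero-variance
    column yields NaN r and p for its pairs.
    """
    data = pd.DataFrame(data).astype(float)
    n = len(data)
    if n < 3:
        raise ValueError("need at least 3 observations for correlation p-values")
    cols = list(data.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for a, b in combinations(cols, 2):
        x, y = data[a].to_numpy(), data[b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rij, pij = np.nan, np.nan
        else:
            rij, pij = stats.pearsonr(x, y)
        r.loc[a, b] = r.loc[b, a] = rij
        p.loc[a, b] = p.loc[b, a] = pij
    np.fill_diagonal(p.values, np.nan)
    return r, p


def trait_distance_matrix(values: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Euclidean genotype-by-genotype distances on z-scored trait values.

    ``values`` holds one row per genotype and one column per trait in
    the set (a Series is treated as a single trait, where the distance
    reduces to the absolute z-score difference).
    """
    if isinstance(values, pd.Series):
        values = values.to_frame()
    X = values.astype(float)
    sd = X.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero-variance trait(s) {bad}: z-scores undefined")
    Z = (X - X.mean()) / sd
    D = squareform(pdist(Z.to_numpy(), metric="euclidean"))
    return pd.DataFrame(D, index=values.index, columns=values.index)


def _upper(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(D, k=1)
    return D[iu]


def mantel_test(D1: pd.DataFrame, D2: pd.DataFrame,
                n_perm: int = 9999, seed: int | None = None,
                exact: bool = False) -> MantelResult:
    """One-sided (greater) Mantel test between two distance matrices.

    The statistic is the Pearson correlation of the upper-triangle
    entries; the null is built by simultaneous row/column permutation of
    ``D2``. ``p = (1 + #{r_perm >= r_obs}) / (B + 1)``, never below
    ``1/(B+1)``. With ``exact=True`` all ``n!`` label permutations are
    enumerated instead (feasible only for small n) and the p-value is
    the exact fraction including the identity.
    """
    A = np.asarray(D1, dtype=float)
    B = np.asarray(D2, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrices must be square and of equal size")
    n = A.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 objects")
    for M, name in ((A, "D1"), (B, "D2")):
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError(f"{name} must be symmetric")
        if not np.allclose(np.diag(M), 0, atol=1e-10):
            raise ValueError(f"{name} must have a zero diagonal")
    a = _upper(A)
    if np.std(a) == 0 or np.std(_upper(B)) == 0:
        raise ValueError("constant off-diagonal distances: Mantel r undefined")

    az = (a - a.mean()) / a.std()

    def corr_with(Dperm: np.ndarray) -> float:
        b = _upper(Dperm)
        bs = b.std()
        if bs == 0:
            return 0.0
        return float(np.mean(az * (b - b.mean()) / bs))

    r_obs = corr_with(B)

    if exact:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            idx = np.array(perm)
            total += 1
            if corr_with(B[np.ix_(idx, idx)]) >= r_obs - 1e-12:
                count += 1
        p = count / total
        n_used = total - 1
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            idx = rng.permutation(n)
            if corr_with(B[np.ix_(idx, idx)]) >= r_obs - 1e-12:
                count += 1
        p = (1 + count) / (n_perm + 1)
        n_used = n_perm
    return MantelResult(
        r=r_obs, p_value=p, n_permutations=n_used,
        strength=classify_mantel_strength(r_obs), seed=seed,
    )


def classify_mantel_strength(r: float) -> str:
    """Strength class of a Mantel r: weak < 0.2 <= moderate < 0.4 <= strong."""
    if not np.isfinite(r):
        raise ValueError("r must be finite")
    if r < 0.2:
        return STRENGTH_WEAK
    if r < 0.4:
        return STRENGTH_MODERATE
    return STRENGTH_STRONG


def mantel_screen(means_wide: pd.DataFrame,
                  focal_traits: tuple[str, ...] = ("afw", "pn"),
                  n_perm: int = 9999, seed: int = 0) -> pd.DataFrame:
    """Mantel tests of every single trait against each focal trait.

    ``means_wide`` is a genotype x trait matrix. Each non-focal trait's
    distance matrix is tested against each focal trait's; results carry
    the r, permutation p, strength class and the per-test seed
    (sub-seeded deterministically from ``seed``).
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    tests = [(t, f) for f in focal_traits for t in means_wide.columns if t != f]
    children = ss.spawn(len(tests))
    for (trait, focal), child in zip(tests, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        res = mantel_test(
            trait_distance_matrix(means_wide[trait]),
            trait_distance_matrix(means_wide[focal]),
            n_perm=n_perm, seed=sub_seed,
        )
        rows.append(
            {"trait": trait, "focal": focal, "r": res.r, "p": res.p_value,
             "strength": res.strength, "n_perm": res.n_permutations,
             "seed": sub_seed}
        )
    return pd.DataFrame(rows)
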