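"""Tolerance levels from hierarchical clustering of the CI values.

The comprehensive-index (CI) scores are clustered agglomeratively on
Euclidean distance in one dimension and the tree is cut at ``k = 4``
groups, which are then labelled I (most tolerant, highest mean CI)
through IV (most sensitive). The linkage is a visible knob because the
partition of a 1-D score vector is sensitive to it: average linkage
(UPGMA) is the default, with Ward and complete exposed for sensitivity
checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")

DEFAULT_LINKAGE = "average"
_LINKAGES = ("average", "ward", "complete", "single")


@dataclass(frozen=True)
class LevelAssignment:
    """Genotype-to-level map plus per-level summaries."""

    assignments: pd.DataFrame = field(repr=False)  # genotype, ci, cluster, level
    summary: pd.DataFrame = field(repr=False)      # level, n, mean_ci, min_ci, max_ci

    def counts(self) -> dict[str, int]:
        return dict(zip(self.summary["level"], self.summary["n"]))

    def level_of(self, genotype: str) -> str:
        a = self.assignments
        return a.loc[a["genotype"] == genotype, "level"].iloc[0]


def cluster_ci(ci, k: int = 4, method: str = DEFAULT_LINKAGE) -> np.ndarray:
    """Agglomerative clustering of CI values; returns integer cluster ids.

    Euclidean distance on the 1-D CI vector, tree cut at ``k`` clusters.
    Cluster ids are arbitrary labels in 1..k; order them by mean CI with
    :func:`label_levels`.
    """
    ci = np.asarray(ci, dtype=float)
    if ci.ndim != 1:
        raise ValueError("ci must be a 1-D vector")
    if not np.isfinite(ci).all():
        raise ValueError("CI values must be finite")
    if k < 1 or k > len(ci):
        raise ValueError(f"k={k} must be in 1..{len(ci)}")
    if method not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    Z = linkage(ci.reshape(-1, 1), method=method, metric="euclidean")
    return fcluster(Z, t=k, criterion="maxclust")


def label_levels(cluster_ids, ci, genotypes=None) -> LevelAssignment:
    """Order clusters by descending mean CI and label them I, II, ...

    Tied cluster means are broken by the cluster maximum CI (with a
    warning); level counts always sum to the number of genotypes.
    """
    ids = np.asarray(cluster_ids)
    ci = np.asarray(ci, dtype=float)
    if genotypes is None:
        genotypes = [f"A{i + 1}" for i in range(len(ci))]
    if not (len(ids) == len(ci) == len(genotypes)):
        raise ValueError("cluster ids, ci and genotypes must have equal length")

    stats = []
    for c in np.unique(ids):
        mask = ids == c
        stats.append((c, float(ci[mask].mean()), float(ci[mask].max()),
                      float(ci[mask].min()), int(mask.sum())))
    means = [s[1] for s in stats]
    if len(set(np.round(means, 12))) < len(means):
        warnings.warn("tied cluster mean CIs; breaking ties by max CI", stacklevel=2)
    stats.sort(key=lambda s: (s[1], s[2]), reverse=True)

    level_of_cluster = {c: ROMAN[i] for i, (c, *_rest) in enumerate(stats)}
    assignments = pd.DataFrame(
        {
            "genotype": list(genotypes),
            "ci": ci,
            "cluster": ids,
            "level": [level_of_cluster[c] for c in ids],
        }
    )
    summary = pd.DataFrame(
        [
            {"level": ROMAN[i], "n": n, "mean_ci": m, "min_ci": lo, "max_ci": hi}
            for i, (_c, m, hi, lo, n) in enumerate(stats)
        ]
    )
    return LevelAssignment(assignments=assignments, summary=summary)


def classify_tolerance(ci: pd.Series, k: int = 4,
                       method: str = DEFAULT_LINKAGE) -> LevelAssignment:
    """Cluster a genotype-indexed CI series and label tolerance levels."""
    ids = cluster_ci(ci.to_numpy(), k=k, method=method)
    return label_levels(ids, ci.to_numpy(), genotypes=list(ci.index))
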