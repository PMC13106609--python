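"""Piecewise structural equation modelling over a declared DAG.

The causal structure is supplied as a directed acyclic graph whose
exogenous block codes the experiment (light intensity LI, a genotype
score G, and their interaction LI x G) and whose endogenous nodes are
the measured traits, terminating in aboveground fresh weight (AFW).
The model is fit piecewise: one ordinary-least-squares regression per
endogenous node on its parents, on z-standardised data, so every
coefficient is a standardised path coefficient and a single-parent
coefficient equals the Pearson correlation of the pair.

Goodness of fit follows the d-separation logic: the DAG's basis set of
conditional-independence claims (non-adjacent node pairs, conditioned on
the union of the pair's parents) is tested by t-tests on partial
regression coefficients, and the claim p-values are combined into
Fisher's C = -2 sum ln p, compared to a chi-square with 2k degrees of
freedom. A large model p-value means the data are consistent with the
claimed structure.

Direct, indirect and total standardised effects on the terminal
response are obtained by exact enumeration of directed paths, with the
effect of a path equal to the product of its edge coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

EXOGENOUS = ("LI", "G", "LIxG")
DEFAULT_NODES = ("LI", "G", "LIxG", "FPC", "PH", "LT", "SPAD", "SD", "AFW")

#: Mapping of DAG node names to canonical trait tokens.
NODE_TRAITS = {
    "FPC": "proline",
    "PH": "plant_height",
    "LT": "leaf_thickness",
    "SPAD": "spad",
    "SD": "stem_diameter",
    "AFW": "afw",
}


@dataclass(frozen=True)
class PathDAG:
    """A directed acyclic path diagram with declared exogenous nodes and
    a terminal response."""

    graph: nx.DiGraph = field(repr=False)
    exogenous: tuple[str, ...] = EXOGENOUS
    response: str = "AFW"

    def __post_init__(self):
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path diagram must be acyclic")
        if self.response not in g:
            raise ValueError(f"response node {self.response!r} not in graph")
        if g.out_degree(self.response) != 0:
            raise ValueError("terminal response must have no children")
        for node in g.nodes:
            if node not in self.exogenous and g.in_degree(node) == 0:
                raise ValueError(f"endogenous node {node!r} has no parents")

    @property
    def endogenous(self) -> list[str]:
        return [n for n in nx.topological_sort(self.graph)
                if n not in self.exogenous]

    def parents(self, node: str) -> list[str]:
        return sorted(self.graph.predecessors(node))

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)


def default_dag() -> PathDAG:
    """The default path diagram for the high-light screen.

    The exogenous block (LI, G, LI x G) drives every intermediate trait;
    proline (the stress-response marker) feeds the morphological and
    pigment traits; SPAD feeds morphology; stem diameter feeds height;
    and AFW is predicted by the five traits plus LI and G directly.
    """
    g = nx.DiGraph()
    intermediates = ("FPC", "PH", "LT", "SPAD", "SD")
    for exo in EXOGENOUS:
        for node in intermediates:
            g.add_edge(exo, node)
    for parent in ("PH", "LT", "SPAD", "SD", "FPC", "LI", "G"):
        g.add_edge(parent, "AFW")
    for child in ("SPAD", "SD", "PH", "LT"):
        g.add_edge("FPC", child)
    for child in ("PH", "LT", "SD"):
        g.add_edge("SPAD", child)
    g.add_edge("SD", "PH")
    return PathDAG(graph=g)


def read_dag(path: str | Path, exogenous: tuple[str, ...] = EXOGENOUS,
             response: str = "AFW") -> PathDAG:
    """Parse a plain-text edge list: one ``parent -> child`` per line,
    ``#`` starts a comment."""
    g = nx.DiGraph()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" not in line:
            raise ValueError(f"line {lineno}: expected 'parent -> child'")
        parent, child = (s.strip() for s in line.split("->", 1))
        if not parent or not child:
            raise ValueError(f"line {lineno}: empty node name")
        g.add_edge(parent, child)
    return PathDAG(graph=g, exogenous=exogenous, response=response)


@dataclass(frozen=True)
class PathFit:
    """Standardised path coefficients and d-separation fit statistics."""

    coefficients: pd.DataFrame = field(repr=False)  # source, target, beta, se, p
    r_squared: dict[str, float] = field(default_factory=dict)
    fisher_c: float = float("nan")
    df: int = 0
    p_value: float = float("nan")
    claims: pd.DataFrame | None = field(default=None, repr=False)

    def beta(self, source: str, target: str) -> float:
        c = self.coefficients
        row = c[(c["source"] == source) & (c["target"] == target)]
        return float(row["beta"].iloc[0]) if len(row) else 0.0


def _zscore(data: pd.DataFrame) -> pd.DataFrame:
    sd = data.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero-variance column(s) {bad}: cannot standardise")
    return (data - data.mean()) / sd


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """OLS with intercept; returns (betas, ses, pvals, r2) for the slopes."""
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(X)).fit()
    return (model.params[1:], model.bse[1:], model.pvalues[1:],
            float(model.rsquared))


def fit_path_model(dag: PathDAG, data: pd.DataFrame,
                   standardize: bool = True) -> PathFit:
    """Fit the component regressions and the d-separation test.

    ``data`` holds one column per DAG node. With ``standardize=True``
    (default) all columns are z-scored first so coefficients are
    standardised betas.
    """
    missing = [n for n in dag.graph.nodes if n not in data.columns]
    if missing:
        raise ValueError(f"data missing DAG node column(s): {missing}")
    Z = _zscore(data[list(dag.graph.nodes)]) if standardize else data.copy()

    max_parents = max((dag.graph.in_degree(n) for n in dag.endogenous), default=0)
    if len(Z) <= max_parents + 1:
        raise ValueError("too few observations for the largest parent set")

    rows = []
    r2 = {}
    for node in dag.endogenous:
        parents = dag.parents(node)
        betas, ses, pvals, rsq = _ols(Z[node].to_numpy(),
                                      Z[parents].to_numpy())
        r2[node] = rsq
        for parent, b, s, p in zip(parents, betas, ses, pvals):
            rows.append({"source": parent, "target": node,
                         "beta": float(b), "se": float(s), "p": float(p)})
        X = Z[parents].to_numpy()
        if len(parents) > 1 and np.linalg.cond(X.T @ X) > 1e8:
            import warnings

            warnings.warn(f"collinear parents of {node!r} "
                          f"(condition number > 1e8)", stacklevel=2)
    coefficients = pd.DataFrame(rows)

    claims = basis_set(dag)
    claim_rows = []
    pvals = []
    for x, y, cond in claims:
        p = _claim_pvalue(Z, x, y, cond)
        pvals.append(p)
        claim_rows.append({"independent": x, "dependent": y,
                           "conditioning": "+".join(cond) or "-", "p": p})
    if pvals:
        C, df, model_p = fishers_c(pvals)
    else:
        C, df, model_p = 0.0, 0, 1.0
    return PathFit(
        coefficients=coefficients, r_squared=r2,
        fisher_c=C, df=df, p_value=model_p,
        claims=pd.DataFrame(claim_rows) if claim_rows else None,
    )


def _claim_pvalue(Z: pd.DataFrame, x: str, y: str, cond: tuple[str, ...]) -> float:
    """p-value of x's partial coefficient in y ~ conditioning + x."""
    X = Z[list(cond) + [x]].to_numpy()
    _b, _s, pvals, _r2 = _ols(Z[y].to_numpy(), X)
    return float(pvals[-1])


def basis_set(dag: PathDAG) -> list[tuple[str, str, tuple[str, ...]]]:
    """The DAG's d-separation basis set.

    One claim per non-adjacent node pair, conditioning on the union of
    the pair's parents; claims between two exogenous nodes are excluded
    (their association is not modelled). Each claim is returned as
    ``(x, y, conditioning)`` with ``y`` the topologically later node, so
    the test regresses ``y`` on the conditioning set plus ``x``.
    """
    g = dag.graph
    order = {n: i for i, n in enumerate(nx.topological_sort(g))}
    claims = []
    for a, b in combinations(sorted(g.nodes, key=order.get), 2):
        if g.has_edge(a, b) or g.has_edge(b, a):
            continue
        if a in dag.exogenous and b in dag.exogenous:
            continue
        x, y = (a, b) if order[a] < order[b] else (b, a)
        cond = tuple(sorted(set(g.predecessors(a)) | set(g.predecessors(b))))
        claims.append((x, y, cond))
    return claims


def fishers_c(p_values) -> tuple[float, int, float]:
    """Combine independence-claim p-values into Fisher's C.

    ``C = -2 sum ln p_i`` with ``df = 2k``; the model p-value is the
    upper-tail chi-square probability of C. A claim p of exactly 0 makes
    C infinite and is rejected.
    """
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        raise ValueError("need at least one claim p-value")
    if np.any((p <= 0) | (p > 1)):
        bad = np.nonzero((p <= 0) | (p > 1))[0]
        raise ValueError(f"claim p-values must be in (0, 1]; offending index {bad[0]}")
    C = float(-2.0 * np.log(p).sum())
    df = 2 * len(p)
    return C, df, float(stats.chi2.sf(C, df))


def effects(fit: PathFit, dag: PathDAG) -> pd.DataFrame:
    """Direct, indirect and total standardised effects on the response.

    Direct = the source -> response edge coefficient (0 if absent);
    indirect = sum over all directed paths of length >= 2 of the product
    of edge coefficients; total = direct + indirect. Path enumeration is
    exact.
    """
    target = dag.response
    rows = []
    for node in dag.graph.nodes:
        if node == target:
            continue
        direct = fit.beta(node, target)
        indirect = 0.0
        for path in nx.all_simple_paths(dag.graph, node, target):
            if len(path) <= 2:
                continue
            prod = 1.0
            for a, b in zip(path[:-1], path[1:]):
                prod *= fit.beta(a, b)
            indirect += prod
        rows.append({"node": node, "direct": direct,
                     "indirect": indirect, "total": direct + indirect})
    return pd.DataFrame(rows).set_index("node")


def sem_table(means, genotype_score: pd.Series) -> pd.DataFrame:
    """Assemble the node-level data table from aggregated trait means.

    One row per (genotype, treatment): LI is the standardised stress
    indicator, G the standardised genotype score (e.g. a latent
    tolerance proxy), LI x G their re-standardised product, and the
    trait nodes are the replicate means. Columns are returned raw;
    standardisation happens inside :func:`fit_path_model`.
    """
    frames = []
    for treatment, li in (("control", 0.0), ("stress", 1.0)):
        wide = means.wide(treatment)
        df = wide[[NODE_TRAITS[n] for n in NODE_TRAITS]].copy()
        df.columns = list(NODE_TRAITS)
        df["LI"] = li
        frames.append(df)
    out = pd.concat(frames)
    score = genotype_score.reindex(out.index)
    if score.isna().any():
        missing = list(out.index[score.isna()])[:5]
        raise ValueError(f"genotype score missing for {missing}")
    out["G"] = score
    li_z = (out["LI"] - out["LI"].mean()) / out["LI"].std(ddof=1)
    g_z = (out["G"] - out["G"].mean()) / out["G"].std(ddof=1)
    prod = li_z * g_z
    out["LIxG"] = (prod - prod.mean()) / prod.std(ddof=1)
    return out.reset_index(drop=True)
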