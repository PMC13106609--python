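"""Piecewise SEM: component fits, d-separation basis set, Fisher's C,
and effect decomposition."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import heliotol as ht
from heliotol.sem import PathDAG


def simulate_from_dag(dag: PathDAG, betas: dict, n: int, rng) -> pd.DataFrame:
    """Draw unit-variance Gaussian data that satisfies the DAG exactly.

    Root nodes are independent standard normals; each endogenous node is
    the specified linear combination of its parents plus noise whose
    variance is chosen so the node's marginal variance is exactly 1 —
    the supplied coefficients are then the true standardised betas.
    The model-implied covariance is built recursively, so the data
    satisfy every conditional independence the DAG implies.
    """
    order = list(nx.topological_sort(dag.graph))
    idx = {node: i for i, node in enumerate(order)}
    k = len(order)
    Sigma = np.zeros((k, k))
    W = np.zeros((k, k))  # W[i, j] = coefficient of parent j in node i
    for node in order:
        i = idx[node]
        parents = dag.parents(node)
        if not parents:
            Sigma[i, i] = 1.0
            continue
        b = np.array([betas[(p, node)] for p in parents])
        pj = [idx[p] for p in parents]
        for other in order[: order.index(node)]:
            o = idx[other]
            Sigma[i, o] = Sigma[o, i] = b @ Sigma[pj, o]
        explained = b @ Sigma[np.ix_(pj, pj)] @ b
        if explained >= 1.0:
            raise ValueError("coefficients imply variance >= 1; shrink betas")
        W[i, pj] = b
        Sigma[i, i] = 1.0
    data = rng.multivariate_normal(np.zeros(k), Sigma, size=n,
                                   method="cholesky")
    return pd.DataFrame(data, columns=order)


def _chain() -> PathDAG:
    g = nx.DiGraph([("X", "M"), ("M", "Y")])
    return PathDAG(graph=g, exogenous=("X",), response="Y")


class TestFitPathModel:
    def test_exact_copy_gives_unit_coefficient(self):
        x = np.linspace(-2, 2, 30)
        data = pd.DataFrame({"X": x, "Y": x})
        g = nx.DiGraph([("X", "Y")])
        fit = ht.fit_path_model(PathDAG(graph=g, exogenous=("X",), response="Y"),
                                data)
        assert fit.beta("X", "Y") == pytest.approx(1.0)
        assert fit.r_squared["Y"] == pytest.approx(1.0)

    def test_single_parent_beta_equals_pearson_r(self, rng):
        x = rng.normal(size=80)
        y = 0.5 * x + rng.normal(size=80)
        data = pd.DataFrame({"X": x, "Y": y})
        g = nx.DiGraph([("X", "Y")])
        fit = ht.fit_path_model(PathDAG(graph=g, exogenous=("X",), response="Y"),
                                data)
        assert fit.beta("X", "Y") == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_recovers_known_standardized_coefficients(self):
        """Estimates at n=500 are unbiased: averaged over refits, every
        standardised coefficient lands within +-0.05 of its true value
        (a single fit's sampling error with eight correlated parents can
        exceed that band, so the mean over replicates is what is
        checked; each individual fit must still be in the right
        neighbourhood)."""
        dag = ht.default_dag()
        local = np.random.default_rng(404)
        betas = {e: float(local.uniform(0.05, 0.18)) for e in dag.edges}
        estimates = {e: [] for e in dag.edges}
        for _ in range(20):
            data = simulate_from_dag(dag, betas, n=500, rng=local)
            fit = ht.fit_path_model(dag, data)
            for e in dag.edges:
                estimates[e].append(fit.beta(*e))
        for e in dag.edges:
            assert abs(np.mean(estimates[e]) - betas[e]) < 0.05
            assert max(abs(v - betas[e]) for v in estimates[e]) < 0.2

    def test_zero_variance_column_rejected(self):
        data = pd.DataFrame({"X": [1.0, 1.0, 1.0], "Y": [1.0, 2.0, 3.0]})
        g = nx.DiGraph([("X", "Y")])
        with pytest.raises(ValueError, match="zero-variance"):
            ht.fit_path_model(PathDAG(graph=g, exogenous=("X",), response="Y"),
                              data)

    def test_model_p_uniform_under_true_dag(self):
        """Type-I calibration of the d-separation test: data simulated
        from the declared structure give ~uniform model p-values."""
        from scipy import stats
        dag = ht.default_dag()
        local = np.random.default_rng(55)
        betas = {e: 0.12 for e in dag.edges}
        ps = []
        for _ in range(500):
            data = simulate_from_dag(dag, betas, n=200, rng=local)
            ps.append(ht.fit_path_model(dag, data).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3


class TestBasisSet:
    def test_chain_has_single_claim(self):
        claims = ht.basis_set(_chain())
        assert claims == [("X", "Y", ("M",))]

    def test_fully_connected_dag_has_empty_basis(self):
        g = nx.DiGraph([("A", "B"), ("A", "C"), ("B", "C")])
        dag = PathDAG(graph=g, exogenous=("A",), response="C")
        assert ht.basis_set(dag) == []

    def test_default_dag_has_three_claims(self):
        claims = ht.basis_set(ht.default_dag())
        assert len(claims) == 3
        pairs = {frozenset((x, y)) for x, y, _ in claims}
        assert pairs == {frozenset(("PH", "LT")), frozenset(("LT", "SD")),
                         frozenset(("LIxG", "AFW"))}

    def test_matches_brute_force_oracle_on_small_dags(self):
        """Oracle equivalence on random DAGs with <= 6 nodes."""
        local = np.random.default_rng(808)
        checked = 0
        while checked < 40:
            n = int(local.integers(3, 7))
            nodes = [f"n{i}" for i in range(n)]
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            for i, j in combinations(range(n), 2):
                if local.random() < 0.45:
                    g.add_edge(nodes[i], nodes[j])
            roots = tuple(v for v in nodes if g.in_degree(v) == 0)
            sinks = [v for v in nodes if g.out_degree(v) == 0]
            response = sinks[-1]
            if response in roots:
                continue
            dag = PathDAG(graph=g, exogenous=roots, response=response)
            claims = ht.basis_set(dag)

            expected = set()
            for a, b in combinations(nodes, 2):
                if g.has_edge(a, b) or g.has_edge(b, a):
                    continue
                if a in roots and b in roots:
                    continue
                cond = frozenset(set(g.predecessors(a)) | set(g.predecessors(b)))
                expected.add((frozenset((a, b)), cond))
            got = {(frozenset((x, y)), frozenset(c)) for x, y, c in claims}
            assert got == expected
            checked += 1


class TestFishersC:
    def test_single_claim_at_p_one(self):
        C, df, p = ht.fishers_c([1.0])
        assert (C, df, p) == (0.0, 2, 1.0)

    def test_published_fit_statistic(self):
        # survival of chi-square(6) at the reported C
        from scipy import stats
        assert stats.chi2.sf(3.104, 6) == pytest.approx(0.796, abs=5e-4)

    def test_two_half_pvalues_closed_form(self):
        C, df, p = ht.fishers_c([0.5, 0.5])
        assert C == pytest.approx(-2 * np.log(0.25))
        assert df == 4
        # chi-square(4) survival has closed form exp(-C/2) * (1 + C/2)
        assert p == pytest.approx(np.exp(-C / 2) * (1 + C / 2))
        assert p == pytest.approx(0.5966, abs=5e-4)

    def test_zero_pvalue_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            ht.fishers_c([0.5, 0.0])


class TestEffects:
    def test_chain_product_rule(self):
        g = nx.DiGraph([("LI", "SD"), ("SD", "AFW")])
        dag = PathDAG(graph=g, exogenous=("LI",), response="AFW")
        fit = ht.PathFit(
            coefficients=pd.DataFrame([
                {"source": "LI", "target": "SD", "beta": 0.6, "se": 0.1, "p": 0.01},
                {"source": "SD", "target": "AFW", "beta": 0.5, "se": 0.1, "p": 0.01},
            ]),
        )
        eff = ht.effects(fit, dag)
        assert eff.loc["LI", "direct"] == 0.0
        assert eff.loc["LI", "indirect"] == pytest.approx(0.3)
        assert eff.loc["LI", "total"] == pytest.approx(0.3)
        assert eff.loc["SD", "total"] == pytest.approx(0.5)

    def test_total_is_direct_plus_indirect_everywhere(self, rng):
        dag = ht.default_dag()
        betas = {e: float(rng.uniform(0.05, 0.15)) for e in dag.edges}
        data = simulate_from_dag(dag, betas, n=300, rng=rng)
        fit = ht.fit_path_model(dag, data)
        eff = ht.effects(fit, dag)
        assert np.allclose(eff["total"], eff["direct"] + eff["indirect"],
                           atol=1e-10)

    def test_totals_match_brute_force_path_enumeration(self, rng):
        dag = ht.default_dag()
        betas = {e: float(rng.uniform(0.05, 0.15)) for e in dag.edges}
        fit = ht.PathFit(coefficients=pd.DataFrame(
            [{"source": a, "target": b, "beta": v, "se": 0.0, "p": 0.5}
             for (a, b), v in betas.items()]
        ))
        eff = ht.effects(fit, dag)

        def all_paths_total(source):
            total = 0.0
            for path in nx.all_simple_paths(dag.graph, source, "AFW"):
                prod = 1.0
                for e in zip(path[:-1], path[1:]):
                    prod *= betas[e]
                total += prod
            return total

        for node in eff.index:
            assert eff.loc[node, "total"] == pytest.approx(all_paths_total(node))


class TestDagIO:
    def test_read_edge_list_round_trip(self, tmp_path):
        p = tmp_path / "dag.txt"
        p.write_text("# comment\nX -> M\nM -> Y  # tail comment\nX -> Y\n")
        dag = ht.read_dag(p, exogenous=("X",), response="Y")
        assert set(dag.edges) == {("X", "M"), ("M", "Y"), ("X", "Y")}

    def test_cycle_rejected(self, tmp_path):
        p = tmp_path / "dag.txt"
        p.write_text("X -> Y\nY -> X\n")
        with pytest.raises(ValueError, match="acyclic"):
            ht.read_dag(p, exogenous=(), response="Y")

    def test_response_with_children_rejected(self):
        g = nx.DiGraph([("X", "AFW"), ("AFW", "Z")])
        with pytest.raises(ValueError, match="no children"):
            PathDAG(graph=g, exogenous=("X",), response="AFW")


class TestSemTable:
    def test_assembles_one_row_per_genotype_treatment(self, cohort, means):
        data = ht.sem_table(means, cohort.latent_tolerance)
        assert len(data) == 96
        for col in ("LI", "G", "LIxG", "FPC", "PH", "LT", "SPAD", "SD", "AFW"):
            assert col in data.columns
        assert data["LIxG"].std(ddof=1) == pytest.approx(1.0)

    def test_fit_on_cohort_shows_stress_and_tolerance_signals(self, cohort, means):
        data = ht.sem_table(means, cohort.latent_tolerance)
        fit = ht.fit_path_model(ht.default_dag(), data)
        eff = ht.effects(fit, ht.default_dag())
        # stress lowers fresh weight; proline's total effect is negative
        assert eff.loc["LI", "total"] < 0
        assert eff.loc["FPC", "total"] < 0
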