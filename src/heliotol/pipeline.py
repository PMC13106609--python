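"""End-to-end orchestration of the tolerance-evaluation pipeline.

Stage order: simulate (or ingest) -> descriptive stats -> tolerance
coefficients -> entropy-weight TOPSIS -> tolerance-level clustering ->
trait associations -> permutation importance -> piecewise SEM. Every
stage writes CSV (or plain-text) outputs to the run directory and the
run closes with a manifest recording the configuration, the master
seed, and a checksum per output file, so a rerun with the same
configuration is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, classify, importance as imp, sem, simulate, topsis
from .tolerance import tolerance_coefficients
from .traits import TREATMENTS, aggregate_replicates, descriptive_stats, read_trait_table

log = logging.getLogger("heliotol")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int
    out_dir: str | Path = "heliotol_run"
    input_csv: str | Path | None = None          # if None, simulate
    generator: simulate.GeneratorParams | None = None
    directions: dict[str, str] | None = None     # criterion directions for TOPSIS
    k: int = 4
    linkage: str = classify.DEFAULT_LINKAGE
    mantel_permutations: int = 999
    importance_trees: int = 500
    importance_null: int = 0                     # 0 disables the null refits
    drop_incomplete: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a master seed is required (stochastic stages)")
        if self.k < 2:
            raise ValueError("k must be >= 2")


def _write(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, **kw)
    return path


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    ss = np.random.SeedSequence(config.seed)
    sub = {name: int(child.generate_state(1)[0] % (2**31))
           for name, child in zip(
               ("simulate", "mantel", "importance"), ss.spawn(3))}

    # -- input ---------------------------------------------------------
    genotype_score = None
    if config.input_csv is None:
        cohort = simulate.generate_cohort(config.generator, seed=sub["simulate"])
        table = cohort.table
        genotype_score = cohort.latent_tolerance
        log.info("simulated cohort: %d rows, %d truncated",
                 len(table), cohort.n_truncated)
        written.append(_write(table.data, out / "cohort.csv", index=False))
    else:
        table = read_trait_table(config.input_csv)
        log.info("read %d rows from %s", len(table), config.input_csv)

    # -- descriptive stats --------------------------------------------
    stats = pd.concat([descriptive_stats(table, t) for t in TREATMENTS])
    written.append(_write(stats, out / "descriptive_stats.csv", index=False))

    # -- tolerance matrix ---------------------------------------------
    means = aggregate_replicates(table)
    tol = tolerance_coefficients(means, drop_incomplete=config.drop_incomplete)
    written.append(_write(tol, out / "tolerance_matrix.csv"))

    # -- entropy weights + TOPSIS -------------------------------------
    w = topsis.entropy_weights(tol, config.directions)
    res = topsis.topsis_ci(tol, w, config.directions)
    weights_df = pd.DataFrame(
        {"entropy": w.entropy, "weight": w.weights}
    ).rename_axis("trait")
    written.append(_write(weights_df, out / "weights.csv"))
    written.append(_write(res.table.rename_axis("genotype"),
                          out / "topsis_result.csv"))

    # -- tolerance levels ---------------------------------------------
    levels = classify.classify_tolerance(res.ci, k=config.k, method=config.linkage)
    written.append(_write(levels.assignments, out / "levels.csv", index=False))
    written.append(_write(levels.summary, out / "level_summary.csv", index=False))

    # -- associations --------------------------------------------------
    pooled = pd.concat([means.wide(t) for t in TREATMENTS])
    r, p = association.pearson_matrix(pooled)
    corr = (
        r.rename_axis(index="trait_a", columns="trait_b").stack().rename("r").to_frame()
        .join(p.rename_axis(index="trait_a", columns="trait_b").stack().rename("p"))
        .reset_index()
    )
    written.append(_write(corr, out / "correlations.csv", index=False))
    mantel = association.mantel_screen(
        pooled.groupby(level=0).mean(),
        n_perm=config.mantel_permutations, seed=sub["mantel"],
    )
    written.append(_write(mantel, out / "mantel.csv", index=False))

    # -- permutation importance ---------------------------------------
    feats = pooled.drop(columns=["afw"])
    response = pooled["afw"]
    if config.importance_null:
        imp_res = imp.importance_significance(
            feats, response, n_null=config.importance_null,
            n_trees=config.importance_trees, seed=sub["importance"])
    else:
        imp_res = imp.permutation_importance(
            feats, response, n_trees=config.importance_trees,
            seed=sub["importance"])
    written.append(_write(imp_res.table, out / "importance.csv"))

    # -- piecewise SEM -------------------------------------------------
    if genotype_score is None:
        # without a ground-truth genotype score, use the TOPSIS CI as the
        # genotype-level tolerance proxy
        genotype_score = res.ci
    dag = sem.default_dag()
    data = sem.sem_table(means, genotype_score)
    fit = sem.fit_path_model(dag, data)
    eff = sem.effects(fit, dag)
    written.append(_write(fit.coefficients, out / "paths.csv", index=False))
    written.append(_write(eff, out / "effects.csv"))
    fit_txt = out / "fit.txt"
    lines = [f"Fisher's C = {fit.fisher_c:.4f}",
             f"df = {fit.df}",
             f"model p = {fit.p_value:.4f}"]
    lines += [f"R2[{k}] = {v:.4f}" for k, v in fit.r_squared.items()]
    fit_txt.write_text("\n".join(lines) + "\n")
    written.append(fit_txt)

    # -- manifest ------------------------------------------------------
    cfg = dataclasses.asdict(config)
    cfg["out_dir"] = str(cfg["out_dir"])
    if cfg.get("input_csv") is not None:
        cfg["input_csv"] = str(cfg["input_csv"])
    if cfg.get("generator") is not None:
        gen = cfg["generator"]
        gen.pop("correlation", None)
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "stage_seeds": sub,
        "outputs": {p.name: _checksum(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
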