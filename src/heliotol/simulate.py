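"""Synthetic seedling cohorts with the correlation and stress structure
the downstream evaluation assumes.

The generator emulates a germplasm screen: ``n_genotypes`` accessions
measured for the nine traits under a control and a high-light stress
treatment, with ``n_replicates`` biological replicates per cell. Each
genotype receives

* a correlated vector of control trait means — a single latent "vigor"
  factor with per-trait loadings induces the observed positive block
  among height, stem diameter, leaf thickness, SPAD and Rubisco and its
  negative coupling with proline;
* a latent tolerance scalar ``tau`` that scales the stress response
  multiplicatively — positively for traits that decline under stress,
  inversely for proline, which accumulates. This plants a genotype-level
  tolerance gradient that the TOPSIS/clustering stages must recover;
* independent replicate residual noise proportional to the trait mean.

Strictly positive, right-skewed traits (proline, fresh/dry weight,
Rubisco) are generated log-normally; the rest are normal on the natural
scale. Values are clipped at zero and clip events counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .traits import TRAITS, TraitTable, trait_table

#: Control-treatment grand mean and inter-genotype SD per trait, and the
#: multiplicative stress effect on the genotype mean (stress/control ratio
#: of the cohort grand means).
_CALIBRATION: Mapping[str, tuple[float, float, float]] = {
    # trait: (control_mean, control_sd, stress_factor)
    "plant_height": (35.82, 4.95, 31.51 / 35.82),
    "stem_diameter": (1.81, 0.30, 1.55 / 1.81),
    "spad": (30.19, 6.98, 24.37 / 30.19),
    "leaf_thickness": (0.52, 0.11, 0.46 / 0.52),
    "afw": (0.54, 0.21, 0.42 / 0.54),
    "adw": (0.07, 0.03, 0.06 / 0.07),
    "pn": (6.98, 2.63, 4.13 / 6.98),
    "proline": (422.41, 266.55, 571.95 / 422.41),
    "rubisco": (210.43, 69.05, 168.22 / 210.43),
}

#: Loading of each trait on the latent vigor factor. The implied
#: trait-trait correlation is l_i * l_j (factor model), giving a positive
#: block among the growth/photosynthesis traits and negative couplings of
#: that block with proline.
_LOADINGS: Mapping[str, float] = {
    "plant_height": 0.70,
    "stem_diameter": 0.75,
    "spad": 0.75,
    "leaf_thickness": 0.65,
    "afw": 0.75,
    "adw": 0.60,
    "pn": 0.60,
    "proline": -0.55,
    "rubisco": 0.65,
}

#: Sign of the tolerance multiplier: +1 where a larger stress/control
#: ratio means better tolerance (all declining traits), -1 for proline.
_TOLERANCE_SIGN: Mapping[str, int] = {t: (-1 if t == "proline" else +1) for t in TRAITS}

#: Traits generated on the log scale: strictly positive with CVs of
#: ~33-63%, where a natural-scale normal would put appreciable mass
#: below zero.
_LOG_SCALE = frozenset({"proline", "afw", "adw", "rubisco", "pn"})


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic cohort model.

    ``control_means``/``control_sds`` set the cohort grand mean and
    inter-genotype SD of each trait under control; ``stress_factors`` the
    expected stress/control mean ratio. ``tolerance_sd`` is the SD of the
    latent log tolerance multiplier (0.12 ~ +-12% genotype spread in the
    stress ratio). ``residual_cv`` is the replicate residual SD as a
    fraction of the genotype-treatment mean; the replicate-level variance
    is a free choice of the generator, not an observed quantity.
    """

    control_means: Mapping[str, float]
    control_sds: Mapping[str, float]
    stress_factors: Mapping[str, float]
    loadings: Mapping[str, float]
    tolerance_sd: float = 0.12
    residual_cv: float = 0.10
    n_genotypes: int = 48
    n_replicates: int = 3
    correlation: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        for name, m in (("control_means", self.control_means),
                        ("control_sds", self.control_sds),
                        ("stress_factors", self.stress_factors),
                        ("loadings", self.loadings)):
            missing = set(TRAITS) - set(m)
            if missing:
                raise ValueError(f"{name} missing trait(s): {sorted(missing)}")
        if any(v < 0 for v in self.control_sds.values()):
            raise ValueError("control SDs must be >= 0")
        if any(f <= 0 for f in self.stress_factors.values()):
            raise ValueError("stress factors must be > 0")
        if any(abs(l) > 1 for l in self.loadings.values()):
            raise ValueError("factor loadings must lie in [-1, 1]")
        if self.tolerance_sd < 0 or self.residual_cv < 0:
            raise ValueError("tolerance_sd and residual_cv must be >= 0")
        if self.correlation is not None:
            _validate_correlation(np.asarray(self.correlation, dtype=float))

    def correlation_matrix(self) -> np.ndarray:
        """Trait-trait correlation of the latent genotype effects."""
        if self.correlation is not None:
            return np.asarray(self.correlation, dtype=float)
        l = np.array([self.loadings[t] for t in TRAITS])
        R = np.outer(l, l)
        np.fill_diagonal(R, 1.0)
        return R


def _validate_correlation(R: np.ndarray) -> None:
    if R.shape != (len(TRAITS), len(TRAITS)):
        raise ValueError(f"correlation matrix must be {len(TRAITS)}x{len(TRAITS)}")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    w = np.linalg.eigvalsh((R + R.T) / 2)
    if w.min() < -1e-10:
        raise ValueError(f"correlation matrix not positive semidefinite "
                         f"(min eigenvalue {w.min():.3e})")


def default_params(**overrides) -> GeneratorParams:
    """Cohort parameters calibrated to the observed screen: 48 genotypes,
    3 replicates, control means/SDs and stress factors matching the
    study-scale descriptive statistics."""
    base = dict(
        control_means={t: _CALIBRATION[t][0] for t in TRAITS},
        control_sds={t: _CALIBRATION[t][1] for t in TRAITS},
        stress_factors={t: _CALIBRATION[t][2] for t in TRAITS},
        loadings=dict(_LOADINGS),
    )
    base.update(overrides)
    return GeneratorParams(**base)


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: the replicate table, the per-genotype latent
    tolerance scalar (ground truth for recovery checks), and the number
    of values clipped at zero."""

    table: TraitTable
    latent_tolerance: pd.Series = field(repr=False)
    latent_vigor: pd.Series = field(repr=False)
    n_truncated: int = 0


def generate_cohort(params: GeneratorParams | None = None,
                    seed: int = 0) -> SyntheticCohort:
    """Draw a replicate-level trait table from the cohort model.

    Deterministic given ``seed``. Per-genotype random sub-streams are
    spawned from the master seed, so genotype ``G01`` receives identical
    draws whether the cohort has 48 or 500 genotypes.
    """
    if params is None:
        params = default_params()
    use_factor = params.correlation is None
    if use_factor:
        l = np.array([params.loadings[t] for t in TRAITS])
        uniq = np.sqrt(1.0 - l * l)
    else:
        R = params.correlation_matrix()
        _validate_correlation(R)
        L = np.linalg.cholesky(R + 1e-12 * np.eye(len(TRAITS)))

    n_g, n_r = params.n_genotypes, params.n_replicates
    width = max(2, len(str(n_g)))
    names = [f"G{i + 1:0{width}d}" for i in range(n_g)]
    children = np.random.SeedSequence(seed).spawn(n_g)

    records = []
    taus = np.empty(n_g)
    vigors = np.empty(n_g)
    n_trunc = 0
    for gi, (name, child) in enumerate(zip(names, children)):
        rng = np.random.default_rng(child)
        if use_factor:
            f = rng.standard_normal()
            z = l * f + uniq * rng.standard_normal(len(TRAITS))
            vigors[gi] = f
        else:
            z = L @ rng.standard_normal(len(TRAITS))
            vigors[gi] = np.nan
        tau = rng.normal(0.0, params.tolerance_sd)
        taus[gi] = tau
        for ti, trait in enumerate(TRAITS):
            mean = params.control_means[trait]
            sd = params.control_sds[trait]
            if trait in _LOG_SCALE:
                cv = sd / mean
                sigma = np.sqrt(np.log1p(cv * cv))
                mu = np.log(mean) - sigma * sigma / 2.0
                g_control = float(np.exp(mu + sigma * z[ti]))
            else:
                g_control = mean + sd * z[ti]
            factor = params.stress_factors[trait] * np.exp(_TOLERANCE_SIGN[trait] * tau)
            g_stress = g_control * factor
            for treatment, g_mean in (("control", g_control), ("stress", g_stress)):
                noise = rng.normal(0.0, params.residual_cv * abs(g_mean), size=n_r)
                vals = g_mean + noise
                n_trunc += int(np.sum(vals < 0))
                vals = np.clip(vals, 0.0, None)
                for rep, v in enumerate(vals, start=1):
                    records.append((name, treatment, rep, trait, v))

    df = pd.DataFrame(
        records, columns=["genotype", "treatment", "replicate", "trait", "value"]
    )
    return SyntheticCohort(
        table=trait_table(df),
        latent_tolerance=pd.Series(taus, index=names, name="tolerance"),
        latent_vigor=pd.Series(vigors, index=names, name="vigor"),
        n_truncated=n_trunc,
    )


def params_from_yaml(path) -> GeneratorParams:
    """Load generator parameters from a YAML file; unspecified fields
    fall back to the calibrated defaults."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = default_params()
    merged = {}
    for key in ("control_means", "control_sds", "stress_factors", "loadings"):
        d = dict(getattr(base, key))
        d.update(raw.pop(key, {}) or {})
        merged[key] = d
    for key in ("tolerance_sd", "residual_cv", "n_genotypes", "n_replicates"):
        if key in raw:
            merged[key] = raw.pop(key)
    if raw:
        raise ValueError(f"unknown generator parameter(s): {sorted(raw)}")
    return replace(base, **merged)
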