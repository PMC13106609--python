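"""Replicate-level trait tables: ingestion, validation, aggregation, summaries.

The pipeline's single data-entry point is a long-format table of seedling
trait measurements: one row per (genotype, treatment, replicate, trait).
Nine traits are recognised, covering morphology (plant height, stem
diameter, leaf thickness), biomass (aboveground fresh and dry weight),
photosynthetic physiology (SPAD, net photosynthetic rate, Rubisco
activity) and osmotic adjustment (free proline).

All downstream stages consume replicate means per (genotype, treatment,
trait); descriptive summaries are computed over genotype means so that
standard deviations and coefficients of variation describe inter-genotype
variation, not measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical trait tokens, in reporting order.
TRAITS: tuple[str, ...] = (
    "plant_height",
    "stem_diameter",
    "spad",
    "leaf_thickness",
    "afw",
    "adw",
    "pn",
    "proline",
    "rubisco",
)

TRAIT_LABELS: Mapping[str, str] = {
    "plant_height": "Plant height (cm)",
    "stem_diameter": "Stem diameter (mm)",
    "spad": "SPAD value",
    "leaf_thickness": "Leaf thickness (mm)",
    "afw": "Aboveground fresh weight (g)",
    "adw": "Aboveground dry weight (g)",
    "pn": "Net photosynthetic rate (umol m-2 s-1)",
    "proline": "Free proline (ug/g)",
    "rubisco": "Rubisco activity (nmol/min/g)",
}

TREATMENTS: tuple[str, str] = ("control", "stress")

_REQUIRED_COLUMNS = ("genotype", "treatment", "replicate", "trait", "value")


class SchemaError(ValueError):
    """Input table is missing required columns."""


class TraitValidationError(ValueError):
    """Input rows violate the trait-table contract."""


@dataclass(frozen=True)
class TraitTable:
    """Validated long-format replicate measurements.

    Wraps a DataFrame with columns ``genotype, treatment, replicate,
    trait, value``. Construct via :func:`trait_table` or
    :func:`read_trait_table` so the invariants hold: finite values,
    non-negative measurements, canonical trait/treatment tokens, and
    unique replicate indices within each (genotype, treatment, trait).
    """

    data: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    @property
    def traits(self) -> list[str]:
        return [t for t in TRAITS if t in set(self.data["trait"])]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class GenotypeTreatmentMeans:
    """Replicate means per (genotype, treatment, trait) plus counts."""

    means: pd.DataFrame = field(repr=False)  # columns: genotype, treatment, trait, mean, n_reps

    def value(self, genotype: str, treatment: str, trait: str) -> float:
        m = self.means
        row = m[
            (m["genotype"] == genotype)
            & (m["treatment"] == treatment)
            & (m["trait"] == trait)
        ]
        if row.empty:
            raise KeyError((genotype, treatment, trait))
        return float(row["mean"].iloc[0])

    def wide(self, treatment: str) -> pd.DataFrame:
        """Genotype x trait matrix of means for one treatment."""
        sub = self.means[self.means["treatment"] == treatment]
        w = sub.pivot(index="genotype", columns="trait", values="mean")
        return w.reindex(columns=[t for t in TRAITS if t in w.columns])


def trait_table(records: pd.DataFrame | Iterable[Mapping]) -> TraitTable:
    """Validate records and build a :class:`TraitTable`.

    Treatment tokens are canonicalised case-insensitively (``CK`` and
    ``high_light`` aliases are accepted for control/stress).
    """
    df = pd.DataFrame(records).copy()
    if list(df.columns) == list(range(len(_REQUIRED_COLUMNS))):
        df.columns = _REQUIRED_COLUMNS  # bare 5-tuples in schema order
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df[list(_REQUIRED_COLUMNS)]

    df["genotype"] = df["genotype"].astype(str)
    df["trait"] = df["trait"].astype(str).str.strip().str.lower()
    unknown = sorted(set(df["trait"]) - set(TRAITS))
    if unknown:
        raise TraitValidationError(f"unknown trait name(s): {', '.join(unknown)}")

    aliases = {"control": "control", "ck": "control", "stress": "stress",
               "high_light": "stress", "hl": "stress", "t": "stress"}
    norm = df["treatment"].astype(str).str.strip().str.lower().map(aliases)
    bad = df.loc[norm.isna(), "treatment"].unique()
    if len(bad):
        raise TraitValidationError(f"unknown treatment token(s): {list(bad)}")
    df["treatment"] = norm

    values = pd.to_numeric(df["value"], errors="coerce")
    nonnum = df.index[values.isna() & df["value"].notna()]
    if len(nonnum):
        raise TraitValidationError(
            f"non-numeric value at row(s) {list(nonnum[:5])}: "
            f"{df.loc[nonnum[:5], 'value'].tolist()}"
        )
    df["value"] = values.astype(float)
    if df["value"].isna().any() or not np.isfinite(df["value"]).all():
        raise TraitValidationError("values must be finite and non-missing")
    if (df["value"] < 0).any():
        rows = df.index[df["value"] < 0][:5]
        raise TraitValidationError(f"negative measurement(s) at row(s) {list(rows)}")

    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    if (df["replicate"] < 1).any():
        raise TraitValidationError("replicate indices must be positive integers")
    dup = df.duplicated(subset=["genotype", "treatment", "trait", "replicate"])
    if dup.any():
        rows = df.index[dup][:5]
        raise TraitValidationError(
            f"duplicate replicate index within a (genotype, treatment, trait) "
            f"group at row(s) {list(rows)}"
        )
    return TraitTable(df.reset_index(drop=True))


def read_trait_table(path: str | Path,
                     schema: Mapping[str, str] | None = None) -> TraitTable:
    """Read a long-format CSV into a validated :class:`TraitTable`.

    Parameters
    ----------
    path
        CSV with header ``genotype,treatment,replicate,trait,value``
        (UTF-8, comma-separated, decimal point).
    schema
        Optional mapping from required column name to the name actually
        used in the file, e.g. ``{"genotype": "accession"}``.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return trait_table(df)


def aggregate_replicates(table: TraitTable) -> GenotypeTreatmentMeans:
    """Arithmetic mean over replicates per (genotype, treatment, trait)."""
    g = (
        table.data.groupby(["genotype", "treatment", "trait"], sort=True)["value"]
        .agg(mean="mean", n_reps="count")
        .reset_index()
    )
    return GenotypeTreatmentMeans(g)


def completeness_summary(means: GenotypeTreatmentMeans,
                         traits: Iterable[str] = TRAITS) -> pd.DataFrame:
    """Keys absent from the aggregated means, one row per missing cell."""
    m = means.means
    genotypes = sorted(m["genotype"].unique())
    full = pd.MultiIndex.from_product(
        [genotypes, TREATMENTS, list(traits)],
        names=["genotype", "treatment", "trait"],
    )
    have = pd.MultiIndex.from_frame(m[["genotype", "treatment", "trait"]])
    missing = full.difference(have)
    return missing.to_frame(index=False)


def descriptive_stats(table: TraitTable, treatment: str) -> pd.DataFrame:
    """Per-trait range, mean, SD and CV over genotype means.

    Statistics are computed over the genotype replicate means within the
    requested treatment: the SD and CV therefore measure inter-genotype
    variation. The sample (n-1) standard deviation is used. Values are
    returned at full precision; round only at the reporting layer.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"treatment must be one of {TREATMENTS}")
    means = aggregate_replicates(table).wide(treatment)
    rows = []
    for trait in means.columns:
        v = means[trait].dropna().to_numpy()
        if len(v) < 2:
            raise TraitValidationError(
                f"need >= 2 genotype means for trait {trait!r}, got {len(v)}"
            )
        mean = float(np.mean(v))
        sd = float(np.std(v, ddof=1))
        cv = float("nan") if mean == 0 else 100.0 * sd / mean
        rows.append(
            {
                "trait": trait,
                "treatment": treatment,
                "min": float(np.min(v)),
                "max": float(np.max(v)),
                "mean": mean,
                "sd": sd,
                "cv_percent": cv,
                "cv_defined": mean != 0,
            }
        )
    return pd.DataFrame(rows)


def percent_change(control_mean: float, stress_mean: float) -> float:
    """Signed percent change of the stress mean relative to control."""
    if control_mean == 0:
        raise ZeroDivisionError("percent change undefined for control mean 0")
    return 100.0 * (stress_mean - control_mean) / control_mean
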