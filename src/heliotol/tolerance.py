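"""Per-genotype stress-tolerance coefficients.

The high-light tolerance coefficient of a genotype for a trait is the
ratio of its replicate-mean value under stress to its replicate-mean
value under control. A coefficient near 1 indicates stability under
stress; proline routinely exceeds 1 because it accumulates. The genotype
x trait matrix of coefficients is the decision matrix for the TOPSIS
evaluation and the clustering input — no rescaling or capping happens
here.
"""

from __future__ import annotations

import pandas as pd

from .traits import TRAITS, GenotypeTreatmentMeans


class CompletenessError(ValueError):
    """A (genotype, treatment, trait) cell required for the ratio is absent."""


def tolerance_coefficients(means: GenotypeTreatmentMeans,
                           drop_incomplete: bool = False) -> pd.DataFrame:
    """Genotype x trait matrix of stress/control mean ratios.

    Parameters
    ----------
    means
        Aggregated replicate means; both treatments must be present for
        every genotype and trait.
    drop_incomplete
        Drop genotypes with any missing cell instead of raising.

    Returns
    -------
    DataFrame indexed by genotype with one column per trait, every entry
    finite and positive.
    """
    control = means.wide("control")
    stress = means.wide("stress")
    traits = [t for t in TRAITS if t in control.columns or t in stress.columns]
    control = control.reindex(columns=traits)
    stress = stress.reindex(index=control.index, columns=traits)

    incomplete = control.isna().any(axis=1) | stress.isna().any(axis=1)
    if incomplete.any():
        bad = list(control.index[incomplete])
        if drop_incomplete:
            control = control.loc[~incomplete]
            stress = stress.loc[~incomplete]
        else:
            raise CompletenessError(
                f"missing treatment/trait cells for genotype(s) {bad[:10]}"
            )
    nonpos = (control <= 0)
    if nonpos.any().any():
        g = control.index[nonpos.any(axis=1)][0]
        t = control.columns[nonpos.loc[g]][0]
        raise ZeroDivisionError(
            f"control mean <= 0 for genotype {g!r}, trait {t!r}: "
            f"tolerance ratio undefined"
        )
    ratio = stress / control
    ratio.index.name = "genotype"
    ratio.columns.name = "trait"
    return ratio
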