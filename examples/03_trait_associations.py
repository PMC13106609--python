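"""Pearson correlations and Mantel tests on a simulated screen.

Computes the trait-by-trait Pearson matrix over pooled genotype means
and runs seeded Mantel permutation tests of each trait's genotype
distance matrix against the aboveground-fresh-weight matrix — the hub
of the trait network.
"""

import pandas as pd

import heliotol as ht

cohort = ht.generate_cohort(seed=7)
means = ht.aggregate_replicates(cohort.table)
pooled = pd.concat([means.wide(t) for t in ht.TREATMENTS])

r, p = ht.pearson_matrix(pooled)
print("Pearson r of selected trait pairs (pooled control + stress):")
for a, b in [("plant_height", "spad"), ("spad", "proline"),
             ("stem_diameter", "afw")]:
    print(f"  {a:>13s} ~ {b:<13s} r = {r.loc[a, b]:+.3f}  (p = {p.loc[a, b]:.2e})")

screen = ht.mantel_screen(pooled.groupby(level=0).mean(),
                          focal_traits=("afw",), n_perm=999, seed=1)
print("\nMantel tests against the fresh-weight distance matrix:")
print(screen.sort_values("r", ascending=False)
      [["trait", "r", "p", "strength"]].round(3).to_string(index=False))
print("\n(r >= 0.4 counts as a strong distance-matrix association; "
      "p is a one-sided permutation p-value)")
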