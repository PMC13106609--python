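# heliotol

Multi-trait evaluation of high-light stress tolerance in germplasm
screens.

In alpine regions, midday irradiance routinely exceeds the light
saturation point of forage crops, and screening collections for
high-light tolerance has become part of breeding programmes for oat
(*Avena sativa*) and related species. A typical screen grows dozens of
accessions under a control and a high-light treatment, measures a panel
of morphological and physiological traits (plant height, stem diameter,
leaf thickness, fresh and dry shoot weight, SPAD chlorophyll value, net
photosynthetic rate, free proline, Rubisco activity), and must then
reduce nine noisy, partially redundant responses per genotype to a
single defensible tolerance ranking. `heliotol` implements that
reduction as a tested, seeded, reusable pipeline.

## What it computes

For genotype *i* and trait *j*, the **tolerance coefficient** is the
ratio of treatment means

> x<sub>ij</sub> = mean(stress)<sub>ij</sub> / mean(control)<sub>ij</sub>,

so values near 1 indicate stability under stress (proline, which
accumulates under stress, routinely exceeds 1). The genotype × trait
matrix **X** is evaluated by **entropy-weight TOPSIS**:

1. min–max normalise each criterion column and form
   p<sub>ij</sub> = x′<sub>ij</sub> / Σ<sub>i</sub> x′<sub>ij</sub>;
   the entropy e<sub>j</sub> = −(1/ln n) Σ<sub>i</sub> p<sub>ij</sub> ln p<sub>ij</sub>
   gives objective weights w<sub>j</sub> ∝ 1 − e<sub>j</sub>
   (criteria on which genotypes barely differ get near-zero weight);
2. vector-normalise, weight, and score each genotype by its relative
   closeness CI = D⁻/(D⁺ + D⁻) to the per-criterion ideal points,
   with CI ∈ [0, 1] and higher = more tolerant.

The CI vector is then cut into **tolerance levels I–IV** by
agglomerative clustering (Euclidean distance; average linkage by
default — see `docs/methods.md` for the linkage sensitivity), and the
trait structure behind the ranking is dissected three ways:

* **Pearson / Mantel tests** — trait correlations and seeded
  permutation tests between genotype distance matrices, with Mantel r
  classed weak / moderate / strong at 0.2 and 0.4;
* **permutation importance** — %IncMSE of each trait for predicting
  aboveground fresh weight under a bootstrap tree ensemble, with
  response-permutation p-values;
* **piecewise SEM** — standardised regressions over a declared DAG,
  d-separation goodness of fit via Fisher's C = −2 Σ ln p (χ² with 2k
  df), and exact direct/indirect/total effect decomposition.

Raw replicate data from such screens are rarely deposited, so the
package ships a calibrated **synthetic-cohort generator**: 48 genotypes
× 2 light levels × 3 replicates with realistic trait means, CVs,
inter-trait correlations and a planted per-genotype latent tolerance
scalar, so every downstream stage can be validated against a known
ground truth.

## Worked example

```python
from scipy.stats import spearmanr
import heliotol as ht

cohort = ht.generate_cohort(seed=42)                 # 48 x 2 x 9 x 3
means  = ht.aggregate_replicates(cohort.table)
tol    = ht.tolerance_coefficients(means)            # 48 x 9 decision matrix
result = ht.topsis_ci(tol, ht.entropy_weights(tol))
levels = ht.classify_tolerance(result.ci, k=4)

rho = spearmanr(result.ci,
                cohort.latent_tolerance.reindex(result.ci.index))[0]
print(result.table.sort_values("ci", ascending=False).head(3).round(3))
print(f"rank recovery vs planted tolerance: rho = {rho:.3f}")
```

prints

```
          d_plus  d_minus     ci  rank
genotype
G34        0.012    0.025  0.672     1
G45        0.012    0.018  0.610     2
G05        0.014    0.022  0.607     3
rank recovery vs planted tolerance: rho = 0.902
```

G34 sits closest to the ideal point (CI 0.672) and the CI ordering
recovers the generator's hidden tolerance gradient almost perfectly
(Spearman ρ = 0.90). The scripts in `examples/` walk through each
capability the same way: simulation + TOPSIS, level clustering,
associations, importance, and the path model.

The same pipeline runs from a shell:

```bash
heliotol all --seed 42 --out run/            # full pipeline + manifest
heliotol cluster --out levels.csv            # skip-to-stage from a CI table
```

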