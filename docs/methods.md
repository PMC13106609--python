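# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, and the places where the design was
genuinely open.

## Data model

The unit of input is the replicate-level long-format table: one row per
(genotype, treatment, replicate, trait), nine canonical traits, two
treatments (`control`, `stress`). All downstream analyses consume the
replicate means per (genotype, treatment, trait); descriptive
statistics (range, mean, SD, CV = 100·SD/mean) are computed **over
genotype means**, so SD and CV describe inter-genotype variation rather
than measurement noise, and use the sample (n−1) SD. Computation is at
full precision; rounding to two decimals happens only at the reporting
layer. Aggregation keys missing after replicate averaging abort the run
by default because the TOPSIS decision matrix must be complete; a
`drop_incomplete` switch removes the offending genotype from every
stage instead.

## Tolerance coefficients

The stress-tolerance coefficient of genotype *i* for trait *j* is the
ratio of its stress replicate mean to its control replicate mean,
computed genotype-wise (never from cohort grand means — the evaluation
needs a per-genotype matrix). Coefficients are not capped or rescaled;
proline exceeds 1 by design, and normalisation is deferred to the
TOPSIS stage, which absorbs scale.

## Entropy-weight TOPSIS

The entropy stage uses min–max normalisation (cost criteria reversed),
the distance stage uses vector (L2) normalisation — the standard
pairing; both are stated here so results are reproducible bit for bit.
Zero cells after min–max use the exact limit 0·ln 0 = 0 rather than an
epsilon shift. A constant criterion has entropy 1 and weight 0 (with a
warning); if all criteria are constant the weights are undefined and
the run fails. All nine criterion directions default to `benefit`
(a higher stress/control ratio read as better tolerance), overridable
per trait: whether proline's accumulation should count for or against
a genotype is genuinely ambiguous — its total effect on biomass is
negative — so the direction is configuration, not code. CI ties get
competition ranks (ties share the minimum rank). If an alternative is
identical to every other (D⁺ + D⁻ = 0) its CI is defined as 0.5 with a
warning.

## Tolerance levels

CI values are clustered agglomeratively on Euclidean distance in one
dimension and cut at k = 4 (the number of levels is asserted by the
screening design, not chosen by an index); clusters are labelled I–IV
by descending mean CI, ties broken by maximum CI. **Linkage matters**:
on the packaged reference CI values for the 48 accessions, average
linkage (UPGMA) yields the four-level partition with sizes
(1, 27, 11, 9) — a single extremely tolerant accession at CI 0.806 and
nine highly sensitive ones — while Ward gives (11, 17, 10, 10) and
complete (23, 10, 6, 9). Average linkage is therefore the default, and
`ward`, `complete` and `single` are exposed as flags so the sensitivity
is documented rather than hidden. For distinct CI values the 1-D
partition is contiguous: level CI ranges do not overlap (asserted in
tests).

## Associations

Pearson correlations are computed across genotypes on replicate-mean
trait values, pooled over both treatments by default (one row per
genotype × treatment) with a per-treatment mode; pooling is what
surfaces the strong trait–SPAD couplings the stress contrast induces.
p-values use the exact t-transform of r. Mantel tests operate on
genotype distance matrices built as Euclidean distances on z-scored
trait values (a single trait reduces to |Δz|); z-scoring makes traits
with different units comparable. The Mantel statistic is the Pearson
correlation of upper-triangle entries; the null permutes rows and
columns of one matrix simultaneously; the test is one-sided (greater),
with p = (1 + #{r_perm ≥ r_obs})/(B + 1), floor 1/(B+1), B = 9999 by
default, fully seeded. An exact mode enumerates all n! permutations
for small n. The default screen tests each single trait against the
fresh-weight and net-photosynthesis matrices — the two hubs of the
trait network; whether composites should be used instead is not
determinable from the screen design, so single traits are the
documented default. Strength classes: weak r < 0.2 ≤ moderate
< 0.4 ≤ strong.

## Permutation importance

The ensemble members are standard CART regression trees
(`DecisionTreeRegressor`); the bootstrap resampling, out-of-bag
bookkeeping, %IncMSE scoring and the significance wrapper are
implemented in-package so every draw is seeded. Defaults: 500 trees,
mtry = ⌈p/3⌉ candidate features per split, OOB evaluation. For each
tree, each predictor is permuted among that tree's OOB samples and the
percent increase in OOB MSE recorded; the importance is the mean over
trees. Significance refits the whole ensemble on n_null response
permutations (p-floor 1/(n_null+1); n_null ≥ 19 required to resolve
0.05; star cutoffs are inclusive because permutation p-values are
discrete). Whether the forest should be fit on tolerance coefficients,
pooled means or stress-only means is a free modelling choice; pooled
genotype × treatment means are the default and the mode is an argument.

## Piecewise SEM

One OLS regression per endogenous node on its parents, all variables
z-scored, so coefficients are standardised betas and a single-parent
beta equals the Pearson r of the pair. Model fit follows the
d-separation logic: the basis set contains one claim per non-adjacent
node pair, conditioned on the union of the pair's parents, excluding
pairs of exogenous nodes; each claim is tested by the t-test on the
partial coefficient of the claimed-independent variable, and Fisher's
C = −2 Σ ln p is referred to χ²(2k). Effects on the terminal response
are decomposed by exact path enumeration (the DAG is small): direct =
the edge coefficient, indirect = Σ over length-≥2 paths of the product
of edge coefficients, total = direct + indirect.

The default DAG routes the exogenous block {LI, G, LI×G} into the five
trait nodes {FPC, PH, LT, SPAD, SD}; FPC (the stress-response marker)
feeds SPAD, SD, PH and LT; SPAD feeds PH, LT and SD; SD feeds PH; and
AFW is predicted directly by the five traits plus LI and G. This
mediation structure — pigment status and stem development shaping the
other morphological traits, proline upstream of all of them — leaves
exactly three independence claims (PH⊥LT, LT⊥SD, LI×G⊥AFW), i.e. 6
degrees of freedom for Fisher's C. The DAG is data, not code: any edge
list can be supplied as plain text (`parent -> child`).

Exogenous coding is the minimal one that makes the block estimable: LI
is the standardised stress indicator, G a standardised genotype-level
score (the generator's latent tolerance scalar in synthetic data; a
user-supplied score, by default the TOPSIS CI, on real data), LI×G the
re-standardised product. With CI as the G proxy the exogenous block is
partially endogenous to the traits, so path coefficients should then
be read as descriptive, not causal.

## Synthetic cohort generator

The generator emulates the screen the pipeline targets: default 48
genotypes × 2 light levels × 3 replicates. Per genotype it draws

* a latent **vigor** factor f ~ N(0,1) with per-trait loadings
  (0.60–0.75 for the growth/photosynthesis block, −0.55 for proline),
  giving the observed positive trait block and its negative proline
  coupling while guaranteeing a positive-semidefinite correlation
  matrix by construction (Σ = ℓℓᵀ + diag(1 − ℓ²)); a full custom
  correlation matrix can be supplied and is validated for PSD;
* a latent **tolerance** scalar τ ~ N(0, 0.12) on the log-multiplier
  scale: stress mean = control mean × f_trait × exp(±τ), positive sign
  for declining traits, negative for proline — this plants the
  genotype tolerance gradient the evaluation must recover;
* replicate values = genotype-treatment mean + N(0, 10% of the mean),
  clipped at zero with clip events counted (< 1% under defaults).

Control grand means, inter-genotype SDs and stress factors are
calibrated to the published screen's descriptive statistics (e.g. net
photosynthetic rate 6.98 → 4.13 µmol·m⁻²·s⁻¹, a 40.8% decline; proline
factor ≈ 1.35; dry weight ≈ 0.86). Strictly positive traits with CVs
above ~33% (proline, fresh and dry weight, Rubisco, net photosynthetic
rate) are generated log-normally so genotype means cannot go
non-positive; the rest are natural-scale normal. The replicate residual
SD (10% of the mean) is a free choice — replicate-level variance is not
recoverable from published summaries. Seeding uses one master seed with
per-genotype spawned sub-streams, so genotype G01 receives identical
draws regardless of cohort size.

What the generator does **not** emulate: treatment × trait interaction
shapes beyond a multiplicative factor, non-Gaussian replicate error,
spatial/chamber effects, and any genetic relatedness structure among
accessions. Passing tests on synthetic cohorts therefore validate the
estimators' correctness and calibration, not field realism.

## Problem sizes and numerical choices

Property tests run the cohort at its default size (48) with larger
cohorts (200–500 genotypes) only for convergence checks; the SEM
type-I calibration uses 500 replicates of n = 200 drawn from the
model-implied covariance; Mantel calibration uses 200 seeds at B = 999.
Permutation counts in example runs (B = 999, n_null = 99) are chosen so
the whole suite and the examples complete in a couple of minutes on a
single core; production runs should raise them (B = 9999 is the library
default for Mantel). Degenerate inputs have defined behaviour
throughout: constant criteria (weight 0), identical alternatives
(CI 0.5 + warning), constant distance matrices (error), zero control
means (error naming genotype and trait), claim p = 0 (error naming the
claim).
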