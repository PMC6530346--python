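# Methods

## Setting

A two-channel 2D-DiGE experiment quantifies, per gel, an individually
labeled sample and an internal pooled standard (IPS) — one pool of all
study samples, labeled in a single batch and co-separated on every
gel. Spot volumes are integrated fluorescence; one protein can occupy
several spots. In tissue-surface material, high-abundance plasma
proteins contribute a large and *sample-dependent* share of total
volume, so any normalization that scales by whole-column totals ties
every cellular spot's relative abundance to the sample's plasma
content. The pipeline addresses this by restricting all scaling
statistics to cellular-type spots.

## Zero handling

Exact zeros come from dye/scanner detection limits and rounding, not
from missing spots (spot detection runs on a fused image, so the
matrix is complete). Before log transformation, zeros in the sample
channel are replaced by the smallest positive value of the whole
sample channel; zeros in the IPS channel by the smallest positive IPS
value of the same spot (the IPS is one pool, so a spot's standard
level is a property of the spot). "Smallest observed" is read as
smallest *positive* — the literal minimum of a matrix containing
zeros is zero and would replace nothing. The replacement is
idempotent, never decreases a value, and never touches a positive
value. A spot whose IPS row is entirely zero has no defined
replacement and is a hard error. Zero replacement runs before
library-size computation so that libraries are finite on the log
scale; the alternative ordering is not meaningfully different because
replaced values are at the detection floor and contribute negligibly
to column totals.

## Class-restricted TMM normalization

Per gel×channel column *k*:

* **library size** `N_k` = sum of volumes over cellular spots only;
* **TMM factor** `f_k` computed against a reference column over
  cellular spots, exactly as in the published trimmed-mean-of-M-values
  algorithm: `M_s = log2((y_sk/N_k)/(y_sr/N_r))`,
  `A_s = ½(log2(y_sk/N_k) + log2(y_sr/N_r))`, rank-based double
  trimming (30% per tail of M, 5% per tail of A), and a
  precision-weighted mean of the surviving M with weights
  `1/v_s`, `v_s = (N_k−y_sk)/(N_k y_sk) + (N_r−y_sr)/(N_r y_sr)`.
  The reference is the column whose 75th percentile of `y/N` is
  closest to the mean of those percentiles, lowest index on ties.
  Factors are rescaled to geometric mean 1 per channel. The
  implementation agrees with edgeR's `calcNormFactors(method="TMM")`
  on the cellular submatrix to 1e-12 (cross-checked in the test
  suite);
* **normalized value** `log2(y_sk/(N_k f_k) · 10⁶ + prior)` with
  `prior = 0.5` on the per-million scale, keeping the transform finite
  and stabilizing near-floor values. The 10⁶ multiplier is nominal
  (volumes are continuous), retained for familiarity of scale.

The sample and IPS channels are normalized independently; the IPS has
fixed composition, so its factors sit near 1. Unidentified spots are
excluded from library sizes and trimming (their class is unknown and
they are on average of very low abundance) but are normalized and
modeled like all others.

Two consequences worth knowing:

* **plasma invariance is exact**: rescaling plasma-spot volumes in any
  column changes no cellular spot's normalized value, bit for bit,
  because no scaling statistic touches non-cellular spots;
* **pure column rescaling is removed only approximately**: the library
  size absorbs a scalar factor exactly, but the precision weights are
  scale-dependent, so the weighted TMM factor moves slightly (≈0.06
  log2 for a 37.5× rescaling of a 400-spot column, versus the 5.23
  log2 that normalization removes). Unweighted TMM would be exactly
  invariant; the weighted form is kept because it is the published
  default. Likewise, strongly one-sided differential abundance
  (changes all in one direction in ≳10% of cellular spots) displaces
  the symmetric trim window and biases factors — the standard
  trimmed-mean caveat. Balanced up/down changes do not.

## Per-spot mixed model

For spot *s* (models are fit independently per spot):

    y_{g,c} = α_{grp(g)} + δ·1[c=sample] + Σ_e β_e x_e(g) 1[c=sample] + b_g + ε_{g,c}

with gel random intercept `b_g ~ N(0, σ²_gel)` and channel noise
`ε ~ N(0, σ²_resid)`. The coefficients are `fluid_SCB` (active on the
sample channel of SCB and SCB+AG gels), `fluid_DCB` (DCB, DCB+AG),
and the incremental additive effects `additive_SCB_AG`,
`additive_DCB_AG` (active in the respective +AG group only);
`2^β` is the fold-change. The channel-shared group main effects
`α_grp` absorb the entire between-gel projection of the treatment
covariates, so the β's are identified purely from within-gel
sample−IPS differences.

Because every gel contributes exactly two observations, the REML
problem is balanced and splits into orthogonal strata, giving a closed
form that the implementation uses directly (vectorized across spots):

* within-gel: OLS of `d_g = y_{g,sample} − y_{g,ips}` on
  `[1 | treatment design]` yields the β's and their standard errors —
  *exactly* the REML values, for any variance components (verified
  against a generic REML fitter to 1e-8);
* between-gel: the residual variance of per-gel means around group
  means estimates `σ²_gel + σ²_resid/2`, giving the variance
  components (truncated at zero at the boundary) and shrunken (BLUP)
  gel intercepts.

Wald t statistics use the within-stratum residual degrees of freedom
(n_gels − 5 = 54 in the reference design), the df under which the
difference-OLS equivalence makes the t distribution exact; with 118
observations per spot, fancier df corrections change nothing
noticeable. A config switch replaces Wald tests with post-hoc
two-sample t-tests of the per-gel differences between the two groups
each coefficient contrasts; the estimates are identical group-mean
contrasts either way. Spots with degenerate (zero) residual variance
— in practice spots flattened to constants by detection-limit
censoring — are flagged and excluded from significance counts.

BH q-values are computed per coefficient across all (converged) spots;
significance counting reports spot counts, unique-accession counts
(spots without accession never contribute) and pairwise coefficient
overlaps at p<0.05, p<0.01 and q<0.05, plus the percent reduction
from p<0.05 to p<0.01.

For visualization, fitted BLUP gel intercepts are subtracted from the
normalized values; this removes shared between-gel level differences
and cannot change any coefficient estimate (contrasts are
within-gel).

## Standard-workflow comparator

The classic processing chain — scale each column by its total over
*all* spots, log2, subtract IPS from sample per gel, two-sample
t-tests of treated vs reference differences (SCB vs control, DCB vs
control, SCB+AG vs SCB, DCB+AG vs DCB) — is implemented with an
identical output schema. Under group-shifted plasma contamination the
total-sum scaling pushes a spurious common shift into every cellular
spot (inflating fluid-effect counts) while the per-sample
contamination variability it fails to remove costs power for the
subtle additive effects; the simulation comparison reproduces both
directions of this contrast.

## Enrichment

Over-representation per gene set: one-tailed Fisher exact test
(upper-tail hypergeometric) of the significant molecules against a
background of the unique identified proteins in the experiment —
over-representation among *detected* proteins is the question being
asked; the background is configurable. Sets are intersected with the
background; the enrichment ratio is overlap / |set ∩ background|; BH
runs across sets. The activation z-score is
`(n_consistent − n_inconsistent)/√n_annotated` over overlap genes
that carry an expected direction, undefined (reported blank) when
none does; it is antisymmetric under flipping all predictions and
bounded by `√n_annotated`. Spot-level estimates are averaged per gene
before taking the observed sign.

## Synthetic experiments

The generator emulates the reference study's structure: 744 spots on
59 gels in groups control/SCB/SCB+AG/DCB/DCB+AG = 6/14/13/15/11.
Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| spot classes | 30% plasma, 32% unidentified, rest cellular | unidentified = 1 − 505/744 identified; plasma share qualitative |
| baseline log2 volume | cellular N(10, 1.8), plasma N(11, 1.2), unidentified N(7, 1.5) | plasma high-abundance (≈½ of total volume at 30% of spots), unidentified dim |
| gel intercept σ_gel | 0.5 log2 | between-gel technical spread |
| channel noise σ_eps | 0.25 log2 | within-gel replicate noise |
| contamination | logit-normal, mean 0.15 (control) / 0.35 (treated), logit SD 0.35; IPS fixed at 0.30 | plasma fraction covaries with treatment; the pool is constant |
| fluid effects | 200 cellular spots per fluid, log2 magnitude U(0.5, 1.5), random sign | strong, balanced-direction changes |
| additive effects | 60-spot subset of the fluid-affected, magnitude U(0.2, 0.5) | subtle incremental effects |
| detection limit | 16 volume units | produces ≈1% exact zeros |
| accessions | ≈0.44 proteins per identified spot | 222 unique IDs / 505 identified spots |

Contamination multiplies plasma-spot volumes by the sample's
contamination odds relative to the pool's; cellular generating
parameters never depend on it — this is precisely the confound the
normalization must remove. Baselines are floored slightly above the
detection limit because an exported spot must be visible on the fused
image; zeros still arise from per-channel noise dipping below the
limit. The IPS is generated as a property of the gel (shared
intercept, fixed composition), consistent with single-batch labeling.

Not emulated: gel warping and spot co-migration, dye bias between the
two fluorophores, spot-shape/saturation effects, and any real
correlation structure among proteins. Passing tests therefore
demonstrate the statistical machinery under the stated generative
assumptions, not robustness to image-analysis artifacts.

Problem sizes used by the test suite and acceptance script — chosen
to make every check a from-scratch simulation: 20-seed null and
workflow-contrast batches at full size (744×59), an 8-seed recovery
batch (200 affected-spot replicates), 500×6 matrices for TMM oracle
checks, and a 120-spot dataset for the per-spot generic-REML
cross-check.

## Error-control behavior worth knowing

* Under the global null the per-spot p-values are uniform (pooled
  p<0.05 fraction ≈ 0.054 over 59,520 tests). For any one coefficient
  family, the probability that BH at q<0.05 makes *at least one*
  rejection over 744 independent null spots is exactly α = 0.05
  (Simes identity); across four families per run, roughly one null
  run in five shows some discovery. This is the designed behavior of
  BH — FDR, not family-wise error, is controlled.
* Per-sample contamination makes all plasma spots of a gel share one
  latent draw. Under a null with contamination variation, an unlucky
  group-level draw can shift the whole plasma block coherently and
  produce a correlated burst of discoveries in one run; this is a
  genuine property of block-dependent data, not an implementation
  artifact, and it is why the fluid-effect counts on contaminated
  data include plasma spots that truly differ between groups.

## Limitations

* No empirical-Bayes variance moderation; each spot's variance is
  estimated from its own 59 differences. With this many observations
  moderation gains little, but very small designs would benefit.
* The activation z-score ignores correlation among genes and weights
  all annotated genes equally.
* Enrichment p-values depend strongly on the chosen background;
  results against other backgrounds (e.g., whole-genome) are not
  comparable.
* The standard-workflow comparator implements one common variant of
  classic DiGE processing; other houses differ in detail.
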