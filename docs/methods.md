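# Methods

## Model and procedure

The package operates on two GWAS summary-statistic tables joined by SNP id.
All statistics are two-sided: `|z| = Phi^-1(1 - p/2)`, with the sign taken
from the direction of effect of the A1 allele when available.  The join is
by SNP id only; disagreeing alleles between the two tables are logged as a
warning, not harmonized (strand flipping and allele matching are out of
scope).  SNPs present in only one table are dropped and counted.

### Genomic control

The inflation factor is estimated as `lambda_GC = median(z^2) / m` with
`m = 0.4549364...` the median of the chi-square distribution with one
degree of freedom, computed on intergenic SNPs (5'UTR/exon/intron/3'UTR
annotations define "genic"; everything else is intergenic).  Intergenic
SNPs are depleted of true associations, so their median is a robust null
anchor that avoids the over-correction a polygenic signal causes in
all-SNP genomic control.  Correction divides the squared statistic by
lambda, i.e. `z <- z / sqrt(lambda)`, and recomputes p from the corrected
z.  Dividing z^2 rather than z was chosen because lambda is defined on the
z^2 scale; it is the standard genomic-control convention and makes the
correction idempotent (re-estimating lambda on corrected statistics returns
1).  The alternative reading ("divide z by lambda") is not implemented.
No lower bound of 1 is imposed: deflation is corrected symmetrically.
If fewer than `min_n` (default 100) intergenic SNPs are annotated, the
estimate falls back to all SNPs with a warning.

### Conditional FDR

For p-value threshold `p` and a SNP subset with empirical cdf
`q = N_p / N` (ties counted inclusively), the conservative Empirical Bayes
FDR estimate is `min(p/q, 1)`; the null proportion is fixed at 1, which
biases the estimate upward, and `1 - p/q` is the corresponding downward-
biased TDR.  Conditioning subsets contain the SNPs whose secondary p-value
satisfies `-log10(p2) >= t` — cumulative, inclusive at the threshold, and
nested across thresholds; cumulative subsets vary much more smoothly in `t`
than disjoint strata.

Per-SNP assignment goes through a two-dimensional look-up table:

- Grid: `-log10 p` from 0 to 10 in steps of 0.1 on both axes (defaults;
  configurable).  The grid is finer than the four diagnostic Q-Q
  thresholds but coarse enough for stable cells.
- Cell value: `min(p1/q, 1)` with `q` the conditional subset's empirical
  cdf at `p1`.  Cells where `p1` falls below the subset's smallest p-value
  (`q = 0`) are set to 1 and flagged — the conservative choice.
- Conditioning columns whose subset has fewer than `min_subset_size`
  (default 100) SNPs inherit the nearest looser populated column and are
  flagged; extreme thresholds otherwise produce wildly variable cells.
- Queries interpolate bilinearly in `(-log10 p1, -log10 p2)` on
  `log10(FDR)` — FDR spans orders of magnitude, and log-space interpolation
  prevents large cells from dominating.  Outside the grid, queries clamp
  to the boundary.  Node queries return the stored value bit-identically
  (query coordinates within 1e-9 of a node are snapped, since
  `-log10(10^-g)` can miss `g` by a few ulp).
- No monotonization along `p1` is applied by default; the estimate is used
  as computed.

The conjunction FDR is the maximum of the two directional conditional
FDRs, a conservative estimate of the posterior probability that the SNP is
null for at least one trait.

### What "conservative" does and does not guarantee

The cell estimate `p/q` is upward-biased for the FDR of its own region
`{P1 <= p1, P2 <= p2}` (null proportion set to 1, empirical cdf in place of
F).  Per-SNP calls, however, evaluate each SNP at its *own* (p1, p2) — on
the boundary of its region, where the p2-stratum is less enriched than the
region average (the region also contains all smaller p2).  On ground-truth
simulations the realized false discovery proportion among
`condFDR <= 0.05` calls therefore runs above the nominal level —
roughly 0.08–0.11 across the scenarios we simulate, partly offset by the
pi0 = 1 slack — while remaining far below the FDR of equally-sized
unconditional call sets.  The conjunction call set, requiring both
directions, is markedly more conservative in practice.  Tests bound the
realized proportion by nominal + 3 binomial standard errors at desk-scale
call counts; users should read per-SNP conditional FDR values as
calibrated rankings with approximately (not strictly) controlled error.

### Loci

Significant SNPs (FDR < 0.05 by default) are ranked by ascending FDR, ties
broken by smaller nominal p then (chromosome, position) — the ranking rule
needs a deterministic tie-break and the source procedure does not state
one.  Greedy pruning keeps a SNP iff its r^2 with every higher-ranked kept
SNP is at or below 0.2; absent LD pairs count as r^2 = 0.  Retained SNPs
are grouped into loci by single-linkage over r^2 > threshold among all
significant SNPs (so a "complex" locus lists several retained SNPs under
one index), and loci are numbered in genomic order.  Single-linkage is a
declared choice; the exact grouping rule behind published complex loci is
not specified, and locus counts are sensitive to the LD reference used.

### Mixture models

Univariate two-groups model: `f(z) = pi0 N(0, s0) + (1-pi0) N(0, s0+s1)`.
Bivariate four-groups model: components null/null, non-null trait 1 only,
non-null trait 2 only, non-null both, with mixing proportions pi0..pi3.
The shared null sampling covariance is diagonal `diag(s01, s02)`;
components 1 and 2 add effect variance only to their own coordinate; the
pleiotropic component adds a free symmetric PSD 2x2 effect covariance, so
cross-trait effect correlation lives only there.  Parameterizing
component 3's effect covariance as free (rather than tying its diagonal to
the single-trait effect variances) keeps every EM M-step closed-form.

Both models are fitted by EM on the exact latent-effect formulation
`z = u + e` (`e` null noise, `u` the effect, zero in null components), which
guarantees a monotone observed-data log-likelihood — asserted in tests.
Fitting uses magnitudes mirrored to +/- (the model is symmetric; sign
information is ignored), 5 random restarts by default, convergence at
relative log-likelihood change < 1e-8 or 10^4 iterations.  MCMC posterior
inference is out of scope; EM point estimates suffice here.  Degenerate
fits are flagged (`boundary=True`), not raised: a vanishing component or
effect variance, or a fit whose likelihood improvement over a single
zero-mean Gaussian is below a chi-square-scale margin (2*dLL < 6
univariate, < 12 bivariate) — the latter catches null data, where the
two-component likelihood surface is a flat ridge and interior parameter
values are meaningless.

Local fdr is `pi0 f0(z) / f(z)`, the posterior probability of being null
given z (the term is sometimes loosely described as the non-null posterior;
the formula is the null posterior and that is what is implemented).  The
conditional local fdr from the four-groups fit is
`(pi0 f0 + pi2 f2) / f` at `(z1, z2)`.  Significance cut-points (smallest
|z| with local fdr <= level) are found by bisection to 1e-6, returning
infinity with a warning when the level is unattainable.  Power curves
integrate the trait's non-null density over the region where the relevant
local fdr is at or below each level, on a fixed grid over [-15, 15]
(step 0.01 univariate, 0.05 bivariate); the univariate mixture density
normalizes to 1 within 1e-6 on that grid.  Scaling effective sample size
by `c` multiplies the effect variance component by `c` (non-centrality
grows linearly with n) and leaves the null variance unchanged.

## Simulator

`simulate_pair` draws each SNP's component from pi, then its z-scores from
the component's bivariate Gaussian; p-values are two-sided, floored at
1e-300.  Defaults define the reference scenario: 100k SNPs,
pi = (0.97, 0.009, 0.009, 0.012), unit null variances, effect variance 2.0
per trait, rho3 = 0.  The effect variance was chosen so that roughly 1 in
10^4 SNPs passes local fdr <= 0.05 unconditionally (computed analytically
from the mixture), matching a highly polygenic regime in which almost all
signal hides below significance thresholds; pleiotropy is carried by
shared non-nullness alone (rho3 = 0), which already produces conditional
enrichment.  Optional features: per-trait inflation (z scaled by
sqrt(lambda)), genic/intergenic labels (independent Bernoulli, fraction
0.5), and LD blocks — block-mates receive the lead SNP's z scaled by
sqrt(r2) plus sqrt(1-r2) noise, and a matching pairwise r^2 table is
generated.  Deterministic given the seed.

What the simulator does **not** emulate: realistic human LD maps (blocks
are uniform and disjoint), allele-frequency-dependent power, population
stratification beyond a scalar inflation factor, case/control ascertainment
and liability-scale effects, or between-cohort heterogeneity.  Passing
tests demonstrate the estimators behave as designed under the stated
generative model, not that real GWAS pairs satisfy that model.

## Numerical and interface choices

- p-values of 0 (or underflow) clip to 1e-300, keeping `-log10 p` finite
  without materially affecting FDR estimates; p > 1 clips to 1.
- SNP positions are 1-based; BED intervals 0-based half-open; a SNP at
  position x is genic iff x-1 lies in a genic interval.
- Duplicate SNP ids within a table keep the first occurrence (logged);
  duplicate LD pairs keep the maximum r^2; self-pairs are ignored.
- `p = 1` maps to `z = 0` exactly; z/p round-trip is accurate to 1e-10
  relative down to p = 1e-300.
- Unknown effect direction: z is carried as a magnitude; conjunction
  reporting then omits the sign rather than fabricating one.

## Problem sizes

The test suite exercises the estimators at 50k–200k SNPs: conservativeness
on three pooled 100k-SNP replicates, two-groups recovery at 100k,
four-groups recovery at 200k, oracle equivalence of pruning on 1000 random
instances of up to 20 SNPs.  These sizes give stable Monte-Carlo behavior
for every property tested while keeping a full run under a few minutes;
the estimators themselves scale linearly in SNP count and have been run at
4x these sizes in development.

## Known limitations

- Per-SNP conditional FDR calls control error only approximately (see
  "conservative" section); strict FDR control would require monotone
  region-based rejection, which the assignment procedure does not do.
- The two-groups effect variance is weakly identified when non-null SNPs
  are few: pi0 and sigma1^2 trade off along a likelihood ridge, so
  sigma1^2 scatters by ~10% (sd) across replicates at 1e3 non-null SNPs.
- No allele harmonization, liftover, or genotype-level computation; LD
  must be supplied (or simulated).
- pi0 is fixed at 1 in all conditional FDR estimates; no pi0 estimation
  option is provided.
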