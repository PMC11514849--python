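# Methods

`mgomics` implements a magnesium-centric multi-omics association screen for
paired tumor cohorts: isobaric-label (TMT) data cleaning with
internal-standard bridging, Spearman screens of protein and phosphosite
levels against tissue Mg content, Mg-group somatic-mutation association,
survival analysis with a maximally selected cutpoint, and local enrichment
statistics. A synthetic cohort generator with known planted effects makes
every stage testable without patient data. This note records the models,
the defaults that matter, and the design choices that were genuinely open.

## The cleaning model

Each TMT batch quantifies up to `plex_size` channels, one of which is a
pooled internal standard (IS) common to all batches. The pipeline assumes:

1. a per-channel multiplicative loading factor (pipetting/labeling depth),
   removed by scaling every channel so its total observed intensity equals
   the batch mean (`scale_total_intensity`; sums run over nonzero values
   only, since a zero intensity is a non-detection, not a measurement);
2. a per-batch multiplicative scale (instrument drift between runs),
   removed by dividing each sample channel row-wise by the IS channel
   (`bridge_to_is`), giving sample-to-standard (S/S) ratios comparable
   across batches. A row with IS = 0 is unquantifiable in that batch and
   becomes missing for all of its samples;
3. log-normal residual variation, addressed by `log2` transform and
   z-scoring.

Consequence (tested as an invariance): multiplying every intensity of one
batch by any positive constant leaves the final matrix unchanged — the
constant cancels in the S/S ratio.

Zeros are treated as missing from the raw stage onward, including in the
scaling sums. The z-score order (columns i.e. samples first, then rows
i.e. features) is a convention choice; samples-first removes residual
loading before features are standardized, and the order is a config switch
(`zscore_order`) because the opposite convention is equally defensible.
Feature filters follow the strict published inequalities: proteins need
>= 2 unique peptides, phosphosites need localization probability
strictly > 0.75, and features missing in strictly more than 50% of
samples are dropped (a feature missing in exactly half is kept).

Differential abundance uses the two-sided Wilcoxon rank-sum test — exact
when the smaller group has <= 10 untied observations, tie-corrected normal
approximation otherwise — with the median log2 fold change as effect size
(per-pair differences when paired). The cell-line screening rule flags a
feature when the fold ratio is > 1.2 or < 0.83 and p < 0.05.

## Association screens

`spearman_screen` correlates each feature with Mg content over
pairwise-complete samples (>= `min_pairs` = 10, a floor the source
protocol leaves unstated), with average ranks for ties. For n <= 9 the
two-sided p is exact by full permutation enumeration; otherwise the
t-approximation on rho with n − 2 df. Screens call significance at raw
p < 0.05, matching the screening convention of the field; BH q-values are
reported alongside. Because only ranks enter, every screen is invariant
under strictly monotone transforms of Mg (tested).

"Independent of protein levels" for a phosphosite is operationalized as a
partial Spearman correlation: rank-transform site, Mg, and parent protein;
residualize site- and Mg-ranks on protein ranks; correlate the residuals
(t-test, n − 3 df). A site qualifies as protein-independent when marginal
and partial p are both < alpha with concordant sign. Calibration (tested):
when the protein drives the association and the site is protein + noise,
<= 10% of sites pass; planted site-level effects of |rho| = 0.5 at n = 100
are detected with power > 0.8.

High-/Low-Mg dichotomization defaults to the survival-optimal
(maximally selected log-rank) cutpoint on the full cohort, with the
threshold then reusable on subcohorts; median and fixed-threshold modes
exist for sensitivity analysis. Low-Mg means Mg strictly below the
threshold.

## Somatic association

TMB is mutations per megabase over a configurable captured-exome size
(default 38 Mb — a standard whole-exome capture figure; the denominator is
a convention, not a measurement). A sample is excluded as an
MMR-attributable hypermutator only when BOTH conditions hold: TMB
strictly > 10/Mb AND a non-silent mutation in one of MSH2, MSH6, MLH1,
PMS2, POLD1, POLE (list configurable). Hypermutators without such
mutations are retained. Genes encoding >= 5000 amino acids are removed
from frequency analyses (strict "fewer than"); the shipped
`data/gene_lengths.tsv` covers common colorectal-cancer genes and the
giant muscle proteins, and unknown genes are retained.

The per-gene screen builds (mutated, wild-type) × (High-Mg, Low-Mg)
tables for genes with >= 3 mutated samples and applies the two-sided
Fisher exact test under the probability-mass convention (sum of all
fixed-margin tables whose point probability does not exceed the observed
table's) — the convention of mainstream implementations. SNV spectra
collapse substitutions to the six pyrimidine-referenced classes by
complementing purine references. Somatic interactions test every pair of
the top-20 most frequently mutated genes for co-occurrence (odds ratio
> 1) or mutual exclusivity (< 1) with the same Fisher test at two
significance tiers (0.01, 0.05).

Note on calibration: an exact conditional test is discrete and therefore
conservative; at 30% mutation frequency and 200 samples its attainable
type-I rate is ~4% at nominal 5%. Calibration checks use replicate counts
(~500–800) at which the binomial 99% interval around the nominal level
contains this attainable rate.

## Survival kit

All survival statistics are computed from first principles (the point of
the module is a verifiable, dependency-free reference):

- **Kaplan–Meier**: product-limit estimator; Greenwood variance; log-log
  95% bands. At a tied event/censoring time the censored subject remains
  in the risk set (the standard convention).
- **Log-rank**: k-group observed-minus-expected with the hypergeometric
  variance; chi-square with k − 1 df.
- **Maximally selected cutpoint**: every admissible split (both sides
  >= ceil(minprop × n), default minprop 0.1, the reference
  implementation's default) is scored with the standardized log-rank
  statistic. The two-group log-rank numerator equals the sum of per-subject
  log-rank (Savage) scores delta_i − Lambda(t_i) in one group, so the scan
  is a cumulative sum over the covariate order, standardized by the exact
  permutational moments of a rank-score sum (the Hothorn–Lausen linear
  statistic). The p-value of the maximum is computed by permutation of the
  covariate against the (time, event) pairs (default 2000, seeded) —
  simpler to verify than the analytic approximation; the naive single-test
  p is also reported and is demonstrably anti-conservative.
  A caveat established during validation: with complete event observation
  the argmax drifts by ±1 subject around even a perfect covariate gap
  (a single short-lived good-prognosis subject can raise the statistic),
  so gap-recovery rates above ~75% are unattainable in that regime
  regardless of hazard contrast. Under a finite follow-up window — the
  realistic clinical design, which censors most of the good-prognosis
  group and makes their scores strictly negative — the cutpoint pins the
  gap in >= 90% of replicates; the recovery suite uses that design
  (hazard means 3 vs 300 months, follow-up 20 months, n = 100).
- **Cox proportional hazards**: Newton–Raphson on the Breslow partial
  likelihood (months-resolution survival guarantees ties) with
  step-halving; convergence at max |score| < 1e-8 or relative
  log-likelihood change < 1e-10; Wald CIs from the observed information;
  diverging coefficients (monotone likelihood / perfect separation) are
  flagged non-converged. Verified against lifelines, against the
  two-sample exponential MLE, and via the score-test = log-rank identity.

## Enrichment

Preranked GSEA: running-sum weighted Kolmogorov–Smirnov statistic with hit
increments |score|^weight (weight 1 default; 0 gives the classic KS form,
invariant under monotone score transforms) normalized over the set's hits,
and miss decrements 1/(N − |set|). ES is the signed extreme deviation,
computed only at hit boundaries (the running sum is linear between hits).
The null is by gene-label permutation — the standard convention for a
preranked input, where no phenotype labels exist to permute. NES divides
ES by the mean |null ES| of the same sign; nominal p is the same-sign null
tail (floored at 1/(n_perm + 1)); FDR follows the signed-pooling
convention. Set-size bounds default to [5, 500]. Calibration (tested):
with 199 permutations the nominal p is uniform under random scores.

Over-representation is the hypergeometric upper tail of the hit/set
overlap within an explicit background, with BH q-values — a local,
auditable replacement for web-service enrichment.

## The synthetic cohort generator

The generator emulates the study conditions, not the instrument: 10-plex
batches with one IS channel; tumor + paired normal per patient scattered
across batches; Mg content uniform (or log-uniform) on 162–920 μg per g
protein; per-batch log-normal scale (sd 0.3) and per-sample loading
(sd 0.1); measurement noise (sd 0.10 ln-scale) and IS noise (sd 0.05) —
free knobs, since replicate-level noise is not quantified at this grain in
published TMT protocols.

Correlation planting uses a Gaussian copula: Mg derives from a standard
normal latent z via its CDF, and a planted feature's latent is
r·z + sqrt(1 − r²)·eps. The Spearman correlation of a bivariate normal
pair is (6/pi)·arcsin(r/2), so r = 2·sin(pi·rho_s/6) targets rho_s; r is
further inflated by sqrt(latent² + noise² + IS-noise²)/latent to
compensate rank perturbation by downstream noise, so the *realized*
post-pipeline Spearman matches `target_rho` (Monte-Carlo verified to
±0.1). An unreachable target (|r| > 1) raises rather than clipping.
One coupling to be aware of: total-intensity normalization divides every
feature by the channel total, so a strongly one-sided planted fraction
makes the totals themselves correlate with Mg and attenuates all realized
correlations. Defaults plant balanced positive and negative fractions
(as in the screens this generator emulates), under which the coupling
cancels; heavily one-sided configurations will under-realize the target.

Mutations: per-gene Bernoulli background (rate 0.05); planted genes with
group-specific frequencies relative to the true cutpoint (cohort median
Mg) — defaults 62%/26%, 51%/22%, 44%/30% for the High-/Low-Mg initiation
driver contrast; hypermutators exceeding 10/Mb (half carrying an MMR
mutation, to exercise both exclusion paths); Low-Mg SNVs enriched for
T>C (40% vs 20%). Survival is exponential with log-hazard linear in the
Mg latent (default log-HR −0.7 per SD: lower Mg, higher hazard), with
independent exponential censoring calibrated to the configured rate.

What the generator does NOT emulate — and hence what passing tests do not
show about real data: peptide-to-protein inference (proteins are
simulated directly, with a unique-peptide count column sufficient to
exercise the filter), informative missingness beyond the simple MNAR
option, batch-covariate confounding (batch assignment is random),
copy-number structure, and mutational-signature composition beyond the
six-class spectrum.

## Problem sizes in the validation suites

The test and acceptance suites size their simulations to the smallest
scale at which each property is statistically decidable: 2000 features at
n = 100 for screen calibration; 500–760 replicates for type-I rates
(binomial 99% bands); 200 replicates at n = 500 for Cox recovery
(±0.05 band); 60 replicates for cutpoint recovery; 3 cohorts of 100
patients for copula recovery. Power analyses are anchored to exact
enumeration oracles: the Fisher screen's Monte-Carlo detection rate is
compared against exhaustively computed power (0.88 at a 40/40 split with
the 62%/26% contrast; at the published 39/23 split exact power is 0.76,
which is why the recovery suite uses the larger balanced split).

## Known limitations

- The per-gene screen defaults to raw p < 0.05 (the field's screening
  convention); q-values are reported but not used for calling.
- Breslow tie handling only (Efron is a noted possible extension).
- The maximally selected cutpoint's permutation p is exchangeability-based
  and does not adjust for informative censoring.
- GSEA FDR uses the signed-pooling convention, which can exceed nominal p
  for small set collections.
- The simplified quantification dialect captures only the columns the
  pipeline uses; it is not a general search-engine output parser.
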