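# Methods

## Scope and data model

The package analyses per-cell variant call sets (VCF) plus one bulk
call set per individual. Variant calling itself, read alignment, and
annotation (deleteriousness scores, gene assignment) are upstream: calls
and annotations are inputs. Keys are biallelic
`(chrom, pos, ref, alt)` tuples; alleles are left-normalized on read
(shared suffix trimmed, then shared prefix with the position advanced,
always keeping an anchor base), so germline subtraction cannot be
defeated by representation differences in INDELs. Multi-allelic records
are split; equal-length multi-base substitutions (MNVs) are outside the
SNV/small-INDEL scope and are rejected with a distinct error rather than
decomposed.

Germline correction is exact set subtraction of bulk keys; variants
matching on position but not on alleles are retained as somatic.
Genome-wide burden extrapolates the observed count by the cell's
callable fraction (burden = count / f). Downstream count models round
extrapolated burdens to the nearest integer, since NB likelihoods need
integer support; an offset-based mode (log f as offset on raw counts)
is available as an alternative.

## Burden models

Per-cell mutation counts are overdispersed relative to Poisson, so both
group comparisons use the NB2 parameterization (variance μ + μ²/θ) on a
log link.

- **NBGLM** (unit: per-individual medians, even cell counts → mean of
  the central pair). Coefficients and θ jointly by maximum likelihood
  (statsmodels). Reported: fold change exp(β₁) of carrier versus the
  control/reference group, Wald z p-value, θ̂.
- **NBGLMM** (unit: cells) adds a Gaussian random intercept per
  individual. The marginal likelihood integrates each individual's
  intercept with adaptive Gauss–Hermite quadrature: the integrand's mode
  is found per cluster, its curvature sets the node scaling, and 15
  probabilists' Hermite nodes are used. Parameters (β₀, β₁, log θ,
  log σ) by L-BFGS-B; standard errors from the numerical Hessian, with a
  fall-back to the fixed-effects SE when σ̂ ≈ 0 makes the Hessian
  singular. Observations are sorted canonically before fitting so the
  result is invariant to input order. Against R's glmmTMB (nbinom2) the
  fixed effect, its SE, θ and σ agree to 2–4 decimals on shared data.

Wald inference uses t critical values with small-sample degrees of
freedom — n − 2 for the NBGLM, individuals − 2 for the NBGLMM (the
between-within convention familiar from lmerTest/SAS). The common
z-based intervals (glm.nb, glmmTMB defaults) measurably under-cover at
the study's design size: simulation at folds 2.3 and 1.3 with θ = 10,
intercept SD 0.3, 8 vs 7 individuals × 2–8 cells puts z-interval
coverage at ≈90% (NBGLM on 15 medians) and ≈91% (NBGLMM), against 95%
nominal; the t reference restores coverage to ≈93–95%. The NBGLM test's
type-I error at α = 0.05 is ≈0.05 under a 1000-replicate null.

Outlier flagging uses Tukey's fences, quartiles by linear interpolation
of order statistics (type 7 — a convention that must be fixed for
reproducibility; the rule itself does not prescribe one). The pipeline
excludes flagged cells before fitting by default (`--no-exclude-outliers`
to keep them); excluded cells form their own spectrum group so an
aberrant cell can be profiled separately.

## Spectra

SNVs: COSMIC 96-category convention — six pyrimidine-centred
substitution types × 16 flank pairs, flanks ordered A, C, G, T;
purine-centred calls are reverse-complemented first. The 192 raw
(context, alt) pairs map exactly 2→1 onto the 96 categories (verified
by enumeration).

INDELs: full COSMIC ID-83 scheme. 1-bp events are typed by base (C/T
after strand collapse — an A run is a T run on the opposite strand) and
homopolymer run length, counted on the 3' flank of the left-normalized
event (deletion runs include the deleted base; suffix 5 means run ≥6
for deletions and ≥5 existing bases for insertions). Longer events are
typed by length class (2, 3, 4, 5+) and tandem repeat-unit count;
non-repetitive deletions by microhomology length (longest overlap of
the deleted tract's prefix with the 3' flank or suffix with the 5'
flank), capped per length class. Because mutations live on a virtual
genome, flanking sequence travels with each record (INFO F5/F3; SNV
3-mer context in INFO CTX).

Calls lacking context are tallied per group as "skipped" and logged,
never silently dropped; spectrum row sums plus skipped counts equal the
classified input exactly.

## Signature extraction

NMF minimizes generalized KL divergence D(V ‖ WH) with the classical
multiplicative updates — the standard objective for count spectra.
Defaults: 100 restarts (50 in the pipeline), convergence when the
relative objective change over 10 iterations falls below 1e-8, cap
10,000 iterations, a 1e-12 pseudocount inside logarithms and
denominators only (never added to data). The best restart by final
objective is kept; W columns are renormalized to sum to 1 with the
scale folded into H, leaving WH unchanged. Signatures are presented in
decreasing total-exposure order.

Rank selection runs all restarts per candidate k, matches every
restart's signatures to the best run by greedy maximal-cosine
assignment (ties to the lower index — deterministic and adequate for
k ≤ 5), and defines stability(k) as the mean matched cosine. The chosen
rank is the largest k with stability ≥ 0.95 whose KL objective improves
on k−1 by ≥1% relative; the search stops once the objective flattens,
since further components only split noise. This concrete rule is one of
several defensible readings of "stability subject to error decrease";
it returns the planted rank on noiseless low-rank input and k = 1 on
rank-1 input.

NMF is identifiable only up to the geometry of the data: with shared
support between signatures and no near-pure samples, exact
factorizations other than the planted one exist. The exact-recovery
experiment therefore plants signatures on disjoint category blocks with
one pure sample each (anchor condition), where recovery is unique and
the measured matched cosine is 1.0. On realistic mixed cohorts, de novo
profiles are expected to be rotations of the generating signatures;
refitting against the known catalog (NNLS) is the calibrated estimator
there, and recovers the generator's mixture weights within ±0.01 at
cohort scale.

Bootstrap CIs for relative contributions resample each group's spectrum
as a multinomial over categories at fixed total (cells are pooled per
group, matching how the spectra are built; no cell-level scheme is
assumed) and refit exposures per replicate; the 2.5/97.5 percentiles
form the interval. The percentile endpoints are Monte-Carlo estimates:
with ≤500 replicates their noise measurably erodes coverage, so 2000
replicates are used in validation (measured coverage ≈95% for a 50/50
two-signature mixture at 10⁴ mutations). The group-profile test is
Pearson's χ² on the groups × signatures table of attributed counts
(NNLS exposures × group totals, rounded); expected cells < 1 set a
warning flag in the result.

## Clonality

A mutation's support set is the exact set of cells carrying it. The
clone tree nests support sets (size ≥2) from largest to smallest under
the root (all cells), breaking ties lexicographically; each cell's leaf
carries its private mutations. Support sets that partially overlap an
existing sibling cannot be placed on a tree; they are reported as
conflicts and their mutations attached, flagged, to the first member
cell's leaf so that every distinct mutation is placed exactly once
(edge counts sum to the distinct-mutation total). On conflict-free
input each leaf's root-path union reproduces its call set exactly.
The shared-mutation percentage uses distinct mutations across the
individual as denominator (each mutation counted once); a per-cell-mean
denominator is available as an option since published percentages do
not always state theirs.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes, not
raw reads: two groups of individuals; per-cell true burden NB(μ_group,
θ); a balanced clone tree of configurable depth whose edges carry
Poisson-distributed clonal mutations so that an expected fraction
(clonal_fraction) of a cell's mutations is inherited; SNV contexts
drawn from a configurable mixture of catalog signatures (ID categories
likewise); germline SNVs present in the bulk set and every cell;
observation as binomial thinning by a per-cell callable fraction drawn
uniformly from a configured range; and Poisson-distributed artifact
calls (private, uniformly contexted, never in the truth). Positions are
drawn uniformly without replacement from a virtual genome (24 × 125 Mb
contigs; a single 3 Gb contig would overflow the int32 POS field), so
germline and somatic truth sets are disjoint by construction. All
randomness flows from one integer seed through spawned substreams;
outputs are byte-identical across runs.

Defaults mirror the motivating study design: 8 carrier vs 7 control
individuals, 2–8 cells each, group mean burdens 1902 vs 1506 SNVs
(the published per-individual medians), θ = 10 (matching the reported
between-cell spread of roughly 30% of the mean), INDEL fraction 0.08
(published INDEL:SNV ratio), carrier-shifted signature mixtures over
the bundled toy catalog using the published HMEC contribution values
(0.297/0.571/0.132 vs 0.069/0.728/0.203), clonal fraction 0.05 (shared
percentages in primary cells are a few percent), and 200 germline
variants per individual — a representative subsample, since germline
handling is exact set subtraction and therefore scale-free. The
callable-fraction range (0.5–0.9) and artifact rate (10 per cell) are
placeholders for quantities the published analyses do not state.

What passing tests on synthetic data do **not** show: robustness to
amplification-error structure beyond uniform-context artifacts, to
chromosome-scale context composition (contexts are drawn from
signatures, not a reference genome), to copy-number events, or to
caller-specific biases. The bundled catalogs are synthetic toy
signatures (5 SBS-like, 3 ID-like) so that no COSMIC download is
required; real COSMIC TSVs are accepted wherever a catalog is taken.

## Validation problem sizes

The validation experiments (`scsomatic.experiments`, reused by
`scripts/acceptance.py`) use: 200 replicates for NB fold-change
coverage at the study design size; 1000 replicates for NBGLM type-I
error (n = 30 per group, μ = 1500, θ = 10); 400 runs × 2000 bootstrap
replicates for contribution-CI coverage; 8-sample exact rank-3 spectra
for NMF recovery; and a 6-individual noiseless cohort for end-to-end
identity. These sizes put the Monte-Carlo error of each reported
percentage at roughly one point or less.
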