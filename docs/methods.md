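# Methods

This note documents the models behind `honeygbs`, the defaults and why they
were chosen, and what the synthetic-data generator does and does not
emulate.

## Allele-frequency estimation

For a marker covered by REF-supporting and ALT-supporting reads, the
alternative-allele frequency is the raw ratio

    AF = 100 · ALT / (REF + ALT)   [percent],

reported when total depth DP ≥ `min_dp` and missing otherwise. The default
`min_dp = 1` treats a marker as "called" as soon as one read covers it;
stricter cutoffs are configuration options everywhere a call rate or AF is
computed. For a pool of bees (or honey), the ratio estimates the pooled
colony allele frequency; for a single diploid individual it can only take
0/50/100, which is also the encoding used for reference genotype tables.
Production variant callers apply model-based shrinkage to their AF fields;
the raw-ratio estimator is the documented, transparent choice here. Under
binomial sampling at depth DP with a symmetric per-read error rate ε, the
estimator's expectation is q = f(1−ε) + (1−f)ε (bias ε(1−2f), < 1
percentage point at the default ε) and its RMSE is 100·√(q(1−q)/DP); both
are verified empirically in the test suite.

Allele-copy accounting (resolution of the AF estimate in units of
chromosomal copies) is Σ ploidy × n_individuals over samples. Honey
matrices are refused rather than guessed: the number of workers whose DNA
ended up in a honey aliquot is unknown (plausibly thousands), so no copy
number is defined for them.

## Call-rate QC

"Called" is defined purely by depth (DP ≥ `min_dp`). Sample call rate
divides by the full panel size (not the markers present in the VCF), so a
truncated VCF lowers the rate rather than hiding markers. SNP call rate is
the dual over samples; the mean of either equals the called-cell fraction
of the matrix, an invariant the tests exercise on random matrices. Markers
strictly below the 90% threshold within a stratum (typically the honey
matrices) are flagged; the boundary case (exactly 90%) is not flagged.

## Duplicate concordance (ICC)

Two aliquots of one sample, extracted and sequenced independently, should
agree in absolute terms, not merely correlate. Concordance is therefore the
two-way, absolute-agreement, single-measurement intraclass correlation
ICC(A,1) with k = 2 raters (aliquots) and n targets (markers):

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E)),

with mean squares from the standard two-way ANOVA decomposition. The
agreement framework itself does not pin down one variant; absolute
agreement with single measures is the one that matches the reason for
rejecting plain correlation (a constant shift between aliquots leaves
Pearson's r at 1 but pushes ICC below 1), and it is what the implementation
commits to. Markers missing in either aliquot are dropped pairwise before
computing anything — listwise behavior is made explicit because honey
samples do carry missing markers. Two constant, equal vectors return
ICC = 1 by convention (logged). Markers whose AF differs between aliquots
by more than `outlier_delta` = 20 percentage points (configurable; the
choice of 20 is a round default, not an estimate) are reported as outliers.

## Classical MDS and lineage assignment

The combined query + reference matrix restricted to the 97
ancestry-informative markers is embedded by Torgerson's classical scaling:
Euclidean distances D on the percent scale (no per-marker standardization),
B = −½·J·D∘²·J with J = I − 11ᵀ/n, eigendecomposition of B, coordinates
X = V_k·Λ_k^½. Distances on percent-scale AFs and the Euclidean metric are
the documented choices; nothing in the pipeline depends on the overall
scale since classical MDS commutes with it. Missing cells are imputed with
the column (marker) mean over all stacked rows before embedding — a
deterministic rule that keeps all 97 columns; a column missing everywhere
is dropped with a warning. Reflection indeterminacy is fixed per dimension
by making the largest-magnitude coordinate positive (ties resolved toward
the last sample in row order), so coordinates are bit-reproducible across
runs. Negative eigenvalues (possible for non-Euclidean perturbations) are
truncated at zero in the variance-explained denominator; requesting more
dimensions than there are positive eigenvalues is an error.

Assignment is nearest-centroid: the centroid of each lineage's reference
samples in the first k dimensions, Euclidean distance, ties broken
lexicographically by lineage label (with a warning). The admixture flag is
raised when d(nearest)/d(second-nearest) > τ, default τ = 0.8: a sample
well inside one cloud has a small ratio, a sample between clouds
approaches 1. The value 0.8 formalizes "intermediate position or at the
border of a cluster" and is deliberately conservative; it is a flag for
inspection, not an admixture-proportion estimate (no STRUCTURE-style
likelihood model is attempted). The maternally inherited mitotype provides
an independent check: concordant when its mapped lineage (C1 → C, A → A,
M → M, O → O) equals the assigned lineage, discordant on a single mismatch
(a nuclear-introgression signal), mixed when several distinct mitotypes
were recorded for one sample (multi-colony honey), unavailable when none
was. Lineage Y is accepted as a label throughout but has no simulation
defaults.

## Trait-marker reporting

Per-group mean AFs of the 24 trait markers are reported on the 0–1 scale.
Fixation is strict by default (`tol = 0`): a marker is fixed_ref in a group
when every non-missing AF is 0 (fixed_alt at 100); the summary counts
markers fixed_ref in every group simultaneously. When duplicates are
excluded, each duplicate group is represented by the aliquot with the
highest call rate (ties: most reads, then lexicographic id).

## The synthetic-data generator

The generator replaces the sequencing runs of a real study with a model
whose truth is known. What it emulates, and the defaults:

* **Lineage differentiation** — Balding–Nichols: ancestral frequency
  p ~ Uniform(0.05, 0.95) per marker; lineage frequency ~
  Beta(p(1−F)/F, (1−p)(1−F)/F), so E = p, Var = p(1−p)F. Default F = 0.2,
  a divergence at which four lineages separate cleanly in two MDS
  dimensions, as the real ancestry panel was designed to achieve; the
  recovery tests also probe smaller F. Balding–Nichols is the minimal
  standard model for differentiated population frequencies.
* **Colony founding (haplodiploidy)** — one diploid queen (two Bernoulli
  draws per marker from her lineage frequency) mated to `n_drones` haploid
  drones; each drone derives from the paternal lineage with probability
  `alpha` (admixture), else the maternal one. Each worker inherits one
  uniformly chosen queen allele and one uniformly chosen drone's allele.
  Defaults: `n_drones = 15` (the order of a queen's typical mating number)
  and `n_workers = 500` as a computational stand-in for the thousands of
  workers contributing to honey — large enough that worker-sampling noise
  is small against sequencing noise. The colony's true AF is recomputed
  from the realized workers, never taken from the expectation.
* **Depth tiers** — per-marker total depth is negative binomial (size 2,
  mimicking the high run-to-run variability of amplicon sequencing) with
  matrix-dependent means: larvae 26,450×, worker pools 17,480×, honeycomb
  honey 5,560×, bulk honey 1,140× — the magnitudes observed per matrix in
  the assay, reflecting DNA quality from pristine larval tissue down to
  degraded processed honey.
* **Dropout** — a marker drops out with probability
  logistic(2.0 − 1.0·ln(DP+1) + 4.0·fragile + 1.5·honey). The offsets were
  chosen once so that the six default "fragile" markers fall below a 90%
  call rate only in the honey tiers while bee-DNA tiers genotype essentially
  completely, reproducing the qualitative degradation pattern of honey eDNA
  without a mechanistic DNA-damage model.
* **Sequencing error** — folded into the binomial success probability as
  q = f(1−ε) + (1−f)ε with ε = 0.005; no per-base quality modeling.
* **Duplicates and references** — duplicate aliquots are two independent
  sequencing draws from the same colony truth; reference individuals are
  two Bernoulli draws per marker from their lineage frequency, encoded
  0/50/100.

Not emulated: recombination and mutation, amplicon primer bias, unequal
DNA contribution of individual workers to honey (the equal-contribution
assumption is an idealization — in real honey the per-bee contribution is
unknown), csd-locus effects, and multi-colony bulk honey (a simulated bulk
sample still derives from one colony; only its depth tier and dropout
differ). Passing recovery tests therefore show that the estimators are
correct under the stated sampling model, not that real honey eDNA meets
that model.

## Problem sizes and numerics

The test suite runs the recovery analyses at 50 colonies per lineage
(lineage assignment), 50 duplicate pairs (concordance), and 15 + 15
colonies (admixture flagging), sizes at which the Monte-Carlo margins of
the asserted thresholds are comfortable while the whole suite stays fast.
All simulation randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical inputs and seeds give bit-identical
outputs, which the pipeline's hash manifest makes checkable end to end.
Marker matching against VCFs is exact on (chrom, pos, ref, alt); a record
with swapped ref/alt alleles is left missing with a warning, never flipped,
because a silent flip corrupts AF estimates in the worst possible way
(100 − AF). Multi-allelic records contribute only the panel alt allele's
depth; other alleles count toward neither REF nor ALT. Positions are
1-based everywhere.

## Known limitations

* The raw-ratio AF estimator ignores mapping and base-quality information
  a production caller would use.
* Nearest-centroid assignment presumes the reference clouds are roughly
  isotropic in the retained dimensions; closely related populations within
  one lineage (e.g. *A. m. ligustica* vs *A. m. carnica*, both lineage C)
  are not separable by design.
* The admixture flag is a distance heuristic, not a proportion estimate.
* ICC is computed without confidence intervals and only for 2-aliquot
  designs; groups of ≠ 2 aliquots are an error rather than a generalized
  replicate model.
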