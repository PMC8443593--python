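# Methods

## Specialization index

The index scores how unevenly a taxon is distributed over habitat
classes. For taxon *t* with densities `d_1..d_K` over K classes, the
raw score is the coefficient of variation `CV = s/m` with the sample
standard deviation (n−1 denominator; the convention is configurable in
principle but n−1 is used throughout). The reported score subtracts the
expected CV of a uniformly distributed taxon observed with Poisson
noise: if a taxon's N total reads fall into K classes with equal
intensity λ = N/K, then per-class counts have variance ≈ mean, so
CV ≈ √λ/λ = √(K/N). Subtracting √(K/N) therefore removes the
undersampling artifact that otherwise inflates the apparent
specialization of rare taxa; the correction shrinks to 0 as N grows.

Semantics deliberately exposed as options:

* **Habitat classes.** Default is one class per sample (K = number of
  samples), the literal reading of a CV "across samples". A grouped
  mode pools samples by metadata keys (e.g. zone × depth), treating
  dates as replicates within a class. Both are available because the
  two readings genuinely differ and neither is forced by the method.
* **Densities.** Mean *relative* abundance per class of the raw
  (post-filter, unrarefied) table, because CV is scale-invariant per
  taxon and closure removes depth differences between samples. N is
  always the taxon's raw total count — the bias term needs the true
  sampling effort, which rarefaction would distort. Computing on a
  rarefied table is possible by passing that table explicitly.
* **Classification.** Generalist iff SI strictly below the cutoff; the
  default cutoff is the community mean SI over taxa with defined SI
  (absent taxa are excluded, labelled NA). Ties go to specialist.

Calibration is limited by the CV estimator itself: the sample CV has a
finite-K downward bias of order CV/(4K) that the √(K/N) term does not
model. At K = 48 this residual is roughly 1–1.5 standard errors of a
1000-taxon mean — visible but small; the calibration checks run at
Poisson intensities λ = 5, 20 and 50 (N = 240, 960, 2400), spanning
rare to common taxa while staying in the regime where the Poisson
approximation is the dominant term.

## Pre-analysis filters

Singleton removal drops taxa with dataset-wide total count 1 ("occurred
once" read literally as one individual, not one occupied sample — a
taxon with many reads in a single sample is clearly real). The sample
filter drops samples with total reads strictly below 1000. Filters are
applied in that order; each is idempotent, but the composition is not
(removing samples can push a taxon's total below 2), which is why
provenance records the exact removed-id lists at every step.
Contaminant removal is accepted only as a user-supplied exclusion list
(`exclude_taxa`); no statistical contaminant inference is attempted.
Rank aggregation sums counts within phylum…genus values and can drop
"unassigned" rows; without dropping, column sums are conserved exactly.

## Rarefaction and occupancy

Rarefaction is without replacement (multivariate hypergeometric),
excluding samples below the target depth — consistent with filtering
shallow samples rather than padding them. Occupancy is the number of
retained samples with ≥1 post-rarefaction read, averaged over repeated
rarefactions (default 200 at depth 5000); a presence threshold of one
read is used because detection, not abundance, is the quantity of
interest. Per-repetition random streams are spawned from the master
seed (`numpy.random.SeedSequence.spawn`), so repetitions are
independent and reproducible regardless of execution order. The
closed-form check: one read in a 10,000-read sample survives rarefaction
to 5,000 with probability 1 − C(9999,5000)/C(10000,5000) = 1/2 exactly.
Shannon diversity uses natural log (the common ecology convention; the
base is not otherwise forced).

## Zeta diversity

`ζ_i` is computed either by exact enumeration of all C(n, i) sample
combinations (used automatically up to 100,000 combinations) or by
seeded Monte-Carlo over uniformly drawn combinations of i distinct
samples. Jaccard normalization is applied per combination
(|∩| / |∪|) and then averaged — not as a ratio of averages — keeping
values in [0, 1]; a combination with an empty union contributes 0.
Exact unnormalized ζ is non-increasing in i (set-intersection
monotonicity) and this is asserted on every exact run.

Decline fitting regresses ln ζ on ln i (power law) and ln ζ on i
(exponential) over orders 2..max with ζ > 0; zero orders are dropped
with a warning rather than pseudo-counted, which would manufacture
curvature. Both AICs are computed from the Gaussian log-likelihood on
the shared ln-ζ response scale with k = 3 (intercept, slope, error
variance), so the two families are directly comparable; this
transform-scale convention is a documented choice, and the selected
family is the AIC argmin. Temporal decay evaluates pairwise ζ₂ for
every sample pair, regresses ln ζ on ln Δt over pairs with ζ > 0 and
Δt > 0 (requiring ≥ 3 distinct positive Δt), and bootstraps pairs for a
percentile 95% CI of the slope. "Bootstraps" means Monte-Carlo
combination draws per order in decline mode and pair resampling in
decay mode; the two are independent parameters.

## Gene profiles

Hit tables are reduced to one best hit per read (max bitscore, ties
broken by higher identity, then first occurrence) *before* threshold
filtering, then filtered by query coverage strictly > 80% and percent
identity ≥ the gene family's threshold (default 50, per-family
overrides for fast-evolving or promiscuous families, e.g. CoxL 60,
PsbA 70, PsaA 80). The minimum read length (>140 bp) is applied by the
caller upstream and recorded in the config for provenance. Removal
counts per reason plus retained rows always equal the input row count.

RPKM = count / (total reads / 10⁶) / (gene length / 10³). Per-cell
copy number divides a gene's RPKM by the geometric mean RPKM of 14
universal single-copy ribosomal marker genes (the marker list is
user-supplied configuration); 100 × copy number is the percent of
community members carrying the gene. A zero marker RPKM is an error by
default — the geometric mean would collapse — with an opt-in pseudo
floor (smallest positive marker RPKM / 10) for exploratory use.
Process roll-ups sum member-gene percentages capped at 100 (a cell with
two genes of a process is still one cell); oxygenic photosynthesis
instead averages PsaA and PsbA, since both photosystems are required
and each hit set estimates the same cells. MAG gene occurrence per
order divides the raw carriage percent by the order's mean completeness
fraction (incomplete genomes undercount genes); values above 100 are
reported capped with the uncapped value alongside. Pathway presence is
strict: detected/required > 0.7. Quality tiers: high iff completeness
> 90 and contamination < 5; else medium iff > 50 and < 10; else fail.

## Synthetic data

The community generator emulates a 2-zone × 3-depth × 8-date survey
(48 samples, one per cell). Generalists share one expected density over
all six zone × depth classes; each specialist is positive on a random
1–2 of the six classes. Per sample, densities are perturbed by
log-normal noise (sd 0.3 for generalists, 0.8 for specialists —
specialists are both restricted and temporally noisier) and reads are
drawn multinomially at a uniform random depth of 5,000–50,000. Base
abundances are log-normal(0, 1). These defaults were fixed once as a
realistic mid-ground for structured sediment surveys: noise sd 0.3
corresponds to ~30% temporal CV for a stable taxon, and the read-depth
range brackets common amplicon library sizes after filtering.

The hit-table generator plants known genome content (every genome
carries the 14 ribosomal markers exactly once), draws per-gene read
counts as Poisson with mean ∝ abundance × copy number × gene length,
and emits one hit row per read with identity/coverage from truncated
normals (defaults 75 ± 8 and 92 ± 5) — enough structure to exercise
the threshold filters, with no pretence of modelling sequence
evolution.

What the generators do **not** emulate: phylogenetic correlation among
taxa, overdispersion beyond log-normal × multinomial, chimeras or
contamination, spatial autocorrelation within zones, read-level
sequence evolution, or assembly/binning artifacts. Passing tests
therefore demonstrate the statistics are implemented and calibrated
correctly under the stated model, not that the model captures every
property of field data.

## Problem sizes and numerics

Test and acceptance runs use deliberately modest sizes chosen to give
stable statistics: 1000 taxa × 48 classes for calibration, 20 seeds of
the 80-taxon default community for role recovery, 100 random ≤10-sample
instances × 1000 draws for the Monte-Carlo/exact zeta comparison, 200
replicates for model selection, 200 rarefactions for occupancy, and 12
replicate hit simulations of ~100,000 reads for copy-number recovery.
Monte-Carlo checks compare means to truth within 3 standard errors
computed from the replicates themselves. Degenerate inputs fail loudly:
zero-sum samples, all-NA SI vectors, empty pathways, out-of-range
percentages and missing markers all raise typed errors rather than
propagating NaNs.

## Known limitations

* The residual finite-K bias of the sample CV (above) means the mean
  corrected SI of truly uniform taxa sits slightly below 0 — about
  −0.001 to −0.4% of the raw CV at K = 48 — rather than exactly at 0.
* Exact zeta enumeration is limited to 100,000 combinations; beyond
  that the Monte-Carlo estimator's error decays only as draws^−1/2.
* AIC comparability across decline families holds only under the
  shared-response (ln ζ) convention; fits on the natural scale would
  need a different treatment.
* The completeness normalization for MAG gene occurrence assumes gene
  loss in incomplete bins is uniform, which overcorrects for genes in
  hard-to-assemble regions.
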