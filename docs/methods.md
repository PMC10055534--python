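# Methods

This note documents the models, defaults and numerical choices behind
`mirscreen`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the design was genuinely open.

## Small-RNA quantification

Trimming follows single-3′-adapter chemistry: one leading base is removed
(`trim_first=1`, matching the library's templated base), then the read is
cut at the leftmost qualifying alignment of the adapter
`TGGAATTCTCGGGTGCCAAGG`. An alignment at position *i* covers
`overlap = min(len(adapter), len(read)−i)` bases and qualifies when
`overlap ≥ 3` and its Hamming mismatches are at most `floor(0.1·overlap)`;
`N` never matches. Indels are not modelled — mature miRNAs are 16–28 nt
and substitution-only matching is adequate at these lengths. Inserts
shorter than 15 nt are discarded. The pure adapter stage
(`trim_first=0`) is idempotent; the leading-base removal is intentionally
not (it models a templated base, not adapter).

Assignment replaces a seed-and-extend aligner with dictionary lookup
against the mature reference (U→T-converted on load): a read counts
toward a miRNA iff it equals the mature sequence exactly or with up to
`tolerate_3p = 2` terminal 3′ bases added or removed — the dominant
isomiR mode. `tolerate_3p = 0` is a strict exact-match mode. Reads
matching k reference entries (identical paralogs) contribute 1/k to each;
the final per-miRNA counts are rounded half-up so the count matrix stays
integral. Because rounding can change column sums by ±a few counts,
conservation is enforced on read-level accounting
(`n_assigned_reads + n_unassigned = n_reads`), which is exact.

## QC, normalization and housekeeping

Wells with total annotated counts strictly below 1,000 are excluded
(a well at exactly 1,000 is retained); exclusions decided outside the
pipeline (e.g. by microscopy) carry the `external` reason and are
respected everywhere. Excluded wells never enter normalization, COV or
detection summaries.

CPM is plain total-count scaling. Fold changes are computed per
sequencing batch against the batch's DMSO vehicle wells; the default
baseline is the **geometric mean** of vehicle CPMs because it is robust
to a single outlier vehicle well and makes the per-batch mean vehicle
log₂FC exactly zero (arithmetic mean and median are selectable — the
upstream convention is stated only as "normalized to the DMSO controls").
A pseudocount of 1 CPM is added symmetrically to numerator and baseline,
bounding fold changes for undetected miRNAs; it damps signal for miRNAs
below ~a few CPM, which is a deliberate bias/variance trade. Fold
changes are never computed across batches; no model-based batch
correction (ComBat-style) is attempted — vehicle-relative scaling is the
stated remedy, and it cancels any batch-common multiplicative factor
exactly (verified to ~1e-15 at pseudocount 0).

COV (sample SD / mean, ddof = 1) is computed per miRNA per batch on CPM
over all retained wells — compounds included, since the batch is the
stated unit — with a vehicle-only mode available; zero-mean miRNAs are
recorded missing, not zero. Housekeeping selection takes the k = 10
smallest-COV miRNAs per batch (ties by mean COV, then id) and intersects
across batches; an empty intersection warns rather than errors.

## Hit ranking and class profiles

Waterfall ranking orders compounds by descending log₂FC of the chosen
miRNA within each plate; the default grouping is the pooled sequencing
batch (the unit on which a 384-barcode pool is displayed), with the
physical 96-well culture plate selectable. Ties break lexicographically
by compound id, making ranks a deterministic permutation. Vehicle and
positive-control wells are annotated but never ranked; a compound with
several wells in a group is ranked on its mean.

Hit selection orders candidates by (best plate rank, number of satisfied
secondary flags descending, specificity ascending, id). The specificity
score counts other miRNAs moved beyond |log₂FC| > 1 (a configurable
convention). Unannotated compounds are retained but satisfy no secondary
flag.

Class profiles use the median log₂FC across member compounds per miRNA.
Significance comes from a permutation null resampling size-matched
compound sets from the whole library (B = 10,000 by default; B < 100 is
refused), two-sided with the +1/(B+1) correction so p is never zero, and
Benjamini–Hochberg across miRNAs within each class (one decision family
per class). This null is an extension: the upstream convention displays
class heatmaps without a stated test. Multi-valued class labels
(`"a; b"`) are treated as multi-label. Positive-control wells are
excluded from class analyses by default. Note a discreteness floor: the
smallest attainable BH q-value is `n_mirnas/(k·(B+1))` for k hits at the
p-floor, so detecting 1–2 true hits at q < 0.05 with B = 2,000 requires
≲ 100–200 miRNAs in the tested family.

Correlation maps are Pearson (or Spearman) correlations of log₂FC
vectors across compound wells only, defaulting to the 20 most abundant
miRNAs by mean CPM. Zero-variance miRNAs get missing off-diagonals, never
0; the diagonal is exactly 1.

## Dose-response and qPCR

The "sigmoidal, 4-parameter" model is the standard 4PL,
y(x) = bottom + (top−bottom)/(1+(EC50/x)^h), fitted by trust-region least
squares on log₁₀ dose with each replicate as an individual point.
Initialization: bottom/top from the min/max dose-mean response, h = 1,
EC50 by grid search over the observed doses; bounds bottom, top > 0,
h ∈ (0.1, 10]. Standard errors come from the Gauss–Newton covariance;
the EC50 SE uses the delta method on log₁₀EC50. Non-convergence is
flagged but parameters are still reported. ECf = EC50·(f/(1−f))^(1/h);
"EC100", which strictly does not exist for a logistic, is reported as
EC99 (f = 0.99) by a declared, configurable convention.

An identifiability caveat established by the package's own spread study:
on a 1 nM–100 µM half-log grid with a ~3 nM EC50 and 10% CV noise, the
lowest dose already sits at ~32% of the dynamic range, the bottom plateau
is extrapolated, and se(EC50)/EC50 ≈ 50% — the median relative EC50 error
across noise realizations is ~40%. The fixed-seed recovery study lands
within a few percent; the spread study reports the honest variability.

ΔΔCt uses amplification efficiency 2.0 throughout: ΔCt = Ct_target −
mean(reference Cts) (the arithmetic mean of Cts equals the geometric mean
of reference expression at efficiency 2), ΔΔCt = ΔCt − mean(ΔCt of
control samples), fold = 2^−ΔΔCt; the group fold is 2^(−mean ΔΔCt), which
makes the control group's fold against itself exactly 1. Samples missing
a reference are dropped with a warning; Ct must lie in (0, 50). Per-gene
efficiencies and Ct outlier rejection are out of scope. The closed-form
error model (ΔΔCt SD = σ·√(1/n_t + 1/n_c)·√(1 + 1/n_ref) at Ct noise σ)
says 4+4 replicates with 2 references at σ = 0.2 give ~97% of fold
estimates within ±30% of truth — not ±15%, a band sometimes assumed but
inconsistent with the arithmetic.

## The synthetic-screen generator

`simulate_screen` emulates: 340 quantifiable miRNAs; 6 sequencing batches
of four 96-well culture plates pooled per run (2,304 wells); 8 DMSO
vehicle and 4 positive-control wells per batch at fixed plate positions;
log-normal baseline abundances (σ = 2, spanning sub-CPM to tens of
thousands); mean library size 55,529 reads/well with log-normal spread
(σ = 0.3); negative-binomial counts (size = 20 — the standard
overdispersed RNA-seq model; this sets a per-well log₂ noise floor of
~0.33 that dominates above a few hundred counts); multiplicative
per-(batch, miRNA) batch factors (log-normal σ = 0.2); ~5% failed wells;
planted compound effects; and a co-regulated pair sharing every effect
(the miR-132/212 locus analog), planted by default at the 0.92 abundance
quantile to match the real locus's top-decile abundance. The positive
control induces the pair 2.5-fold. Compound ids are assigned
deterministically in well order so effect tables can reference them.

Two deliberate departures from naive sampling: failed wells draw a
*realized* total uniformly below 1,000 reads (multinomial over miRNAs)
rather than an NB around a uniform mean, so the low-count QC oracle is
exact rather than boundary-fuzzy; and failed wells are drawn among
compound wells only, so every batch keeps its vehicle baseline. For
co-regulation studies the default planted-effect table
(`coregulation_effects`) moves the target in 25% of compounds with
log-uniform 2–6× folds — a bioactive library at screening concentration
acting on an activity-dependent locus.

What the generator does **not** model: sequencing errors and quality
scores, isomiRs beyond the 3′ tolerance, position/edge effects within
plates, image-based well pathology (failed wells are purely low-depth),
compound effects on total RNA content, and cross-miRNA covariance beyond
the compositional constraint and the declared co-regulated pair. Passing
tests therefore demonstrate correctness of the pipeline's arithmetic and
its statistical calibration under a realistic noise model — not
robustness to ligation bias, spatial artifacts or heavy-tailed real-data
contamination.

## Study problem sizes

The packaged studies (`mirscreen.studies`) use: 20 replicate single-batch
screens for the QC oracle; one full-size screen (σ_batch = 0.5) for
normalization identities; 200 replicate 221-compound plates for hit
recovery (the ranked plate is reduced to 221 compounds by external
exclusion, mirroring image-based QC; failed wells are disabled in studies
that measure ranking, not QC); 200 random classes × 60 miRNAs at B = 2,000
for null calibration (~12,000 p-values) and 30 replicates of a 16-member
class split over two batches for power (60 miRNAs keeps the BH q-floor at
0.015, below the 0.05 threshold — see the discreteness note above); 20
replicate screens for co-regulation; 10,000 random reads for the trimming
oracle; and 500 curves for the 4PL recovery sweep. These sizes give each
binary claim ≥ 20–200 Bernoulli trials while the full battery completes
in about a minute.
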