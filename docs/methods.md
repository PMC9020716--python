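# Methods

## Scope

`turboprox` implements the downstream statistics of a TurboID
proximity-labeling experiment and the companion FRAP quantification: it
consumes MaxQuant-style label-free quantification (LFQ) output and a
sample design, and produces filtered, imputed, tested enrichment tables
and single-exponential recovery fits. Upstream steps (spectral search,
LFQ normalization, peptide FDR control) are assumed done by MaxQuant and
are out of scope.

## Enrichment pipeline

### Filtering

Protein groups are removed when they are reverse (decoy-database) hits,
potential contaminants, identified only by a modified peptide, supported
by fewer than 2 razor+unique peptides, or quantified in fewer than 2
samples of one design group. Removals are attributed to the first failing
rule in the fixed order (reverse, contaminant, only-by-site,
min-group-values, min-razor) so report counts partition the input; the
retained set itself is order-independent because the rules are a
conjunction of per-record predicates.

The min-group-values rule is deliberately configurable
(`group_value_mode`). The phrase "fewer than two quantitative values in
one group" is ambiguous between *either* group and *the experimental*
group. The default `any_group` keeps a protein quantified in ≥2 samples
of either group: true proximity interactors are expected to be absent
from every control, and requiring values in both groups would delete
exactly the hits the experiment exists to find. `experimental_group` and
`both_groups` are available for sensitivity analyses.

The bait is never special-cased; it passes or fails filters like any
other record and typically tops its own hit list.

### Log transformation and missing values

LFQ intensities are analysed on the log2 scale. MaxQuant reports 0 for
"not quantified"; those cells become missing. Because failure to quantify
is driven by the instrument detection limit, missingness is left-censored
and missing-not-at-random: low-abundance proteins (the interesting ones)
are the ones that go missing, predominantly in controls.

Two imputation schemes are provided:

* **LOD (lowest of detection, default for presentation).** Each missing
  cell takes the minimum observed log2 value of its own sample column —
  one MS run per column, so "within a run" is a column-wise minimum. The
  minimum is computed over post-filter records (the pre-filter variant
  would only lower it by contaminant-level values). Deterministic.
* **ND (left-censored normal draws).** Missing cells are drawn
  independently from `Normal(m − 1.8·s, (0.3·s)²)`, where `m` and `s`
  are the mean and SD of **all** observed log2 values in the matrix
  (whole-dataset moments, not per-column). A single seeded
  `numpy.random.default_rng` stream per run makes outputs reproducible;
  the seed is recorded in the provenance header of every output table.

Neither scheme ever alters an observed cell, and a provenance mask
records exactly which cells were filled.

The two schemes disagree most where it matters: for a protein observed
only in experimental samples near the dataset floor, LOD fills its
controls at the column minimum (yielding a positive, sometimes large,
fold change), while ND fills them at `m − 1.8·s`, which in such datasets
lies *above* the column minima — shrinking or inverting the apparent
enrichment. The pipeline therefore exposes both routes plus a comparison
table flagging sign inversions (`compare-imputation`).

### Testing and hit calling

Per protein, the log2 fold change is the difference of group means of
log2 values (not the log of the ratio of means — the standard choice in
log-space LFQ analysis, and the one consistent with imputing in log
space). The p-value is a classical two-sided pooled-variance (Student)
two-sample t-test; Welch's form is a config switch. With 3-vs-3 designs
the pooled test is the default reading of "unpaired t-test". If both
groups have zero variance and equal means, p = 1 by convention (t = 0/0
carries no evidence); zero variance with unequal means gives p = 0.

A protein is significant iff log2 FC > 1 **and** p < 0.05, both strict.
No multiple-testing correction enters the call — this mirrors the
raw-p<0.05 definition the enrichment lists use — but a Benjamini–Hochberg
q-value column is written for information. Volcano
(−log10 p vs log2 FC) and MA (mean log2 experimental intensity vs
log2 FC) tables are pure projections of the enrichment table.

## FRAP quantification

Centrosomal signal per frame is measured from two concentric rectangles:
`(mean(inner) − mean(ring)) × area(inner)`, the ring between the boxes
estimating local cytoplasmic background. Traces are normalized by the
mean of the pre-bleach points (all of them by default; `n_pre` restricts
the window). Post-bleach points, with X = time since the first
post-bleach frame, are fitted by nonlinear least squares to

    Y = A·(1 − e^(−kX)) + B

with A the mobile fraction, B the signal remaining immediately after the
bleach, and half-time t½ = ln 2 / k. Initialization: B₀ = first
post-bleach value, A₀ = post-bleach range, k₀ from the time to reach half
the apparent plateau; up to 5 restarts with jittered initials on
non-convergence. Fits with k ≤ 0 *or* A ≤ 0 raise "no recovery detected":
a non-positive rate or mobile fraction means the signal never recovers
toward a plateau, and on monotone-declining traces the optimizer
otherwise escapes into a degenerate near-linear regime (A → −∞,
k → 0⁺). R² = 1 − SS_res/SS_tot over the fitted (post-bleach) points
only; pre-bleach points serve normalization only. Time-translation of
the post-bleach segment does not change the fit.

Out of scope: acquisition-photobleaching correction, diffusion-dominated
(non-exponential) FRAP models, z-handling beyond a single plane.

## Synthetic data

The proteome generator draws per-protein log2 abundances from
class-specific normals (log-normal intensities), adds replicate noise
(SD 0.4 log2 units), boosts interactors and the bait in experimental
samples only, and censors any value below a hard detection threshold to
"not quantified". Defaults emulate a 3-vs-3 pulldown of 205 protein
groups: 20 interactors with mean log2 abundance 21 (below the detection
limit of 22, so control values censor) boosted +4 log2 units in
experimental samples; one bait at +6; 4 carboxylase-like records at mean
31 — abundant, biotinylated regardless of bait, present in both groups,
and correctly *not* called enriched; 150 background proteins at mean 26;
30 decoys cycling through the reverse/contaminant/only-by-site/1-razor
removal modes. Hard-threshold censoring keeps every oracle exactly
invertible (a value is missing iff its pre-censoring draw fell below the
limit); a logistic-dropout option adds probabilistic censoring for
robustness testing. Carboxylase-like abundance offsets are synthetic
choices made for clear class separation, not estimates.

What the generator does **not** model: correlated replicate noise,
intensity-dependent variance, peptide-level effects, ratio compression,
or between-run normalization artifacts. Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
structure, not robustness to every real-data pathology.

FRAP traces are simulated as pre-bleach points at 1.0 and post-bleach
points following the recovery model plus Gaussian noise; image fixtures
render a trace as a unit-integral Gaussian spot on a flat background so
that region-based measurement can be checked against the known amplitude
series.

## Problem sizes and numerical choices

Test and analysis runs use desk-scale sizes chosen to make the
statistics informative: ~205-protein proteomes (20 seeds for truth-
recovery rates), 10⁴ imputed cells for distributional checks on ND
imputation, 16-trace FRAP ensembles at 1 s sampling over 30 s for
ensemble means, and 100-trace ensembles for per-trace error quantiles.
The per-trace parameter-recovery bound (median relative error of A and
t½ ≤ 5% at noise SD 0.05) is assessed at 0.5 s sampling, i.e. ~10 frames
per half-time for the 4–5 s half-times tested — the temporal resolution
fast-recovery FRAP is actually acquired at; at 1 s sampling the t½ error
quantile sits just above that bound while ensemble means remain accurate
within 5%.

Numerical conventions: strict inequalities at both significance
thresholds; `t½·k = ln 2` exactly by construction; LOD is bit-exact
(assignment of column minima, no arithmetic); ND determinism is
bit-exact under a fixed seed; enrichment results are invariant to row
and column order because samples are resolved by name.

## Known limitations

* The t-test after imputation treats imputed values as data; with LOD the
  control pseudo-values have zero variance, which deflates the pooled SD
  and can overstate significance for fully censored proteins. This is
  inherent to the published procedure being implemented, not corrected
  here.
* Hit counts from re-exported spreadsheets depend on the exact column
  mapping of the export; the `column_map` config must be set by
  inspection of the sheet headers.
* The recovery model is a single exponential; binding- or
  diffusion-dominated recoveries with multiple timescales will fit poorly
  (visible as low R²).
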