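# Methods

## Data model and scope

The package analyses two-channel microarray data in which each sample is
co-hybridized with a universal reference RNA and expression is carried as the
log2 sample/reference ratio per spot. Spots map to genes many-to-one
(duplicate spots are deliberately kept as separate rows everywhere — they are
never averaged), values may be missing, and subjects may contribute several
samples, so samples are not independent. The design is case/control at the
subject level.

## Synthetic-data generator

For gene g on sample s the generator draws

    x_gs = μ_g + Δ_g·1[group(s)=case] + b_{g,subject(s)} + o_{array(s)}(A_g) + ε_gs

with baseline μ_g ~ N(0, baseline_sd²); a fixed shift Δ_g that is zero for
null genes and ±Uniform(lo, hi) in log2 units for the differential ones;
per-gene per-subject intercepts b ~ N(0, subject_sd²) drawn independently per
gene (matching the per-gene mixed model downstream; a global per-subject
shift is not simulated); an array term o_a(A) = offset_a + amp_a·sin(2π(A−6)/10)
with offset_a ~ N(0, array_offset_sd²) and amp_a ~ U(−1,1)·dye_bias_amplitude,
evaluated at the spot's mean log intensity A_g ~ U(6, 16); and residual noise
ε ~ N(0, residual_sd²). The sinusoidal bias shape is an arbitrary smooth
choice that exercises intensity-dependent centering; no claim is made about
the bias shape of any real scanner. Duplicate spots copy a parent gene's
signal and array term but draw independent residuals. Missingness masks each
cell independently with probability `missing_rate`.

Defaults mirror the target study design: 26 case subjects contributing 35
samples (the first nine subjects carry the extra sample), 33 control
subjects with one sample each, 21,671 genes of which 383 are differential
with |log2 FC| between log2 1.5 and log2 4.812 — the bounds of the observed
fold-change range. Values the study does not state were fixed once at levels
typical for PBMC array data: subject_sd 0.3 and residual_sd 0.3 (log2 scale),
baseline_sd 0.5, array_offset_sd 0.1, dye_bias_amplitude 0.2, missing_rate
0.02, duplicate_spot_fraction 0.1 (the platform's spot/gene ratio is not
published; this is a free parameter, not a claim).

All randomness derives from one seed through fixed substream labels
(`sample_counts`, `baseline`, `de_spots`, `effects`, `intensity`, `arrays`,
`subject_effects`, `residual`, `duplicates`, `missing`, `ct`, `folds`), so
each stage is independently reproducible and identical (config, seed) pairs
give bit-identical outputs.

What the generator does **not** emulate: probe-level/image artifacts,
print-tip or spatial effects, dye-swap designs, batch structure beyond the
per-array term, correlated gene modules, or heavy-tailed noise. Passing
tests therefore demonstrate correctness of the statistical machinery under
its own assumptions, not robustness to every failure mode of real arrays.

## Preprocessing

Raw ratios are log2-transformed (nonpositive values are a hard error naming
the cell). Each array is centered by subtracting a robust lowess fit of
log-ratio on mean spot log-intensity — frac 0.3, 3 robustifying iterations,
a common choice for two-channel centering; the source analysis names the
smoother but not its parameters. Whether the covariate should be intensity
or intensity rank is not stated either; plain intensity is used and
configurable. With no intensity data (or fewer than 10 present spots) the
array is median-centered, the degenerate "center" operation. Missing values
are never imputed. The missingness filter drops spots whose missing fraction
*strictly exceeds* the threshold (default 0.5): a spot missing exactly half
its samples is retained, reading "exceeded" literally.

## Differential expression

Each spot is fit independently with `y = μ + β·1[case] + b_subject + ε` by
REML, dropping that spot's missing samples only. The marginal covariance is
block diagonal by subject, so the fit profiles everything onto the variance
ratio λ = σ²_b/σ²_e: given λ, GLS estimates, the profiled σ̂²_e and the REML
criterion reduce to sums over per-subject aggregates, and one bounded scalar
optimisation over log λ (λ ∈ [e⁻¹², e¹⁴], xatol 1e-6) completes the fit.
This keeps a 2,200-spot experiment near one second on one CPU and makes the
boundary behaviour explicit:

- λ = 0 (or every subject a singleton, where λ is unidentifiable and the
  REML criterion is flat): the model collapses to OLS with pooled variance —
  exactly the pooled two-sample t-test, flagged `two_sample_fallback`,
  df = n − 2.
- λ at the upper bound (σ²_e → 0, e.g. exact within-subject duplicates): the
  fit collapses to the two-sample t-test on subject means, df = subjects − 2.
- Otherwise: two-sided Wald t with between-within df = subjects − 2. The
  source analysis does not state a df method; between-within is the
  conservative classical choice for a subject-level contrast.

statsmodels' MixedLM is used in the test suite as an independent REML oracle
(estimates agree to ~1e-4), never as the implementation.

Fold change is reported as 2^β from the model estimate rather than from raw
group means, so a single estimand drives the tables, the selection rule and
the qPCR comparison. Multiplicity is controlled by Benjamini–Hochberg
step-up adjustment (via statsmodels); the study names only a "10% false
discovery rate" and BH is the standard step-up realization — declared here
as this package's choice, not claimed as the original tool's internal
estimator. Gene selection takes q ≤ 0.10 and optionally
max(FC, 1/FC) ≥ 1.5. Spots whose fit fails (a group all-missing, zero
variance) carry NaN statistics and are excluded from the adjustment.

The same machinery serves subgroup comparisons (surgical status,
chemotherapy, diabetes history, tumor location, stage): any two-level
covariate in the sample table can be the grouping, with the caller
restricting to the relevant samples.

## Clustering

Distance between profiles is 1 − Pearson correlation over pairwise-complete
positions, each vector centered by its own mean on those positions ("centered"
correlation, as opposed to the about-zero variant), so d ∈ [0, 2] and is
invariant to additive shifts and positive rescaling. Pairs sharing fewer
than 3 present positions, or constant on them, are hard errors rather than
silent NaNs. Complete linkage merges by maximum pairwise distance
(Lance–Williams max update), which makes heights monotone; among tied minima
the pair with the lexicographically smallest creation-order indices merges
first, so output is reproducible. Display order puts the child containing
the smallest original index on the left. By default the pipeline clusters
samples on the DE-selected spots (the published heatmap uses all
statistically significant genes); clustering genes, or using all spots, is a
flag away. Export follows Java TreeView conventions: CDT with rows/columns
in leaf order, GTR/ATR with one line per merge carrying similarity
1 − height.

## Classification

CCP weights are pooled-variance two-sample t statistics (case − control);
the printed weights of the published eight-gene model (magnitudes 4.4–5.0)
are consistent with t statistics on ~44 training samples. A Welch variant
sits behind a flag. The threshold is the midpoint of the class means of the
compound covariate — the classical construction; the original study prints
only its fitted value (38.98), which the model file format stores and
reloads verbatim. The decision rule is strict: a score exactly at the
threshold is called negative.

Gene screening (two-sample p ≤ 1e-4 and fold ≥ 1.5) is recomputed inside
every CV fold. The original description is ambiguous on this point;
in-fold selection is the unbiased reading, and the test suite demonstrates
the alternative (screening once on all samples) inflates accuracy on pure
noise. If a fold's screen selects nothing, that fold falls back to the
single smallest-p training gene so every sample still receives a prediction.
Folds are stratified by class and seeded; k = n is treated as leave-one-out
(stratification is then moot). "Repeated 1 times" is read as repeats = 1,
configurable. Missing values at training/prediction time are an error by
default, or imputed by per-gene training means behind a flag (the means
travel with the saved model). SVM and Bayesian-CCP variants are deliberately
absent — the study discarded them as non-best.

The pipeline's blinded validation splits *subjects* (not samples) into
training and hold-out, stratified by group, so no subject leaks across the
split; the hold-out fraction defaults to 0.35, matching the study's 24-of-68
hold-out.

## qPCR concordance

2^−ΔΔCt with an explicit housekeeping gene — there is no default because
the usual choice (GAPDH) is itself differentially expressed in PBMCs of the
target disease — and the universal-reference sample as default calibrator,
mirroring the bench protocol. Per gene, the cross-group ratio of median
per-sample fold changes is compared with the microarray fold change; the
gene validates iff both ratios are strictly on the same side of 1, and a
ratio of exactly 1 conservatively counts against concordance. No
amplification-efficiency correction or standard-curve quantification.

## Numerical and design notes

- REML boundary tie: when the interior optimum does not beat λ = 0 by more
  than 1e-8 on the criterion, λ = 0 wins (deterministic, and correct for the
  flat singleton case).
- lowess is evaluated at the observed points via `return_sorted=False`; the
  `xvals` path mishandles robustness weights when residuals vanish.
- The distance matrix is symmetrized and clipped to [0, 2] after the
  vectorized pairwise-complete computation to absorb float round-off.
- TSV everywhere: UTF-8, tab-separated, LF, "NA" missing token; a per-spot
  intensity column round-trips through the matrix writer.
- Problem sizes in the test suite and acceptance script (2,200 spots × 20
  replicates for error control; hundreds of spots elsewhere) are chosen so
  the whole suite runs in about half a minute while keeping Monte-Carlo
  error well inside the asserted tolerances.

## Known limitations

Real two-channel data violate several generator assumptions (correlated
genes, non-Gaussian tails, spatial artifacts); the FDR and power results
here certify the implementation, not field performance. The Wald-t
inference is approximate for very small subject counts; with ≤ 4 subjects
per group, permutation inference would be preferable and is not
implemented. The classifier assumes two classes throughout.
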