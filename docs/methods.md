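# Methods

This note documents the statistical procedure the package implements, the
choices made where the design was genuinely open, the synthetic data
generator, and the limits of what the tests demonstrate.

## Data model and preprocessing

The unit of quantification is the peptide precursor ion, observed on two
MS levels (1 = precursor isotope envelope, 2 = fragment signal) in every
run. `X_iprg` denotes the log2 intensity of precursor `p` at level `i` in
replicate `r` of group `g`. Intensities arrive on the linear scale (a
Spectronaut-style export) or already log2-transformed; the container
carries an explicit scale flag so every operation can demand the scale it
needs instead of guessing. Duplicate (protein, precursor, run, level) keys
are hard errors, never aggregated: one value per key is the unit of
analysis, and silent aggregation would change every downstream statistic.

Preprocessing order, as the workflows apply it:

1. **MS1 detection floor** (linear scale): MS1 intensities strictly below
   100 become missing. The boundary is read literally as `< 100`; a value
   of exactly 100 is retained. The floor applies to whatever linear values
   are loaded — if the upstream software normalized them, the floor acts
   on normalized values; the package does not re-derive raw intensities.
2. **log2 transform**; non-positive non-missing values are an error (they
   must be floored to missing first).
3. **Global-median normalization** (log2 scale, per level, optional): each
   run is shifted by `grand median − run median`, medians taken over a
   reference protein set (housekeeping proteins when supplied, all
   proteins otherwise). Runs are anchored at the grand median rather than
   zero to preserve an interpretable intensity scale; any constant anchor
   yields identical test statistics. Note that all-protein normalization
   is not innocuous when abundance changes are predominantly in one
   direction: the run median then absorbs part of the true signal and
   biases unchanged proteins in the affected group (see "Error control"
   below).
4. **Complete-case precursor filter**: a precursor with any missing MS1 or
   MS2 value over all design runs is dropped entirely. No imputation
   anywhere. The filter is idempotent and commutes with blocklist-based
   protein removal.
5. **Summarization**: per protein, run and level, the median over the
   protein's precursors. Medians of even counts are the midpoint of the
   two central order statistics (numpy convention) — stated because every
   summary depends on it.

The per-level workflows use run-normalized but *uncentered* summaries
`Z_irg`. The combined workflow first centers each precursor profile at
each level to zero median across runs (`X′_iprg = X_iprg − median_rg`),
then summarizes to `Z′_irg`; centering removes the precursor-specific
ionization-efficiency and level offsets so MS1 and MS2 values of the same
precursor become commensurable.

## Models and tests

**Single level.** One-way ANOVA per protein with sum-to-zero group
deviations. `σ_i² = MS_Error`; omnibus `F = MS_Group/MS_Error` on
`(G−1, N−G)` df. Pairwise contrast of groups a and b:
`SE² = MS_Error (1/R_a + 1/R_b)`, t on `N−G` df.

**Combined.** Nested two-level model with a random run effect shared by
both levels. On balanced designs the fit is closed-form nested ANOVA with

* `MS_Group` on `G−1` df, `MS_Rep(Group)` on `G(R−1)` df, `MS_Error` on
  `GR−1` df (N = 2GR observations);
* moment estimates `σ² = MS_Error` and
  `σ_R² = max(0, (MS_Rep(Group) − MS_Error)/2)` — the divisor 2 is the
  number of observations per run (one per MS level); negative moment
  estimates are truncated to zero and flagged;
* Group omnibus `F = MS_Group / MS_Rep(Group)` on `(G−1, G(R−1))` df. The
  replicate stratum is the correct denominator because runs, not
  level-observations, are the experimental units; using `MS_Error` would
  anticonservatively treat MS1 and MS2 as independent samples;
* contrast `SE² = MS_Rep(Group)(1/(2R_a) + 1/(2R_b))`, t on `G(R−1)` df
  (for a balanced pair, `Var(diff) = (2σ_R² + σ²)/R = E[MS_Rep]/R`).

Unbalanced designs (run failures) fall back to a REML fit of the identical
model (statsmodels `MixedLM`, sum-to-zero fixed-effect coding, random
intercept per run). Contrasts and the Wald-type omnibus F use the
containment df `Σ_g (R_g − 1)` — the replicate-stratum df, which coincides
exactly with the balanced closed-form df and avoids the numerical
machinery of a Satterthwaite approximation; for the mildly unbalanced
designs this fallback serves, the difference is immaterial. The balanced
path remains closed-form, vectorized across proteins, and exactly
testable.

**Multiple testing.** Benjamini–Hochberg step-up per (method, contrast)
family across proteins, delegated to statsmodels. Degenerate proteins
(constant values, zero residual df) are flagged untestable and excluded
from the family rather than assigned p = 1, keeping the BH denominator
meaningful. Zero-residual perfect separation reports the smallest positive
double with a flag rather than exactly 0. Both omnibus F tests and
model-based pairwise contrasts are supported; contrasts are the default
evaluation surface, with an omnibus option for one-list benchmarks.

## Benchmark metrics

* **CV**: sd/mean per (precursor, level, condition) on the linear scale
  with the sample (n−1) sd; cells with fewer than two values or
  non-positive mean are omitted with a count. The reporting threshold
  `CV < 20%` is strict.
* **MS1↔MS2 correlation**: Pearson r between a precursor's MS1 and MS2
  log2 profiles across runs (≥ 3 runs, zero-variance profiles omitted);
  invariant to per-level affine rescaling.
* **TP curves**: candidates ranked by the two-step rule — preselect the
  Top-N by adjusted p, sort that list by raw p. Ties, common at the
  p-value floor, break by larger |log2FC| first and then by protein id for
  determinism; a plain raw-p ranking is available as an option. Top-N
  defaults to 200 for spike-in-style truth and 2000 for proteome-mixture
  truth.
* **Confusion counts** at `adj p < α` with empirical FDR
  `FP / max(1, FP + TP)` and sensitivity.

## The synthetic generator

Per protein: a log2 baseline `~ N(16, 2²)` (linear intensities around
6·10⁴, a mid-range Spectronaut scale); truly changed proteins (10% by
default) receive per-group log2 spike factors. Per run: a biological
effect `~ N(0, σ_bio²)` shared by both levels of that run — the generative
counterpart of `Replicate_r(g)`. Per precursor: an ionization-efficiency
offset (sd 1) shared across runs, and a constant MS1-vs-MS2 offset
(sd 1 log2 unit) that makes the `MS_i` term meaningful. Per cell:
Gaussian measurement noise with level-specific sd. Interference is sparse
and multiplicative on the linear scale — with probability 0.1 a cell is
multiplied by `1 + U`, `U ~ Uniform(0, 1)`, independently per level —
because coeluting signal only ever inflates an extracted ion current.
Finally, linear MS1 values below 100 are recorded as missing.

Defaults: `σ_bio = 0.3`, `σ_ms1 = σ_ms2 = 0.2` — the canonical noise
levels used throughout the calibration experiments; symmetric level noise
is a deliberate simplification (real MS2 is typically somewhat more
precise than MS1, and the CV-count metric is checked against an
explicitly asymmetric configuration in the tests). Under these defaults
the simulated per-condition median CVs land near 25%, at the upper end of
realistic DIA precision. The spike-in configuration mirrors a
five-concentration series (0.75, 0.83, 1.07, 2.04, 7.54 units, log2
factors relative to the first) with 48 spiked proteins on a 2000-protein
background, five replicates per concentration.

One seeded numpy Generator drives all draws in a fixed, documented order,
so identical configs give bit-identical output, and the latent values
(group shifts, replicate effects, interference masks) are returned for
oracle checks.

What the generator does **not** emulate: chromatographic peak shapes,
retention-time drift, correlated missingness beyond the MS1 floor,
precursor-level abundance-dependent noise (variance is homoscedastic in
log space), shared peptides, or run-level systematic shifts (so
normalization is a no-op in expectation on simulated data). Passing tests
therefore demonstrate the statistical machinery under the stated model
plus independent multiplicative contamination — not robustness to every
artifact of real DIA data.

## Error control in the calibration experiments

The type-I and FDR experiments run with one precursor per protein,
normalization off and interference off: one precursor isolates model
calibration from the median-over-precursors summarizer (which shrinks
level noise by an order-statistic factor and would change the estimand of
"recovered σ"); normalization off because with all changes in one
direction the all-protein run median absorbs true signal and biases the
nulls — a property of global-median normalization under asymmetric
change, not of the tests; interference is a non-Gaussian robustness
stressor exercised separately by the power and interference-mitigation
experiments. Variance-component recovery uses a replicate-rich design
(G=2, R=100, 2000 proteins) because the per-protein relative error of any
variance estimate is bounded below by its chi-square spread at small df.

Problem sizes used by the test suite and the reproduction script: 5000
proteins for the null calibration, 20 × 600 proteins for FDR control,
10 × 2048 proteins (five groups × five replicates) for the power and
interference benchmarks, 100 random designs for each oracle-equivalence
check. These sizes give stable Monte-Carlo estimates at interactive
runtimes on one CPU.

## Known limitations

* The REML fallback's containment df is exact for balanced data but only
  an approximation under strong unbalance; severe unbalance (a group
  reduced to one run) marks the protein untestable.
* No moderated (shrunken) variance estimation: the models are plain
  ANOVA / mixed ANOVA by design, so per-protein variance estimates are
  noisy at very small R, and power at R = 2 is limited for all methods.
* The complete-case filter discards every precursor with a single missing
  value; in floor-heavy data this can remove low-abundance proteins
  entirely. No imputation is offered, deliberately.
* Shared-peptide and interference-prone-protein removal is caller-driven
  via blocklists; the package has no protein-database knowledge.
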