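# dianova

Differential protein abundance from DIA proteomics, using the precursor
(MS1) and fragment (MS2) quantitative signals **jointly**.

## The problem

In SWATH-type data-independent acquisition, every peptide precursor yields
two quantitative readouts per run: the MS1 isotope-envelope signal and the
MS2 fragment signal. Both are distorted by interference from coeluting
peptides — but the interferences occur **independently** at the two levels.
Standard practice tests for differential abundance on one level only.
Treating MS1 and MS2 as technical replicates of the same biological sample
doubles the observations per run and lets a model separate biological from
technical variation, which increases the power to detect differentially
abundant proteins, especially at small fold changes and few replicates.

## The models

Let `X_iprg` be the log2 intensity of precursor `p` at MS level
`i ∈ {1,2}` in replicate `r` of group `g`. Per protein, after median
summarization over precursors (`Z_irg = median_p X_iprg`):

**Single-level (MS1-only or MS2-only)** — one-way ANOVA per level:

    Z_irg = μ + Group_ig + ε_irg,    ε_irg ~ N(0, σ_i²)

**Combined** — precursors are first centered
(`X′_iprg = X_iprg − median_rg X_iprg`) so the two levels are comparable,
then both levels enter one nested mixed model:

    Z′_irg = μ + MS_i + Group_g + Replicate_r(g) + ε_irg
    Replicate_r(g) ~ N(0, σ_R²),     ε_irg ~ N(0, σ²)

The run-level random effect `Replicate_r(g)` is shared by both MS levels
of the same run, so the Group test uses the replicate stratum
(`F = MS_Group / MS_Rep(Group)` on `(G−1, G(R−1))` df) rather than
treating MS1 and MS2 as independent samples. p-values are
Benjamini–Hochberg adjusted across proteins.

The package also implements the surrounding workflow: Spectronaut-style
long/wide table readers, the MS1 detection floor (linear intensities below
100 are missing), complete-case precursor filtering, housekeeping
global-median normalization, spike-in benchmark metrics (per-condition
CVs, MS1↔MS2 correlation, true-positive curves, Top-N cuts), and a
synthetic dual-level generator with known ground truth, a spike-in
concentration series, independent sparse interference and an MS1 floor.

## Worked example

Simulate a spike-in series (24 spiked proteins following the S1..S5
concentration ladder among 400 unchanged background proteins, two
replicates per concentration), test with all three methods, and score
against the known truth:

```python
from dianova import (simulate_dataset, spikein_series_config,
                     tp_curve, confusion_at_threshold)
from dianova.cli import run_analysis

cfg = spikein_series_config(n_background=400, n_spike=24,
                            replicates_per_group=2, seed=7)
out = simulate_dataset(cfg)
results = run_analysis(out.quant, out.design, contrasts="omnibus")
for method in ("ms1", "ms2", "combined"):
    table = results[method]
    curve = tp_curve(table, out.truth, top_n=50, contrast="omnibus")
    conf = confusion_at_threshold(table, out.truth, alpha=0.05, contrast="omnibus")
    print(f"{method:8s}  TP@50={curve.tp_at_top_n:2d}  "
          f"sensitivity={conf.sensitivity:.2f}  empirical FDR={conf.empirical_fdr:.3f}")
```

prints

```
ms1       TP@50=24  sensitivity=0.88  empirical FDR=0.000
ms2       TP@50=24  sensitivity=0.83  empirical FDR=0.048
combined  TP@50=24  sensitivity=0.96  empirical FDR=0.115
```

All 24 spiked proteins rank at the top of every candidate list (TP@50),
but at two replicates only the combined model calls 23 of 24 at
BH-adjusted p < 0.05, against 21 (MS1) and 20 (MS2); its empirical false
discovery proportion in this single realization is 3 false calls among 26
(the long-run average is controlled at the nominal level — see the
reproduction script below).

The same workflow is available from the shell:

```sh
dianova simulate --spike-in --seed 7 --out sim/
dianova run --quant sim/quant.tsv --design sim/design.tsv \
            --truth sim/truth.tsv --contrasts both --out analysis/
dianova benchmark --seed 7 --out benchmark.tsv   # fold-change & replicate ladders
```

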