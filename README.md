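# bh3map

Mapping BCL-2-family gene dependencies of cancer cell lines from a
combinatorial BH3-mimetic drug panel.

Selective inhibitors of the anti-apoptotic proteins BCL-2 (ABT-199 /
venetoclax), BCL-X<sub>L</sub> (WEHI-539) and MCL-1 (A-1210477) can be crossed
into an 8-condition panel — vehicle plus every single, double and triple
combination — and read out with a luminescence viability assay.  `bh3map`
implements the full computational side of such a screen for analysts in
drug discovery and functional genomics:

* **Dependency scoring** — percentage viability loss per cell line per
  condition, `100 · (1 − mean treated / mean vehicle)` clamped to
  [0, 99], with strict sensitivity classes (sensitive >50, dependent >25,
  non-responding <20, innately resistant <10).
* **Bliss synergy** — for BCL-X<sub>L</sub>+MCL-1 co-inhibition, with
  dependences rescaled to 0–1: the canonical Bliss excess
  `c − [1 − (1−x)(1−m)]` (default) and the printed-protocol variant
  `(1−x)(1−m) − c`, plus grouping into single-dependent, synergistically
  co-dependent and insensitive lines.
* **Biomarkers** — OLS comparison of tissue-of-origin vs mutation-status
  predictors via `R² = 1 − SS_res/SS_tot`; per-gene expression–dependency
  regression; a sliding-scale search for the expression cutpoint whose
  two-sample t-test best separates responders (with an optional
  permutation-adjusted p-value, since a minimum over splits is a selected
  statistic); fixed-threshold validation on independent cohorts; and
  tissue-average outlier reports.
* **EMT signatures** — marker-sum epithelial (MUC1, CDH1, EPCAM, CLDN3)
  and mesenchymal (SNAI1, SNAI2, TWIST1, TWIST2, VIM, CDH2) scores,
  tissue averages and Pearson correlations against synergy and
  dependence.
* **CRISPR screen scoring** — reads-per-million normalisation, per-sgRNA
  log2 fold change (treated vs DMSO), and the per-gene depletion metric
  (DM): the mean of the 3 most depleted sgRNAs ("three-score"),
  contextualised against control pseudo-genes.
* **Synthetic cohorts** — a seeded generator that emulates the study
  design (78 lines, ten tissues, triplicates; 398-gene × 5-sgRNA screen
  with 50 controls) with planted expression rules, EMT coupling and
  sensitiser genes, recording every planted parameter so recovery is
  testable.

## Worked example

```python
from bh3map import (SimConfig, simulate_screen, build_profiles,
                    score_matrix, find_threshold, validate_threshold)

bundle = simulate_screen(SimConfig(seed=7))
mat = score_matrix(build_profiles(bundle.viability_panel))
expr = bundle.expression.loc["PMAIP1", mat.index]       # NOXA, log2
res = find_threshold(expr, mat["W539"])                 # BCL-XL dependence
```

Running `examples/04_threshold_biomarker.py` (which adds validation on a
second, independently simulated cohort) prints:

```
best NOXA cutpoint: 9.97 log2 (above-sensitive, p = 3.86e-19; 54 below / 24 above)
independent cohort: mean score 60.1 above vs 18.3 below the cutpoint (t-test p = 8.18e-20)
```

The generator plants BCL-X<sub>L</sub> dependence in lines with NOXA above 10.0
log2; the finder recovers a cutpoint at 9.97 (within one inter-point gap),
and lines above it lose on average 60 viability points under WEHI-539 in
the held-out cohort versus 18 below — the planted biology, recovered
end to end.  The other `examples/` scripts walk through cohort
simulation, dependency scoring, synergy grouping, EMT-signature
correlations and CRISPR screen ranking, each printing the numbers it
computes and one line on their meaning.

A thin CLI mirrors the library:

```bash
bh3map simulate --out sim/ --seed 7
bh3map score --panel sim/panel.tsv --out profiles.tsv
bh3map run-all --out run/ --seed 7     # full pipeline + manifest
```

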