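# Methods

## Dependency scoring

Raw panel signals are arbitrary luminescence units from a viability
assay.  For each cell line and treatment condition the dependency score
is

    score = clamp(100 · (1 − mean(treated) / mean(vehicle)), 0, 99)

Replicates are aggregated mean-first (ratio of replicate means), as the
formula is written, not as a mean of per-replicate ratios.  The upper
clamp is 99, not 100, taken literally from the protocol's stated 0–99
range; as a consequence the 0–1 rescaled dependence used by the synergy
layer never reaches exactly 1.  Scores are scale-invariant (multiplying
all of a line's signals by any positive constant changes nothing) and a
condition with no replicates propagates as missing — never imputed.

Sensitivity classes use strict comparisons against the stated cutoffs
(>50 sensitive, >25 dependent, <20 non-responding, <10 innately
resistant).  Scores in the 20–25 band are matched by none of the named
cutoffs; they are labelled `intermediate`, an explicit catch-all of this
package.

The caliper tumour-volume helper `V = (L² · W)/2` lives in the same
module; it rejects swapped diameters (W > L) rather than silently
reordering them.

## Bliss synergy

Dependences are divided by 100 onto the 0–1 scale.  Two variants are
computed for each line:

* printed protocol: `(1 − x)(1 − m) − c`
* canonical Bliss excess: `c − [1 − (1 − x)(1 − m)]`

The printed formula assigns +1 to a line with no response to anything,
which cannot coexist with an "insensitive" response group or with a
synergy range topping out near +1 for strongly co-dependent lines; the
excess variant is therefore the default for grouping and correlations,
and the printed value is always emitted alongside for fidelity.  The two
are linked by `printed + excess = 2(1 − x)(1 − m) − 1`, which is
regression-tested, and the excess is exactly zero (in floating point,
not merely approximately) on Bliss-additive triples because the
expectation is computed with the same expression it is subtracted from.

Grouping: single-dependent if either single-agent dependence exceeds
0.25 (mirroring the 25-point single-agent cutoff); otherwise
synergistically co-dependent if the synergy score exceeds a configurable
cutoff (default 0.25, chosen to mirror the single-agent cutoff — no
published value exists) *and* the combination itself clears the
dependent>25 class; otherwise insensitive.

## Linear models and predictor comparison

`fit_linear` is ordinary least squares, `y = Xβ + ε`, `ε ~ N(0, σ²I)`
(statsmodels under the hood), with per-column two-sided p-values from
the t distribution on n − p degrees of freedom.  Rank-deficient designs
are rejected with the collinear columns named.  `R² = 1 − SS_res/SS_tot`
with SS_tot about the mean of y; a constant response defines R² as 0
with a warning.

The tissue-vs-mutation comparison fits *separate* models per predictor
set (tissue one-hot dummies; the 11-gene binary mutation table, where
"mutant" includes amplifications and deletions as a single state) and
compares their R².  A joint model is possible with the same machinery
but the comparison itself is between the separate fits, since a joint
fit cannot attribute a single goodness-of-fit number to either
predictor family.

## Sliding-scale threshold search

Candidate cutpoints are the midpoints between consecutive *distinct*
sorted expression values; ties in expression collapse to one candidate.
Splits leaving fewer than `min_group_size` lines (default 3 — no
published value; this parameter changes the admissible split set and is
surfaced prominently) on either side are inadmissible.  Each admissible
split is scored with a two-sample t-test on the phenotype scores —
pooled-variance Student's by default, Welch behind a flag — and the
split with the smallest p wins.  Ties on the minimal p are broken by the
larger between-group mean difference, then by the lower threshold, so
output is deterministic.  The scan is implemented as a vectorised
cumulative-sum pass; tests verify it against independent brute-force
enumeration with `scipy.stats.ttest_ind` for every dataset size up to 12.

Degenerate cases: if both sides of a split have zero score variance the
t statistic is defined as 0 (p = 1) when the means agree and ±∞ (p = 0)
when they differ.  A cohort with constant scores returns p = 1 and is
flagged non-significant.

Because the reported p is a *minimum over many candidate splits*, its
null distribution is far from uniform — the raw p rejects a true null
several times more often than its nominal level.  An optional
permutation adjustment (`n_permutations`) re-runs the scan on score
permutations and reports the rank of the observed minimum; its null
rejection rate at 0.05 is calibrated to 0.05 (tested over 500 seeds).
Validation of a threshold on an external cohort applies the *fixed*
cutpoint without re-fitting and runs a single two-sample t-test, so no
selection correction is needed there.

Multiple testing across genes in the association scan is not applied by
default (the analysis reports raw 1/p for ranking); Benjamini–Hochberg
is available as a helper.

## Tissue-average outliers

Per line, the dependency delta is `100 · (score − tissue mean) / tissue
mean`, defined as 0 when both the score and its tissue mean are 0.
Expression deltas are computed after un-logging (2^log2) so "percentage
difference" keeps its meaning on the measurement scale.  A concordance
flag marks lines whose dependency and driver-gene expression deltas
deviate in the direction the association table predicts (defaults:
BCL-2 expression ↑ → BCL-2 dependence ↑; NOXA ↑ → BCL-X_L dependence ↑;
BCL-X_L expression ↑ → MCL-1 dependence ↓).  Singleton tissues are
skipped: there is no average to compare against.

## EMT signatures

Signature scores are plain sums of log2 expression over fixed marker
lists (epithelial: MUC1, CDH1, EPCAM, CLDN3; mesenchymal: SNAI1, SNAI2,
TWIST1, TWIST2, VIM, CDH2).  Literature names (SNAIL, SLUG, NOXA,
BCL-XL, …) resolve through an alias table at read time.  Absent markers
reduce the sum and are reported — mean imputation would fabricate
signal — and scores carry their gene lists so cross-matrix comparisons
can be restricted to complete cases.  Scores are not z-scored (the
canonical score is the raw sum); a standardised variant exists behind a
flag for cross-dataset use.  Tissue averages weight lines equally.
Pearson correlations use the t transform with n − 2 df for p-values.

## CRISPR screen scoring

Normalisation is reads-per-million with a pseudocount (default 1):
`(count + pc) / (total + pc · n) · 10⁶`.  No normalisation is published
for this assay; RPM is the minimal standard for pooled screens and the
pseudocount is configurable.  Replicates are averaged on the RPM scale
*before* the log (mean-then-log), which keeps constructs with a zero in
one replicate finite; the alternative (mean of logs) is regression-
tested against to prevent silent drift.  Per-sgRNA fold change is
`log2(mean treated RPM) − log2(mean DMSO RPM)`.

The depletion metric (DM) of a gene is the mean of its 3 most depleted
sgRNA fold changes — "best" is read as most-depleted, since the screen
is negative-selection and sensitisers drop out under treatment.  Genes
are ranked ascending (rank 1 = strongest sensitiser).  Control sgRNAs
are chunked, in sgRNA-id order (making results invariant to row order),
into pseudo-genes of the modal real-gene size; a gene is flagged a hit
when its DM falls below the 5th percentile of the control pseudo-gene
DM distribution.  The hit rule is a convention of this package — the
original analysis highlighted genes by inspection.

Note that the DM is a mean of order statistics: even under a pure null
it is biased slightly negative (≈ −0.55 × sd of a single sgRNA fold
change for 3-of-5 selection).  This is inherent to the metric, applies
equally to real genes and control pseudo-genes, and is why hits are
called against the control distribution rather than against zero.

## Synthetic-data generator

The generator mirrors the profiled study design: 78 lines over ten
tissue types (8 each, 6 GBM), triplicate wells across the 8-condition
panel, a log2 expression matrix over 6 BCL-2-family drivers, 10 EMT
markers and 20 filler genes, an 11-gene binary mutation table, and a
398-gene × 5-sgRNA + 50-control screen in duplicate.

Latent single-protein dependencies (fractions of viability lost) are
per-tissue base rates, shaped after the reported qualitative landscape
(leukaemias lean on BCL-2/MCL-1; bladder, pancreas and melanoma show
single-agent BCL-X_L dependence; breast on MCL-1; colorectal, ovarian
and lung broadly insensitive), plus planted rules:

* expression thresholds — by default NOXA > 10.0 log2 adds 40 points of
  BCL-X_L dependence, BCL-X_L expression < 6.5 adds 40 points of MCL-1
  dependence (the anti-correlation), BCL-2 > 9.0 adds 30 points of
  BCL-2 dependence;
* optional mutation rules (the mirror case for predictor comparison);
* a latent epithelial/mesenchymal Bernoulli class per line (tissue-
  dependent probability) that shifts the class's own markers by +1 log2
  and couples to response: epithelial lines gain +0.40 combo loss on
  BCL-X_L + MCL-1 co-inhibition, mesenchymal lines +15 points of
  single-agent BCL-X_L dependence;
* per-line biological jitter (sd 0.05 on the loss scale) and clamping
  to [0, 0.99].

Combination losses compose Bliss-independently — combo survival is the
product of single-agent survivals — plus the planted synergy term for
epithelial lines.  No generative model is published for combinations;
this choice makes the synergy scorer's null behaviour exactly testable.
Observed replicate signals are `untreated · (1 − loss) · (1 + N(0, σ))`
with the untreated level log-normal around 10⁶ (luminescence-like; the
scale cancels in scoring) and σ defaulting to 5% of signal — no
replicate-level noise magnitude is published, so the default is a
typical well-to-well CV and is trivially overridable.  With all noise
terms zero, downstream scores equal 100 × the planted losses exactly.

Screen counts are negative binomial (pooled screens are overdispersed;
Poisson at dispersion 0) around log-normal per-construct baselines
(~2000 reads, matching ~1000× coverage designs).  The default
dispersion of 0.005 was set analytically from the order-statistic bias
above so that a null screen's DM distribution centres within ±0.1 of
zero, as a deep-coverage screen's should.  Sensitiser genes (defaults:
BCL2L2/BCL-w and BCL2A1/BFL-1) receive a −2 log2 depletion on a random
3 of their 5 sgRNAs.  Every planted parameter is recorded in the
bundle's truth record.

What the generator does **not** emulate: dose–response structure (the
panel is single-concentration by design), correlated noise across
conditions or plate effects, mutation–tissue dependence, partial
knockout efficiency or sgRNA-specific activity, and any mitochondrial-
priming readouts.  Passing recovery tests therefore demonstrates that
the analysis recovers the effects it models under realistic noise — not
that those effects are identifiable in any real dataset.

## Problem sizes and determinism

Recovery experiments use 50 seeded replicates at the study's own sizes
(60–78 lines; full 2,040-construct screens); the permutation-calibration
check uses 500 seeds of 20-line nulls with 199 permutations each, which
the vectorised scan makes cheap.  All randomness flows from
`numpy.random.default_rng` seeded per run; an identical config and seed
reproduces every table byte-for-byte, and the pipeline manifest records
parameters, seed and output SHA-256 hashes so a run can be verified
bit-identically.

## Known limitations

* The printed synergy formula and the reported synergy range cannot
  both be reproduced; the package implements both variants and defaults
  to the internally consistent one (see above) rather than guessing
  which produced the published figures.
* The published expression cutpoints (10.33 log2 NOXA, 6.44 log2
  BCL-X_L) derive from a proprietary screen matrix joined to public
  expression data and are not re-derivable here; the finder is instead
  validated by oracle equivalence and planted-parameter recovery.
* Hit calling in the screen and the `intermediate` viability class are
  conventions of this package, stated as such.
* The unadjusted threshold p-value is anti-conservative by
  construction; use the permutation adjustment when the question is
  "is there any threshold at all" rather than "where is it".
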