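# Methods

## Problem and model

HLA class I molecules present short peptides (canonically 9-mers) to CD8+
T cells. Prediction tools such as NetMHCpan score a peptide–allele pair four
ways: a predicted binding affinity (IC50, nM; lower = stronger), its
percentile rank among random peptides (BA rank), an eluted-ligand likelihood
(EL score, higher = better) and its percentile rank (EL rank). Practical
epitope discovery needs a *cutoff* on one of these scores. This package
implements and benchmarks the threshold-calibration strategy in which the
cutoff is set empirically so that a fixed fraction of known positive
peptides — mass-spectrometry-eluted ligands or T-cell epitopes — is captured.

All thresholding metrics are oriented lower-is-positive; a peptide is
predicted positive when its score is **at or below** the threshold
(inclusive). Inclusivity matters: thresholds are observed order statistics,
so the inclusive rule makes re-applied calibration land exactly on target,
while a strict inequality would systematically undershoot.

### Calibration at fixed sensitivity

Given `n` positive scores and target sensitivity `s`, the threshold is the
`k`-th order statistic with `k = ceil(s·n)` — the smallest observed value
capturing at least `s` of the positives. Two families:

* **allele-specific** — calibrated on each allele's positives separately;
  with tie-free scores every allele's re-applied sensitivity is exactly
  `k/n` (mean 80%, SD 0 at the defaults), eliminating between-allele
  variability by construction;
* **common** — calibrated once on all alleles pooled; its per-allele
  sensitivity varies widely because alleles differ in repertoire breadth.
  The common threshold always lies between the per-allele minimum and
  maximum.

A third, **binder-fraction-derived** family converts each allele's
repertoire breadth — the fraction of background decoys predicted to bind at
an IC50 cutoff (500 nM, the classical binder definition) — into an EL-rank
percentile cutoff (×100). The pooled fraction gives its common value. A zero
fraction is retained but flagged degenerate.

### Rescaling to epitope sensitivity

Thresholds calibrated on eluted ligands under-capture T-cell epitopes,
because eluted ligands are enriched for high-scoring binders relative to
epitopes. `scale_to_target` therefore multiplies every threshold in a family
by `(1 + step)` per iteration — one shared multiplier, never per-allele
re-tuning — stopping at the first iteration where the *unweighted* mean over
alleles of per-allele sensitivity on the epitope set reaches the target. The
cumulative fold is recorded as `scale_applied = (1+step)^i`. Steps default
to 0.05 for ligand-derived and 0.1 for binder-derived families. The stepwise
increase is read as compounding multiplication (a geometric ladder), which
is the reading consistent with multi-fold resulting increases; an additive
+0.05 ladder could not produce them. The mean is unweighted (each allele
counts once) rather than weighted by epitope count; monotonicity of
sensitivity in the threshold guarantees termination whenever any finite
threshold can achieve the target. A `1e-12` tolerance on the stopping
comparison guards against float-summation artifacts when every allele sits
exactly on target.

### Benchmarking

Positives at or below threshold are TP, above FN; background decoys at or
below are FP, above TN. The five rates are sensitivity TP/(TP+FN),
specificity TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN), accuracy
(TP+TN)/total, all reported as fractions (formatted as percentages only in
reports). A 0/0 rate is *undefined*, reported as missing, excluded from
across-allele Mean/SD with an exclusion count — silent zeros would bias the
summaries. SD across alleles is the sample SD (ddof = 1). ROC/AUC uses
lower-is-positive orientation (scores negated into the standard machinery)
with half-credit for tied positive–negative pairs (Mann–Whitney
convention); ROC is computed pooled across alleles for metric comparisons,
with per-allele ROC available. Repertoire size is the fraction of background
at or below a threshold; it is nondecreasing in the threshold.

## Curation rules

From IEDB-style exports the package retains 9-mers of canonical amino acids
with a defined four-digit HLA restriction (serotype-only names dropped),
excludes two PubMed IDs (28188227, 29393594) whose ligands derive from
transgenic rat cells, keeps one instance per (sequence, allele), and drops
alleles below a minimum count (100 unique ligands; 20 retained epitope
assay records, counted after deduplication). Duplicate epitope records keep
the most positive outcome under the strict total order

    tetramer > positive-high > positive-intermediate > positive > positive-low

with ties broken by input order (deterministic). This ordering is a design
choice: graded outcome labels do not come with a canonical ordering of
"positive" against "positive-intermediate", and we place the unqualified
label below the explicitly intermediate one so that each label appears
exactly once in a strict hierarchy. Per-allele subsampling (100 ligands, 50
epitopes) uses one RNG consumed in sorted-allele order, so selections are
independent of input row order. Validation epitope sets are drawn from the
complement of the primary sample (no peptide reuse); alleles without enough
spare records are omitted with a notice.

Background decoys are all distinct 9-mer windows of the source proteins
(windows containing non-canonical residues B/J/O/U/X/Z discarded — prediction
tools reject them), sampled uniformly without replacement after removing any
sequence present in a positive set of *any* allele (one shared decoy list),
then assigned to every analyzed allele.

## Synthetic data generator

The generator emulates the phenomena the analysis depends on, not binding
chemistry; peptides are random distinct 9-mers without motif structure.
Per-allele parameters (`SyntheticProfile`):

| parameter | default | meaning |
|---|---|---|
| `repertoire_breadth` | log-spaced 0.002–0.08, ±10% jitter | fraction of background predicted to bind at 500 nM |
| `ligand_rank_scale` | 20 × breadth | scale of the ligand EL-rank law |
| `epitope_inflation` | 2.0 | multiplicative widening of the epitope law vs ligands |
| `ic50_location`, `ic50_spread` | anchored to breadth; 2.5 (ln-nM) | lognormal background IC50 law |

Score laws: background EL rank ~ Uniform(0, 100] per allele; ligand EL rank
~ `scale`·LogNormal(0, 1) truncated to (0, 100] by resampling; epitope EL
rank uses the same law with `scale` multiplied by `epitope_inflation` — one
interpretable knob controlling the ligand→epitope gap rather than an
independent family. The IC50 channel is generated from the EL rank through a
Gaussian copula (correlation 0.8), with the lognormal location chosen so
that P(IC50 ≤ 500 nM) equals `repertoire_breadth` exactly in law; BA rank is
the Gaussian percentile of the same latent variable, and EL score is a
decreasing transform `exp(-el_rank/10)` of the EL rank.

Consequences of these defaults, all verified by the test suite rather than
asserted: allele-specific 80% EL-rank thresholds span roughly 0.07–4.5
percentile units (about the published order of magnitude for real alleles);
binder-fraction thresholds recover `repertoire_breadth`·100 within binomial
error at n = 10,000; with inflation 2 the ligand-derived thresholds capture
only ~52–65% of epitopes, and stepwise 5% scaling terminates near 2.1-fold.
The generator makes no attempt to match the absolute fold-changes of
real-data recalibration (which depend on the true, much heavier discrepancy
between ligand and epitope score distributions), nor sequence-level effects
(anchor residues, length preferences, source-protein bias). In this
generator the binder-derived family often needs little or no rescaling,
because 100×breadth is already loose on the EL-rank scale; on real data the
two scales differ more sharply. Passing tests therefore demonstrate the
*machinery* — exact calibration, geometric scaling ledger, recovery of
generating parameters — not real-data threshold values.

## Problem sizes and numerics

The analysis drivers and the acceptance script run the full default design
(72 alleles × 100 ligands, 50 epitopes, one 10,000-decoy background scored
per allele ≈ 720k background rows); unit tests use 6–12 alleles with
reduced backgrounds. Everything completes in seconds. `ceil(s·n)` is
computed as `ceil(round(s·n, 10))` so that float artifacts (0.8·100 binding
to 80.000…01) cannot jump an order statistic. Ties at the cutoff are kept:
the threshold is the order statistic itself and the resulting sensitivity
may exceed the target; it is reported, never truncated. Degenerate inputs
(empty score lists, alleles without background, datasets with neither
positives nor negatives) raise informative errors rather than returning
NaNs.

## Interfaces and layout

The library (`src/hla_thresholds/`) holds all computation: `curation`,
`background`, `scores`, `calibration`, `evaluation`, `synthetic`,
`pipeline`. `ThresholdSet` may carry a common scalar, a per-allele map, or
both; resolution prefers the per-allele value. This lets the common family
be scaled and evaluated on its own, which the pipeline does because common
and allele-specific families reach the target at different folds. Numbered
drivers under `analysis/` narrate the study; the `hlathresh` CLI exposes the
same stages (`synth`, `curate`, `background`, `calibrate`, `scale`,
`evaluate`, `report`) for shell use. Stage outputs are TSV with full float
precision, so reruns are byte-identical under a fixed seed.

## Known limitations

Only 9-mers and MHC class I are supported; predictions are ingested, never
computed (no NetMHCpan invocation); thresholds optimize captured
sensitivity only, not PPV/F1 or cost-weighted objectives; AUC comes without
confidence intervals or DeLong tests; the synthetic generator's
distributional families are artifacts of this package constrained only by
the stochastic-ordering properties above.
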