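# Methods

## Problem and model

CD4 T-cell responses in outbred human populations concentrate on a small
set of dominant epitopes. The package models the probability that a
15-mer peptide is such an epitope from its sequence alone, with no HLA
typing, and optionally combines that estimate with a population-level
HLA class II binding summary.

The sequence model is a motif-alignment network: a feed-forward net with
one hidden layer of 5 sigmoid units that scores every length-L core of a
peptide and returns the maximum over placements. Because the maximum is
taken inside the model, training discovers both the motif and its
position in each peptide. Assumptions built into this architecture:

- the discriminative signal is a *contiguous* core of fixed length L
  (default 9, matching the class II binding groove and TCR footprint);
- one core per peptide suffices (no multi-motif mixtures);
- flanking residues outside the core carry no signal (the original
  NNAlign tool's peptide-flanking-region and length features are
  deliberately not implemented here);
- peptides are independent training examples; dependence through shared
  sequence is handled at the *split* level, not the model level.

Targets are 1.0/0.0 for immunogenic/non-recognized. Per-example SGD
re-aligns the peptide under the current weights and backpropagates the
squared error through the best core only.

## Training parameters

| parameter | default | notes |
|---|---|---|
| motif length L | 9 | scan over 1–15 available via `motif_length_scan` |
| hidden units | 5 | fixed architecture |
| encodings | one-hot and BLOSUM50/5 | X encodes as a zero block; no input rescaling |
| seeds per (fold, encoding) | 10 | random restarts, averaged |
| folds | 5 | common-motif CV (shared 9-mer ⇒ same fold) |
| learning rate | 0.05 | per-example updates, seeded shuffled order |
| epochs | ≤ 300 | snapshot at best inner-holdout AUC |
| patience | 40 | stop after 40 epochs without improvement |
| inner holdout | 10% | stratified, for the early-stopping snapshot |
| weight init | U(−0.1, 0.1) | from the per-network seed |

The early-stopping rule (best-AUC snapshot on a 10% stratified holdout,
patience 40) and the BLOSUM variant (BLOSUM50 divided by 5, the NNAlign
convention) are this package's own choices; both are exposed as
configuration. If the holdout is single-class the
snapshot criterion falls back to negative MSE. Ties between equal core
scores resolve to the lowest offset. Training is bitwise reproducible
for a fixed seed; the SGD inner loop is JIT-compiled with numba.

The production model is the bag of *all* cross-validation networks
(folds × seeds × encodings, 100 by default) — there is no refit on the
full data, so the pooled out-of-fold AUC describes exactly the shipped
model. Averaging across both encodings (rather than selecting one) is
the default.

## Cross-validation splitting

Peptides sharing any 9-mer substring are connected; connected components
are assigned whole to folds by greedy bin packing (largest component
first into the currently smallest fold; equal-size components are
shuffled by the seed). This prevents near-duplicate peptides from
appearing on both sides of a split. The same 9-mer rule, applied
between a training and an evaluation set (`remove_cross_redundancy`),
removes training peptides that would leak into validation.

## Scoring and combination

`Imm_score = (1 − nn) × 100` is a linear rescale of the network output
onto the 0–100 "lower = more immunogenic" scale so it is commensurate
with binding percentile ranks; despite the percentile-style range it is
not a rank transform (an optional rank-based conversion against a
background pool exists behind a flag, off by default). `HLA_score` is
the median per-allele predicted binding percentile over seven
representative DR alleles; the engine accepts any allele set since only
the median is used, and expects precomputed percentiles in production
(TSV sidecar). The built-in `ToyAllelePredictor` (random 9×20
position-weight matrices, percentile-calibrated against a random-peptide
background) exists so the full pipeline runs and is testable offline; it
is a synthetic stand-in, not a trained binding model.

`Combined = α·Imm + (1−α)·HLA` with default α = 0.4. The α-sweep
evaluates the unweighted mean per-study AUC on a grid including both
endpoints, which reproduce the single-channel AUCs exactly.

## Evaluation machinery

- ROC/AUC: tie-grouped staircase, trapezoidal area; equal to the
  Mann–Whitney pairwise probability with half-ties (verified to 1e−12
  against a brute-force oracle in the tests). Percentile-type scores
  are negated before ranking so "lower = positive" is uniform.
- Per-study means are unweighted; single-class studies are skipped with
  a warning.
- Method comparison: two-sided Wilcoxon signed-rank with Pratt's zero
  handling (zeros ranked, then dropped from the statistic). Exact
  enumeration of sign assignments for n ≤ 12 pairs; otherwise a normal
  approximation whose variance uses mid-ranks (which subsumes tie and
  zero corrections). Swapping the inputs leaves the p-value unchanged;
  all-zero differences give p = 1.
- Threshold calibration: predicted-immunogenic iff combined ≤ cutoff;
  sensitivity, specificity and the fraction of peptides to synthesize
  are computed per study in percent and averaged unweighted. Default
  cutoff grid {8, 18, 36, 43, 66}.

## Two-sample logo

Per (position 1–15, residue) cell, a Welch t-test on the per-peptide
binary indicator, flagged enriched/depleted at raw p < 0.01 with no
multiple-testing correction (a Bonferroni switch exists, off by default,
mirroring the raw-p convention of the published logo). Peptides longer
than 15 are truncated to their N-terminal 15 residues. Degenerate cells
(residue absent from both sets) are neutral with p = 1; zero-variance
separated cells are flagged. The binary-indicator t-test is
asymptotically equivalent to a two-proportion z-test, which serves as
the independent oracle in the tests. Subset stability re-runs the logo
on five seeded 80% subsamples and reports per-cell status concordance
with the full data.

## Synthetic data

The generator emulates the *structure* of epitope screening data, not
its biology:

- positives embed a 9-mer core sampled from a PWM at a random offset in
  a background 15-mer; negatives are pure background (uniform residue
  frequencies by default; a SwissProt-like preset is included);
- the default PWM enriches R/K, depletes D/E and places hydrophobic
  anchors near the core start — the charge signature that separates real
  epitopes from non-recognized peptides — with mixing strength λ
  (λ = 0 null, λ = 0.9 default for training fixtures);
- validation studies use λ = 0.5 and an HLA channel calibrated to
  AUC ≈ 0.70, emulating the domain shift between controlled training
  data and heterogeneous literature studies — 0.70 is the design target
  for a realistic cross-study binding channel;
- HLA percentiles are binormal latent scores (shift from the identity
  AUC = Φ(δ/√2)) mapped through the pooled empirical CDF, so their
  label correlation is controlled independently of the motif.

What passing tests on this data do **not** show: real epitope signal is
far weaker and confounded (HLA-binding selection in how peptides were
chosen, assay noise, donor cohort effects, shared antigen families
between studies). Synthetic AUCs (reported by `scripts/acceptance.py`) are therefore
upper bounds on what the same code would achieve on literature data.
Everything is deterministic under a master seed; per-study and
per-network seeds derive from it via seed sequences.

## Problem sizes and numerical choices

The standard fixtures are 400+400 peptides for training/null checks
(5 folds × 10 seeds × 2 encodings = 100 networks) and 57 studies of
2–28 positives / 2–60 negatives for validation; the motif-length scan
uses 2 seeds per (fold, encoding). Model JSON serializes weights as
plain floats and round-trips predictions bitwise. Degenerate inputs:
single-class training data is an error; single-class folds report NaN
AUC and are excluded from fold means (the pooled AUC still covers their
peptides); empty redundancy components beyond the fold count produce a
warning, not an error.

## Known limitations

- No peptide-flanking-region, length or offset-realignment features.
- The toy binding predictor shares none of the statistics of real class
  II binding predictors; production use requires precomputed percentile
  ranks.
- The exact Wilcoxon branch is O(2^m) and restricted to n ≤ 12.
- The logo's t-test variant (Welch) is a choice; the published logo
  service does not document pooled vs Welch.
- Long epitopes are deconstructed with step 1 by default (maximal
  coverage); the original assembly step for long epitopes is unstated.
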