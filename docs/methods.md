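# Methods

## Problem and model

`pipel` classifies short linear peptides (canonical 20-letter alphabet,
5–25 residues after filtering) as proinflammatory-inducing (PIP) or not.
The statistical model is a *random under-sampling ensemble*: because
validated negatives outnumber positives roughly 3:1, a single classifier
trained on the raw data optimizes accuracy by favouring the majority class,
producing a large gap between sensitivity and specificity. Instead, the
majority class is sampled into k balanced 1:1 subsets, one classifier is
trained per (feature scheme, subset) pair, and the per-peptide class
probability is the unweighted mean over all members. The final call
thresholds this mean at an MCC-optimized cutoff.

Assumptions worth stating explicitly:

* class-conditional information is compositional — the five schemes are
  order-insensitive (AAC, PCP, AAI) or only locally order-sensitive
  (DPC adjacency, CTD transitions/distribution); no alignment or motif
  model is used;
* members are exchangeable at fusion time: every member's probability gets
  weight 1/50 regardless of scheme or subset quality;
* the benchmark is representative: cutoff optimization on out-of-fold
  benchmark scores transfers to unseen data.

## Feature encodings

* **AAC** (20): count(i)/L. Sums to 1.
* **DPC** (400): overlapping adjacent-pair counts over the L−1 positions,
  lexicographic dipeptide order. Requires L ≥ 2. Sums to 1.
* **CTD** (147): seven attribute tables (hydrophobicity, normalized van der
  Waals volume, polarity, polarizability, charge, secondary structure,
  solvent accessibility), each a three-class residue partition vendored in
  `src/pipel/data/ctd_groups.tsv`. Per attribute: 3 composition
  percentages; 3 transition percentages — adjacent residue pairs in
  *distinct* groups, counted regardless of order, divided by L−1; and
  5 × 3 distribution values — for each group, the sequence position
  (as % of L) of its first, 25 %-, 50 %-, 75 %-quantile and last
  occurrence. The quantile occurrence index is `max(1, floor(q·N + 0.5))`
  (nearest, ties up) of the N occurrences; an absent group contributes
  five zeros.
* **AAI** (20 default, 160 full): eight cluster-central AAindex scales
  (BLAM930101, BIOV880101, MAXF760101, TSAJ990101, NAKH920108, CEDJ970104,
  LIFS790101, MIYS990104), vendored in `src/pipel/data/aaindex8.tsv` and
  each min-max scaled to [0,1] over the 20 residues. The full form is the
  outer product AAC(i) · scale_j(i); the default averages the eight scales
  per residue. Note one scale (LIFS790101) has a tied maximum (Ile/Val), so
  the scaled value 1 is attained at two residues there.
* **PCP** (9): hydrophobic (FIWLVMYCA), hydrophilic (RKNDEP), neutral
  (THGSQ), positive (KHR) and negative (DE) fractions; turn-forming
  fraction (N+G+P+S)/n; absolute net charge per residue
  |(R+K−D−E)/n − 0.03|; average molecular weight (vendored average residue
  masses plus one water, 18.01528 Da); aliphatic index
  (A + 2.9·V + 3.9·I + 3.9·L)/n.

Feature matrices are min-max normalized to [0,1] per feature. The
normalizer is always fitted on training data only; constant features map
to 0; unseen values are clipped into [0,1]. SVM members rely on this
normalization; tree members tolerate it harmlessly.

## Dataset preparation

* **Length filter**: bounds 5 and 25 are inclusive (a peptide of length
  exactly 5 or 25 is kept).
* **Redundancy reduction**: greedy incremental clustering, sequences
  visited longest-first; a sequence joins the first retained representative
  with identity > threshold (default 0.8), else founds a cluster.
  Identity = matches in the match-maximizing global alignment (match 1,
  mismatch 0, gap 0 — so the alignment score *is* the match count) divided
  by the shorter sequence's length. Exact pairwise alignment is tractable
  at peptide scale, so no external clustering binary is needed.
* **Split**: stratified per class at the benchmark fraction (default 0.8),
  reproducible from the seed.
* **Balanced subsets**: majority ids are drawn from a shuffled pool without
  replacement across subsets; when the pool empties it refills with a fresh
  shuffle, skipping ids already inside the subset being filled. This makes
  the coverage guarantee (every majority sample used at least once)
  deterministic whenever k · n_minority ≥ n_majority, which is validated up
  front with the minimal feasible k reported in the error.

## Training and fusion

Per member: encode the subset under its scheme, fit the normalizer, tune
hyperparameters, fit on the whole subset. Tuning runs `repeats` (default
10) independent stratified 5-fold CV grid searches scored by mean MCC and
returns, per numeric parameter, the lower median of the per-repeat winners
and, per categorical parameter, the mode with ties toward the candidate
listed first (grids list less complex options first). A singleton grid
short-circuits the search — that combination is returned regardless of
repeats, which the fast paths in the tests and the acceptance script use.

Default grids: trees ∈ {100, 200, 500}, features-per-split ∈ {√p, log₂p,
p/3}, min-samples-to-split ∈ {2, 5, 10} for RF/ERT; C ∈ {2⁻¹⁵…2¹⁰} and
γ ∈ {2⁻¹⁰…2¹⁰} in log₂ steps for the SVM. Member probabilities are the
tree-vote fraction (RF/ERT) or the calibrated SVC probability estimate, so
fusion averages quantities on a common [0,1] scale.

**Cutoff**: unless fixed by the caller, the fusion cutoff is optimized on
*out-of-fold* scores: each member scores the peptides inside its own
training subset via 5-fold cross-val-predict (with per-fold normalization
inside the CV pipeline, so no leakage) and all other benchmark peptides
with its final fit; the per-peptide mean over members is then scanned at
cutoffs 0.00–1.00, step 0.01, for maximal MCC, ties resolved toward 0.5
and then downward. Scoring unseen data uses each member's stored
normalizer and final fit; a score exactly at the cutoff is called PIP.

Seeds thread from a single master seed: member m of composition c uses
`seed + 1000·c_index + subset_id`, so retraining with the same seed
reproduces subsets, selected hyperparameters, the cutoff and all scores
bit for bit.

## Evaluation

Sensitivity, specificity, accuracy and MCC from confusion counts (MCC with
a zero denominator is defined as 0, the standard convention); trapezoidal
ROC/AUC; ΔS = |Sn − Sp|. Cross-validation is stratified k-fold with
per-fold reports plus a pooled report from summed counts and pooled
scores. Model comparison is a two-sided *paired* t-test over matched
per-subset metric values (the natural pairing of the 10 balanced subsets);
identical lists return p = 1, and a nonzero constant difference (zero
variance, infinite t) is reported as p = 0 with a `zero_variance` flag
rather than NaN.

## Sequence analysis

Compositional contrasts are per-feature Welch's t-tests on per-peptide AAC
or DPC values (default α = 0.01), with direction by mean difference.
Positional contrasts test, per terminus × position (1–10) × residue, the
occurrence indicator with the same two-sample test (default α = 0.05) —
the two-sample-logo convention. N-terminal positions count forward from
the first residue, C-terminal positions backward from the last; peptides
shorter than the window contribute only the positions they have (no
padding residues are fabricated). Two identical degenerate samples (zero
variance, equal means) are treated as indistinguishable (p = 1) rather
than NaN.

## Synthetic data generator

The generator emulates the structure of the curated immune-epitope data
the method targets: lengths uniform on 5–25, default class imbalance
1:2.9, and class-specific residue biases — Arg and Leu boosted in
positives, Gly/Asp/Pro in negatives (default multiplier 2 each). Residues
are i.i.d. from a base distribution reweighted by the class bias;
the base is uniform by default so the null case is exactly calibrated
(a natural-abundance base is available as a flag). `effect_size` scales
the multipliers linearly, `applied = 1 + (m−1)(effect_size−1)`: 1 makes
the classes identically distributed, 2 applies the multipliers as given,
5 turns a ×2 bias into ×5.

What the generator does **not** emulate: positional/motif structure,
length–class dependence, residue autocorrelation, label noise, and the
phylogenetic relatedness that makes redundancy reduction matter in real
extracts. Passing tests on this generator therefore demonstrates the
correctness and the balancing behaviour of the machinery, not the
real-data benchmark performance of any retrained model.

## Problem sizes and study conditions used in tests and the acceptance run

* Balance comparison: 10 replicates of 120 positives / 360 negatives
  (the 1:3 regime), moderate effect size 2.5, 75/25 train/test split;
  balanced AAC-only 10-subset ensemble with optimized cutoff vs one model
  trained on the same imbalanced data at cutoff 0.5.
* Null calibration: 1000 peptides per class at effect size 1, 80/20 split,
  single AAC random forest; held-out AUC expected in [0.45, 0.55].
* Separability check: 500 per class at effect size 5; AAC+PCP ensemble,
  k = 5; out-of-fold MCC expected above 0.8.
* Structural checks (encoder dimensions, 50 members, coverage over 200
  random configurations) run at small n with singleton grids.

These sizes are the package's own choice of a compact, reproducible study
design; all randomness in the acceptance script derives from its `--seed`.

## Known limitations

* The AAindex rows and residue masses are vendored constants; each AAindex
  row is rescaled to [0,1] before use, so the encoding depends only on the
  relative ordering and spacing of the published values.
* Greedy clustering is order-dependent (longest-first, then input order),
  like any single-pass representative clusterer; the all-pairs property
  tests assert the representative set is threshold-consistent, not unique.
* The paired t-test is a parametric choice over 10 correlated CV
  measurements; its p-values are indicative rather than exact.
* SVM members use Platt-style calibrated probabilities, which adds an
  internal CV and makes SVM training markedly slower than RF/ERT.
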