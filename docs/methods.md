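# Methods

## The WFS model

Weighted Feature Significance is a two-step scoring algorithm for
multi-label binary prediction from sparse binary features.

**Step 1 — enrichment fingerprint.**  For a given adverse effect (ADE)
and a training set of compounds, every feature receives a one-sided
Fisher exact p-value for enrichment among ADE-positive compounds.
Implementation details and conventions:

- Rows with a missing feature value are dropped from that feature's 2×2
  table only (missingness is feature-local, not row-global).
- If the feature's frequency among ADE-positives is *strictly* lower than
  among ADE-negatives, p is pinned to 1: depletion is treated as "no
  evidence for the ADE", not evidence against.  Equal frequencies are
  *not* pinned — the one-sided test is computed (and is necessarily
  ≥ 0.5), reading "less frequent" strictly.
- The fingerprint's key set M contains the features present (value 1) in
  at least one ADE-positive *training* compound; features present only in
  negatives are excluded by construction.
- The one-sided Fisher p equals the hypergeometric upper tail, so the
  fingerprint is computed vectorised via the hypergeometric survival
  function; the test suite verifies exact agreement (to 1e-12) with both
  an exact-rational tail-summation oracle and an independent library
  implementation of the Fisher test.
- If one label class has no non-missing values the p-value is undefined;
  1 is returned with a warning.

**Step 2 — scoring.**  A drug with present-feature set C scores

    WFS = Σ_{i∈M∩C} ln p_i / ( min_{i∈M} ln p_i × (α·N_{C−M} + N_{M∩C}) )

Two index-set choices are genuinely open in this formulation and were
decided as follows:

- The numerator sums over M∩C only — p-values exist only for M.
- The min is taken over **all of M**, not M∩C.  With min over M∩C any
  drug carrying a single fingerprint feature would score exactly 1
  regardless of how weak that feature is, destroying the interpretation
  of high scores as strong evidence.  Normalising by the best attainable
  evidence in the fingerprint means only drugs carrying the most
  significant features approach 1.  Both variants are available
  (`WFSModel(min_over="M"` or `"M∩C")`) for sensitivity analysis.
- Natural logarithms are used; the ratio is base-invariant (tested).
- Degenerate cases score 0: empty M∩C, or a fingerprint whose p-values
  are all 1 (min ln p = 0).  Features with p = 1 inside M∩C contribute 0
  to the numerator but still count in N_{M∩C}, diluting the score — the
  literal reading of the formula, kept deliberately.
- α ≥ 0 penalises features outside the fingerprint; it is fixed at 1 in
  every model here.  With α = 1 and C ⊆ M the score lies in [0, 1], and
  adding a feature outside M strictly decreases any positive score (both
  properties are asserted on random instances).
- Missing feature values at scoring time are treated as "not present":
  they can neither add evidence nor trigger the N_{C−M} penalty.

## Evaluation protocol

- Repeated 50/50 holdout, default 10 splits, unstratified uniform draws.
  Train and test partition the compounds with sizes differing by at most
  one.  The same split plan is shared by every model set in a comparison,
  so differences reflect inputs rather than split luck.
- If a split leaves one class empty for some ADE in train or test, that
  (ADE, split) cell redraws a fresh split (bounded at 100 tries, logged),
  then skips with a warning.  If the training positives carry no features
  at all (empty fingerprint), all test scores are 0 and AUC is 0.5 by the
  tie convention rather than an error.
- AUC-ROC uses the rank/Mann-Whitney formulation with 0.5 tie credit
  (delegated to scikit-learn; verified against an O(n²) concordance
  oracle).  Balanced accuracy = (sensitivity + specificity)/2 at the
  feature-present cutoff.
- Label-permutation null: each replicate permutes every ADE column
  independently, reruns the full protocol and records the grand mean AUC;
  empirical p uses the add-one estimator (1 + #{null ≥ obs})/(n_perm + 1).
- Feature-block permutation shuffles block *rows* against compound ids —
  column marginals are preserved exactly, only the compound↔annotation
  linkage is severed.
- Model sets are compared by one-way ANOVA on per-ADE mean AUCs with
  pairwise two-sample t-tests, Bonferroni-adjusted (p × number of pairs,
  capped at 1).  Identical sets report adjusted p = 1 directly.

## Univariate screening

Each DTA (or assay readout) is scored as a standalone predictor of each
ADE: AUC with the binary feature as the score, and balanced accuracy of
predict-positive-iff-feature-present (no cutoff search).  Selection takes
any feature strictly exceeding the block threshold — 0.6 for DTAs, 0.65
for readouts — on either metric for at least one ADE.  The screen runs on
the full compound set with no holdout: it is a screening step, and the
recorded AUC/BA values are *not* unbiased performance estimates.
Constant features are recorded at 0.5/0.5 with a flag.

## Assay QC

Activity calls binarise the signed curve rank at |rank| > 0.5 (strict);
the sign is kept separately as direction (+ activation, − inhibition).
Triplicate reproducibility categories are direction-aware: *active match*
means all three replicates active in the same direction, *inactive match*
all three inactive, *mismatch* means both directions appear, and
everything else (partial agreement, inconclusive calls) is
*inconclusive*.  Score = 2·%active match + %inactive match −
%inconclusive − 2·%mismatch; grades A (≥ 90), B (80–90), C (70–80),
D (< 70), closed-lower/open-upper.

## The synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated.  Latent structure: each of 300 compounds interacts with each
of 40 targets independently (base probability 0.15, plus a +0.2 boost on
the five targets favoured by the compound's scaffold, of eight
scaffolds).  Observables:

- **Assay block** — 30 readouts covering only the first 15 targets
  (round-robin), each value the interaction flipped with probability
  0.05 and masked missing at rate 0.02.  The partial coverage emulates a
  real screening panel's limited biological space.
- **DTA block** — 40 annotations, one per target, marking true
  interactions with probability 0.9 and *never* marking non-interactions
  (annotation databases under-report but rarely invent interactions).
- **Structure block** — 64 bits reporting scaffold membership with 10%
  bit noise; structure correlates with toxicity only through the
  scaffold→target interaction bias, mimicking similarity-based signal.
- **Animal block** — 12 endpoints, each a noisy OR (15% flip, 2%
  missing) over 3 random targets.
- **ADE labels** — each of 20 ADEs draws 3 causal targets with 0.8 of
  the selection weight on *unassayed* targets; a compound is labelled
  positive with probability min(1, 0.1 + 0.5 × #causal targets hit) — an
  additive, capped, noisy-OR-like link chosen for monotonicity and
  recoverability.

The rates were fixed by closed-form reasoning before any end-to-end runs:
with these values a DTA annotating a causal target has an expected
univariate AUC ≈ 0.63 (comfortably above the 0.6 selection threshold but
far from trivial), assay-only models average AUC ≈ 0.55 (signal exists
but most causal targets are unassayed), and combined assay+DTA models
gain substantially — reproducing the qualitative ordering such a study
reports.  Structure-only models are the weakest at these settings
(scaffold→ADE signal is two steps removed); we kept that rather than
inflating the scaffold boost.

All randomness flows from one seed; every matrix uses its own
deterministically derived sub-stream, so generating an extra block never
perturbs the others.  Triplicate call tables corrupt a latent call per
replicate with a configurable probability (uniform redraw over the call
states).

**What the generator does not emulate:** dose-response shapes, realistic
pharmacology or chemistry-aware fingerprints, correlated missingness
(untested compounds missing whole assay panels), annotation synonymy and
curation noise, and the heavy-tailed ADE frequency distribution of
pharmacovigilance data.  Passing tests therefore demonstrate the
pipeline's internal correctness and calibration — not that these
performance levels transfer to real qHTS/annotation data.

## Problem sizes

Default study conditions (300 compounds × 30 readouts × 20 ADEs, 10
splits) run one full repeated holdout in well under a second; the
50-replicate label-permutation calibration completes in under a minute on
one CPU.  These sizes were chosen as the smallest at which binomial noise
on a grand mean AUC is comfortably inside ±0.02.

## Known limitations

- The repeated holdout draws splits unstratified; extremely rare labels
  rely on the redraw guard rather than stratification.
- Fingerprint p-values are scoring weights, not inference: no
  multiple-testing correction is applied, by design.
- The ANOVA treats per-ADE mean AUCs as independent observations across
  model sets even though they share splits; this mirrors the standard
  practice for such comparisons but is anti-conservative in principle.
- Triplicate QC category definitions (direction-aware matching) are one
  reasonable reading; alternative conventions exist for the inconclusive
  versus mismatch boundary.
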