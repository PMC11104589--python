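# Methods

This note documents the models, numerical conventions and design choices
behind `petselect`, and what its synthetic experiments do and do not show.

## Disease State Index classifier

The DSI is described in the literature qualitatively — similarities of a
patient's values to the training-group distributions, accuracy-weighted
combination — and the exact fitness function of the original tool is not
recoverable.  This package adopts the standard misclassification-ratio
construction and declares it precisely so every piece is oracle-checkable:

* **Per-feature score.**  For pair (P, N), orient the feature so higher is
  more P-like (direction = +1 iff mean(P) ≥ mean(N) on the training values;
  the tie goes to +1).  Then `DSI = FN/(FN+FP)` with `FN` the fraction of P
  training values *strictly below* x and `FP` the fraction of N values *at
  or above* x.  The strict-< / inclusive-≥ convention is fixed so a counting
  oracle can match bit for bit.  When `FN + FP = 0` (x falls in a gap
  between fully separated samples) the score is defined as 0.5
  (uninformative).  Empirical distributions are used raw — no kernel or
  parametric smoothing — because the smallest training group (VaD, n = 10)
  makes density estimation fragile and counting is exactly testable.
* **Binary features** (APOE carrier, PET visual read) use Laplace-smoothed
  (add-one) group frequencies: `DSI(x) = p̂_P(x) / (p̂_P(x) + p̂_N(x))`.
* **Relevance.**  A feature's weight in a pair is the maximum Youden index
  (sensitivity + specificity − 1) over all thresholds on the training data,
  clamped at 0.  Identical group samples get exactly 0, fully separated
  samples exactly 1.  Weights enter linearly; a `relevance_exponent`
  parameter (default 1) exists for sensitivity analysis because it is not
  recoverable whether the original tool weights by relevance or its square.
* **Missing data.**  Features missing for a patient are skipped from the
  weighted mean; a pair with no observed positive-relevance feature is
  undefined and is skipped from the group average.  This gives the exact
  contract: a profile with feature f missing equals the profile with f
  removed from the feature selection.
* **Aggregation.**  Six unordered pairs cover the four groups; each pair is
  fitted once and the reverse orientation is obtained as 1 − value (exact
  anti-symmetry away from training points, and the missing-data contract is
  preserved).  The per-group DSI is the mean of the three pairs containing
  the group.  The top label is the argmax with a deterministic canonical
  tie-break CN < AD < FTD < VaD and an explicit tie flag; the margin is the
  difference of the two highest values.
* **Feature set.**  The classifier trains on APOE, neuropsychology (MMSE,
  RAVLT learning/recall, animal fluency, TMT-A/B, NPI) and six quantified
  MRI markers.  Age and sex are carried in the data model but excluded from
  the evidence by default (togglable); MRI markers are consumed as
  already-normalized values.  PET (visual read or Centiloid), when enabled,
  enters all six pairwise comparisons like any other feature.
* **Cross-validation.**  Five label-stratified folds; members of each group
  are shuffled by the seeded generator and dealt round-robin, which keeps
  the 10 VaD patients spread 2-per-fold and still works for groups smaller
  than k.  Each patient is scored exactly once by models fitted on the
  complementary folds.

## Probability of correct class

The certainty of a profile is read off a reference database of
(dmax, margin, correct) triples obtained by cross-validating a labelled
reference cohort.  "Comparable cases" are operationalised as the k_ref = 50
nearest neighbours after dividing each coordinate by its reference-set SD
(a zero-spread coordinate is ignored); the PCC is their fraction correct.
The estimate does not condition on the predicted label.  One database is
built per feature configuration (without PET / with PET), because adding a
strong feature shifts the DSI geometry.  The published 770-patient reference
cohort is private, so the default reference is a synthetic cohort with the
published composition (308/338/89/35).  Optional isotonic smoothing of
correctness over margin (off by default) yields a PCC monotone in margin.

The calibration report bins held-out estimated PCCs into ten equal-width
bins ([0, 0.1), …, [0.9, 1.0]; empty bins omitted) and compares each bin's
mean estimated PCC with its empirical accuracy.  With matched 2,000-patient
reference and held-out cohorts the per-bin gap statistic carries binomial
noise of 2–5 pp (bins hold roughly 100–1,300 patients), so individual-seed
maxima fluctuate in the 0.02–0.08 range around an essentially unbiased
centre; across seeds the mean per-bin gap is within ±2 pp everywhere.

## Decision scenarios

All scenarios share one certainty rule, PCC ≥ τ (default τ = 0.75; the
inclusive comparison is used consistently in every step, and the sweep grid
admits τ up to 1.0).  Scenario A follows the three-step hypothetical-PET
flow; the step-3 diagnosis is taken from the PET-augmented profile, so the
suggested label may legitimately flip relative to baseline once the scan
result is known.  Scenario B is the baseline test only; scenario C adds PET
for AUC-positive patients (in synthetic cohorts the AUC flag is sampled per
group at the published rates — 4/75/61/60% — because pre-PET clinician
confidence cannot be simulated from summary statistics; `classify_auc`
implements the two published clauses for real data); scenario D adds PET for
everyone.  Group labels 1–4 (directly certain / PET not useful / PET
helpful / not diagnosed despite PET) are native to scenario A; for B–D the
same semantics are applied (diagnosed-without-PET = 1, etc.) so the
invariants group ⇒ (scanned, diagnosed) hold uniformly.  A patient whose
flow reaches step 3 without an available PET value is an error, not a
silent skip — in Centiloid mode this means full-cohort scenarios D/C require
complete Centiloids (the default generator leaves 13% missing, matching the
published availability).

## Synthetic cohorts

The generator emulates the published per-group summary statistics: group
sizes 135/108/33/10; continuous features as truncated normals on their
physical ranges (MMSE [0, 30], TMT > 0, cMTA [0, 4], cGCA [0, 3],
AD-similarity [0, 1], volumes ≥ 0); sex, APOE, visual read and AUC flag as
per-group Bernoulli draws at the exact published count fractions; Centiloid
conditional on the sampled read, with read-specific normals whose mixture
reproduces the published group marginal means within 10% (the conditional
split is unidentifiable from published marginals and is a config choice);
missingness completely at random at the published per-feature rates
(MMSE 1% … NPI 26%, Centiloid 13%, visual read 0%).

Two deliberate numerical choices:

* **Mean-matched truncation.**  The truncated normal's location parameter is
  solved (Brent root-finding on the analytic truncated mean) so the realized
  mean equals the configured one.  A naive truncated or clipped normal is
  biased wherever a bound sits within ~2 SDs of the mean (control MMSE
  28 ± 2 truncated at 30 would have mean 27.4); matching the location keeps
  the generator faithful to the published means, which is what the summary
  tests assert.  Realized SDs are those of the truncated distribution and
  hence somewhat smaller than the configured parent SDs near active bounds.
* **Independence within patient.**  No covariances are published, so
  features are sampled independently per patient by default.  Real cognitive
  and imaging markers are strongly correlated; independent features carry
  more joint information, so synthetic cohorts are *easier* to classify than
  the clinical population (cross-validated accuracies around 85% without
  PET, and higher shares of directly certain patients).  Consequently,
  passing tests demonstrate the correctness and internal consistency of the
  pipeline — partition identities, dominance of the computer-supported
  policy over no-PET, monotone cutoff curves, calibrated PCC — not the
  published cohort's headline proportions.  An optional Gaussian-copula
  severity factor (`severity_loading`) induces realistic positive
  correlations for sensitivity analyses while preserving every marginal
  exactly via the probability-integral transform.

The separable fixture cohorts put group means `gap` unit-SDs apart on
orthogonal synthetic axes with uninformative PET/AUC attributes: gap 0 is a
pure negative control (chance accuracy, 25%), gap 10 a positive control
(near-perfect accuracy; almost no patient needs PET, so the enrichment rule
should advise almost none).

## Degenerate inputs and tie-breaks

Exact DSI ties resolve to the canonical order with `tie_flag` set; a patient
with no usable feature in any pair raises an error naming them; a group
summary over an empty group or an all-missing feature reports n = 0 with
undefined statistics rather than raising; PCC queries outside [0, 1] are
rejected; reference databases must be non-empty, and k_ref is capped at the
database size.

## Known limitations

* The per-feature DSI form and the relevance weighting are declared
  reconstructions of a tool whose exact smoothing details are unpublished;
  they match its documented behaviour but are not claimed identical.
* The PCC neighbourhood rule (kNN, k = 50) is one reasonable reading of
  "comparable cases"; alternatives (kernel weights, conditioning on the
  predicted label) are out of scope.
* Synthetic cohorts have no inter-feature correlation by default, no
  longitudinal structure, no scanner/site effects, and only MCAR
  missingness.
* DLB, MCI and other diagnoses outside {CN, AD, FTD, VaD} are not modelled.
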