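# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `fibrodefer`. It describes what the
code computes; every number quoted in the README is produced by the code
itself.

## Ordinal encoding and decoding

Staging is decomposed into four nested binary tasks; a stage *s* becomes the
cumulative bit vector (1[s≥1], …, 1[s≥4]). Decoding returns the largest
task index whose probability *strictly* exceeds the cut-off (default 0.5):
a component exactly at the cut-off does not fire, and a vector with no
exceeding component decodes to S0 — including vectors like
(0.4, 0.45, 0.1, 0.0) whose mass suggests mid-stage disease; the rule is
applied literally, with no isotonic projection of non-monotone vectors.
Both choices are deliberate: the decoder is a fixed, auditable rule, and any
repair of inconsistent vectors belongs upstream in the classifier.

## Decision model

For one task, with confidence score *z*, binarised reader opinion *h* and
binarised truth *y*:

* **Factorisation.** p(z, h=a | y=b) = p(z | h=a, y=b) · p(h=a | y=b).
* **Reader priors.** p(h=a | y=b) = (n_{ab} + s) / (n_b + 2s) with add-λ
  smoothing s (default 0.5). Unsmoothed priors can be exactly zero on small
  tuning sets, which silently zeroes whole advantage branches; the default
  keeps every branch informative while perturbing well-supported priors
  negligibly.
* **Discretized KDE.** Scores are binned into T uniform bins over [0, 1]
  (half-open, last bin closed so z = 1 is included). Raw counts get a
  pseudocount κ per bin, then a discrete Gaussian kernel of SD σ (in
  bin-index units, truncated at ±⌈4σ⌉) is applied with per-source-bin
  renormalisation, so no mass leaks outside the support and the total is
  preserved to 1e-9; the result is normalised. Adding κ *before* smoothing
  keeps the smoother linear and makes the κ→∞ limit exactly uniform. The
  kernel family and edge handling are this package's choice — a
  Gaussian-on-bins estimator is the simplest smoother with a single
  interpretable bandwidth. An empty (h, y) cell with κ = 0 falls back to
  the uniform density with a logged warning rather than erroring, so grid
  search never crashes on sparse cells.
* **Advantage rule.** Defer iff Advantage(z) ≥ 0, boundary included. The
  rule is provably the argmax of the expected contribution to
  λ·Sens + (1−λ)·Spec over {adopt, defer} computed from the fitted
  discretized joint; the test suite checks this equivalence by brute-force
  enumeration on randomized models.
* **Routing.** ŷ ∈ {S0, S1} routes to D2–4 only (there is no deferral gate
  on the S0-vs-S1–4 task, so no D1–4 model exists); ŷ = S2 → D2–4 ∧ D3–4;
  ŷ = S3 → D3–4 ∧ D4; ŷ = S4 → D4. Two-model routes adopt only on
  unanimity. The decision log records, per case, the decoded stage, the
  consulted sub-models, their advantages and the final stage; the audit of
  "positive impact" is computed from this log.
* A deferred case without a reader stage raises a data error; the
  retrospective data model assumes every case was read.

## Hyperparameter tuning

Each sub-model is tuned independently on its binarised task by exhaustive
search over (θ, λ, κ, T, σ). For each grid point the densities are
re-fitted, the combined system simulated (AI call z > θ when adopted,
reader call when deferred) and scored with λ·sens + (1−λ)·spec, the grid
point's λ serving as both the advantage weight and the evaluation weight.
Named operating points pin λ: OP1 = 0.67 (sensitivity-leaning),
OP2 = 0.33 (specificity-leaning). Default grids: θ ∈ {0.05, …, 0.95} step
0.05; λ ∈ {0.1, …, 0.9} step 0.1; κ ∈ {0, 0.5, 1, 2}; T ∈ {5, 10, 20};
σ ∈ {0, 0.5, 1, 2}. Sentinel candidates (never defer / always defer) are
included by default so the search can recognise the degenerate optima of a
perfect classifier or a perfect reader. Ties are broken deterministically:
lowest deferral rate, then smaller T, σ, κ, then θ closest to 0.5 —
cheaper and simpler policies first. Sensitivity or specificity of an empty
class is defined as 1 with a warning.

## Synthetic cohort generator

The generator emulates the joint structure (z, h, y) that the decision
model consumes:

* Truth stage y ~ Categorical(prevalence); default
  (0.37, 0.10, 0.12, 0.08, 0.33) — a tertiary-care staging mix with many
  S0 work-ups and many cirrhotics and thin mid stages.
* Latent severity u = y + N(0, τ²); confidence
  z_k = logistic((u − (k − 0.5)) / s). A shared latent with increasing
  thresholds yields component-wise non-increasing, approximately calibrated
  confidences; τ (default 0.8, task AUCs ≈ 0.95–0.99) controls
  discrimination and s (default 0.3) confidence sharpness. τ = 0 with tiny
  s gives a perfect classifier.
* Reader h drawn from a 5×5 row-stochastic confusion matrix. Published
  reader-level confusion matrices are not available for this setting, so
  the default is **illustrative**: ~60–80% diagonal with adjacent-stage
  errors, harder early stages. Three-level clinical reads (basically normal
  S0–1 / chronic liver disease S2–3 / cirrhosis S4) are derived by
  coarsening; re-refinement of the S2–3 band is emulated by a configurable
  Bernoulli split (default 0.5), since the original refinement was a human
  second read.
* Markers (AST, ALT, PLT, age) from stage-conditional normals truncated to
  positive values (transaminases rising, platelets falling with stage), and
  a liver-stiffness-like score from a stage-conditional log-normal
  (medians 4.8–18 kPa). Markers are drawn independently of z given y: only
  their formulas, not their correlation with the classifier, are in scope.
* One global seed spawns fixed per-component substreams (truth, latent,
  reader, markers, auxiliary), so adding a field never perturbs earlier
  draws; the same seed and config reproduce a byte-identical cohort file.

What the generator does **not** emulate: scanner/protocol covariates,
reader confidence, marker–classifier correlation, and any real-data
idiosyncrasies (missingness, label noise from biopsy sampling error).
Passing tests on synthetic cohorts therefore validate the *mechanics* of
the decision layer — not clinical performance on patient data.

## Toy classifier and test-time adaptation

The classifier is a normalization layer (x̂ = γ(x − μ)/√(σ² + ε) + β)
followed by a tanh hidden layer and four task logits, trained full-batch
with Adam (default step 1e-2 with step decay — halved every 100 of 300
epochs — and weight decay 1e-4) on the summed task-wise binary
cross-entropy. Because normalization is at the input, μ and σ² depend only
on the data and are fixed throughout training.

Test-time adaptation recomputes (μ, σ²) from the unlabeled target batch and
runs plain gradient descent (default 10 steps, step 1e-2) on (γ, β) only,
minimizing the mean prediction entropy −Σ_k [p ln p + (1−p) ln(1−p)]
(natural logarithm; the per-task Bernoulli form, summed over the four
tasks). Both mechanisms — statistics recomputation and entropy-driven
affine updates — are applied, matching the common practice for
normalization-layer adaptation; all other weights are bit-identical after
adaptation, and labels are never consulted. The step count and size are
configurable; no stopping rule is applied beyond the fixed budget.

The covariate-shift fixture draws stage-conditional Gaussian features
(stage means along a fixed direction, unit covariance) and maps the target
domain through x → 1.5x + (2.5, −1.5, 2.0, 1.0) — a scale change plus an
offset of several within-class SDs. A source-trained model degrades
substantially on the target and recovers after adaptation, which is the
behaviour the fixture is designed to exhibit; an identity shift leaves
accuracy within ±0.02.

## Diagnostic statistics

* **Sens/spec CIs** use the case bootstrap (percentile, default B = 2000,
  clipped to [0, 1]). A single closed form cannot reproduce all published
  CI styles for proportions, so the method and B are configurable and
  recorded in each report.
* **AUC** is the midrank Mann–Whitney statistic (ties one half); the
  DeLong paired comparison uses the structural-components variance and a
  two-sided normal p. Identical inputs give z = 0, p = 1 by definition.
* **Obuchowski index**: weighted mean of all pairwise-category AUCs;
  default weights n_i·n_j (each pair weighted by its case support), with
  an equal-weights option — the weighting is always stated in the report.
  CI by case-jackknife with a normal approximation. The difference test is
  a paired z on the jackknife variance of the index difference; a label-swap
  permutation test is provided as an alternative. Equivalence uses TOST
  against a user-supplied margin — no default margin is assumed.
* **Matched operating points**: among candidate thresholds, those whose
  fixed metric is non-inferior to the reference are kept and the free
  metric maximised; infeasibility is reported, not raised.
* **Positive impact** of a deferral = final (reader) stage equal to the
  truth, or strictly closer in absolute ordinal distance than the AI stage;
  equal distances do not count.
* Rounding half-up to the printed precision is applied only in report
  rendering; internal values keep full precision.

## Degenerate inputs and tie-breaks (summary)

Empty density cells → uniform with warning; empty sens/spec classes → 1
with warning; advantage exactly 0 → defer; decode exactly at cut-off → does
not fire; grid ties → deterministic preference order; z = 1 → last bin;
bootstrap CIs clipped to [0, 1].

## Problem sizes

Tests and the acceptance script run at desk scale by design: cohorts of
400–2000 cases, 120 randomized oracle models, 1000-case source/target
fixtures, 50-set property sweeps. These sizes give stable Monte-Carlo
behaviour for every property checked while keeping a full run in seconds.

## Known limitations

* Reader confidence is not modelled; the decision uses only the AI score.
* The reference tables bundled for arithmetic checks contain two cells
  whose printed values are inconsistent with their own bracketed fractions;
  they are flagged in the fixture and excluded from the exact-match
  contract (see the acceptance test's docstring).
* The Obuchowski comparison is one reasonable choice among several; rank
  tests applied directly to index values are not well defined and are not
  guessed at.
* Hyperparameter search is exhaustive only; no continuous optimisation.
* The ordinal machinery is parameterized for five stages; other stage
  counts are supported in encoding but untested beyond five.
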