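# fibrodefer

An ordinal learn-to-defer toolkit for noninvasive liver fibrosis staging.

Liver fibrosis is graded on the Scheuer scale S0 (none) to S4 (cirrhosis).
AI staging models and human readers have complementary strengths — models
tend to do better on early fibrosis, experienced readers on cirrhosis — so a
practical system should decide, case by case, whether to adopt the model's
prediction or defer to the reader. `fibrodefer` implements that decision
layer, imaging-free: it consumes a model's confidence scores, a reader's
staged opinion and (for tuning/evaluation) the histological truth, and is
aimed at biostatisticians and clinical-AI researchers studying human–AI
complementarity in ordinal diagnosis.

## The model

**Ordinal encoding.** Stage *y* ∈ {0,…,4} is represented by four nested
binary tasks (S0 vs S1–4, S0–1 vs S2–4, S0–2 vs S3–4, S0–3 vs S4): bit
*k* = 1 iff *y* ≥ *k*. A probabilistic classifier emits one confidence score
*z<sub>k</sub>* per task; the predicted stage ŷ is the highest *k* with
*z<sub>k</sub>* > 0.5.

**Deferral rule.** For one task with reader opinion *h* and truth *y*
(both binarised), call threshold θ and trade-off λ ∈ [0,1], the advantage of
deferring a case with score *z* is

```
Advantage(z) =  (1−λ)·p(z, h=0 | y=0) − λ·p(z, h=0 | y=1)     if z > θ
             = −[(1−λ)·p(z, h=1 | y=0) − λ·p(z, h=1 | y=1)]   if z ≤ θ
```

and the case is deferred iff Advantage(z) ≥ 0. This is exactly the sign of
the expected gain, under the fitted joint of (z, h, y), of the reader's call
over the AI call in the objective λ·Sensitivity + (1−λ)·Specificity. The
joint factorises as p(z, h=a | y=b) = p(z | h=a, y=b)·p(h=a | y=b); the
reader priors come from smoothed counts and p(z | h, y) from a discretized
kernel density estimate (T uniform bins, pseudocount κ, discrete Gaussian
bandwidth σ). Hyperparameters (θ, λ, κ, T, σ) are tuned per sub-model by
exhaustive grid search on a tuning cohort.

**Composite policy.** Three sub-models D2–4, D3–4 and D4 gate the three
clinically meaningful endpoints. Routing follows ŷ: S0/S1 → D2–4 on
*z<sub>2</sub>*; S2 → D2–4 and D3–4; S3 → D3–4 and D4; S4 → D4. On
two-model routes the AI stage is adopted only if both sub-models agree;
otherwise the final stage is the reader's.

**Test-time adaptation.** A toy ordinal classifier (normalization layer +
two-layer perceptron, summed task-wise binary cross-entropy) demonstrates
unsupervised adaptation to covariate shift: normalization statistics are
recomputed from the unlabeled target batch and only the layer's affine
parameters (γ, β) are updated by gradient descent on the Shannon entropy of
the predictions; all other weights stay frozen.

**Statistics.** Sensitivity/specificity with bootstrap CIs, empirical AUC
with DeLong's paired comparison, the Obuchowski index (weighted mean of all
pairwise-category AUCs; reduces to AUC for binary truth) with jackknife CI,
difference and TOST equivalence tests, matched-operating-point contrasts,
deferral audits, and the serum indices APRI = AST/PLT and
FIB-4 = Age·AST/(PLT·√ALT).

## Worked example

Cohorts here come from the bundled simulator (no real patient data is
shipped): truth stages from a configurable prevalence, ordinal confidences
from a latent-severity logistic link, reader opinions from a confusion
matrix, serum markers from stage-conditional distributions.

```sh
fibrodefer simulate --seed 7 --n 1000 --out tuning.csv
fibrodefer simulate --seed 8 --n 500  --out test.csv
fibrodefer tune  --cohort tuning.csv --op-name OP1 --policy-out op1.json
fibrodefer apply --cohort test.csv --policy op1.json --log-out log.csv
fibrodefer evaluate --log log.csv --cohort test.csv --report-out report.json
```

With a reduced grid (θ ∈ {0.3,…,0.7}, T = 10, κ ∈ {0.5, 1}, σ ∈ {0.5, 1})
this prints:

```
OP1: tuning objective 0.9605, deferral rate 0.317
deferral rate 0.326 (163/500 deferred)
Obuchowski (final stage) 0.936; adoption 67.4%
```

The tuning objective is the mean over the three sub-models of
λ·sens + (1−λ)·spec on the tuning cohort (λ = 0.67 for OP1). On the test
cohort, 163 of 500 cases were deferred to the reader (adoption 67.4%), 109
of them with positive impact (the reader's stage equal to, or ordinally
closer to, the truth than the AI's). The report JSON carries the per-endpoint
detail — e.g. significant fibrosis (S2–4): sensitivity 0.94, specificity
0.94, confidence-score AUC 0.982 — and the Obuchowski index of the combined
system, 0.936 (95% CI 0.923–0.949).

`fibrodefer train-toy` and `fibrodefer tta-demo` exercise the toy classifier
and its test-time adaptation on a covariate-shifted feature fixture.

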