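# Methods

This note documents the generative model behind the synthetic EHR data, the
estimators, and the numerical and design choices, in enough detail to
reproduce or re-derive every number the package computes.

## Estimand and estimators

The estimand is a risk difference: the mean difference in hospitalization
probability with versus without exposure, over the analyzed cohort. With
stored potential outcomes the finite-sample truth is τ = mean(y1) − mean(y0)
over the persons entering a contrast; all recovery claims are made against
this quantity, not a super-population limit.

Three estimators are implemented:

* **unadjusted** — difference in arm means;
* **one-hot IPTW** — L1-penalized logistic propensity on the sparse
  code/demographic indicator matrix, weights 1/p (treated) and 1/(1−p)
  (comparator), Hájek-normalized weighted difference;
* **embedding IPTW** — random-forest propensity on the averaged concept
  embedding plus demographics, same weighting.

The Hájek (normalized) form is used rather than Horvitz–Thompson: it is
invariant to constant rescaling of the weights (so equal weights reproduce
the unadjusted estimator exactly, a tested identity) and has smaller
variance with heavy-tailed weights. HT remains available via
`iptw_ate(..., normalized=False)`.

**Positivity.** Predicted propensities are clipped symmetrically into
[ε, 1−ε], ε = 0.01 by default. The generator's calibration (below) keeps
true any-drug propensities inside roughly [0.10, 0.90], so clipping is a
guardrail rather than an active truncation.

## Bootstrap inference

CIs come from a stratified nonparametric bootstrap: persons are resampled
with replacement *within each arm* (arm sizes preserved), the propensity
model is refit on every replicate, and the 2.5/97.5 percentiles of the B
replicate ATEs form the CI (B = 100 by default). The full-sample estimate is
the reported point estimate. A replicate whose refit degenerates is redrawn,
capped at 10·B attempts.

Inside replicates the L1 strength is fixed to the value selected on the
full sample (a reduced grid); re-running model selection inside each of 100
replicates roughly octuples cost while changing the selected strength
almost never.

Two p-values are reported. The sign-count bootstrap p with a continuity
correction, 2·min(#{θ*≤0}+1, #{θ*≥0}+1)/(B+1), is bounded below by
2/(B+1) ≈ 0.02 at B = 100 and therefore cannot express strong evidence; the
headline p is instead the normal approximation 2·Φ(−|θ̂|/SE*) using the
bootstrap standard error. Both appear in the results tables (`p`, `p_sign`).

## The synthetic generator

Each person has a latent health state z ~ N(0, I₄). Observables express z:

| parameter | default | meaning |
|---|---|---|
| `n_latent` | 4 | latent health factors |
| `treat_coefs` | (0.4, 0.4, 0, 0.2) | per-factor log-odds for every drug flag |
| `outcome_coefs` | (1.0, 0, 1.0, 0.5) | per-factor log-odds for hospitalization |
| `treatment_effect` | −0.5 | log-odds shift of the outcome under exposure |
| `base_outcome_rate` | 0.20 | target mean of y0 (intercept calibrated by root-finding per sample) |
| `n_drugs` | 16 | drug flags, 4 mechanism classes, independent given z |
| `drug_intercept_base/step` | −4.0 / 0.08 | per-drug prevalence gradient (mimics unequal prescription volumes) |
| `code_signal` | 1.5 | log-odds loading of a code on its factor |
| `code_base_range` | (−3.5, −1.5) | per-code base log-odds (uniform), ≈ 70 codes/person at 500 codes |
| `missing_severity_frac` | 0.3 | nonhospitalized persons with a missing severity score |
| `nc_prevalence` | 0.15 | prevalence of the 5 negative-control codes |

Codes are partitioned into factor territories by chunking them in top-level
subtree order of the ontology, so codes in the same subtree load on the same
factor wherever possible while every factor is guaranteed territory even
when the root has fewer children than there are factors. (Assigning factors
by subtree index alone can leave a factor with no codes — an unmeasurable
confounder by construction — which defeats the purpose of a recovery test.)

Potential outcomes use a shared-uniform coupling: one u ~ U(0,1) per person
thresholds both sigmoid(a + c·z) and sigmoid(a + c·z + effect). Hence
`treatment_effect = 0` gives y1 ≡ y0 exactly, and the coupling is monotone.
The observed outcome is y1 for anyone exposed to ≥ 1 study drug, else y0,
and the 5-level severity score is drawn consistently with it (levels 3–5 iff
hospitalized; a configurable fraction of the nonhospitalized get a missing
score, exercising the missing→nonhospitalized rule downstream).

Demographics: age and gender are correlated with z (true confounders
flowing through the same latent state); race, ethnicity and zip3 are
exogenous. ~2% of zips are missing and history lengths are uniform on
[0, 5) years, so the eligibility filters have real work to do.

**Calibration.** The default coefficients were calibrated once, by
simulation at n = 20,000, to produce (a) an unadjusted any-drug bias of
about +0.06 — comfortably past the ≥ 0.05 the recovery experiment requires —
while (b) keeping true propensities away from 0/1 (weighting by the *true*
propensities recovers τ to ≈ ±0.005) and (c) making code histories
informative enough that the one-hot model removes most confounding (IPTW
error ≈ +0.008 ± 0.005). Earlier, stronger treatment coefficients pushed
any-drug propensities past 0.99 and even oracle weights failed; weak code
signal leaves residual confounding that no estimator can remove. Both
failure modes are worth knowing about when changing these knobs.

**What the generator does not emulate.** Real code co-occurrence structure,
visit/temporal dynamics, dose and duration, informative missingness beyond
the severity score, per-drug heterogeneous effects (all drugs share one
`treatment_effect`), and OMOP identifier semantics. Passing tests show the
estimators behave correctly *when the propensity model's covariates span the
confounders*; they say nothing about unmeasured confounding in real data.

## Embeddings

Concept vectors are trained on the synthetic ontology by uniform random
walks (10 walks/node, length 40) and skip-gram with 5 negative samples
(window 5, one epoch over shuffled pairs, linearly decaying learning rate,
unigram^0.75 negative distribution), i.e. the p = q = 1 special case of
node2vec, implemented in numpy, single-threaded and exactly reproducible
for a fixed seed. The only property the pipeline relies on is walk
locality — graph-adjacent codes embed closer than random pairs (measured:
mean cosine 0.97 vs 0.40 at 500 nodes) — since a patient is represented as
the mean of their distinct code vectors. Dimension defaults to 128, the
size of the pretrained clinical-concept embeddings this table stands in
for; other hyperparameters are ordinary skip-gram defaults, not tuned.

Duplicate codes are collapsed before averaging (the history is a set);
multiplicity-weighted averaging is available via
`embed_patient(..., collapse_duplicates=False)`. In embedding mode the
design matrix appends raw age (one numeric column) and one-hot categorical
demographics to the 128-dim vector, so both propensity models condition on
the same confounder set; in one-hot mode age enters as 10-year bins.

## Numerical choices

* **L1 grid (0.3, 3.0), 3-fold CV on log-loss.** Strengths below ~0.1
  overshrink the propensity toward the marginal treated fraction; this can
  *win* on predictive log-loss while badly under-correcting the weights
  (observed: C = 0.03 gave IPTW error +0.047 where C = 0.3 gave +0.007).
  The grid therefore spans mild regularization only.
* **liblinear tol 1e-2.** Loosening the solver tolerance from 1e-4 changes
  the ATE by < 0.001 at both n = 5,000 and n = 20,000 while cutting fit time
  30–100×; this is what makes refit-per-replicate bootstraps routine.
* **Random forest: 200 trees, unlimited depth, min 25 samples/leaf,
  single-threaded, seeded.** The leaf-size floor keeps leaf probabilities
  from memorizing labels.
* **Degenerate inputs.** Zero-variance covariates report SMD 0 with a flag;
  constant-outcome negative controls are reported inestimable rather than
  raised; empty cohort arms fail loudly with the contrast name; unseen codes
  at transform time are dropped with a logged count, and patients with no
  embeddable codes are excluded and counted.

## Design choices

* **Clean comparator (default).** "Not taking the drug of interest" could
  admit users of other study drugs into the nonuser arm; the default
  excludes users of *all* retained study drugs, avoiding same-class
  contamination. `comparator="drug_only"` restores the literal reading.
* **Active comparator excludes dual users** (standard practice), and the
  16×16 grid's antisymmetry ate(A,B) ≈ −ate(B,A) is reported, not enforced —
  independent refits break it except for the unadjusted estimator, where it
  is exact.
* **Drug retention is applied after eligibility-independent counting** of
  distinct users per drug, with a threshold scaled to population size
  (default 50 for desk-scale runs; the enclave-scale rule is > 5000).
* **Negative-control outcomes are removed from their own confounder set**
  (vocabulary column and embedding average) so the analysis never
  conditions on its outcome.
* **Coverage experiment design.** The bootstrap-calibration study fixes
  n = 5,000 and B = 100 and asks whether the 95% percentile CI covers the
  true (zero) effect at its nominal rate. It uses randomized assignment
  (`treat_coefs = 0`) with the full refit pipeline: at n = 5,000 the one-hot
  estimator carries residual confounding bias of ≈ +0.02 (≈ 1.7 SE) under
  the default confounded conditions, so coverage there would measure that
  bias, which the recovery study already quantifies at n = 20,000, rather
  than CI calibration.
* **Index dates.** The generator guarantees all code events are pre-index;
  no date filtering is performed downstream.

## Problem sizes used by the validation suite

Recovery: 20 seeds at n = 20,000 with 500 codes. Randomized-arm agreement:
one draw at n = 20,000 with all three estimators. Coverage: 40 simulation
reps at n = 5,000, B = 100. Negative controls: 10 seeds × 5 controls at
n = 5,000, B = 100. Oracle balance: one draw at n = 20,000. The analysis
drivers run a single narrative study at n = 5,000. These sizes were chosen
so the full validation completes on one core in a few minutes while keeping
each check's noise floor well below its tolerance.

## Known limitations

* The embedding path is validated for calibration (randomized arms) and
  shape/permutation properties, not for confounding *removal*: a mean of
  code vectors compresses the history, and with only 128 dimensions the
  propensity model can miss code-level confounders. This mirrors the known
  caveat of embedding-based propensity scores and is why the one-hot path
  is the reference estimator here.
* Bootstrap p-values at B = 100 are floor-limited (sign-count) or rely on a
  normality approximation (headline); neither is exact.
* The generator's independence of drug flags given z makes "any drug"
  prevalence high (~45%) relative to single drugs; per-drug nonuser
  contrasts at desk scale have small treated arms and correspondingly wide
  CIs.
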