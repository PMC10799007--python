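# Methods

This note documents the models, algorithms, default parameters and design
choices in `revlearn`, and what the synthetic-data checks do and do not
establish about real data.

## Task model

The task presents two shapes; exactly one is rewarded per trial.  A
`TaskDesign` fixes the block structure: by default 80 stable trials with the
high-probability shape rewarded at p = 0.75 and 100 volatile trials at
p = 0.80 with the identity of the high shape reversing every 20 trials
(volatile length must divide evenly into runs).  Outcomes are *coupled*: one
Bernoulli(p_high) draw per trial puts the reward on the high or the low
shape, making the two shapes' reward probabilities complementary (75/25,
80/20).  Independent per-shape draws were rejected because the printed
contingencies are complementary and the task family this design descends
from uses coupled schedules.  The high-shape trajectory is deterministic
given the design; only outcome draws consume the seed, so schedules with the
same seed are bit-identical and different seeds share the reversal
structure.  Block order is exposed as a flag (default stable-first);
downstream analyses are order-agnostic.  Non-response trials are not
simulated; real-data loaders drop them (with a logged count) before fitting.

## Observation models

All models start from v_A = v_B = 0.5, the midpoint of the binary outcome
range, so the first choice is at chance and the first prediction error is
symmetric for reward and punishment (the initial value is a config knob:
`FitConfig.v0`).  Updates touch only the chosen option.

- **RP**: v_c ← v_c + α⁺(R − v_c) after reward, v_c ← v_c + α⁻(R − v_c)
  after non-reward, α⁺, α⁻ ∈ [0, 1].  The branch is selected by the realized
  outcome (reward = 1 = positive feedback), not by the sign of the
  prediction error.
- **RW**: the same rule with a single α.
- **EWA**: per-option experience weight n (init 1) with decay ρ, value decay
  φ: n′ = ρn + 1, v′ = (φ n v + R)/n′, with φ, ρ ∈ [0, 1].  The exact EWA
  and RW parameterizations follow the conventions of the hierarchical-
  Bayesian fitting package standard in this literature; they are convention
  choices, not quantities defined by this package's own contribution.

Choice is softmax on the value difference: P(A) = σ(β(v_A − v_B)), β ≥ 0,
computed in an overflow-safe form (no overflow for |β·Δv| ≤ 700).  The
likelihood of a subject's sequence advances the state *after* each trial's
feedback, so trial t's probability uses values learned through t − 1.

## Hierarchical estimation

Fits are per treatment × context cell — four independent fits — matching
the design in which each cell's parameters are estimated separately.  For
each model parameter k: group location μ_k ~ N(0, 1) and scale
σ_k ~ N(0, 0.2) truncated at zero (a scale cannot be negative; the printed
normal prior on σ is read as half-normal).  Subject deviates are
non-centered, z_sk ~ N(0, 1), and the native value is ub_k · Φ(μ_k + σ_k
z_sk) with ub = 1 for unit-interval parameters and ub = β_max = 10 for the
inverse temperature (`FitConfig.beta_max`).  σ is sampled on the log scale
with the Jacobian folded in.

Sampling is static-trajectory **Hamiltonian Monte Carlo** with analytic
gradients: the per-subject likelihood gradient is propagated forward through
the value recursion (exact forward-mode accumulation) in numba-compiled
kernels, and the chain rule through Φ adds the hierarchical part.  Warmup
adapts the step size by dual averaging (target acceptance 0.8) and estimates
a diagonal mass matrix from the first warmup half; the leapfrog path length
is jittered uniformly in [16, 32] steps to avoid resonances.  Chains run
sequentially and are deterministic given the seed.  Defaults are 4 chains
with 1000 + 1000 draws; the internal experiments use 4 × (500 + 500) for
the convergence check and 2 × (300 + 300) for recovery studies — problem
sizes chosen so the full battery runs comfortably on one CPU while leaving
the checks' conclusions unchanged.

Convergence is reported, never enforced: `fit_hierarchical` returns split-R̂
for every group-level and subject-level parameter and leaves the decision to
the caller (the conventional threshold is 1.1).  Split-R̂ is the classic
half-chain potential-scale-reduction factor; constant draws return NaN as a
flagged sentinel.  Model comparison uses PSIS-LOO (via arviz) on a
per-subject pointwise log-likelihood — the leave-one-out unit is the
subject, each entry the sum of that subject's trial log-likelihoods, which
matches the granularity conventional for hierarchical subject models; the
arrangement is a documented choice, and LOOIC = −2·elpd_loo.  A warning is
attached when more than half the Pareto k exceed 0.7.  Posterior-predictive
accuracy simulates every subject on a schedule for a thinned set of draws
and averages the optimal-choice indicator per trial.

## Synthetic cohort

`default_effect_config()` encodes the orderings the analysis is built to
detect, with native-scale cell means (mean ± between-subject SD in
parentheses; SDs α: 0.15, β: 1.0):

| parameter | OT stable | PLC stable | OT volatile | PLC volatile |
|-----------|-----------|------------|-------------|--------------|
| α⁺        | 0.30      | 0.30       | 0.75        | 0.60         |
| α⁻        | 0.20      | 0.30       | 0.65        | 0.50         |
| β         | 5.5       | 4.0        | 2.5         | 2.5          |

These means are **this package's own choices** with moderate effect sizes;
no published native-scale means exist for them.  The within-cell SDs are
likewise defaults ("realistic individual differences" in this literature
span a substantial fraction of the native range) and are exposed in
`CohortSpec.sds`.  A `null_config()` sets all cells equal for calibration
studies.  Parameters are truncated normals on the native scale (truncation
bounds = native ranges) — chosen over logit-normals for transparency.  The
trait-anxiety covariate is unit-scaled (z-scores; no attempt to mimic
questionnaire score ranges) and is coupled to β through a Gaussian copula at
r = −0.27 per context, the rough mean of the two published context-wise
rank correlations.

Synthetic ERP epochs are sums of Gaussian-bump component templates plus
noise on four channels (FCz, Pz, PO7, PO8) at 250 Hz.  Injected P300 and
N2pc group means/SDs are the published group averages (3.75 ± 2.59 vs
5.57 ± 3.31 µV; −0.29 ± 0.59 vs 0.18 ± 0.70 µV); ERN/FRN amplitudes are
plausible defaults (no published group means).  Bump centers sit on the
sample grid inside each analysis window (ERN 28 ms, FRN 300 ms, P300
448 ms, N2pc 224 ms) so noiseless recovery is exact.  Noise is white by
default with a 1/f option; per-epoch DC offsets (SD 2 µV) exercise baseline
correction; an optional artifact fraction injects >80 µV excursions.
Epoch bundles are materialized lazily per subject so a full cohort never
sits in memory.

**What the synthetic checks show** — that the estimation, extraction and
inference machinery recovers known ground truth under the study's structure:
schedule statistics, parameter and model recovery, ERP amplitude recovery,
null calibration of the group test.  **What they do not show** — anything
about real EEG (no 1/f-dominated spectra by default, no ocular artifacts,
no latency jitter or component overlap) or about real behavioral data
(agents are exactly RP-generated; misspecification is unexplored beyond the
RW/EWA comparison).

## ERP extraction

Component recipes (window, electrode, polarity, contrast) are fixed in
`COMPONENTS`: ERN 0–60 ms at FCz on the incorrect−correct difference wave;
FRN 252–352 ms at FCz on negative−positive; P300 300–600 ms at Pz on the
correct-trial average; N2pc 200–252 ms on the contralateral−ipsilateral
difference at PO7/PO8 (ipsi = PO7|left + PO8|right, contra = the converse).
Baselines: −800 to −700 ms for the response-locked ERN, −200 to 0 ms for
feedback- and stimulus-locked components, and the full −100 to 0 ms
pre-stimulus span for the N2pc (its source recipe names no baseline; the
full pre-stimulus interval is the natural choice).  Numerical conventions:
"exceeding ±80 µV" is a strict inequality (boundary epochs retained); the
peak is the signed windowed extremum of the stated polarity (not a rectified
max-abs), ties broken to the earliest latency; "peak difference" is read as
the peak of the difference wave (standard difference-waveform practice),
with difference-of-peaks available behind `mode="peak_difference"`.
Scoring is per subject; inference belongs to the stats layer.

## Group statistics

The 2 × 2 mixed ANOVA decomposes the two strata separately: the between
effect is tested against subjects-within-groups, context and interaction
against the subject × context residual; all three F's have (1, N − 2)
degrees of freedom and partial η² = SS_eff/(SS_eff + SS_err).  With unequal
group sizes the main effects use unweighted (Type III) marginal means,
matching standard ANOVA software.  A two-level within factor satisfies
sphericity trivially (ε = 1), so the Greenhouse–Geisser correction is a
documented pass-through.  Simple effects are uncorrected two-sample t-tests
at one context level (no correction is prescribed by the design).  The
Fisher z test is z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)); the
subtraction order is the caller's (the CLI prints both orders, because the
published usage is ambiguous about it).  The Spearman-vs-Pearson choice is
an explicit argument, never automated normality screening.

## Reproducibility

A single global seed is expanded into per-stage child seeds through
`numpy.random.SeedSequence([seed, stage_key])`; the pipeline writes a
manifest (config echo, stage seeds, study hash, SHA-256 of every artifact)
sufficient to re-derive every output.  Fits, cohorts, schedules and epoch
bundles are all bit-reproducible from their seeds.

## Known limitations

- The HMC sampler uses static trajectories, not a dynamic
  no-U-turn criterion; heavily multimodal posteriors are out of scope
  (the non-centered hierarchical posteriors here are well behaved, with
  occasional divergences at small scales that are rejected, not silently
  accepted).
- EWA gradients assume per-option experience weights; other EWA variants
  (shared weight, attraction-scale softmax) are not implemented.
- The ERP layer operates on already-epoched data; continuous-EEG
  preprocessing (filtering, re-referencing, ICA) is deliberately outside the
  package.
- Posterior-predictive simulation is implemented for the RP/RW family only.
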