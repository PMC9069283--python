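# Methods

## The decision problem

Sequential therapy for oropharyngeal squamous cell carcinoma is modelled as a
three-stage, finite-horizon Markov decision process.  Each patient episode
carries three binary decisions:

* **D1** — induction chemotherapy (IC) or not,
* **D2** — concurrent chemotherapy (CC) or radiotherapy alone,
* **D3** — neck dissection (ND) or not.

The state at each junction is the patient's *complete* recorded history:
pretreatment features (group 1) at D1; groups 1–2 plus a one-hot encoding of
D1 at D2; groups 1–3 plus one-hots of D1 and D2 at D3.  Outcome columns
(group 4: 4-year overall survival `os`, feeding-tube dependence at 6 months
`ft`, aspiration after therapy `ar_after`) never enter a state vector — this
is enforced structurally by the stage/group layout.

Rewards are zero at D1 and D2.  The terminal reward is the composite

    r = OS − (FT + AR_after − AR_before)

whose image over binary inputs is exactly {−2, −1, 0, 1, 2}; a patient whose
pre-existing aspiration resolves while surviving scores +2.  Because reward
is terminal-only, no discount factor is applied (equivalently γ = 1).  A
survival-only mode (`outcome_mode="os"`) replaces the composite with `os`.

## Preprocessing

Parsing marks unreadable cells missing rather than dropping rows.  Single
imputation uses the training-set median (numeric) or mode (categorical); HPV
/P16 status is the one exception — unknown is a legitimate clinical state and
is coded as the distinguished value 0, never imputed.  Ordinals (grade, T, N,
AJCC stage, prescribed chemotherapy none<single<doublet<triplet<quadruplet)
keep integer codes; unordered categoricals are one-hot expanded.  Every
encoded column is affinely mapped to [−1, +1] using training-set min/max;
held-out values outside that range are clipped, and constant columns map to
0.  All statistics are fitted once on the training split and reused
(`Preprocessor.fit_count` lets tests audit that no refit happens on held-out
data).  The 75/25 split uses round-half-up, so 536 patients give 402/134.

An optional radiomics block (~10³ correlated numeric columns) is reduced by
PCA fitted on training rows after centring; the number of components is the
smallest reaching 90% cumulative explained variance (a fixed-k override
exists).  Fitting PCA on training data only is a leakage-safe choice.

## Fitted Q-learning (the prescriber twin)

Three action-value regressions are trained backward:

* **Q3**: terminal reward on (state before D3, D3);
* **Q2**: `max_a Q3(s2, a)` on (state before D2, D2);
* **Q1**: `max_a Q2(s1, a)` on (state before D1, D1).

Actions are appended to the state as one-hot pairs, matching the state
convention.  Networks sweep 0–8 hidden layers (0 = ordinary linear
regression); defaults are 64 ReLU units per layer, adam at learning rate
10⁻³, full-batch updates, stopping when the loss improvement stays below
10⁻⁴ (for 10 epochs) or at 5000 epochs.  Width, activation, optimiser and
the stopping rule are this package's choices, recorded in `NetworkSpec`; the
stopping rule realises weight convergence through the optimiser's loss
tolerance.  A non-finite loss aborts with the offending learning rate, since
too-large steps make the mean reward fluctuate instead of converging.

At prescription time the stack runs forward: at each junction the action
with the larger Q is chosen, exact ties resolving to 0 (no intervention —
deterministic and clinically conservative).  Uncertainty comes from a
bootstrap ensemble: B resamples (with replacement, size n) of the training
trajectories, one self-consistent stack per resample (each member's Q3 feeds
its own Q2), percentile 2.5/97.5 intervals over members for every downstream
quantity.  The ensemble also prescribes via the member-mean Q, which
substantially de-noises individual decisions.  B defaults to 1000 for
production runs; desk-scale studies in the test-suite use B = 10–100.

## The treatment simulator (patient twin)

Off-policy evaluation needs an environment.  The simulator holds one
RBF-kernel support-vector classifier per output feature per stage: group-1
inputs + one-hot(D1) → each group-2 feature; groups 1–2 + one-hots(D1, D2) →
each group-3 feature; groups 1–3 + all three one-hots → the group-4 outcomes.
Cost C and kernel width γ are tuned per feature by stratified 5-fold
cross-validation maximising macro F1 over the grid C ∈ {0.1, 1, 10, 100},
γ ∈ {10⁻³, …, 1}; example weights are inversely proportional to class
frequency (normalised to average 1) to counter the strong imbalance of
toxicity flags.  A feature observed in a single class falls back to a
constant predictor with a logged warning; a class with fewer members than
folds shrinks the fold count, and a singleton class skips CV at mid-grid
parameters.  Predictions are hard labels (matching value-prediction
accuracy reporting); a probability-sampling switch enables stochastic
simulation.

Accuracy is reported as *one-step* (each junction predicted from the
recorded history under the physician's recorded action; percentile 95%
intervals from B bootstrap resamples of the test patients, stratified by the
evaluated feature's value) and *start-to-finish* (all three transitions
chained under recorded decisions; only final outcomes scored, with dysphagia
DP = FT OR AR_after derived on both sides).

## Evaluation protocol

Policy and simulator are trained on the same training split but evaluated
decoupled: the policy never sees the simulator during training (no
model-based optimisation), and at test time each decision is taken from the
current simulated state only — the audit log records a strict
decide-before-transition ordering, and any overlap between test ids and
either model's training ids raises a `ProtocolError`.  Reported quantities:
simulated OS and DP-free rates with ensemble CIs against the observed
test-set baseline; per-decision and overall similarity to recorded care
(evaluated on recorded histories — this metric needs no simulator);
prescription-rate deltas in percentage points with counts; and a guideline
audit — advanced-stage disease (T3–4 or N1–3) must receive chemotherapy at
D1 or D2; unknown T (Tx) counts as non-advanced on the T axis and is
tabulated separately.  Similarity/delta CIs are bootstrapped over ensemble
members.

Two planning references bound what any policy can achieve: Monte-Carlo
open-loop scoring of the 8 fixed sequences (with standard errors and a
lexicographic tie-break), and exact backward induction on enumerable tabular
processes, for which closed-loop value provably dominates the best open-loop
sequence — both are used as oracles in the test-suite.

## Synthetic cohort generator

The real cohort is single-institution and private, so the package ships a
generator whose defaults *are* the study conditions: every printed marginal
(feature frequencies, decision rates d1 36.2%, d2 76.5%, d3 20.7%, outcome
rates os 85.3%, ft 18.3%, ar_after 18.3%) is a calibration target.  Each
binary feature is Bernoulli with logit

    base + Σ_k effect[d_k → feature]·d_k + Σ_j w_j·x_j (+ u),

intermediate features conditionally independent given history and decisions
(mirroring the simulator's per-feature architecture); `u` is an optional
shared latent for stress-testing that assumption.  Intercepts are calibrated
against the realised cohort so the marginal targets hold whatever causal
effects are configured.  Three structural links reflect the data's logic:
prescribed chemotherapy is "none" exactly when D1 = 0 (the printed counts
imply this identity), the concurrent regimen is "none" exactly when D2 = 0,
and DLT grade > 0 exactly when the DLT flag is set.  Physician decisions
follow a logistic policy favouring chemotherapy for advanced disease and
withholding neck dissection after complete nodal response, calibrated to the
printed decision rates.

Choices not derivable from printed numbers, made once: per-organ DLT flag
rates (small values consistent with the 17.7% overall DLT rate); the 0.6%
"not otherwise specified" chemotherapy patients folded into "single";
pre-therapy aspiration prevalence 3% (the only number printed on that row);
default decision effects of moderate clinical plausibility (IC drives
response and toxicity; CC improves survival at some toxicity cost; ND is
toxic).  Intermediate features may depend on group-1 covariates only — this
keeps the exact sequence-value computation tractable: for each of the 8
sequences, the expected composite reward is computed by enumerating the
joint outcomes of the (few, conditionally independent) stochastic parents of
each outcome, with Gauss–Hermite quadrature over the shared latent when
correlated noise is on.  Only the pretreatment states are Monte Carlo, and
their sampling standard error is reported.  Radiomics columns are correlated
Gaussians from 6 planted factors (so ~6 components explain 90% variance) —
no claim of textural realism.

Two derived configurations support testing: `noiseless()` (deterministic
transitions driven purely by decisions, wide logit margins — the simulator
must be exactly 100% accurate there) and `dominant_sequence()` (one sequence,
(0, 1, 0), better than every other by ≥ 0.3 expected reward; survival is
kept off the saturated logit region so the gap survives calibration).

What passing tests on synthetic cohorts do *not* show: real clinical data
violate the conditional-independence of intermediate features, contain
informative missingness, unmeasured confounding of physician decisions, and
non-logistic outcome laws.  The generator's correlated-noise and
missing-rate switches probe the first two only crudely.

## Problem sizes and numerical choices

The test-suite runs at desk scale on one CPU: oracle-equivalence uses 20
random tabular processes (≤8 states/stage, 5000 sampled episodes each, gap
tolerance 0.05 at the start state); sequence recovery uses a 2400-patient
dominant-sequence cohort with a B=10 ensemble of 1×32 networks; the depth
sweep covers all 9 depths at B=10 on a 240-patient cohort with 16-unit
networks.  Ties in argmax comparisons are rounded at 10⁻¹² before breaking
toward no-intervention.  Degenerate inputs: empty cohorts generate, constant
columns scale to 0, single-class features become constant predictors, B=1
bootstrap intervals collapse to points.

## Known limitations

Binary 4-year survival only (no time-to-event modelling); three stages and
binary actions are hard-wired; evaluation through a learned simulator is
inherently partly self-referential (importance-sampling and doubly-robust
estimators are out of scope by design, being variance-limited at n=134);
the SVC grid is a compact default, not an exhaustive search; hard-label
simulation understates outcome variance relative to probability sampling.
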