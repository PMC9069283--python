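# oncotwin

**A patient–physician digital twin dyad for sequential therapy of
oropharyngeal squamous cell carcinoma.**

Treatment of head-and-neck cancer is a multistage decision problem: whether
to give induction chemotherapy (D1), whether to add concurrent chemotherapy
to radiotherapy (D2), and whether to perform a neck dissection (D3).  Each
choice changes the patient's state and the options downstream, so an optimal
course cannot be pieced together from three locally optimal decisions.
`oncotwin` addresses this with two coupled models:

* a **prescriber twin** — finite-horizon fitted Q-learning.  Three
  action-value networks are trained *backward* from the terminal composite
  reward

  `r = OS − (FT + AR_after − AR_before)`

  (4-year overall survival minus incident feeding-tube dependence and
  aspiration), Q3 → Q2 → Q1 with no discounting, then applied forward to
  prescribe the value-maximising action at each junction.  Bootstrap
  ensembles give percentile 95% intervals.

* a **patient twin** — a treatment simulator made of one RBF support-vector
  classifier per clinical feature per stage, each tuned by stratified 5-fold
  cross-validation on macro F1 with inverse-frequency class weights.  Given a
  history and a decision it predicts the next-stage features, so a policy
  can be evaluated *off-policy* by rolling test patients through simulated
  courses — the policy never sees the simulator during training, and at test
  time it sees only the current simulated state.

Because the motivating cohort (N=536, single institution) is private, the
package includes a calibrated synthetic cohort generator whose defaults
reproduce the published marginal frequencies of every feature, decision and
outcome, with configurable causal effects of decisions — including exact
ground-truth expected rewards for all 8 open-loop decision sequences, used
to validate the learners.  This is intended for audiences in biostatistics
and clinical machine-learning who study dynamic treatment regimes.

## Worked example

```python
import oncotwin as ot

# 1. a reproducible synthetic cohort at the study's size
cohort = ot.generate_cohort(ot.GeneratorConfig(n=536, seed=7))
train, test = ot.split_cohort(cohort, train_fraction=0.75, seed=7)

# 2. preprocessing fitted on the training split only
pre = ot.Preprocessor(cohort.schema).fit(train)
train_i, test_i = pre.transform(train), pre.transform(test)

# 3. the patient twin
twin = ot.TreatmentSimulator(train_i, pre).fit(seed=7)
acc = ot.one_step_accuracy(twin, test_i, B=200, seed=7)
chain = ot.start_to_finish_accuracy(twin, test_i)

# 4. the prescriber twin: backward-fitted Q ensemble
trajs = ot.assemble_trajectories(train_i, pre, outcome_mode="os+dp")
spec = ot.NetworkSpec(n_hidden_layers=2, width=32, max_epochs=500, seed=7)
ensemble = ot.TreatmentPolicy(trajs).fit_ensemble(spec, B=20, seed=7)

# 5. off-policy evaluation against the twin
report = ot.evaluate_policy(ensemble, twin, test_i, seed=7)
```

This prints (exact output of the run above):

```
cohort: 536 patients -> 402 train / 134 test
one-step accuracy: mean 76.87%, median 71.64%
start-to-finish: {'os': '76.12%', 'dp': '48.51%', 'ft': '73.88%', 'ar_after': '58.96%'}
simulated OS rate: 85.49% (95% CI 76.32-93.71), baseline 83.58%, delta +1.90
simulated DP-free rate: 68.69%, baseline 72.39%, delta -3.69
similarity to physicians: 54.1%
guideline violations: 75 of 132 advanced-stage patients
```

Reading it: the simulator predicts individual next-stage features with 77%
mean accuracy on held-out patients; chaining all three simulated transitions
degrades final-outcome accuracy (error compounding).  Rolling the learned
policy through the twin yields a simulated survival rate 1.9 points above
the physician baseline, with a wide interval at B=20 — the default
stochastic cohort has weak causal effects, so gains are modest by
construction.  The guideline audit counts advanced-stage patients (T3–4 or
N1–3) that the policy would leave without chemotherapy at both D1 and D2.

A `PolicyStack` prints a `summary()` table (per-stage epochs, final MSE,
parameter counts), and `run_pipeline` / the `oncotwin` CLI (`generate`,
`fit-twin`, `fit-policy`, `evaluate`, `run`) bind the whole study together
from a YAML config, emitting `report.json` plus accuracy, compliance,
depth-sweep and prescription-delta tables.

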