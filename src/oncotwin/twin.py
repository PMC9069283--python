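"""The patient digital twin: per-stage, per-feature transition classifiers.

The treatment simulator predicts a patient's course under any decision
sequence.  For each stage it holds one support-vector classifier (RBF kernel)
per output feature: stage 1 maps pretreatment features + a one-hot of d1 to
every post-induction feature; stage 2 maps groups 1-2 + one-hots of (d1, d2)
to the post-concurrent features; stage 3 maps groups 1-3 + one-hots of
(d1, d2, d3) to the final outcomes.  Cost and kernel width of every
classifier are tuned by stratified 5-fold cross-validation on macro F1;
training examples are weighted inversely to their class frequency to counter
the heavy imbalance of toxicity flags.  Features observed in only one class
fall back to a constant predictor with a logged warning.

Predictions are hard labels by default (a probability-sampling switch exists
for stochastic simulation).  Accuracy is reported two ways: *one-step*
(predict each junction's features under the physician's recorded action and
compare with the recorded next-stage values) and *start-to-finish* (chain all
three simulated transitions under the recorded decisions and compare only the
final outcomes, including dysphagia = feeding tube OR aspiration).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from sklearn.dummy import DummyClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .cohort import CohortTable, InputError, Preprocessor, StateVector
from .schema import DECISIONS, Feature

logger = logging.getLogger(__name__)

DEFAULT_GRID = {"C": [0.1, 1.0, 10.0, 100.0], "gamma": [1e-3, 1e-2, 1e-1, 1.0]}


class ProtocolError(RuntimeError):
    """Train/test decoupling violated (e.g. twin evaluated on its own data)."""


def inverse_frequency_weights(labels) -> dict:
    """Class weights proportional to 1/frequency, normalised to average 1."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty labels")
    classes, counts = np.unique(labels, return_counts=True)
    inv = 1.0 / counts
    inv = inv / inv.mean()
    return {c.item(): float(w) for c, w in zip(classes, inv)}


@dataclass
class TransitionModel:
    """Per-feature transition classifiers for one decision junction."""

    stage: int  # 1, 2 or 3
    classifiers: dict  # output feature name -> fitted estimator
    best_params: dict  # output feature name -> tuned hyperparameters
    input_layout: list[str]
    output_features: list[str]


def _scaled_block(
    frame: Mapping[str, np.ndarray], features: Sequence[Feature], pre: Preprocessor
) -> np.ndarray:
    """Scale a code-level feature frame with the fitted training statistics."""
    cols = []
    for f in features:
        if f.name not in frame:
            raise InputError(f"missing input feature {f.name!r}")
        col = np.asarray(frame[f.name], dtype=float)
        if f.kind == "categorical":
            raw = [(col == f.code_of(lv)).astype(float) for lv in f.levels]
            names = [f"{f.name}={lv}" for lv in f.levels]
        else:
            raw = [col]
            names = [f.name]
        for name, r in zip(names, raw):
            lo, hi = pre.scaling_map[name]
            if hi == lo:
                cols.append(np.zeros_like(r))
            else:
                cols.append(np.clip(2.0 * (r - lo) / (hi - lo) - 1.0, -1.0, 1.0))
    return np.stack(cols, axis=1)


def _onehot_block(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=int)
    out = np.zeros((len(values), 2))
    out[np.arange(len(values)), values] = 1.0
    return out


class FittedSimulator:
    """Fitted treatment simulator: three transition models + bound preprocessor."""

    def __init__(self, models: dict, pre: Preprocessor, training_ids: list):
        self.models = models  # stage -> TransitionModel
        self.pre = pre
        self.training_ids = list(training_ids)
        self.audit_log: list[tuple] = []

    @property
    def schema(self):
        return self.pre.schema

    # -- input construction -------------------------------------------------
    def _transition_inputs(
        self, frame: Mapping[str, np.ndarray], stage: int, decisions: Mapping[str, np.ndarray]
    ) -> np.ndarray:
        feats = [f for f in self.schema.features if f.group <= stage]
        blocks = [_scaled_block(frame, feats, self.pre)]
        for k in range(1, stage + 1):
            blocks.append(_onehot_block(decisions[f"d{k}"]))
        return np.hstack(blocks)

    def _policy_state(
        self, frame: Mapping[str, np.ndarray], stage: int, decisions: Mapping[str, np.ndarray]
    ) -> np.ndarray:
        """State matrix the policy sees at a junction (current state only)."""
        feats = self.schema.state_features(stage)
        blocks = [_scaled_block(frame, feats, self.pre)]
        if self.pre.radiomics_projection is not None:
            if "_radiomics_scores" not in frame:
                raise InputError("radiomics-enabled preprocessor needs _radiomics_scores")
            blocks.append(np.asarray(frame["_radiomics_scores"], dtype=float))
        for k in range(1, stage + 1):
            blocks.append(_onehot_block(decisions[f"d{k}"]))
        return np.hstack(blocks)

    # -- stepping -----------------------------------------------------------
    def step_batch(
        self,
        frame: dict,
        stage: int,
        decisions: Mapping[str, np.ndarray],
        rng=None,
    ) -> dict:
        """Predict the next-stage feature block for a whole cohort frame."""
        model = self.models[stage]
        X = self._transition_inputs(frame, stage, decisions)
        self.audit_log.append(("step", stage))
        out = {}
        for name in model.output_features:
            clf = model.classifiers[name]
            if rng is not None and hasattr(clf, "predict_proba"):
                proba = clf.predict_proba(X)
                cum = np.cumsum(proba, axis=1)
                draws = rng.random(len(X))[:, None]
                idx = (draws > cum).sum(axis=1)
                out[name] = clf.classes_[idx].astype(float)
            else:
                out[name] = clf.predict(X).astype(float)
        return out

    def simulate_step(self, history: Mapping[str, float], action: int, stage: int) -> dict:
        """Single-patient transition: complete next-stage feature map."""
        frame = {k: np.array([v], dtype=float) for k, v in history.items()
                 if not k.startswith("_")}
        if "_radiomics_scores" in history:
            frame["_radiomics_scores"] = np.atleast_2d(history["_radiomics_scores"])
        decisions = {}
        for k in range(1, stage):
            if f"d{k}" not in history:
                raise InputError(f"history missing decision d{k} before stage {stage}")
            decisions[f"d{k}"] = np.array([float(history[f"d{k}"])])
        decisions[f"d{stage}"] = np.array([float(action)])
        out = self.step_batch(frame, stage, decisions)
        return {k: float(v[0]) for k, v in out.items()}

    # -- trajectory simulation ----------------------------------------------
    def simulate_chain(
        self,
        table: CohortTable,
        decider="recorded",
        rng=None,
    ) -> tuple[dict, np.ndarray]:
        """Roll every patient through all three simulated transitions.

        ``decider`` is ``"recorded"`` (the physician's logged decisions), a
        fixed 3-sequence, a PolicyStack (queried on the evolving *simulated*
        current state only), or a callable ``(stage, state_matrix) -> actions``.
        Returns the simulated frame (with predicted groups 2-4) and the
        (n, 3) decision matrix used.
        """
        n = table.n
        frame = {
            f.name: table.df[f.name].to_numpy(dtype=float)
            for f in self.schema.group(1)
        }
        if self.pre.radiomics_projection is not None:
            if table.radiomics is None:
                raise InputError("radiomics-enabled simulator needs table radiomics")
            frame["_radiomics_scores"] = self.pre.radiomics_projection.transform(
                table.radiomics.to_numpy()
            )
        decisions: dict = {}
        dmat = np.zeros((n, 3), dtype=int)
        for stage in (1, 2, 3):
            if decider == "recorded":
                acts = table.df[DECISIONS[stage - 1]].to_numpy(dtype=float)
                if np.isnan(acts).any():
                    raise InputError(f"recorded decision d{stage} has missing values")
                acts = acts.astype(int)
            elif isinstance(decider, (tuple, list, np.ndarray)) and len(decider) == 3:
                acts = np.full(n, int(decider[stage - 1]))
            elif hasattr(decider, "prescribe_batch"):
                state = self._policy_state(frame, stage - 1, decisions)
                self.audit_log.append(("decide", stage))
                acts = decider.prescribe_batch(stage, state)
            elif callable(decider):
                state = self._policy_state(frame, stage - 1, decisions)
                self.audit_log.append(("decide", stage))
                acts = np.asarray(decider(stage, state), dtype=int)
            else:
                raise ValueError(f"unsupported decider {decider!r}")
            dmat[:, stage - 1] = acts
            decisions[f"d{stage}"] = acts.astype(float)
            frame.update(self.step_batch(frame, stage, decisions, rng=rng))
        return frame, dmat

    def simulate_trajectory(
        self, s0_features: Mapping[str, float], decider, rng=None
    ) -> tuple[dict, dict]:
        """Single-patient rollout; returns (full feature map, outcome dict).

        The outcome dict carries os, ft, ar_after, dp and the composite
        reward (using the patient's own pretreatment aspiration status).
        """
        import pandas as pd

        from .mdp import compute_reward

        for f in self.schema.group(1):
            if f.name not in s0_features or np.isnan(float(s0_features[f.name])):
                raise InputError(f"missing input feature {f.name!r}")
        row = {self.schema.id_column: "sim"}
        row.update({k: v for k, v in s0_features.items() if not k.startswith("_")})
        for f in self.schema.features:
            row.setdefault(f.name, np.nan)
        for d in DECISIONS:
            row.setdefault(d, np.nan)
        table = CohortTable(pd.DataFrame([row]), self.schema)
        frame, dmat = self.simulate_chain(table, decider, rng=rng)
        outcomes = {k: float(frame[k][0]) for k in ("os", "ft", "ar_after")}
        outcomes["dp"] = float(outcomes["ft"] == 1.0 or outcomes["ar_after"] == 1.0)
        ar_before = float(s0_features.get("ar_before", 0.0))
        outcomes["reward"] = compute_reward(
            outcomes["os"], outcomes["ft"], outcomes["ar_after"], ar_before
        )
        full = {k: float(v[0]) for k, v in frame.items() if not k.startswith("_")}
        full.update({d: int(a) for d, a in zip(DECISIONS, dmat[0])})
        return full, outcomes


class TreatmentSimulator:
    """Model object: configure and fit the per-feature transition classifiers."""

    def __init__(self, train: CohortTable, pre: Preprocessor):
        if train.has_missing():
            raise InputError("simulator training table must be imputed first")
        self.train = train
        self.pre = pre

    def fit(
        self,
        stages: Sequence[int] = (1, 2, 3),
        cv_folds: int = 5,
        grid: Mapping | None = None,
        seed: int = 0,
        probability: bool = False,
    ) -> FittedSimulator:
        grid = dict(grid or DEFAULT_GRID)
        fitted = FittedSimulator({}, self.pre, list(self.train.ids))
        for stage in stages:
            fitted.models[stage] = self._fit_stage(
                fitted, stage, cv_folds, grid, seed, probability
            )
        return fitted

    def _fit_stage(
        self, fitted: FittedSimulator, stage: int, cv_folds: int, grid, seed: int,
        probability: bool,
    ) -> TransitionModel:
        schema = self.pre.schema
        out_feats = schema.group(stage + 1)
        frame = {
            f.name: self.train.df[f.name].to_numpy(dtype=float)
            for f in schema.features
            if f.group <= stage
        }
        decisions = {
            f"d{k}": self.train.df[f"d{k}"].to_numpy(dtype=float)
            for k in range(1, stage + 1)
        }
        X = fitted._transition_inputs(frame, stage, decisions)
        classifiers: dict = {}
        params: dict = {}
        for f in out_feats:
            y = self.train.df[f.name].to_numpy(dtype=float).astype(int)
            classifiers[f.name], params[f.name] = _fit_one_classifier(
                X, y, cv_folds, grid, seed, probability, label=f.name
            )
        layout = [f.name for f in schema.features if f.group <= stage] + [
            f"d{k}" for k in range(1, stage + 1)
        ]
        return TransitionModel(
            stage=stage,
            classifiers=classifiers,
            best_params=params,
            input_layout=layout,
            output_features=[f.name for f in out_feats],
        )


def _fit_one_classifier(X, y, cv_folds, grid, seed, probability, label=""):
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        logger.warning("feature %r has a single class; using constant predictor", label)
        clf = DummyClassifier(strategy="constant", constant=classes[0]).fit(X, y)
        return clf, {"constant": int(classes[0])}
    weights = inverse_frequency_weights(y)
    extra = {"probability": True} if probability else {}
    base = SVC(kernel="rbf", class_weight=weights, random_state=seed, **extra)
    min_count = int(counts.min())
    folds = min(cv_folds, min_count)
    if folds < 2:
        logger.warning(
            "feature %r: a class has a single example; skipping CV", label
        )
        clf = base.set_params(C=1.0, gamma="scale").fit(X, y)
        return clf, {"C": 1.0, "gamma": "scale"}
    search = GridSearchCV(
        base,
        {"C": list(grid["C"]), "gamma": list(grid["gamma"])},
        scoring="f1_macro",
        cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed),
        n_jobs=1,
        refit=True,
    )
    with warnings.catch_warnings():
        # rare classes can vanish from a CV fold; macro F1 then warns
        warnings.simplefilter("ignore")
        search.fit(X, y)
    return search.best_estimator_, dict(search.best_params_)


# ---------------------------------------------------------------------------
# accuracy evaluation


@dataclass
class AccuracyReport:
    """Per-feature one-step accuracies and final-outcome chain accuracies (%)."""

    per_feature: dict = field(default_factory=dict)  # name -> (acc, lo, hi)
    mean_accuracy: float | None = None
    median_accuracy: float | None = None
    final_outcomes: dict = field(default_factory=dict)  # os/dp/ft/ar -> acc
    overall_final: float | None = None

    def as_rows(self) -> list[tuple]:
        return [(k, *v) for k, v in self.per_feature.items()]


def _check_disjoint(fitted: FittedSimulator, test: CohortTable) -> None:
    overlap = set(map(str, fitted.training_ids)) & set(map(str, test.ids))
    if overlap:
        raise ProtocolError(
            f"test set overlaps simulator training data: {sorted(overlap)[:5]}"
        )


def one_step_accuracy(
    fitted: FittedSimulator, test: CohortTable, B: int = 1000, seed: int = 0
) -> AccuracyReport:
    """Per-feature accuracy under the physician's recorded actions.

    At each junction the recorded history is fed to the stage's classifiers
    and predictions are compared with the recorded next-stage values; 95%
    intervals are percentile bootstrap over B resamples of the test patients,
    stratified by the evaluated feature's recorded value.
    """
    _check_disjoint(fitted, test)
    rng = np.random.default_rng(seed)
    schema = fitted.schema
    report = AccuracyReport()
    accs = []
    for stage in (1, 2, 3):
        frame = {
            f.name: test.df[f.name].to_numpy(dtype=float)
            for f in schema.features
            if f.group <= stage
        }
        decisions = {
            f"d{k}": test.df[f"d{k}"].to_numpy(dtype=float)
            for k in range(1, stage + 1)
        }
        preds = fitted.step_batch(frame, stage, decisions)
        for name, pred in preds.items():
            truth = test.df[name].to_numpy(dtype=float)
            correct = (pred == truth).astype(float)
            acc = 100.0 * correct.mean()
            lo, hi = _stratified_bootstrap_ci(correct, truth, B, rng)
            report.per_feature[name] = (acc, lo, hi)
            accs.append(acc)
    report.mean_accuracy = float(np.mean(accs))
    report.median_accuracy = float(np.median(accs))
    return report


def _stratified_bootstrap_ci(correct, strata, B, rng):
    if B <= 1:
        acc = 100.0 * correct.mean()
        return acc, acc
    groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    boots = np.empty(B)
    n = len(correct)
    for b in range(B):
        total = 0.0
        for g in groups:
            take = rng.integers(0, len(g), size=len(g))
            total += correct[g[take]].sum()
        boots[b] = 100.0 * total / n
    return float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))


def start_to_finish_accuracy(fitted: FittedSimulator, test: CohortTable) -> AccuracyReport:
    """Chain all three transitions under recorded care; score final outcomes.

    Dysphagia is derived as feeding tube OR aspiration, on both the simulated
    and the recorded side.
    """
    _check_disjoint(fitted, test)
    frame, _ = fitted.simulate_chain(test, decider="recorded")
    report = AccuracyReport()
    truth = {k: test.df[k].to_numpy(dtype=float) for k in ("os", "ft", "ar_after")}
    sim = {k: np.asarray(frame[k], dtype=float) for k in ("os", "ft", "ar_after")}
    truth["dp"] = ((truth["ft"] == 1) | (truth["ar_after"] == 1)).astype(float)
    sim["dp"] = ((sim["ft"] == 1) | (sim["ar_after"] == 1)).astype(float)
    for k in ("os", "dp", "ft", "ar_after"):
        report.final_outcomes[k] = float(100.0 * np.mean(sim[k] == truth[k]))
    report.overall_final = float(np.mean(list(report.final_outcomes.values())))
    return report


# functional wrappers matching the operation vocabulary
def fit_transition(
    train: CohortTable,
    pre: Preprocessor,
    stage: int,
    cv_folds: int = 5,
    grid: Mapping | None = None,
    seed: int = 0,
) -> TransitionModel:
    sim = TreatmentSimulator(train, pre)
    return sim.fit(stages=(stage,), cv_folds=cv_folds, grid=grid, seed=seed).models[stage]


def simulate_step(fitted: FittedSimulator, history: Mapping[str, float], action) -> dict:
    stage = action.decision_point if hasattr(action, "decision_point") else history["_stage"]
    value = action.value if hasattr(action, "value") else int(action)
    return fitted.simulate_step(history, value, stage)


def simulate_trajectory(fitted: FittedSimulator, s0_features, decider, rng=None):
    return fitted.simulate_trajectory(s0_features, decider, rng=rng)
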