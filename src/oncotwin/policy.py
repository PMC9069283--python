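"""Stage-wise fitted Q-learning for the three treatment decisions.

The treatment-decision digital twin is a stack of three action-value
regressions trained *backward*: Q3 regresses the terminal composite reward on
(state before D3, D3); Q2 regresses max_a Q3(s2, a) on (state before D2, D2);
Q1 regresses max_a Q2(s1, a) on (state before D1, D1).  No discounting is
applied.  At prescription time the stack is used forward: at each junction
the action with the larger Q-value is chosen, ties broken toward 0 (no
intervention).

Networks follow a configurable shallow-to-deep sweep (0-8 hidden layers; 0 is
an ordinary linear model).  Uncertainty comes from a bootstrap ensemble: B
resamples of the training trajectories, one full stack per resample,
percentile 95% intervals downstream.

Organised in the model/results idiom: :class:`TreatmentPolicy` is the model
(built from trajectories), ``fit`` returns a :class:`PolicyStack` results
object and ``fit_ensemble`` a :class:`PolicyEnsemble`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor

from .cohort import StateVector
from .mdp import Action, Trajectory

_ACTIVATIONS = {
    "relu": lambda z: np.maximum(z, 0.0),
    "tanh": np.tanh,
    "logistic": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "identity": lambda z: z,
}


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and optimisation settings for one Q-network.

    ``n_hidden_layers`` ranges over the 0-8 sweep (0 = linear model); width,
    activation and the adam learning rate are the remaining knobs.  Training
    runs full-batch and stops once the loss improvement stays below
    ``convergence_tolerance`` or after ``max_epochs``.
    """

    n_hidden_layers: int = 2
    width: int = 64
    activation: str = "relu"
    learning_rate: float = 1e-3
    max_epochs: int = 5000
    convergence_tolerance: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.n_hidden_layers <= 8):
            raise ValueError("n_hidden_layers must lie in [0, 8]")
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


class QFunction:
    """Fitted action-value regression for one decision point.

    Stores the layer weights explicitly; prediction is a plain forward pass,
    which keeps serialisation exact and independent of the fitting backend.
    """

    def __init__(self, stage: int, spec: NetworkSpec):
        self.stage = stage
        self.spec = spec
        self.coefs_: list[np.ndarray] = []
        self.intercepts_: list[np.ndarray] = []
        self.n_iter_: int | None = None
        self.final_loss_: float | None = None

    # -- fitting ------------------------------------------------------------
    @staticmethod
    def _design(states: np.ndarray, actions: np.ndarray) -> np.ndarray:
        onehot = np.zeros((len(actions), 2))
        onehot[np.arange(len(actions)), actions.astype(int)] = 1.0
        return np.hstack([states, onehot])

    def fit(self, states: np.ndarray, actions: np.ndarray, targets: np.ndarray) -> "QFunction":
        X = self._design(states, actions)
        y = np.asarray(targets, dtype=float)
        if len(X) != len(y):
            raise ValueError("targets not aligned with trajectories")
        spec = self.spec
        if spec.n_hidden_layers == 0:
            reg = LinearRegression().fit(X, y)
            self.coefs_ = [np.atleast_2d(reg.coef_).T]
            self.intercepts_ = [np.atleast_1d(reg.intercept_)]
            self.n_iter_ = 1
            self.final_loss_ = float(np.mean((reg.predict(X) - y) ** 2))
        else:
            mlp = MLPRegressor(
                hidden_layer_sizes=(spec.width,) * spec.n_hidden_layers,
                activation=spec.activation,
                solver="adam",
                learning_rate_init=spec.learning_rate,
                max_iter=spec.max_epochs,
                tol=spec.convergence_tolerance,
                n_iter_no_change=10,
                batch_size=max(1, len(X)),  # full batch
                random_state=spec.seed,
                alpha=1e-5,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                mlp.fit(X, y)
            if not np.isfinite(mlp.loss_):
                raise FloatingPointError(
                    f"non-finite training loss at learning rate {spec.learning_rate}; "
                    "lower it so the mean reward converges smoothly"
                )
            self.coefs_ = [c.copy() for c in mlp.coefs_]
            self.intercepts_ = [b.copy() for b in mlp.intercepts_]
            self.n_iter_ = int(mlp.n_iter_)
            self.final_loss_ = float(mlp.loss_)
        return self

    # -- prediction ----------------------------------------------------------
    def _forward(self, X: np.ndarray) -> np.ndarray:
        h = X
        for k, (W, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            h = h @ W + b
            if k < len(self.coefs_) - 1:
                h = _ACTIVATIONS[self.spec.activation](h)
        return h.ravel()

    def predict(self, states: np.ndarray, action: int) -> np.ndarray:
        states = np.atleast_2d(states)
        actions = np.full(len(states), action)
        return self._forward(self._design(states, actions))

    def q_values(self, states: np.ndarray) -> np.ndarray:
        """(n, 2) array of Q(s, a) for both actions."""
        return np.stack([self.predict(states, a) for a in (0, 1)], axis=1)

    @property
    def n_parameters(self) -> int:
        return int(sum(W.size for W in self.coefs_) + sum(b.size for b in self.intercepts_))


def fit_stage_q(
    trajectories: list[Trajectory],
    stage: int,
    targets: np.ndarray,
    spec: NetworkSpec,
) -> QFunction:
    """Regress per-trajectory targets on (state before the stage, action)."""
    if stage not in (1, 2, 3):
        raise ValueError("stage must be 1, 2 or 3")
    states = np.stack([t.states[stage - 1] for t in trajectories])
    actions = np.array([t.actions[stage - 1] for t in trajectories])
    try:
        return QFunction(stage, spec).fit(states, actions, np.asarray(targets, float))
    except FloatingPointError as exc:
        raise FloatingPointError(f"stage {stage}: {exc}") from exc


class PolicyStack:
    """Results object: the three fitted Q-functions and the prescription rule."""

    def __init__(self, q1: QFunction, q2: QFunction, q3: QFunction, spec: NetworkSpec,
                 training_metadata: dict, training_ids: list):
        self.q1, self.q2, self.q3 = q1, q2, q3
        self.spec = spec
        self.training_metadata = training_metadata
        self.training_ids = training_ids

    def q(self, stage: int) -> QFunction:
        return (self.q1, self.q2, self.q3)[stage - 1]

    def prescribe(self, state: StateVector) -> Action:
        """Greedy action at the state's junction; ties go to 0 (no intervention)."""
        stage = state.stage + 1
        qv = self.q(stage).q_values(state.values[None, :])[0]
        value = 1 if qv[1] > qv[0] else 0
        return Action(decision_point=stage, value=value)

    def prescribe_batch(self, stage: int, states: np.ndarray) -> np.ndarray:
        qv = self.q(stage).q_values(states)
        return (qv[:, 1] > qv[:, 0]).astype(int)

    def summary(self) -> str:
        lines = [
            "Fitted Q-learning policy stack",
            "=" * 46,
            f"architecture: {self.spec.n_hidden_layers} hidden layer(s) x "
            f"{self.spec.width} ({self.spec.activation}), "
            f"lr={self.spec.learning_rate}",
            f"trained on {len(self.training_ids)} trajectories "
            f"(backward order: Q3 -> Q2 -> Q1)",
            "-" * 46,
            f"{'stage':>6} {'epochs':>8} {'final MSE':>12} {'params':>8}",
        ]
        for s in (3, 2, 1):
            q = self.q(s)
            lines.append(
                f"{'Q' + str(s):>6} {q.n_iter_:>8} {q.final_loss_:>12.5f} "
                f"{q.n_parameters:>8}"
            )
        return "\n".join(lines)

    # -- serialisation --------------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "spec": self.spec.__dict__,
            "training_metadata": self.training_metadata,
            "training_ids": [str(i) for i in self.training_ids],
        }
        (d / "spec.json").write_text(json.dumps(meta, indent=1))
        for s in (1, 2, 3):
            q = self.q(s)
            arrays = {}
            for k, W in enumerate(q.coefs_):
                arrays[f"W{k}"] = W
            for k, b in enumerate(q.intercepts_):
                arrays[f"b{k}"] = b
            np.savez(d / f"q{s}.npz", **arrays)

    @classmethod
    def load(cls, directory) -> "PolicyStack":
        d = Path(directory)
        meta = json.loads((d / "spec.json").read_text())
        spec = NetworkSpec(**meta["spec"])
        qs = []
        for s in (1, 2, 3):
            data = np.load(d / f"q{s}.npz")
            q = QFunction(s, spec)
            n_layers = sum(1 for k in data.files if k.startswith("W"))
            q.coefs_ = [data[f"W{k}"] for k in range(n_layers)]
            q.intercepts_ = [data[f"b{k}"] for k in range(n_layers)]
            qs.append(q)
        return cls(qs[0], qs[1], qs[2], spec, meta["training_metadata"],
                   meta["training_ids"])


class PolicyEnsemble:
    """B policy stacks fitted on independent bootstrap resamples."""

    def __init__(self, members: list[PolicyStack], seed: int):
        if len(members) < 2:
            raise ValueError("an ensemble needs B >= 2 members")
        self.members = members
        self.seed = seed

    @property
    def B(self) -> int:
        return len(self.members)

    def prescribe_batch(self, stage: int, states: np.ndarray) -> np.ndarray:
        """Greedy action under the ensemble-mean Q (bagged prescription)."""
        qv = np.mean([m.q(stage).q_values(states) for m in self.members], axis=0)
        return (qv[:, 1] > qv[:, 0]).astype(int)

    def summary(self) -> str:
        spec = self.members[0].spec
        return (
            f"Bootstrap policy ensemble: B={self.B}, "
            f"{spec.n_hidden_layers} hidden layer(s) x {spec.width}, "
            f"seed={self.seed}"
        )


class TreatmentPolicy:
    """Model object: fitted Q-learning over a set of training trajectories.

    Parameters
    ----------
    trajectories : the (s0, a1, s1, a2, s2, a3, reward) episodes from the
        *training* cohort; held-out episodes must never be passed here (the
        evaluation layer audits this via the stored trajectory ids).
    """

    def __init__(self, trajectories: list[Trajectory]):
        if len(trajectories) < 2:
            raise ValueError("need at least 2 trajectories")
        self.trajectories = list(trajectories)
        self.training_ids = [t.patient_id for t in self.trajectories]

    @classmethod
    def from_cohort(cls, table, pre, outcome_mode: str = "os+dp") -> "TreatmentPolicy":
        from .mdp import assemble_trajectories

        return cls(assemble_trajectories(table, pre, outcome_mode=outcome_mode))

    # -- fitting ------------------------------------------------------------
    def fit(self, spec: NetworkSpec | None = None, **spec_kwargs) -> PolicyStack:
        """Backward-train Q3 -> Q2 -> Q1 and return the fitted stack."""
        spec = spec or NetworkSpec(**spec_kwargs)
        return self._fit_backward(self.trajectories, spec)

    def _fit_backward(self, trajectories: list[Trajectory], spec: NetworkSpec) -> PolicyStack:
        order = []
        rewards = np.array([t.reward for t in trajectories])
        q3 = fit_stage_q(trajectories, 3, rewards, spec)
        order.append("q3")
        s2 = np.stack([t.states[2] for t in trajectories])
        t2 = q3.q_values(s2).max(axis=1)
        q2 = fit_stage_q(trajectories, 2, t2, spec)
        order.append("q2")
        s1 = np.stack([t.states[1] for t in trajectories])
        t1 = q2.q_values(s1).max(axis=1)
        q1 = fit_stage_q(trajectories, 1, t1, spec)
        order.append("q1")
        meta = {
            "fit_order": order,
            "losses": {f"q{s}": q.final_loss_ for s, q in ((3, q3), (2, q2), (1, q1))},
            "epochs": {f"q{s}": q.n_iter_ for s, q in ((3, q3), (2, q2), (1, q1))},
            "seed": spec.seed,
        }
        return PolicyStack(q1, q2, q3, spec, meta,
                           [t.patient_id for t in trajectories])

    def fit_ensemble(
        self, spec: NetworkSpec | None = None, B: int = 1000, seed: int = 0, **spec_kwargs
    ) -> PolicyEnsemble:
        """Fit B stacks on bootstrap resamples (with replacement, size n).

        Each member's stack is trained self-consistently (its own Q3 feeds
        its own Q2).  Percentile 95% intervals of any downstream quantity are
        taken over members.
        """
        if B < 2:
            raise ValueError("B must be >= 2")
        base_spec = spec or NetworkSpec(**spec_kwargs)
        rng = np.random.default_rng(seed)
        n = len(self.trajectories)
        members = []
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            member_seed = int(rng.integers(2**31 - 1))
            resample = [self.trajectories[i] for i in idx]
            mspec = NetworkSpec(**{**base_spec.__dict__, "seed": member_seed})
            try:
                members.append(self._fit_backward(resample, mspec))
            except Exception as exc:
                raise RuntimeError(f"bootstrap member {b} failed") from exc
        return PolicyEnsemble(members, seed=seed)


# functional aliases matching the operation names used in the docs
def fit_backward(trajectories: list[Trajectory], spec: NetworkSpec) -> PolicyStack:
    return TreatmentPolicy(trajectories).fit(spec)


def prescribe(stack: PolicyStack, state: StateVector) -> Action:
    return stack.prescribe(state)


def fit_bootstrap_ensemble(
    trajectories: list[Trajectory], spec: NetworkSpec, B: int = 1000, seed: int = 0
) -> PolicyEnsemble:
    return TreatmentPolicy(trajectories).fit_ensemble(spec, B=B, seed=seed)
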