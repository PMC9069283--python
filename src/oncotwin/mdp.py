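"""The 3-stage decision process: reward, trajectories, planners and oracles.

The therapy course is a finite-horizon Markov decision process with three
binary actions — induction chemotherapy (d1), concurrent chemotherapy vs.
radiotherapy alone (d2), neck dissection (d3) — zero intermediate reward and
a terminal composite reward

    r = OS - (FT + AR_after - AR_before)

combining 4-year survival with feeding-tube and aspiration toxicity.  No
discounting is applied (terminal-only reward makes the discount structurally
irrelevant).  Besides trajectory assembly for the Q-learners, the module
provides the two planning references: Monte-Carlo open-loop sequence scoring
(8 fixed sequences) and exact backward-induction on enumerable tabular MDPs,
used as the oracle for validating learned policies.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

from .cohort import CohortTable, Preprocessor


@dataclass(frozen=True)
class Action:
    """One treatment decision: decision point 1-3 and a binary value."""

    decision_point: int
    value: int

    def __post_init__(self):
        if self.decision_point not in (1, 2, 3):
            raise ValueError("decision_point must be 1, 2 or 3")
        if self.value not in (0, 1):
            raise ValueError("action value must be 0 or 1")


def compute_reward(os, ft, ar_after, ar_before) -> float:
    """Terminal composite reward: os - (ft + ar_after - ar_before).

    All arguments must be binary; the image over binary inputs is
    {-2, -1, 0, 1, 2}.
    """
    vals = []
    for name, v in (("os", os), ("ft", ft), ("ar_after", ar_after), ("ar_before", ar_before)):
        fv = float(v)
        if fv not in (0.0, 1.0):
            raise ValueError(f"{name} must be binary, got {v!r}")
        vals.append(fv)
    os_, ft_, ar_a, ar_b = vals
    return os_ - (ft_ + ar_a - ar_b)


@dataclass
class Trajectory:
    """One patient's episode: (s0, a1, s1, a2, s2, a3, terminal reward)."""

    states: tuple[np.ndarray, np.ndarray, np.ndarray]
    actions: tuple[int, int, int]
    reward: float
    patient_id: object = None

    #: rewards at the two intermediate junctions are identically zero
    intermediate_rewards: tuple[float, float] = (0.0, 0.0)


def assemble_trajectories(
    table: CohortTable,
    pre: Preprocessor,
    outcome_mode: str = "os+dp",
) -> list[Trajectory]:
    """Build one trajectory per patient from a preprocessed cohort.

    ``outcome_mode`` selects the terminal reward: the composite survival /
    toxicity reward (``"os+dp"``) or survival alone (``"os"``).
    """
    if outcome_mode not in ("os", "os+dp"):
        raise ValueError("outcome_mode must be 'os' or 'os+dp'")
    needed = ["os", "ft", "ar_after"] if outcome_mode == "os+dp" else ["os"]
    states = [pre.state_matrix(table, s) for s in (0, 1, 2)]
    out: list[Trajectory] = []
    for i in range(table.n):
        row = table.df.iloc[i]
        pid = row[table.schema.id_column]
        for col in needed + ["ar_before", "d1", "d2", "d3"]:
            if np.isnan(float(row[col])):
                raise ValueError(f"patient {pid!r}: missing {col}")
        if outcome_mode == "os":
            reward = float(row["os"])
        else:
            reward = compute_reward(row["os"], row["ft"], row["ar_after"], row["ar_before"])
        out.append(
            Trajectory(
                states=(states[0][i], states[1][i], states[2][i]),
                actions=(int(row["d1"]), int(row["d2"]), int(row["d3"])),
                reward=reward,
                patient_id=pid,
            )
        )
    return out


def trajectories_to_csv(trajectories: list[Trajectory], path) -> None:
    """Serialise trajectories to a wide CSV: one row per patient."""
    import pandas as pd

    rows = []
    for t in trajectories:
        row = {"patient_id": t.patient_id}
        for s, state in enumerate(t.states):
            row.update({f"s{s}_{j}": v for j, v in enumerate(state)})
        row.update({f"a{k + 1}": a for k, a in enumerate(t.actions)})
        row["reward"] = t.reward
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def enumerate_sequences(n_decisions: int = 3) -> list[tuple[int, ...]]:
    """All 2^n binary action sequences in lexicographic order."""
    if n_decisions < 1:
        raise ValueError("n_decisions must be >= 1")
    return [tuple(s) for s in itertools.product((0, 1), repeat=n_decisions)]


@dataclass
class SequenceValueTable:
    """Estimated expected reward for each of the 8 open-loop sequences."""

    sequences: list[tuple[int, int, int]]
    values: np.ndarray
    standard_errors: np.ndarray

    def __post_init__(self):
        if len(self.sequences) != len(self.values):
            raise ValueError("sequence/value length mismatch")

    @property
    def best_index(self) -> int:
        # lexicographically smallest among ties (sequences are in lex order
        # and argmax returns the first maximiser; round to kill float dust)
        return int(np.argmax(np.round(self.values, 12)))

    @property
    def best_sequence(self) -> tuple[int, int, int]:
        return self.sequences[self.best_index]

    def to_json(self, path) -> None:
        payload = {
            "sequences": [list(s) for s in self.sequences],
            "values": [float(v) for v in self.values],
            "standard_errors": [float(s) for s in self.standard_errors],
            "best_sequence": list(self.best_sequence),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def open_loop_plan(env, history: dict, n_samples: int, seed: int = 0) -> SequenceValueTable:
    """Monte-Carlo open-loop scoring of all 8 sequences from one start state.

    ``env`` must expose ``rollout(history, sequence, rng) -> feature map``
    containing ``os``, ``ft``, ``ar_after`` and ``ar_before``; the expected
    composite reward of each fixed sequence is estimated from ``n_samples``
    independent rollouts.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    seqs = enumerate_sequences(3)
    values = np.zeros(len(seqs))
    ses = np.zeros(len(seqs))
    for si, seq in enumerate(seqs):
        rewards = np.empty(n_samples)
        for k in range(n_samples):
            try:
                final = env.rollout(dict(history), seq, rng)
            except Exception as exc:  # annotate with sequence context
                raise RuntimeError(f"environment failure under sequence {seq}") from exc
            rewards[k] = compute_reward(
                final["os"], final["ft"], final["ar_after"], final["ar_before"]
            )
        values[si] = rewards.mean()
        ses[si] = rewards.std(ddof=1) / np.sqrt(n_samples) if n_samples > 1 else 0.0
    return SequenceValueTable(sequences=seqs, values=values, standard_errors=ses)


# ---------------------------------------------------------------------------
# tabular oracle


@dataclass
class TabularMDP:
    """Explicit finite 3-stage MDP with binary actions and terminal reward.

    ``p0``: initial distribution over stage-0 states; ``P1[s0, a, s1]`` and
    ``P2[s1, a, s2]``: transition kernels; ``R[s2, a3]``: terminal reward.
    """

    p0: np.ndarray
    P1: np.ndarray
    P2: np.ndarray
    R: np.ndarray

    def __post_init__(self):
        self.p0 = np.asarray(self.p0, dtype=float)
        self.P1 = np.asarray(self.P1, dtype=float)
        self.P2 = np.asarray(self.P2, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        for name, arr in (("p0", self.p0[None, None, :]), ("P1", self.P1), ("P2", self.P2)):
            rows = arr.reshape(-1, arr.shape[-1]).sum(axis=1)
            if not np.allclose(rows, 1.0, atol=1e-8):
                raise ValueError(f"{name}: transition rows must sum to 1")

    @property
    def n_states(self) -> tuple[int, int, int]:
        return (self.P1.shape[0], self.P2.shape[0], self.R.shape[0])


@dataclass
class OracleTables:
    """Exact backward-induction Q and V tables for a tabular MDP."""

    Q1: np.ndarray
    Q2: np.ndarray
    Q3: np.ndarray
    V0: np.ndarray
    V1: np.ndarray
    V2: np.ndarray
    start_value: float

    def greedy(self, stage: int, state: int) -> int:
        q = (self.Q1, self.Q2, self.Q3)[stage - 1][state]
        return int(np.argmax(np.round(q, 12)))  # ties -> action 0


def closed_loop_oracle(mdp: TabularMDP) -> OracleTables:
    """Exact dynamic-programming solution (reference for learned policies)."""
    Q3 = mdp.R.copy()
    V2 = Q3.max(axis=1)
    Q2 = np.einsum("sat,t->sa", mdp.P2, V2)
    V1 = Q2.max(axis=1)
    Q1 = np.einsum("sat,t->sa", mdp.P1, V1)
    V0 = Q1.max(axis=1)
    return OracleTables(
        Q1=Q1, Q2=Q2, Q3=Q3, V0=V0, V1=V1, V2=V2,
        start_value=float(mdp.p0 @ V0),
    )


def open_loop_value(mdp: TabularMDP, sequence) -> float:
    """Exact expected reward of a fixed action sequence on a tabular MDP."""
    a1, a2, a3 = sequence
    d1 = mdp.p0 @ mdp.P1[:, a1, :]
    d2 = d1 @ mdp.P2[:, a2, :]
    return float(d2 @ mdp.R[:, a3])


def best_open_loop_value(mdp: TabularMDP) -> float:
    return max(open_loop_value(mdp, s) for s in enumerate_sequences(3))


def policy_value(mdp: TabularMDP, policy) -> float:
    """Exact value of ``policy(stage, state_index) -> action`` on the MDP."""
    n0, n1, n2 = mdp.n_states
    v2 = np.array([mdp.R[s, policy(3, s)] for s in range(n2)])
    v1 = np.array([mdp.P2[s, policy(2, s)] @ v2 for s in range(n1)])
    v0 = np.array([mdp.P1[s, policy(1, s)] @ v1 for s in range(n0)])
    return float(mdp.p0 @ v0)


def random_mdp(seed: int, max_states: int = 8, reward_scale: float = 1.0) -> TabularMDP:
    """Random small MDP (Dirichlet kernels, uniform rewards) for tests."""
    rng = np.random.default_rng(seed)
    n0, n1, n2 = rng.integers(2, max_states + 1, size=3)
    p0 = rng.dirichlet(np.ones(n0))
    P1 = rng.dirichlet(np.ones(n1), size=(n0, 2))
    P2 = rng.dirichlet(np.ones(n2), size=(n1, 2))
    R = rng.uniform(-reward_scale, reward_scale, size=(n2, 2))
    return TabularMDP(p0=p0, P1=P1, P2=P2, R=R)


def sample_tabular_trajectories(
    mdp: TabularMDP, n: int, seed: int = 0, behavior: str = "uniform"
) -> list[Trajectory]:
    """Sample episodes under a uniform behaviour policy, states one-hot coded."""
    if behavior != "uniform":
        raise ValueError("only the uniform behaviour policy is implemented")
    rng = np.random.default_rng(seed)
    n0, n1, n2 = mdp.n_states
    eye0, eye1, eye2 = np.eye(n0), np.eye(n1), np.eye(n2)
    out = []
    for i in range(n):
        s0 = rng.choice(n0, p=mdp.p0)
        a1 = int(rng.integers(2))
        s1 = rng.choice(n1, p=mdp.P1[s0, a1])
        a2 = int(rng.integers(2))
        s2 = rng.choice(n2, p=mdp.P2[s1, a2])
        a3 = int(rng.integers(2))
        out.append(
            Trajectory(
                states=(eye0[s0], eye1[s1], eye2[s2]),
                actions=(a1, a2, a3),
                reward=float(mdp.R[s2, a3]),
                patient_id=i,
            )
        )
    return out
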