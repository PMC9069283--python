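"""Similarity, prescription deltas, guideline compliance, pipeline contracts."""

import json

import numpy as np
import pandas as pd
import pytest

import oncotwin as ot
from oncotwin.twin import ProtocolError


class _FixedDecider:
    """Stub policy: replays, inverts, or forces recorded decisions."""

    def __init__(self, table, mode="replay"):
        self._d = {
            s: table.df[f"d{s}"].to_numpy(float).astype(int) for s in (1, 2, 3)
        }
        self.mode = mode
        self.training_ids = []

    def prescribe_batch(self, stage, states):
        n = len(states)
        rec = self._d[stage][:n]
        if self.mode == "replay":
            return rec
        if self.mode == "invert":
            return 1 - rec
        if self.mode == "always":
            return np.ones(n, dtype=int)
        return np.zeros(n, dtype=int)


class TestSimilarity:
    def test_replay_is_100(self, split_preprocessed):
        _, test, pre = split_preprocessed
        s = ot.similarity(_FixedDecider(test, "replay"), test, pre)
        assert s == {"d1": 100.0, "d2": 100.0, "d3": 100.0, "overall": 100.0}

    def test_inversion_is_0(self, split_preprocessed):
        _, test, pre = split_preprocessed
        s = ot.similarity(_FixedDecider(test, "invert"), test, pre)
        assert s["overall"] == 0.0

    def test_partial_match_arithmetic(self, split_preprocessed):
        _, test, pre = split_preprocessed
        one = test.subset([0])

        class TwoOfThree:
            training_ids = []

            def prescribe_batch(self, stage, states):
                rec = int(one.df[f"d{stage}"].iloc[0])
                return np.array([rec if stage in (1, 3) else 1 - rec])

        s = ot.similarity(TwoOfThree(), one, pre)
        assert s["overall"] == pytest.approx(200.0 / 3.0)


class TestPrescriptionDelta:
    def test_replay_deltas_are_zero(self, split_preprocessed):
        _, test, pre = split_preprocessed
        d = ot.prescription_delta(_FixedDecider(test, "replay"), test, pre)
        for stage in (1, 2, 3):
            assert d[f"d{stage}"]["delta_points"] == 0.0

    def test_always_and_never_yes(self, split_preprocessed):
        _, test, pre = split_preprocessed
        rate3 = 100.0 * test.df.d3.mean()
        up = ot.prescription_delta(_FixedDecider(test, "always"), test, pre)
        down = ot.prescription_delta(_FixedDecider(test, "never"), test, pre)
        assert up["d3"]["delta_points"] == pytest.approx(100.0 - rate3)
        assert up["d3"]["count_prescribed"] == test.n
        assert down["d3"]["delta_points"] == pytest.approx(-rate3)


class TestCompliance:
    def _table_with(self, t_codes, n_codes):
        sch = ot.compact_schema()
        n = len(t_codes)
        df = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)]})
        for f in sch.features:
            df[f.name] = 0.0
        df["t_category"] = t_codes
        df["n_category"] = n_codes
        for d in ("d1", "d2", "d3"):
            df[d] = 0.0
        return ot.CohortTable(df, sch)

    def test_advanced_without_chemo_is_violation(self):
        t = self._table_with([2.0], [1.0])  # T3, N1
        table = ot.nccn_compliance(t, np.array([[0, 0]]))
        assert table.n_violations == 1 and not table.compliant

    def test_early_stage_exempt(self):
        t = self._table_with([0.0], [0.0])  # T1, N0
        table = ot.nccn_compliance(t, np.array([[0, 0]]))
        assert table.compliant

    def test_induction_only_satisfies_rule(self):
        t = self._table_with([3.0], [0.0])  # T4, N0
        table = ot.nccn_compliance(t, np.array([[1, 0]]))
        assert table.compliant
        assert table.by_t["T4"]["ic_rt"] == 1

    def test_always_concurrent_chemo_is_fully_compliant(self, compact_cohort):
        n = compact_cohort.n
        decisions = np.column_stack([np.zeros(n, int), np.ones(n, int)])
        table = ot.nccn_compliance(compact_cohort, decisions)
        assert table.compliant

    def test_unknown_t_reported_separately(self):
        t = self._table_with([np.nan, 2.0], [0.0, 0.0])
        table = ot.nccn_compliance(t, np.array([[0, 0], [0, 1]]))
        assert sum(table.unknown_t.values()) == 1
        assert table.n_advanced == 1  # Tx counts as non-advanced on the T axis


@pytest.fixture(scope="module")
def ensemble_identical(split_preprocessed):
    train, _, pre = split_preprocessed
    trajs = ot.assemble_trajectories(train, pre)
    spec = ot.NetworkSpec(n_hidden_layers=1, width=16, max_epochs=200, seed=0)
    stack = ot.TreatmentPolicy(trajs).fit(spec)
    return ot.PolicyEnsemble([stack, stack, stack], seed=0)


class TestEvaluatePolicy:
    def test_identical_members_zero_width_cis(
        self, ensemble_identical, fitted_twin_stochastic, split_preprocessed
    ):
        _, test, _ = split_preprocessed
        rep = ot.evaluate_policy(ensemble_identical, fitted_twin_stochastic, test)
        assert rep.os_ci[0] == rep.os_ci[1] == rep.os_rate
        assert rep.dp_free_ci[0] == rep.dp_free_ci[1]
        assert 0.0 <= rep.os_rate <= 100.0
        assert rep.delta_os == pytest.approx(rep.os_rate - rep.baseline_os)

    def test_physician_replay_matches_chain_rates(
        self, fitted_twin_stochastic, split_preprocessed
    ):
        _, test, _ = split_preprocessed
        replay = _FixedDecider(test, "replay")
        ens = ot.PolicyEnsemble([replay, replay], seed=0)
        rep = ot.evaluate_policy(ens, fitted_twin_stochastic, test)
        frame, _ = fitted_twin_stochastic.simulate_chain(test, decider="recorded")
        os_rate = 100.0 * np.mean(frame["os"])
        assert rep.os_rate == pytest.approx(os_rate)
        assert rep.similarity_overall[0] == 100.0

    def test_training_overlap_is_protocol_error(
        self, ensemble_identical, fitted_twin_stochastic, split_preprocessed
    ):
        train, _, _ = split_preprocessed
        with pytest.raises(ProtocolError):
            ot.evaluate_policy(ensemble_identical, fitted_twin_stochastic, train)


class TestPipeline:
    CONFIG = {
        "cohort": {"synthetic": {"n": 160, "schema": "compact"}},
        "outcome_mode": "os+dp",
        "depths": [0, 1],
        "bootstrap_B": 3,
        "accuracy_B": 20,
        "network": {"width": 8, "max_epochs": 100},
        "twin": {"cv_folds": 3, "grid": {"C": [1.0], "gamma": [0.1]}},
        "seed": 3,
    }

    def test_report_contract(self, tmp_path):
        out = ot.run_pipeline(dict(self.CONFIG), out_dir=tmp_path / "rep")
        payload = json.loads((out / "report.json").read_text())
        assert set(payload["depths"]) == {"0", "1"}
        for rep in payload["depths"].values():
            assert 0.0 <= rep["os_rate"] <= 100.0
            assert rep["os_ci"][0] <= rep["os_rate"] <= rep["os_ci"][1]
            assert 0.0 <= rep["dp_free_rate"] <= 100.0
        sweep = pd.read_csv(out / "depth_sweep.csv")
        assert list(sweep.depth) == [0, 1]
        assert (out / "one_step_accuracy.csv").exists()
        assert (out / "compliance.csv").exists()
        assert (out / "prescription_delta.csv").exists()

    def test_rerun_is_byte_identical(self, tmp_path):
        a = ot.run_pipeline(dict(self.CONFIG), out_dir=tmp_path / "a")
        b = ot.run_pipeline(dict(self.CONFIG), out_dir=tmp_path / "b")
        assert (a / "report.json").read_text() == (b / "report.json").read_text()

    def test_outcome_modes_differ_only_in_reward(self, split_preprocessed):
        train, _, pre = split_preprocessed
        tr_combined = ot.assemble_trajectories(train, pre, outcome_mode="os+dp")
        tr_os = ot.assemble_trajectories(train, pre, outcome_mode="os")
        for a, b in zip(tr_combined, tr_os):
            assert a.actions == b.actions
            np.testing.assert_array_equal(a.states[2], b.states[2])
            assert b.reward == train.df.loc[
                train.df.patient_id == b.patient_id, "os"
            ].iloc[0]
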