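"""Transition classifiers, class weighting, stepwise simulation, accuracy."""

import numpy as np
import pytest

import oncotwin as ot
from oncotwin.twin import ProtocolError, _fit_one_classifier, inverse_frequency_weights


class TestInverseFrequencyWeights:
    def test_nine_to_one_imbalance(self):
        labels = np.array([0] * 90 + [1] * 10)
        w = inverse_frequency_weights(labels)
        assert w[1] / w[0] == pytest.approx(9.0)
        assert np.mean(list(w.values())) == pytest.approx(1.0)

    def test_balanced_classes_all_one(self):
        w = inverse_frequency_weights(np.array([0, 1] * 25))
        assert w == {0: 1.0, 1: 1.0}

    def test_three_classes(self):
        labels = np.array([0] * 50 + [1] * 25 + [2] * 25)
        w = inverse_frequency_weights(labels)
        assert w[1] == pytest.approx(w[2])
        assert w[1] / w[0] == pytest.approx(2.0)

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            inverse_frequency_weights(np.array([]))


class TestPerFeatureClassifier:
    def test_separable_labels_learned_exactly(self, rng):
        # margin-separated classes: no points near the boundary
        def draw(n):
            X = rng.normal(size=(n, 4))
            X = X[np.abs(X[:, 0]) > 0.4]
            return X, (X[:, 0] > 0).astype(int)

        X, y = draw(400)
        clf, params = _fit_one_classifier(
            X, y, cv_folds=5, grid={"C": [1.0, 10.0], "gamma": [0.1, 1.0]},
            seed=0, probability=False,
        )
        Xte, yte = draw(300)
        assert np.mean(clf.predict(Xte) == yte) == 1.0

    def test_independent_labels_score_at_chance(self, rng):
        X = rng.normal(size=(1000, 3))
        y = rng.integers(0, 2, size=1000)
        clf, _ = _fit_one_classifier(
            X, y, cv_folds=3, grid={"C": [1.0], "gamma": [0.1]},
            seed=0, probability=False,
        )
        Xte = rng.normal(size=(1000, 3))
        yte = rng.integers(0, 2, size=1000)
        acc = np.mean(clf.predict(Xte) == yte)
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / 1000)

    def test_single_class_becomes_constant_predictor(self, rng):
        X = rng.normal(size=(50, 3))
        y = np.ones(50, dtype=int)
        clf, params = _fit_one_classifier(
            X, y, cv_folds=5, grid={"C": [1.0], "gamma": [0.1]},
            seed=0, probability=False,
        )
        assert params == {"constant": 1}
        assert np.mean(clf.predict(rng.normal(size=(40, 3))) == 1) == 1.0


class TestNoiselessSimulation:
    def test_one_step_predictions_match_generator_truth(self, noiseless_setup):
        twin, te, gen = (
            noiseless_setup["twin"],
            noiseless_setup["test"],
            noiseless_setup["generator"],
        )
        rng = np.random.default_rng(0)
        rec = te.record(0)
        history = dict(rec.group1)
        history["d1"] = float(rec.d1)
        pred = twin.simulate_step(history, int(rec.d1), stage=1)
        truth = gen.step(history, 1, int(rec.d1), rng)
        assert pred == truth

    def test_action_sensitivity_propagates(self, noiseless_setup):
        twin, te = noiseless_setup["twin"], noiseless_setup["test"]
        rec = te.record(0)
        h0 = dict(rec.group1)
        out_no = twin.simulate_step({**h0, "d1": 0.0}, 0, stage=1)
        out_yes = twin.simulate_step({**h0, "d1": 1.0}, 1, stage=1)
        assert any(out_no[k] != out_yes[k] for k in out_no)

    def test_output_feature_set_matches_schema(self, noiseless_setup):
        twin, te = noiseless_setup["twin"], noiseless_setup["test"]
        rec = te.record(0)
        out = twin.simulate_step({**rec.group1, "d1": 1.0}, 1, stage=1)
        assert set(out) == set(twin.schema.group_names(2))

    def test_fixed_sequence_chain_matches_generator(self, noiseless_setup):
        twin, te, gen = (
            noiseless_setup["twin"],
            noiseless_setup["test"],
            noiseless_setup["generator"],
        )
        rng = np.random.default_rng(1)
        rec = te.record(2)
        full, outcomes = twin.simulate_trajectory(rec.group1, decider=(0, 0, 0))
        truth = gen.rollout(dict(rec.group1), (0, 0, 0), rng)
        for k in ("os", "ft", "ar_after"):
            assert outcomes[k] == truth[k]

    def test_missing_input_feature_named(self, noiseless_setup):
        twin = noiseless_setup["twin"]
        with pytest.raises(ot.InputError, match="missing input feature"):
            twin.simulate_step({"age": 60.0, "d1": 1.0}, 1, stage=1)


class TestAccuracyReports:
    def test_perfect_models_give_100_and_zero_width(self, noiseless_setup):
        twin, te = noiseless_setup["twin"], noiseless_setup["test"]
        rep = ot.one_step_accuracy(twin, te, B=64, seed=0)
        for name, (acc, lo, hi) in rep.per_feature.items():
            assert acc == 100.0 and lo == hi == 100.0
        assert rep.mean_accuracy == rep.median_accuracy == 100.0
        repF = ot.start_to_finish_accuracy(twin, te)
        assert all(v == 100.0 for v in repF.final_outcomes.values())

    def test_majority_constant_predictor_counting_oracle(self, split_preprocessed,
                                                         fitted_twin_stochastic):
        """A constant predictor's accuracy equals the majority frequency."""
        train, test, pre = split_preprocessed
        twin = fitted_twin_stochastic
        from sklearn.dummy import DummyClassifier

        name = "dlt"
        stage_model = twin.models[1]
        saved = stage_model.classifiers[name]
        try:
            X1 = np.zeros((train.n, 1))
            stage_model.classifiers[name] = DummyClassifier(
                strategy="constant", constant=0
            ).fit(X1, np.zeros(train.n))
            rep = ot.one_step_accuracy(twin, test, B=1, seed=0)
            majority = np.mean(test.df[name].to_numpy(float) == 0.0) * 100.0
            assert rep.per_feature[name][0] == pytest.approx(majority)
        finally:
            stage_model.classifiers[name] = saved

    def test_single_bootstrap_degenerates_to_point(self, noiseless_setup):
        twin, te = noiseless_setup["twin"], noiseless_setup["test"]
        rep = ot.one_step_accuracy(twin, te, B=1, seed=0)
        for acc, lo, hi in rep.per_feature.values():
            assert lo == hi == acc

    def test_dysphagia_is_or_of_toxicity_flags(self, split_preprocessed,
                                               fitted_twin_stochastic):
        _, test, _ = split_preprocessed
        rep = ot.start_to_finish_accuracy(fitted_twin_stochastic, test)
        frame, _ = fitted_twin_stochastic.simulate_chain(test, decider="recorded")
        sim_dp = ((frame["ft"] == 1) | (frame["ar_after"] == 1)).astype(float)
        true_dp = (
            (test.df.ft.to_numpy(float) == 1) | (test.df.ar_after.to_numpy(float) == 1)
        ).astype(float)
        assert rep.final_outcomes["dp"] == pytest.approx(
            100.0 * np.mean(sim_dp == true_dp)
        )

    def test_accuracy_invariant_to_patient_order(self, split_preprocessed,
                                                 fitted_twin_stochastic):
        _, test, _ = split_preprocessed
        rep_a = ot.one_step_accuracy(fitted_twin_stochastic, test, B=1, seed=0)
        perm = np.random.default_rng(3).permutation(test.n)
        rep_b = ot.one_step_accuracy(fitted_twin_stochastic, test.subset(perm), B=1, seed=0)
        for name in rep_a.per_feature:
            assert rep_a.per_feature[name][0] == pytest.approx(rep_b.per_feature[name][0])

    def test_evaluating_on_training_patients_is_a_protocol_error(
        self, split_preprocessed, fitted_twin_stochastic
    ):
        train, _, _ = split_preprocessed
        with pytest.raises(ProtocolError):
            ot.one_step_accuracy(fitted_twin_stochastic, train, B=1, seed=0)

    def test_chain_error_compounds_relative_to_one_step(self, split_preprocessed,
                                                        fitted_twin_stochastic):
        """Start-to-finish OS accuracy cannot beat one-step OS by much."""
        _, test, _ = split_preprocessed
        one = ot.one_step_accuracy(fitted_twin_stochastic, test, B=1, seed=0)
        chain = ot.start_to_finish_accuracy(fitted_twin_stochastic, test)
        one_os = one.per_feature["os"][0]
        se = 300.0 * np.sqrt(0.25 / test.n)  # 3 binomial SE in points
        assert chain.final_outcomes["os"] <= one_os + se


class TestPolicyDecider:
    def test_policy_queries_only_current_state(self, noiseless_setup):
        """Audit: each junction's decision precedes that junction's transition."""
        twin, te, pre = (
            noiseless_setup["twin"],
            noiseless_setup["test"],
            noiseless_setup["pre"],
        )
        trajs = ot.assemble_trajectories(noiseless_setup["train"], pre)
        stack = ot.TreatmentPolicy(trajs).fit(
            ot.NetworkSpec(n_hidden_layers=1, width=16, max_epochs=300, seed=0)
        )
        twin.audit_log.clear()
        twin.simulate_chain(te, stack)
        events = twin.audit_log
        assert events == [
            ("decide", 1), ("step", 1),
            ("decide", 2), ("step", 2),
            ("decide", 3), ("step", 3),
        ]
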