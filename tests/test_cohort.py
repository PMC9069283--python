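"""Cohort parsing, imputation, scaling, radiomics reduction and state layout."""

import io
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oncotwin as ot
from oncotwin.cohort import encode_and_scale, impute_missing
from oncotwin.schema import SchemaError, compact_schema


def _write_csv(tmp_path, table, name="c.csv"):
    p = tmp_path / name
    table.to_csv(p)
    return p


class TestLoadCohort:
    def test_roundtrip_identity(self, tmp_path, compact_cohort):
        p = _write_csv(tmp_path, compact_cohort)
        loaded = ot.load_cohort(p, compact_cohort.schema)
        assert loaded.n == compact_cohort.n
        for f in compact_cohort.schema.features:
            np.testing.assert_allclose(
                loaded.df[f.name].to_numpy(float),
                compact_cohort.df[f.name].to_numpy(float),
            )

    def test_missing_mandatory_column_names_it(self, tmp_path, compact_cohort):
        p = _write_csv(tmp_path, compact_cohort)
        df = pd.read_csv(p).drop(columns=["os"])
        p2 = tmp_path / "broken.csv"
        df.to_csv(p2, index=False)
        with pytest.raises(SchemaError, match="os"):
            ot.load_cohort(p2, compact_cohort.schema)

    def test_duplicate_patient_id_rejected(self, tmp_path, compact_cohort):
        p = _write_csv(tmp_path, compact_cohort)
        df = pd.read_csv(p)
        df.loc[1, "patient_id"] = df.loc[0, "patient_id"]
        p2 = tmp_path / "dup.csv"
        df.to_csv(p2, index=False)
        with pytest.raises(ot.InputError, match="duplicate"):
            ot.load_cohort(p2, compact_cohort.schema)

    def test_blank_cell_flagged_missing_not_dropped(self, tmp_path, compact_cohort):
        p = _write_csv(tmp_path, compact_cohort)
        df = pd.read_csv(p)
        df["age"] = df["age"].astype(object)
        df.loc[0, "age"] = ""
        p2 = tmp_path / "blank.csv"
        df.to_csv(p2, index=False)
        loaded = ot.load_cohort(p2, compact_cohort.schema)
        assert loaded.n == compact_cohort.n
        assert np.isnan(loaded.df.loc[0, "age"])


class TestImputation:
    def _table(self, ages, hpv=None):
        sch = compact_schema()
        n = len(ages)
        df = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)]})
        for f in sch.features:
            df[f.name] = 0.0
        df["age"] = ages
        if hpv is not None:
            df["hpv_status"] = hpv
        for d in ("d1", "d2", "d3"):
            df[d] = 0.0
        return ot.CohortTable(df, sch)

    def test_numeric_median(self):
        t = self._table([1.0, 2.0, np.nan, 4.0])
        out, imap = impute_missing(t)
        assert out.df.loc[2, "age"] == 2.0
        assert imap["age"] == 2.0

    def test_categorical_mode(self):
        t = self._table([50.0] * 4)
        t.df["t_category"] = [0.0, 0.0, 1.0, np.nan]
        out, _ = impute_missing(t)
        assert out.df.loc[3, "t_category"] == 0.0

    def test_hpv_unknown_coded_zero_never_imputed(self):
        # column mode is "positive" (code 2) but missing must become 0
        t = self._table([50.0] * 4, hpv=[2.0, 2.0, 2.0, np.nan])
        out, _ = impute_missing(t)
        assert out.df.loc[3, "hpv_status"] == 0.0

    def test_entirely_missing_column_errors(self):
        t = self._table([np.nan] * 3)
        with pytest.raises(ot.InputError, match="age"):
            impute_missing(t)

    def test_fitted_map_reused_on_heldout(self):
        train = self._table([1.0, 2.0, 4.0])
        _, imap = impute_missing(train)
        test = self._table([np.nan, 100.0])
        out, _ = impute_missing(test, fitted=imap)
        assert out.df.loc[0, "age"] == 2.0  # training median, not test's


class TestEncodeAndScale:
    def test_affine_endpoints(self, compact_cohort):
        t = compact_cohort.copy()
        t.df["age"] = np.where(np.arange(t.n) % 2, 2.0, 6.0)
        scaled, smap = encode_and_scale(t)
        assert set(np.unique(scaled["age"])) == {-1.0, 1.0}
        assert smap["age"] == (2.0, 6.0)

    def test_constant_column_maps_to_zero(self, compact_cohort):
        t = compact_cohort.copy()
        t.df["age"] = 5.0
        scaled, _ = encode_and_scale(t)
        assert (scaled["age"] == 0.0).all()

    def test_chemo_ordinal_codes_preserve_order(self):
        sch = compact_schema()
        f = sch["chemo_prescribed"]
        assert f.code_of("none") == 0
        assert f.code_of("doublet") == 2
        assert f.code_of("triplet") == 3
        assert f.code_of("none") < f.code_of("doublet") < f.code_of("triplet")

    def test_output_range_on_fitting_table(self, compact_cohort):
        scaled, _ = encode_and_scale(compact_cohort)
        arr = scaled.to_numpy()
        assert arr.min() >= -1.0 and arr.max() <= 1.0

    def test_heldout_clipped_with_training_stats(self, compact_cohort):
        train = compact_cohort.subset(range(0, 200))
        test = compact_cohort.subset(range(200, 240)).copy()
        _, smap = encode_and_scale(train)
        test.df["age"] = 1000.0  # far outside the training range
        scaled, _ = encode_and_scale(test, fitted_on=smap)
        assert (scaled["age"] == 1.0).all()


class TestRadiomics:
    def test_cumulative_ratio_arithmetic(self, rng):
        # per-axis variances (9, 0.5, 0.5): one component reaches 90%
        X = rng.normal(size=(400, 3)) * np.sqrt([9.0, 0.5, 0.5])
        scores, proj = ot.reduce_radiomics(X, target_variance=0.90)
        assert proj.n_components == 1
        assert scores.shape == (400, 1)

    def test_rank_one_data_needs_one_component(self, rng):
        u = rng.normal(size=(50, 1))
        X = u @ rng.normal(size=(1, 20))
        _, proj = ot.reduce_radiomics(X, target_variance=0.99)
        assert proj.n_components == 1

    def test_component_count_matches_eigenvalue_oracle(self, rng):
        X = rng.normal(size=(50, 20)) @ rng.normal(size=(20, 20))
        _, proj = ot.reduce_radiomics(X, target_variance=0.90)
        # independent oracle: eigendecomposition of the covariance matrix
        evals = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        ratio = np.cumsum(evals) / evals.sum()
        k_oracle = int(np.searchsorted(ratio, 0.90 - 1e-12) + 1)
        assert proj.n_components == k_oracle

    def test_monotone_in_target_variance(self, rng):
        X = rng.normal(size=(60, 10)) @ rng.normal(size=(10, 10))
        ks = [
            ot.reduce_radiomics(X, target_variance=v)[1].n_components
            for v in (0.5, 0.7, 0.9, 0.99)
        ]
        assert ks == sorted(ks)

    def test_invalid_target_variance(self, rng):
        with pytest.raises(ValueError):
            ot.reduce_radiomics(rng.normal(size=(10, 3)), target_variance=1.5)


class TestSplit:
    def test_paper_cohort_arithmetic(self):
        cfg = ot.GeneratorConfig(n=536, seed=0, schema="compact")
        table = ot.generate_cohort(cfg)
        train, test = ot.split_cohort(table, 0.75, seed=0)
        assert (train.n, test.n) == (402, 134)

    def test_round_half_up_small_n(self, compact_cohort):
        t = compact_cohort.subset(range(4))
        train, test = ot.split_cohort(t, 0.75, seed=0)
        assert (train.n, test.n) == (3, 1)

    def test_deterministic_and_disjoint_partition(self, compact_cohort):
        a1, b1 = ot.split_cohort(compact_cohort, 0.75, seed=42)
        a2, b2 = ot.split_cohort(compact_cohort, 0.75, seed=42)
        assert list(a1.ids) == list(a2.ids) and list(b1.ids) == list(b2.ids)
        ids_a, ids_b = set(a1.ids), set(b1.ids)
        assert not (ids_a & ids_b)
        assert ids_a | ids_b == set(compact_cohort.ids)

    def test_too_small_cohort(self, compact_cohort):
        with pytest.raises(ot.InputError):
            ot.split_cohort(compact_cohort.subset([0]), 0.75, seed=0)


class TestStateVectors:
    def test_stage0_contains_only_pretreatment_features(self, split_preprocessed):
        train, _, pre = split_preprocessed
        layout = pre.state_layout(0)
        g1 = {f.name for f in pre.schema.group(1)}
        assert all(name.split("=")[0] in g1 for name in layout)
        assert not any(name.startswith("d") and "=" in name for name in layout)

    def test_decision_onehot_convention(self, split_preprocessed):
        train, _, pre = split_preprocessed
        sv = pre.build_state(train, 0, stage=1)
        d1 = train.df.loc[0, "d1"]
        slots = sv.values[-2:]
        expected = np.zeros(2)
        expected[int(d1)] = 1.0
        np.testing.assert_array_equal(slots, expected)
        assert sv.layout[-2:] == ["d1=0", "d1=1"]

    def test_equal_dimensionality_across_patients(self, split_preprocessed):
        train, test, pre = split_preprocessed
        for stage in (0, 1, 2):
            Xtr = pre.state_matrix(train, stage)
            Xte = pre.state_matrix(test, stage)
            assert Xtr.shape[1] == Xte.shape[1] == len(pre.state_layout(stage))

    def test_outcomes_never_in_any_layout(self, split_preprocessed):
        _, _, pre = split_preprocessed
        for stage in (0, 1, 2):
            for name in pre.state_layout(stage):
                assert name.split("=")[0] not in ("os", "ft", "ar_after")

    def test_no_refit_on_heldout_transform(self, split_preprocessed):
        train, test, pre = split_preprocessed
        count = pre.fit_count
        pre.transform(test)
        pre.state_matrix(test, 2)
        assert pre.fit_count == count == 1


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(10, 60), st.integers(0, 2**31 - 1))
def test_split_partition_property(n, seed):
    """train and test always form a disjoint cover of the cohort."""
    cfg = ot.GeneratorConfig(n=n, seed=5, schema="compact")
    table = ot.generate_cohort(cfg)
    train, test = ot.split_cohort(table, 0.75, seed=seed)
    assert train.n == int(np.floor(0.75 * n + 0.5))
    assert set(train.ids) | set(test.ids) == set(table.ids)
    assert not (set(train.ids) & set(test.ids))
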