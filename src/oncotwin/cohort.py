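"""Cohort table parsing, preprocessing and state-vector construction.

The pipeline is: :func:`load_cohort` (CSV -> coded table with explicit
missing), :func:`impute_missing` (training-set median/mode), then
:func:`encode_and_scale` (one-hot expansion of unordered categoricals and an
affine map of every column into [-1, +1]).  :class:`Preprocessor` bundles the
fitted statistics so that held-out data are always transformed with training
statistics, and builds the stage-wise state vectors: stage 0 holds group 1,
stage 1 adds group 2 and a one-hot of d1, stage 2 adds group 3 and a one-hot
of d2.  Outcome (group-4) columns never enter a state vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .schema import DECISIONS, CohortSchema, Feature, SchemaError, default_schema

DEFAULT_NA = ("", "NA", "NaN", "nan", "N/A")


class InputError(ValueError):
    """Malformed cohort input (duplicate ids, non-binary decisions, ...)."""


@dataclass
class PatientRecord:
    """One patient's features partitioned into stage groups plus decisions."""

    patient_id: object
    group1: dict
    group2: dict
    group3: dict
    group4: dict
    decisions: tuple  # (d1, d2, d3); entries may be NaN before validation
    radiomics: np.ndarray | None = None

    @property
    def d1(self):
        return self.decisions[0]

    @property
    def d2(self):
        return self.decisions[1]

    @property
    def d3(self):
        return self.decisions[2]


class CohortTable:
    """Ordered collection of patients sharing one schema.

    ``df`` stores integer/float *codes* (level features coded per schema,
    numerics as floats, NaN for missing).  ``raw`` optionally keeps the
    original string cells (used by the guideline-compliance audit, which needs
    unimputed T/N categories, e.g. Tx).
    """

    def __init__(
        self,
        df: pd.DataFrame,
        schema: CohortSchema,
        raw: pd.DataFrame | None = None,
        radiomics: pd.DataFrame | None = None,
    ):
        self.df = df.reset_index(drop=True)
        self.schema = schema
        self.raw = raw.reset_index(drop=True) if raw is not None else None
        self.radiomics = (
            radiomics.reset_index(drop=True) if radiomics is not None else None
        )

    # -- basic container protocol ------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> pd.Series:
        return self.df[self.schema.id_column]

    def subset(self, indices: Sequence[int]) -> "CohortTable":
        idx = np.asarray(indices)
        return CohortTable(
            self.df.iloc[idx],
            self.schema,
            raw=self.raw.iloc[idx] if self.raw is not None else None,
            radiomics=self.radiomics.iloc[idx] if self.radiomics is not None else None,
        )

    def copy(self) -> "CohortTable":
        return CohortTable(
            self.df.copy(),
            self.schema,
            raw=self.raw.copy() if self.raw is not None else None,
            radiomics=self.radiomics.copy() if self.radiomics is not None else None,
        )

    def record(self, i: int) -> PatientRecord:
        row = self.df.iloc[i]
        groups = {g: {} for g in (1, 2, 3, 4)}
        for f in self.schema.features:
            groups[f.group][f.name] = row[f.name]
        rad = None
        if self.radiomics is not None:
            rad = self.radiomics.iloc[i].to_numpy(dtype=float)
        return PatientRecord(
            patient_id=row[self.schema.id_column],
            group1=groups[1],
            group2=groups[2],
            group3=groups[3],
            group4=groups[4],
            decisions=tuple(row[d] for d in DECISIONS),
            radiomics=rad,
        )

    @property
    def records(self) -> list[PatientRecord]:
        return [self.record(i) for i in range(self.n)]

    def has_missing(self) -> bool:
        cols = [f.name for f in self.schema.features]
        return bool(self.df[cols].isna().any().any())

    def to_csv(self, path) -> None:
        """Write the cohort with level features decoded back to level names."""
        out = self.df.copy()
        for f in self.schema.features:
            if f.kind == "numeric":
                continue
            inv = {v: k for k, v in f.level_codes.items()}
            out[f.name] = out[f.name].map(
                lambda c: inv.get(int(c)) if pd.notna(c) else ""
            )
        for d in DECISIONS:
            out[d] = out[d].astype("Int64")
        out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# parsing


def _parse_cell(cell: str, feat: Feature, na_values: tuple) -> float:
    if cell in na_values:
        return np.nan
    if feat.kind == "numeric":
        try:
            return float(cell)
        except ValueError:
            return np.nan
    codes = feat.level_codes
    if cell in codes:
        return float(codes[cell])
    # accept pre-coded integers
    try:
        val = int(float(cell))
    except ValueError:
        return np.nan
    return float(val) if val in codes.values() else np.nan


def load_cohort(
    path,
    schema: CohortSchema | None = None,
    radiomics_path=None,
    na_values: Iterable[str] = DEFAULT_NA,
) -> CohortTable:
    """Load a patient CSV into a coded :class:`CohortTable`.

    Unparseable cells are marked missing rather than dropped.  Missing
    mandatory columns raise :class:`~oncotwin.schema.SchemaError` naming the
    column; duplicate patient ids raise :class:`InputError`.
    """
    schema = schema or default_schema()
    na_values = tuple(na_values)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in schema.columns:
        if col not in raw.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    if raw[schema.id_column].duplicated().any():
        dup = raw[schema.id_column][raw[schema.id_column].duplicated()].iloc[0]
        raise InputError(f"duplicate patient_id {dup!r}")

    df = pd.DataFrame({schema.id_column: raw[schema.id_column]})
    for f in schema.features:
        df[f.name] = [_parse_cell(c, f, na_values) for c in raw[f.name]]
    for d in DECISIONS:
        vals = []
        for c in raw[d]:
            c = c.strip().lower()
            if c in ("0", "no", "false"):
                vals.append(0.0)
            elif c in ("1", "yes", "true"):
                vals.append(1.0)
            elif c in tuple(v.lower() for v in na_values):
                vals.append(np.nan)
            else:
                raise InputError(f"decision {d}: non-binary value {c!r}")
        df[d] = vals

    radiomics = None
    if radiomics_path is not None:
        rad = pd.read_csv(radiomics_path)
        rad = rad.set_index(schema.id_column).loc[raw[schema.id_column]].reset_index()
        radiomics = rad.drop(columns=[schema.id_column]).astype(float)
    return CohortTable(df, schema, raw=raw, radiomics=radiomics)


# ---------------------------------------------------------------------------
# imputation


def impute_missing(
    table: CohortTable, fitted: Mapping[str, float] | None = None
) -> tuple[CohortTable, dict]:
    """Single imputation: median for numerics, mode for level features.

    Features with a ``missing_code`` (HPV status) are filled with that
    distinguished code and never statistically imputed.  Returns the imputed
    table and the fitted imputation map so a held-out set can be transformed
    with training statistics (pass it back as ``fitted``).
    """
    df = table.df.copy()
    imap: dict = {} if fitted is None else dict(fitted)
    for f in table.schema.features:
        col = df[f.name]
        if f.missing_code is not None:
            fill = float(f.code_of(f.missing_code))
        elif fitted is not None:
            fill = imap[f.name]
        else:
            known = col.dropna()
            if known.empty:
                raise InputError(f"column {f.name!r} is entirely missing")
            if f.kind == "numeric":
                fill = float(known.median())
            else:
                fill = float(known.mode().iloc[0])
        imap[f.name] = fill
        df[f.name] = col.fillna(fill)
    out = CohortTable(df, table.schema, raw=table.raw, radiomics=table.radiomics)
    return out, imap


# ---------------------------------------------------------------------------
# encoding and scaling


def _encoded_columns(feat: Feature) -> list[str]:
    if feat.kind == "categorical":
        return [f"{feat.name}={lv}" for lv in feat.levels]
    return [feat.name]


def encode_columns(table: CohortTable, features: Sequence[Feature]) -> pd.DataFrame:
    """Expand unordered categoricals to one-hot columns; pass others through."""
    out = {}
    for f in features:
        col = table.df[f.name]
        if f.kind == "categorical":
            for lv in f.levels:
                out[f"{f.name}={lv}"] = (col == f.code_of(lv)).astype(float)
        else:
            out[f.name] = col.astype(float)
    return pd.DataFrame(out)


def encode_and_scale(
    table: CohortTable,
    fitted_on: Mapping[str, tuple] | None = None,
    features: Sequence[Feature] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Encode the table and rescale every column into [-1, +1].

    Ordinals keep their integer codes before scaling; unordered categoricals
    are one-hot expanded.  With ``fitted_on`` the stored per-column min/max
    are reused and out-of-range values are clipped, so held-out data respect
    the range contract.  Constant columns map to 0.
    """
    features = (
        list(features)
        if features is not None
        else [f for f in table.schema.features if f.group in (1, 2, 3)]
    )
    if table.df[[f.name for f in features]].isna().any().any():
        raise InputError("encode_and_scale requires a fully imputed table")
    enc = encode_columns(table, features)
    smap: dict = {}
    out = pd.DataFrame(index=enc.index)
    for col in enc.columns:
        if fitted_on is not None:
            if col not in fitted_on:
                raise SchemaError(f"no fitted scaling for column {col!r}")
            lo, hi = fitted_on[col]
        else:
            lo, hi = float(enc[col].min()), float(enc[col].max())
        smap[col] = (lo, hi)
        if hi == lo:
            out[col] = 0.0
        else:
            out[col] = np.clip(2.0 * (enc[col] - lo) / (hi - lo) - 1.0, -1.0, 1.0)
    return out, smap


# ---------------------------------------------------------------------------
# radiomics PCA


@dataclass
class RadiomicsProjection:
    """Fitted PCA projection for the radiomics block."""

    pca: PCA
    n_components: int

    def transform(self, matrix) -> np.ndarray:
        return self.pca.transform(np.asarray(matrix, dtype=float))[
            :, : self.n_components
        ]


def reduce_radiomics(
    matrix,
    target_variance: float = 0.90,
    n_components: int | None = None,
) -> tuple[np.ndarray, RadiomicsProjection]:
    """Keep the minimal leading principal components reaching the variance target.

    The block is centred before the eigendecomposition.  ``n_components``
    overrides the variance rule with a fixed count.
    """
    if not (0.0 < target_variance <= 1.0):
        raise ValueError("target_variance must lie in (0, 1]")
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("radiomics matrix needs at least 2 rows")
    pca = PCA(svd_solver="full").fit(X)
    if n_components is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, target_variance - 1e-12) + 1)
    else:
        k = int(n_components)
    proj = RadiomicsProjection(pca=pca, n_components=k)
    return proj.transform(X), proj


# ---------------------------------------------------------------------------
# train/test split


def split_cohort(
    table: CohortTable, train_fraction: float = 0.75, seed: int = 0
) -> tuple[CohortTable, CohortTable]:
    """Random disjoint split; |train| = round-half-up(train_fraction * N)."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    n = table.n
    if n < 2:
        raise InputError("need at least 2 patients to split")
    n_train = int(np.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return table.subset(np.sort(perm[:n_train])), table.subset(np.sort(perm[n_train:]))


# ---------------------------------------------------------------------------
# state vectors


@dataclass
class StateVector:
    """Scaled feature vector for one patient at one stage."""

    stage: int
    values: np.ndarray
    layout: list[str]


def _onehot(value) -> np.ndarray:
    v = int(value)
    if v not in (0, 1):
        raise InputError(f"decision value must be binary, got {value!r}")
    out = np.zeros(2)
    out[v] = 1.0
    return out


class Preprocessor:
    """Fitted imputation + scaling statistics and stage-wise state builder.

    Fit once on the training table; every subsequent ``transform``/state
    construction reuses the stored statistics (a fit-count audit guards
    against accidental refitting on held-out data).
    """

    def __init__(self, schema: CohortSchema | None = None):
        self.schema = schema or default_schema()
        self.imputation_map: dict | None = None
        self.scaling_map: dict | None = None
        self.radiomics_projection: RadiomicsProjection | None = None
        self.fit_count = 0
        self.fit_ids: list | None = None

    # -- fitting ------------------------------------------------------------
    def fit(self, table: CohortTable, radiomics_variance: float = 0.90) -> "Preprocessor":
        imputed, self.imputation_map = impute_missing(table)
        _, self.scaling_map = encode_and_scale(imputed)
        if table.radiomics is not None:
            _, self.radiomics_projection = reduce_radiomics(
                table.radiomics.to_numpy(), target_variance=radiomics_variance
            )
        self.fit_count += 1
        self.fit_ids = list(table.ids)
        return self

    def _check_fitted(self) -> None:
        if self.imputation_map is None:
            raise RuntimeError("Preprocessor is not fitted")

    def transform(self, table: CohortTable) -> CohortTable:
        """Impute a table with the stored training statistics."""
        self._check_fitted()
        out, _ = impute_missing(table, fitted=self.imputation_map)
        return out

    # -- state construction ---------------------------------------------------
    def state_layout(self, stage: int) -> list[str]:
        names: list[str] = []
        for f in self.schema.state_features(stage):
            names.extend(_encoded_columns(f))
        if self.radiomics_projection is not None:
            names.extend(
                f"radiomics_pc{j + 1}"
                for j in range(self.radiomics_projection.n_components)
            )
        for k in range(stage):
            names.extend([f"d{k + 1}=0", f"d{k + 1}=1"])
        return names

    def state_matrix(self, table: CohortTable, stage: int) -> np.ndarray:
        """Scaled state matrix (n_patients x state_dim) at a stage."""
        self._check_fitted()
        feats = self.schema.state_features(stage)
        scaled, _ = encode_and_scale(table, fitted_on=self.scaling_map, features=feats)
        blocks = [scaled.to_numpy(dtype=float)]
        if self.radiomics_projection is not None:
            if table.radiomics is None:
                raise InputError("preprocessor was fitted with radiomics but table has none")
            blocks.append(self.radiomics_projection.transform(table.radiomics.to_numpy()))
        for k in range(stage):
            dcol = table.df[DECISIONS[k]]
            if dcol.isna().any():
                raise InputError(f"stage {stage} state requires decision d{k + 1}")
            blocks.append(np.stack([_onehot(v) for v in dcol]))
        return np.hstack(blocks)

    def build_state(self, record_table: CohortTable, i: int, stage: int) -> StateVector:
        """State vector for patient ``i`` of a (preprocessed) table."""
        mat = self.state_matrix(table_row(record_table, i), stage)
        return StateVector(stage=stage, values=mat[0], layout=self.state_layout(stage))

    # -- serialisation --------------------------------------------------------
    def to_json(self, path) -> None:
        self._check_fitted()
        payload = {
            "schema": self.schema.to_dict(),
            "imputation_map": self.imputation_map,
            "scaling_map": {k: list(v) for k, v in self.scaling_map.items()},
        }
        if self.radiomics_projection is not None:
            proj = self.radiomics_projection
            payload["radiomics_projection"] = {
                "n_components": proj.n_components,
                "mean": proj.pca.mean_.tolist(),
                "components": proj.pca.components_[: proj.n_components].tolist(),
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def table_row(table: CohortTable, i: int) -> CohortTable:
    """Single-row view of a cohort table (keeps schema and radiomics)."""
    return table.subset([i])


def build_state(
    record_table: CohortTable, i: int, stage: int, pre: Preprocessor
) -> StateVector:
    """Functional wrapper over :meth:`Preprocessor.build_state`."""
    return pre.build_state(record_table, i, stage)
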