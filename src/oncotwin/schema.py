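"""Cohort schema: feature kinds, stage groups, and the default clinical layout.

The cohort is a flat per-patient table whose columns fall into four stage
groups: pretreatment features (group 1), post-induction-chemotherapy features
(group 2), post-concurrent-chemotherapy features (group 3), and final outcomes
(group 4), plus the three binary physician decisions d1 (induction
chemotherapy), d2 (concurrent chemotherapy vs. radiotherapy alone) and d3
(neck dissection).  Group-4 columns are outcomes only and are never part of
any state representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

KINDS = ("numeric", "binary", "ordinal", "categorical")

DECISIONS = ("d1", "d2", "d3")

#: group-4 column names (outcomes; excluded from every state vector)
OUTCOMES = ("os", "ft", "ar_after")


class SchemaError(ValueError):
    """Raised when a table does not conform to its schema."""


@dataclass(frozen=True)
class Feature:
    """One column of the cohort table.

    Parameters
    ----------
    name : column name.
    kind : one of ``numeric``, ``binary``, ``ordinal``, ``categorical``.
    group : stage group, 1-4.
    levels : ordered level names for binary/ordinal/categorical kinds.
    codes : optional explicit level -> integer code map (ordinals whose codes
        are not consecutive positions, e.g. prescribed chemotherapy where
        "none"=0 < "single"=1 < "doublet"=2 < "triplet"=3 < "quadruplet"=4).
    missing_code : level that absorbs missing values instead of imputation
        (e.g. HPV status "unknown", coded as the distinguished value 0).
    """

    name: str
    kind: str
    group: int
    levels: tuple[str, ...] | None = None
    codes: Mapping[str, int] | None = None
    missing_code: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.group not in (1, 2, 3, 4):
            raise SchemaError(f"feature {self.name!r}: group must be 1-4")
        if self.kind != "numeric" and not self.levels:
            raise SchemaError(f"feature {self.name!r}: {self.kind} needs levels")
        if self.kind == "binary" and len(self.levels) != 2:
            raise SchemaError(f"binary feature {self.name!r} needs exactly 2 levels")

    def code_of(self, level: str) -> int:
        if self.codes is not None:
            return int(self.codes[level])
        return self.levels.index(level)

    @property
    def level_codes(self) -> dict[str, int]:
        return {lv: self.code_of(lv) for lv in self.levels}

    @property
    def n_levels(self) -> int:
        return len(self.levels) if self.levels else 0


@dataclass
class CohortSchema:
    """Ordered collection of :class:`Feature` plus the decision columns."""

    features: list[Feature] = field(default_factory=list)
    id_column: str = "patient_id"

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")

    def __getitem__(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def group(self, g: int) -> list[Feature]:
        return [f for f in self.features if f.group == g]

    def group_names(self, g: int) -> list[str]:
        return [f.name for f in self.features if f.group == g]

    @property
    def columns(self) -> list[str]:
        """All mandatory table columns, in canonical order."""
        return (
            [self.id_column]
            + [f.name for f in self.features]
            + list(DECISIONS)
        )

    def state_features(self, stage: int) -> list[Feature]:
        """Features entering the state vector at a stage (complete history).

        Stage 0 is group 1 only; stage 1 adds group 2; stage 2 adds group 3.
        Group 4 never appears.
        """
        if stage not in (0, 1, 2):
            raise ValueError(f"stage must be 0, 1 or 2, got {stage}")
        groups = range(1, stage + 2)
        return [f for f in self.features if f.group in groups]

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "id_column": self.id_column,
            "features": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    "group": f.group,
                    **({"levels": list(f.levels)} if f.levels else {}),
                    **({"codes": dict(f.codes)} if f.codes else {}),
                    **({"missing_code": f.missing_code} if f.missing_code else {}),
                }
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSchema":
        feats = [
            Feature(
                name=fd["name"],
                kind=fd["kind"],
                group=int(fd["group"]),
                levels=tuple(fd["levels"]) if fd.get("levels") else None,
                codes=dict(fd["codes"]) if fd.get("codes") else None,
                missing_code=fd.get("missing_code"),
            )
            for fd in d["features"]
        ]
        return cls(features=feats, id_column=d.get("id_column", "patient_id"))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _binary(name: str, group: int) -> Feature:
    return Feature(name, "binary", group, levels=("no", "yes"))


def default_schema() -> CohortSchema:
    """The default clinical schema for the oropharyngeal-cancer cohort.

    Mirrors the four feature groups of the study table: 14 pretreatment
    features, 20 post-D1 features, 9 post-D2 features and 3 outcomes.
    """
    g1 = [
        Feature("age", "numeric", 1),
        Feature("pathological_grade", "ordinal", 1, levels=("I", "II", "III", "IV")),
        Feature("sex", "binary", 1, levels=("female", "male")),
        Feature(
            "hpv_status",
            "ordinal",
            1,
            levels=("unknown", "negative", "positive"),
            codes={"unknown": 0, "negative": 1, "positive": 2},
            missing_code="unknown",
        ),
        Feature("t_category", "ordinal", 1, levels=("T1", "T2", "T3", "T4")),
        Feature("n_category", "ordinal", 1, levels=("N0", "N1", "N2", "N3")),
        Feature("ajcc_stage", "ordinal", 1, levels=("I", "II", "III", "IV")),
        Feature("smoking_status", "categorical", 1, levels=("current", "former", "never")),
        Feature("smoking_py", "numeric", 1),
        _binary("ar_before", 1),
        Feature("n_nodes", "numeric", 1),
        Feature("laterality", "categorical", 1, levels=("bilateral", "left", "right")),
        Feature("subsite", "categorical", 1, levels=("base_of_tongue", "tonsil", "other")),
        Feature(
            "race",
            "categorical",
            1,
            levels=("black", "asian", "hispanic", "native_american", "white_or_other"),
        ),
    ]
    g2 = [
        Feature(
            "chemo_prescribed",
            "ordinal",
            2,
            levels=("none", "single", "doublet", "triplet", "quadruplet"),
            codes={"none": 0, "single": 1, "doublet": 2, "triplet": 3, "quadruplet": 4},
        ),
        _binary("chemo_modification", 2),
        Feature(
            "chemo_mod_type",
            "categorical",
            2,
            levels=(
                "no_adjustment",
                "modified",
                "delayed",
                "cancelled",
                "delayed_and_modified",
                "regimen_modification",
            ),
        ),
        _binary("dlt", 2),
        Feature("dlt_grade", "ordinal", 2, levels=("0", "1", "2", "3", "4")),
        _binary("dlt_dermatological", 2),
        _binary("dlt_neurological", 2),
        _binary("dlt_gastrointestinal", 2),
        _binary("dlt_hematological", 2),
        _binary("dlt_nephrological", 2),
        _binary("dlt_vascular", 2),
        _binary("dlt_infection", 2),
        _binary("imaging", 2),
        _binary("cr_primary", 2),
        _binary("cr_nodal", 2),
        _binary("pr_primary", 2),
        _binary("pr_nodal", 2),
        _binary("sd_primary", 2),
        _binary("sd_nodal", 2),
    ]
    g3 = [
        Feature("cc_regimen", "categorical", 3, levels=("none", "platinum", "cetuximab", "other")),
        _binary("cc_modification", 3),
        _binary("cr_primary_2", 3),
        _binary("cr_nodal_2", 3),
        _binary("pr_primary_2", 3),
        _binary("pr_nodal_2", 3),
        _binary("sd_primary_2", 3),
        _binary("sd_nodal_2", 3),
        _binary("dlt_2", 3),
    ]
    g4 = [_binary("os", 4), _binary("ft", 4), _binary("ar_after", 4)]
    return CohortSchema(features=g1 + g2 + g3 + g4)


def compact_schema() -> CohortSchema:
    """A reduced schema (5 features per intermediate group) for small studies.

    Same structure and kinds as :func:`default_schema`; intended for quick
    experiments where fitting ~30 per-feature transition classifiers is not
    warranted.
    """
    g1 = [
        Feature("age", "numeric", 1),
        Feature("sex", "binary", 1, levels=("female", "male")),
        Feature(
            "hpv_status",
            "ordinal",
            1,
            levels=("unknown", "negative", "positive"),
            codes={"unknown": 0, "negative": 1, "positive": 2},
            missing_code="unknown",
        ),
        Feature("t_category", "ordinal", 1, levels=("T1", "T2", "T3", "T4")),
        Feature("n_category", "ordinal", 1, levels=("N0", "N1", "N2", "N3")),
        _binary("ar_before", 1),
    ]
    g2 = [
        Feature(
            "chemo_prescribed",
            "ordinal",
            2,
            levels=("none", "single", "doublet", "triplet", "quadruplet"),
            codes={"none": 0, "single": 1, "doublet": 2, "triplet": 3, "quadruplet": 4},
        ),
        _binary("dlt", 2),
        _binary("imaging", 2),
        _binary("cr_primary", 2),
        _binary("pr_nodal", 2),
    ]
    g3 = [
        Feature("cc_regimen", "categorical", 3, levels=("none", "platinum", "cetuximab", "other")),
        _binary("cr_primary_2", 3),
        _binary("cr_nodal_2", 3),
        _binary("pr_nodal_2", 3),
        _binary("dlt_2", 3),
    ]
    g4 = [_binary("os", 4), _binary("ft", 4), _binary("ar_after", 4)]
    return CohortSchema(features=g1 + g2 + g3 + g4)
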