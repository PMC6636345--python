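"""Analysis-ready dataset assembly: demographics, lookback flags, risk scores.

One output row per cohort member: index date, binary treatment group,
age in completed years, sex, one column per covariate spec.  Comorbidity and
comedication flags look back over ``[index - window_days, index)`` and a flag
is set iff at least ``min_count`` matching records fall in that window, so
duplicate identical rows cannot change a ``min_count=1`` flag.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import pandas as pd

from .cohort_builder import CohortNode, IndexAssignment, _age_at
from .emr_model import CodeSet, StudyConfig, Tables, code_matches
from .errors import ConfigError, StructuralError

COVARIATE_SOURCES = ("demographic", "diagnosis_flag", "prescription_flag", "risk_score")


@dataclass(frozen=True)
class ScoreComponent:
    """One additive term of a risk score: a code set or demographic predicate."""

    label: str
    points: int
    code_set: CodeSet | None = None
    window_days: int = 365
    age_min: int | None = None
    age_max: int | None = None  # inclusive
    sex: str | None = None

    def __post_init__(self):
        if self.points < 0:
            raise ConfigError(f"score component {self.label!r}: points must be >= 0")


@dataclass(frozen=True)
class RiskScoreDef:
    name: str
    components: tuple[ScoreComponent, ...]


@dataclass(frozen=True)
class CovariateSpec:
    name: str
    source: str
    code_set: CodeSet | None = None
    window_days: int = 365
    min_count: int = 1
    risk_score: RiskScoreDef | None = None

    def __post_init__(self):
        if self.source not in COVARIATE_SOURCES:
            raise ConfigError(f"covariate {self.name!r}: unknown source {self.source!r}")
        if self.source in ("diagnosis_flag", "prescription_flag") and self.code_set is None:
            raise ConfigError(f"covariate {self.name!r}: code_set required")
        if self.source == "risk_score" and self.risk_score is None:
            raise ConfigError(f"covariate {self.name!r}: risk_score definition required")


# The default "annual stroke risk" score ships as an editable data table of
# additive components (CHA2DS2-VASc-style), not as code: any additive
# component/point definition is accepted in its place.
DEFAULT_STROKE_RISK = RiskScoreDef(
    name="stroke_risk",
    components=(
        ScoreComponent("congestive heart failure", 1,
                       CodeSet("chf", frozenset({"DX_CHF"}))),
        ScoreComponent("hypertension", 1, CodeSet("htn", frozenset({"DX_HTN"}))),
        ScoreComponent("age 75 or older", 2, age_min=75),
        ScoreComponent("diabetes", 1, CodeSet("dm", frozenset({"DX_DM"}))),
        ScoreComponent("prior stroke or TIA", 2,
                       CodeSet("stroke_tia", frozenset({"STROKE", "TIA"}))),
        ScoreComponent("vascular disease", 1, CodeSet("vasc", frozenset({"DX_VASC"}))),
        ScoreComponent("age 65 to 74", 1, age_min=65, age_max=74),
        ScoreComponent("female sex", 1, sex="female"),
    ),
)


def compute_risk_score(
    age_years: int,
    sex: str,
    has_codes: Callable[[CodeSet, int], bool],
    score: RiskScoreDef,
) -> int:
    """Sum of points over satisfied components.

    ``has_codes(code_set, window_days)`` reports whether the subject has at
    least one matching diagnosis in the pre-index window.
    """
    total = 0
    for comp in score.components:
        if comp.code_set is not None:
            ok = has_codes(comp.code_set, comp.window_days)
        else:
            ok = True
            if comp.age_min is not None:
                ok = ok and age_years >= comp.age_min
            if comp.age_max is not None:
                ok = ok and age_years <= comp.age_max
            if comp.sex is not None:
                ok = ok and sex == comp.sex
        if ok:
            total += comp.points
    return total


def assemble(
    cohort: CohortNode,
    index: Mapping[str, IndexAssignment],
    tables: Tables,
    specs: Sequence[CovariateSpec],
    treated_group: str,
) -> pd.DataFrame:
    """Build the analysis-ready dataset for one cohort node.

    Rows are ordered by patient_id; flags default to 0, so the table carries
    no missing values.  ``group`` is 1 for the treated-of-interest exposure
    group and 0 for the comparator.
    """
    missing = [pid for pid in cohort.members if pid not in index]
    if missing:
        raise StructuralError(f"members lack an index assignment: {missing[:5]}")

    patients = {p.patient_id: p for p in tables.patients}
    dx_by_patient: dict[str, list] = {}
    for rec in tables.diagnoses:
        dx_by_patient.setdefault(rec.patient_id, []).append(rec)
    rx_by_patient: dict[str, list] = {}
    for rec in tables.prescriptions:
        rx_by_patient.setdefault(rec.patient_id, []).append(rec)

    rows = []
    for pid in sorted(cohort.members):
        assign = index[pid]
        patient = patients[pid]
        idx = assign.index_date
        age = _age_at(patient.birth_date, idx)

        def count_dx(cs: CodeSet, window_days: int) -> int:
            lo = idx - dt.timedelta(days=window_days)
            return sum(
                1 for r in dx_by_patient.get(pid, [])
                if lo <= r.date < idx and code_matches(r.code, cs)
            )

        def count_rx(cs: CodeSet, window_days: int) -> int:
            lo = idx - dt.timedelta(days=window_days)
            return sum(
                1 for r in rx_by_patient.get(pid, [])
                if lo <= r.start_date < idx and code_matches(r.drug_code, cs)
            )

        row: dict = {
            "patient_id": pid,
            "index_date": idx,
            "group": 1 if assign.index_group == treated_group else 0,
            "age_years": age,
            "sex": 1 if patient.sex == "female" else 0,
        }
        for spec in specs:
            if spec.source == "demographic":
                continue  # age/sex always present
            elif spec.source == "diagnosis_flag":
                row[spec.name] = int(count_dx(spec.code_set, spec.window_days) >= spec.min_count)
            elif spec.source == "prescription_flag":
                row[spec.name] = int(count_rx(spec.code_set, spec.window_days) >= spec.min_count)
            else:  # risk_score
                row[spec.name] = compute_risk_score(
                    age, patient.sex,
                    lambda cs, w: count_dx(cs, w) >= 1,
                    spec.risk_score,
                )
        rows.append(row)

    columns = ["patient_id", "index_date", "group", "age_years", "sex"] + [
        s.name for s in specs if s.source != "demographic"
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Covariate-spec parsing and the template library
# ---------------------------------------------------------------------------

def spec_from_dict(raw: Mapping) -> CovariateSpec:
    kwargs = dict(raw)
    if "codes" in kwargs:
        kwargs["code_set"] = CodeSet(
            name=kwargs.get("name", "covariate"),
            codes=frozenset(str(c) for c in kwargs.pop("codes")),
            match_mode=kwargs.pop("match_mode", "exact"),
        )
    if kwargs.get("source") == "risk_score" and "risk_score" not in kwargs:
        kwargs["risk_score"] = DEFAULT_STROKE_RISK
    return CovariateSpec(**kwargs)


def specs_from_config(config: StudyConfig) -> list[CovariateSpec]:
    return [spec_from_dict(raw) for raw in config.covariate_templates]


class TemplateLibrary:
    """Named, reusable covariate-spec sets (the "template library")."""

    def __init__(self) -> None:
        self._templates: dict[str, tuple[CovariateSpec, ...]] = {}

    def save(self, name: str, specs: Sequence[CovariateSpec]) -> None:
        if name in self._templates:
            raise ConfigError(f"template {name!r} already exists")
        self._templates[name] = tuple(specs)

    def load(self, name: str) -> tuple[CovariateSpec, ...]:
        if name not in self._templates:
            raise ConfigError(f"unknown template {name!r}")
        return self._templates[name]

    def names(self) -> list[str]:
        return sorted(self._templates)
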