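"""Tabular EMR schemas, code-set semantics, study configuration, and file I/O.

All dates are ISO-8601 calendar dates.  Every interval in the pipeline is
closed on the left and open on the right, measured in whole days, so that
person-day arithmetic never double counts a boundary day.  A prescription
covers ``[start_date, start_date + days_supplied)``.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError, SchemaError, ValidationError

SETTINGS = ("outpatient", "inpatient", "emergency")
SEXES = ("female", "male")

PATIENT_COLUMNS = ("patient_id", "birth_date", "sex", "data_end_date")
DIAGNOSIS_COLUMNS = ("patient_id", "date", "code", "setting")
PRESCRIPTION_COLUMNS = ("patient_id", "drug_code", "start_date", "days_supplied")


def parse_date(text: str, *, row: int | None = None) -> dt.date:
    """Parse an ISO calendar date, raising a row-tagged ValidationError."""
    try:
        return dt.date.fromisoformat(text.strip())
    except ValueError:
        where = f" (row {row})" if row is not None else ""
        raise ValidationError(f"unparseable date {text!r}{where}") from None


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    birth_date: dt.date
    sex: str
    data_end_date: dt.date

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r} for {self.patient_id}")
        if self.birth_date > self.data_end_date:
            raise ValidationError(
                f"birth_date after data_end_date for {self.patient_id}"
            )


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    date: dt.date
    code: str
    setting: str

    def __post_init__(self):
        if self.setting not in SETTINGS:
            raise ValidationError(
                f"unknown setting {self.setting!r} for {self.patient_id}"
            )


@dataclass(frozen=True)
class PrescriptionRecord:
    patient_id: str
    drug_code: str
    start_date: dt.date
    days_supplied: int

    def __post_init__(self):
        if self.days_supplied < 1:
            raise ValidationError(
                f"days_supplied must be >= 1, got {self.days_supplied} "
                f"for {self.patient_id}"
            )

    @property
    def end_date(self) -> dt.date:
        """Exclusive end of supply: start + days_supplied."""
        return self.start_date + dt.timedelta(days=self.days_supplied)


@dataclass(frozen=True)
class CodeSet:
    """A named list of codes with exact or prefix matching.

    The coding system is deliberately unspecified: any string vocabulary
    works, so ICD-9/ICD-10/ATC/local codes are all usable.
    """

    name: str
    codes: frozenset[str]
    match_mode: str = "exact"

    def __post_init__(self):
        if not self.codes:
            raise ConfigError(f"code set {self.name!r} is empty")
        if self.match_mode not in ("exact", "prefix"):
            raise ConfigError(
                f"code set {self.name!r}: match_mode must be exact|prefix, "
                f"got {self.match_mode!r}"
            )


def code_matches(code: str, cs: CodeSet) -> bool:
    """True iff ``code`` matches the code set.

    Exact mode is set membership; prefix mode is true iff some member of the
    set is a prefix of ``code`` (so "I48" matches "I48.0" but not vice versa).
    """
    if cs.match_mode == "exact":
        return code in cs.codes
    return any(code.startswith(member) for member in cs.codes)


@dataclass
class Tables:
    """The three validated record collections, in file row order."""

    patients: list[PatientRecord]
    diagnoses: list[DiagnosisRecord]
    prescriptions: list[PrescriptionRecord]

    def patient_ids(self) -> set[str]:
        return {p.patient_id for p in self.patients}


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    study_window: tuple[dt.date, dt.date]
    exposure_sets: dict[str, CodeSet]
    outcome_sets: dict[str, CodeSet]
    incident_exclusion_sets: dict[str, CodeSet] = field(default_factory=dict)
    treated_group: str | None = None  # exposure group coded 1; default: first key
    washout_days: int = 365
    lookback_days: int = 365
    max_followup_days: int = 730
    gap_days: int = 30
    caliper: float = 0.2
    caliper_scale: str = "logit_sd"
    smd_threshold: float = 0.1
    alpha: float = 0.05
    ci_method: str = "poisson_exact"  # or "clopper_pearson"
    covariate_templates: list[dict] = field(default_factory=list)
    criteria: list[dict] = field(default_factory=list)
    risk_scores: list[dict] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        start, end = self.study_window
        if start >= end:
            raise ConfigError("study_window: start must precede end")
        for name in ("washout_days", "lookback_days", "max_followup_days", "gap_days"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.caliper <= 0:
            raise ConfigError(f"caliper must be positive, got {self.caliper}")
        if self.caliper_scale not in ("logit_sd", "raw"):
            raise ConfigError(f"caliper_scale must be logit_sd|raw, got {self.caliper_scale!r}")
        if self.ci_method not in ("poisson_exact", "clopper_pearson"):
            raise ConfigError(f"unknown ci_method {self.ci_method!r}")
        if len(self.exposure_sets) != 2:
            raise ConfigError(
                f"exactly 2 exposure groups required, got {len(self.exposure_sets)}"
            )
        if not self.outcome_sets:
            raise ConfigError("at least one outcome set required")
        if self.treated_group is None:
            self.treated_group = next(iter(self.exposure_sets))
        elif self.treated_group not in self.exposure_sets:
            raise ConfigError(f"treated_group {self.treated_group!r} not an exposure set")
        for name in self.incident_exclusion_sets:
            if name not in self.outcome_sets:
                raise ConfigError(
                    f"incident_exclusion_sets names unknown outcome {name!r}"
                )

    @property
    def comparator_group(self) -> str:
        return next(g for g in self.exposure_sets if g != self.treated_group)


def _parse_code_set(name: str, raw: Mapping) -> CodeSet:
    if not isinstance(raw, Mapping) or "codes" not in raw:
        raise ConfigError(f"code set {name!r}: expected a mapping with a 'codes' list")
    return CodeSet(
        name=name,
        codes=frozenset(str(c) for c in raw["codes"]),
        match_mode=raw.get("match_mode", "exact"),
    )


def _parse_code_set_map(section: Mapping | None, what: str) -> dict[str, CodeSet]:
    out: dict[str, CodeSet] = {}
    for name, raw in (section or {}).items():
        if name in out:
            raise ConfigError(f"duplicate {what} name {name!r}")
        out[name] = _parse_code_set(name, raw)
    return out


def config_from_dict(raw: Mapping) -> StudyConfig:
    """Build a StudyConfig from a parsed mapping, applying defaults."""
    if "study_window" not in raw:
        raise ConfigError("study_window is required")
    window = raw["study_window"]
    if not isinstance(window, Sequence) or len(window) != 2:
        raise ConfigError("study_window must be a [start, end] pair")
    start, end = (
        d if isinstance(d, dt.date) else parse_date(str(d)) for d in window
    )
    kwargs: dict = {
        "study_window": (start, end),
        "exposure_sets": _parse_code_set_map(raw.get("exposure_sets"), "exposure set"),
        "outcome_sets": _parse_code_set_map(raw.get("outcome_sets"), "outcome set"),
        "incident_exclusion_sets": _parse_code_set_map(
            raw.get("incident_exclusion_sets"), "incident exclusion set"
        ),
    }
    passthrough = (
        "treated_group", "washout_days", "lookback_days", "max_followup_days",
        "gap_days", "caliper", "caliper_scale", "smd_threshold", "alpha",
        "ci_method", "covariate_templates", "criteria", "risk_scores", "seed",
    )
    for key in passthrough:
        if key in raw and raw[key] is not None:
            kwargs[key] = raw[key]
    unknown = set(raw) - set(passthrough) - {
        "study_window", "exposure_sets", "outcome_sets", "incident_exclusion_sets",
        "simulation",
    }
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return StudyConfig(**kwargs)


def load_config(path: str | Path) -> StudyConfig:
    """Load a YAML study configuration, applying documented defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")
    return config_from_dict(raw)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def _read_csv_rows(path: Path, columns: Sequence[str], delimiter: str):
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in columns if c not in header]
        if missing:
            raise SchemaError(f"{path.name}: missing column(s) {', '.join(missing)}")
        yield from enumerate(reader, start=2)  # data starts on line 2


def read_tables(
    patients_path: str | Path,
    diagnoses_path: str | Path,
    prescriptions_path: str | Path,
    delimiter: str = ",",
) -> Tables:
    """Read and validate the three EMR tables, preserving row order."""
    patients = []
    seen_ids: set[str] = set()
    for row_no, row in _read_csv_rows(Path(patients_path), PATIENT_COLUMNS, delimiter):
        pid = row["patient_id"]
        if pid in seen_ids:
            raise ValidationError(f"duplicate patient_id {pid!r} (row {row_no})")
        seen_ids.add(pid)
        patients.append(PatientRecord(
            patient_id=pid,
            birth_date=parse_date(row["birth_date"], row=row_no),
            sex=row["sex"],
            data_end_date=parse_date(row["data_end_date"], row=row_no),
        ))

    diagnoses = []
    for row_no, row in _read_csv_rows(Path(diagnoses_path), DIAGNOSIS_COLUMNS, delimiter):
        if row["setting"] not in SETTINGS:
            raise ValidationError(
                f"unknown setting {row['setting']!r} (row {row_no})"
            )
        diagnoses.append(DiagnosisRecord(
            patient_id=row["patient_id"],
            date=parse_date(row["date"], row=row_no),
            code=row["code"],
            setting=row["setting"],
        ))

    prescriptions = []
    for row_no, row in _read_csv_rows(
        Path(prescriptions_path), PRESCRIPTION_COLUMNS, delimiter
    ):
        try:
            days = int(row["days_supplied"])
        except ValueError:
            raise ValidationError(
                f"days_supplied not an integer (row {row_no}): "
                f"{row['days_supplied']!r}"
            ) from None
        prescriptions.append(PrescriptionRecord(
            patient_id=row["patient_id"],
            drug_code=row["drug_code"],
            start_date=parse_date(row["start_date"], row=row_no),
            days_supplied=days,
        ))

    return Tables(patients, diagnoses, prescriptions)


def write_tables(tables: Tables, out_dir: str | Path, delimiter: str = ",") -> dict[str, Path]:
    """Write the three CSVs; returns the file paths keyed by table name."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out_dir / "patients.csv",
        "diagnoses": out_dir / "diagnoses.csv",
        "prescriptions": out_dir / "prescriptions.csv",
    }
    specs = [
        (paths["patients"], PATIENT_COLUMNS, tables.patients),
        (paths["diagnoses"], DIAGNOSIS_COLUMNS, tables.diagnoses),
        (paths["prescriptions"], PRESCRIPTION_COLUMNS, tables.prescriptions),
    ]
    for path, columns, records in specs:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow(columns)
            for rec in records:
                writer.writerow([getattr(rec, f.name) for f in fields(rec)])
    return paths
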