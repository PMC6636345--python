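"""Attrition-tree construction: new-user identification, sequential
inclusion/exclusion criteria, and incident-outcome subcohorts.

Every filter step emits a :class:`CohortNode` carrying its membership and
in/dropped/out counts, so the final tree doubles as the study flowchart.
Pre-index windows are ``[index - k, index)``: the index date itself is never
part of "before the index date", which prevents the index prescription or a
same-day event from self-excluding a subject.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import pandas as pd

from .emr_model import CodeSet, Tables, code_matches, SETTINGS
from .errors import ConfigError, StructuralError

CRITERION_KINDS = (
    "require_diagnosis", "exclude_diagnosis",
    "require_prescription", "exclude_prescription",
    "age_at_least", "custom_flag",
)


@dataclass(frozen=True)
class IndexAssignment:
    patient_id: str
    index_date: dt.date
    index_group: str


@dataclass(frozen=True)
class Criterion:
    label: str
    kind: str
    code_set: CodeSet | None = None
    window: tuple[int, int] = (-365, 0)  # day offsets relative to index
    settings: tuple[str, ...] = SETTINGS
    min_count: int = 1
    threshold: int | None = None  # age_at_least
    predicate: Callable[[str], bool] | None = None  # custom_flag

    def __post_init__(self):
        if self.kind not in CRITERION_KINDS:
            raise ConfigError(f"unknown criterion kind {self.kind!r}")
        if self.window[0] > self.window[1]:
            raise ConfigError(f"criterion {self.label!r}: window offsets out of order")
        if self.min_count < 1:
            raise ConfigError(f"criterion {self.label!r}: min_count must be >= 1")
        if self.kind.endswith(("diagnosis", "prescription")) and self.code_set is None:
            raise ConfigError(f"criterion {self.label!r}: code_set required")
        if self.kind == "age_at_least" and self.threshold is None:
            raise ConfigError(f"criterion {self.label!r}: threshold required")


def criterion_from_dict(raw: Mapping) -> Criterion:
    """Parse a criterion from its config-dialect mapping."""
    kwargs = dict(raw)
    if "codes" in kwargs:
        kwargs["code_set"] = CodeSet(
            name=kwargs.get("label", "criterion"),
            codes=frozenset(str(c) for c in kwargs.pop("codes")),
            match_mode=kwargs.pop("match_mode", "exact"),
        )
    if "window" in kwargs:
        kwargs["window"] = tuple(int(v) for v in kwargs["window"])
    if "settings" in kwargs:
        kwargs["settings"] = tuple(kwargs["settings"])
    return Criterion(**kwargs)


@dataclass
class CohortNode:
    node_id: str
    label: str
    parent: str | None
    members: tuple[str, ...]
    n_in: int
    n_dropped: int
    criterion: Criterion | None = None

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_dropped


def _node_id(parent: str | None, label: str) -> str:
    # deterministic (hash of parent id + label), not a random UUID, so that
    # identical runs produce identical trees
    digest = hashlib.sha1(f"{parent or ''}|{label}".encode()).hexdigest()
    return digest[:12]


class CohortTree:
    """Ordered collection of CohortNodes with parent links."""

    def __init__(self) -> None:
        self._nodes: dict[str, CohortNode] = {}
        self._order: list[str] = []

    def add(
        self,
        label: str,
        members: Iterable[str],
        parent: CohortNode | None = None,
        criterion: Criterion | None = None,
    ) -> CohortNode:
        members = tuple(members)
        parent_id = parent.node_id if parent else None
        if parent is not None:
            if parent.node_id not in self._nodes:
                raise StructuralError(f"parent node {parent.node_id} not in tree")
            extra = set(members) - set(parent.members)
            if extra:
                raise StructuralError(
                    f"node {label!r} gains members absent from its parent: {sorted(extra)[:5]}"
                )
            n_in = len(parent.members)
        else:
            n_in = len(members)
        node = CohortNode(
            node_id=_node_id(parent_id, label),
            label=label,
            parent=parent_id,
            members=members,
            n_in=n_in,
            n_dropped=n_in - len(members),
            criterion=criterion,
        )
        if node.node_id in self._nodes:
            raise StructuralError(f"duplicate node for label {label!r}")
        self._nodes[node.node_id] = node
        self._order.append(node.node_id)
        return node

    def __iter__(self):
        return (self._nodes[i] for i in self._order)

    def __len__(self) -> int:
        return len(self._order)

    def node(self, node_id: str) -> CohortNode:
        return self._nodes[node_id]

    def leaf(self) -> CohortNode:
        return self._nodes[self._order[-1]]


# ---------------------------------------------------------------------------
# New-user identification
# ---------------------------------------------------------------------------

def identify_new_users(
    tables: Tables,
    exposure_sets: Mapping[str, CodeSet],
    study_window: tuple[dt.date, dt.date],
    washout_days: float,
    tree: CohortTree | None = None,
) -> tuple[dict[str, IndexAssignment], CohortTree]:
    """New-user index assignment with a full attrition chain.

    The index date is the first start of any exposure-set drug within the
    study window (both endpoints inclusive).  Subjects with any exposure
    prescription in ``[index - washout_days, index)`` are excluded, as are
    subjects starting drugs from both exposure groups on the index date.
    ``washout_days`` may be ``math.inf`` for an all-history new-user rule.
    """
    if not exposure_sets:
        raise ConfigError("identify_new_users: no exposure sets defined")
    start, end = study_window
    tree = tree if tree is not None else CohortTree()

    patient_order = [p.patient_id for p in tables.patients]
    root = tree.add("all patients", patient_order)

    # per-patient exposure prescriptions, tagged with the matching group(s)
    by_patient: dict[str, list[tuple[dt.date, set[str]]]] = {}
    for rx in tables.prescriptions:
        groups = {g for g, cs in exposure_sets.items() if code_matches(rx.drug_code, cs)}
        if groups:
            by_patient.setdefault(rx.patient_id, []).append((rx.start_date, groups))

    indexed: dict[str, tuple[dt.date, set[str]]] = {}
    for pid in patient_order:
        in_window = [
            (d, g) for d, g in by_patient.get(pid, []) if start <= d <= end
        ]
        if not in_window:
            continue
        index_date = min(d for d, _ in in_window)
        index_groups: set[str] = set()
        for d, g in in_window:
            if d == index_date:
                index_groups |= g
        indexed[pid] = (index_date, index_groups)

    node = tree.add(
        "exposure prescription within study window",
        [pid for pid in patient_order if pid in indexed],
        parent=root,
    )

    def had_prior_use(pid: str) -> bool:
        index_date, _ = indexed[pid]
        for d, _groups in by_patient.get(pid, []):
            if d >= index_date:
                continue
            if washout_days == float("inf") or (index_date - d).days <= washout_days:
                return True
        return False

    node = tree.add(
        "no prior exposure within washout",
        [pid for pid in node.members if not had_prior_use(pid)],
        parent=node,
    )

    node = tree.add(
        "single exposure group on index date",
        [pid for pid in node.members if len(indexed[pid][1]) == 1],
        parent=node,
    )

    assignments = {
        pid: IndexAssignment(pid, indexed[pid][0], next(iter(indexed[pid][1])))
        for pid in node.members
    }
    return assignments, tree


# ---------------------------------------------------------------------------
# Criterion application
# ---------------------------------------------------------------------------

def _age_at(birth: dt.date, on: dt.date) -> int:
    """Age in completed years by date arithmetic (not division by 365.25)."""
    years = on.year - birth.year
    if (on.month, on.day) < (birth.month, birth.day):
        years -= 1
    return years


def _count_matches(
    criterion: Criterion,
    tables: Tables,
    pid: str,
    index_date: dt.date,
) -> int:
    lo = index_date + dt.timedelta(days=criterion.window[0])
    hi = index_date + dt.timedelta(days=criterion.window[1])
    n = 0
    if criterion.kind.endswith("diagnosis"):
        for rec in tables.diagnoses:
            if (rec.patient_id == pid and lo <= rec.date < hi
                    and rec.setting in criterion.settings
                    and code_matches(rec.code, criterion.code_set)):
                n += 1
    else:
        for rec in tables.prescriptions:
            if (rec.patient_id == pid and lo <= rec.start_date < hi
                    and code_matches(rec.drug_code, criterion.code_set)):
                n += 1
    return n


def apply_criterion(
    tree: CohortTree,
    node: CohortNode,
    criterion: Criterion,
    tables: Tables,
    index: Mapping[str, IndexAssignment],
) -> CohortNode:
    """Filter a node by one criterion, emitting the child node."""
    birth = {p.patient_id: p.birth_date for p in tables.patients}

    def satisfied(pid: str) -> bool:
        idx = index[pid].index_date
        if criterion.kind == "age_at_least":
            return _age_at(birth[pid], idx) >= criterion.threshold
        if criterion.kind == "custom_flag":
            if criterion.predicate is None:
                raise ConfigError(f"criterion {criterion.label!r}: predicate required")
            return bool(criterion.predicate(pid))
        count = _count_matches(criterion, tables, pid, idx)
        has = count >= criterion.min_count
        return not has if criterion.kind.startswith("exclude") else has

    kept = [pid for pid in node.members if satisfied(pid)]
    return tree.add(criterion.label, kept, parent=node, criterion=criterion)


def build_incident_subcohort(
    tree: CohortTree,
    node: CohortNode,
    outcome_name: str,
    exclusion_set: CodeSet,
    lookback_days: int,
    tables: Tables,
    index: Mapping[str, IndexAssignment],
) -> CohortNode:
    """Drop members with any exclusion-set diagnosis in the pre-index window.

    Each outcome's subcohort branches from the same parent, giving the tree
    structure of the per-outcome study flows.  A diagnosis ON the index date
    is outside ``[index - lookback, index)`` and therefore retained here; it
    is a follow-up concern, not a history one.
    """
    criterion = Criterion(
        label=f"no prior {outcome_name} within {lookback_days} days",
        kind="exclude_diagnosis",
        code_set=exclusion_set,
        window=(-lookback_days, 0),
    )
    return apply_criterion(tree, node, criterion, tables, index)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def attrition_report(tree: CohortTree) -> pd.DataFrame:
    """Ordered attrition table: one row per node in tree order."""
    seen: set[str] = set()
    rows = []
    for node in tree:
        if node.parent is not None and node.parent not in seen:
            raise StructuralError(f"node {node.node_id} precedes its parent")
        seen.add(node.node_id)
        rows.append({
            "node_id": node.node_id,
            "label": node.label,
            "n_in": node.n_in,
            "n_dropped": node.n_dropped,
            "n_out": node.n_out,
        })
    return pd.DataFrame(rows, columns=["node_id", "label", "n_in", "n_dropped", "n_out"])


def render_tree(tree: CohortTree) -> str:
    """Human-readable indented text flowchart of the attrition tree."""
    depth: dict[str, int] = {}
    lines = []
    for node in tree:
        d = 0 if node.parent is None else depth[node.parent] + 1
        depth[node.node_id] = d
        lines.append(
            f"{'  ' * d}{node.label}: in={node.n_in} dropped={node.n_dropped} out={node.n_out}"
        )
    return "\n".join(lines) + "\n"
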