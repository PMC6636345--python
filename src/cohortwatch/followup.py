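"""ITT/AT follow-up construction and incidence summaries.

Episode stitching implements the refill-gap discontinuation rule: two
consecutive supplies belong to one treatment episode iff the gap between the
end of one supply and the next start is at most ``gap_days`` (a *greater
than* 30-day gap discontinues, so a gap of exactly 30 days does not).
As-treated follow-up censors at the first episode's last supply end.

Incidence density is events per 100,000 person-days (that is what the
published table's arithmetic uses, whatever the unit label says); the
cumulative-incidence confidence interval is exact Poisson (Garwood) on the
event count by default — the method that reproduces the published intervals
— with Clopper-Pearson available by configuration.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .emr_model import CodeSet, DiagnosisRecord, PrescriptionRecord, code_matches
from .errors import StructuralError

END_REASONS = ("outcome", "discontinuation", "max_followup", "data_end")


@dataclass(frozen=True)
class TreatmentEpisode:
    patient_id: str
    episode_start: dt.date
    episode_end: dt.date  # exclusive: end of the last supply in the episode

    def __post_init__(self):
        if self.episode_start >= self.episode_end:
            raise StructuralError("episode start must precede end")


@dataclass(frozen=True)
class FollowUpRecord:
    patient_id: str
    group: str
    mode: str  # ITT | AT
    time_days: int
    event: int
    end_reason: str


@dataclass(frozen=True)
class IncidenceSummary:
    group: str
    mode: str
    outcome: str
    n_subjects: int
    events: int
    person_days: int
    incidence_density: float  # per 100,000 person-days
    cumulative_incidence_pct: float
    ci95: tuple[float, float]  # percent
    ci_method: str


def build_episodes(
    prescriptions: Sequence[PrescriptionRecord],
    gap_days: int,
) -> list[TreatmentEpisode]:
    """Merge one patient's prescriptions of the index drug class into episodes.

    Consecutive supplies merge when ``next.start - current.end <= gap_days``;
    overlapping supplies extend the running end by max().  The episode end is
    the end of the last supply, which is also the AT discontinuation instant.
    """
    if not prescriptions:
        return []
    pids = {rx.patient_id for rx in prescriptions}
    if len(pids) > 1:
        raise StructuralError(f"episodes must be built per patient, got {sorted(pids)}")
    pid = prescriptions[0].patient_id

    ordered = sorted(prescriptions, key=lambda r: (r.start_date, r.end_date))
    episodes: list[TreatmentEpisode] = []
    start = ordered[0].start_date
    end = ordered[0].end_date
    for rx in ordered[1:]:
        gap = (rx.start_date - end).days
        if gap > gap_days:
            episodes.append(TreatmentEpisode(pid, start, end))
            start, end = rx.start_date, rx.end_date
        else:
            end = max(end, rx.end_date)
    episodes.append(TreatmentEpisode(pid, start, end))
    return episodes


def first_outcome(
    diagnoses: Iterable[DiagnosisRecord],
    outcome_set: CodeSet,
    index_date: dt.date,
) -> dt.date | None:
    """Earliest matching diagnosis strictly after the index date, any setting.

    A same-day diagnosis is treated as prevalent, not incident; the
    subcohort history filter is responsible for those subjects.
    """
    dates = [
        rec.date
        for rec in diagnoses
        if rec.date > index_date and code_matches(rec.code, outcome_set)
    ]
    return min(dates) if dates else None


def build_followup(
    patient_id: str,
    group: str,
    mode: str,
    index_date: dt.date,
    episodes: Sequence[TreatmentEpisode],
    outcome_date: dt.date | None,
    max_followup_days: int,
    data_end: dt.date,
) -> FollowUpRecord:
    """One subject's person-time and event indicator under ITT or AT rules.

    Candidate end dates: the outcome, index + max follow-up, the patient's
    data end, and (AT only) the first episode's discontinuation date; the
    earliest wins.  When the outcome falls on the same day as a censoring
    candidate, the outcome wins the tie and the event is counted.
    """
    if mode not in ("ITT", "AT"):
        raise StructuralError(f"unknown follow-up mode {mode!r}")
    candidates: list[tuple[dt.date, str]] = [
        (index_date + dt.timedelta(days=max_followup_days), "max_followup"),
        (data_end, "data_end"),
    ]
    if mode == "AT":
        covering = [e for e in episodes if e.episode_start <= index_date < e.episode_end]
        if not covering:
            raise StructuralError(
                f"{patient_id}: AT follow-up requires an episode covering the index date"
            )
        candidates.append((covering[0].episode_end, "discontinuation"))

    censor_date, censor_reason = min(candidates, key=lambda c: (c[0], END_REASONS.index(c[1])))
    if outcome_date is not None and outcome_date <= censor_date:
        end_date, reason, event = outcome_date, "outcome", 1
    else:
        end_date, reason, event = censor_date, censor_reason, 0

    time_days = (end_date - index_date).days
    if time_days < 0:
        raise StructuralError(f"{patient_id}: negative follow-up time")
    return FollowUpRecord(patient_id, group, mode, time_days, event, reason)


# ---------------------------------------------------------------------------
# Incidence summaries (Table-1 machinery)
# ---------------------------------------------------------------------------

def poisson_exact_ci(events: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) Poisson CI for the event count, scaled to percent of n."""
    lo = 0.5 * chi2.ppf(alpha / 2, 2 * events) if events > 0 else 0.0
    hi = 0.5 * chi2.ppf(1 - alpha / 2, 2 * (events + 1))
    return 100.0 * lo / n, 100.0 * hi / n


def clopper_pearson_ci(events: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) CI for events/n, in percent."""
    lo = beta_dist.ppf(alpha / 2, events, n - events + 1) if events > 0 else 0.0
    hi = beta_dist.ppf(1 - alpha / 2, events + 1, n - events) if events < n else 1.0
    return 100.0 * lo, 100.0 * hi


def incidence(
    records: Sequence[FollowUpRecord],
    outcome: str = "",
    ci_method: str = "poisson_exact",
    alpha: float = 0.05,
) -> IncidenceSummary:
    """Aggregate one group x mode x outcome cell of the incidence table."""
    if not records:
        raise StructuralError("incidence requires at least one follow-up record")
    groups = {r.group for r in records}
    modes = {r.mode for r in records}
    if len(groups) > 1 or len(modes) > 1:
        raise StructuralError("incidence input must be a single group and mode")
    n = len(records)
    events = sum(r.event for r in records)
    person_days = sum(r.time_days for r in records)
    if person_days == 0 and events > 0:
        raise StructuralError("events observed with zero person-days")
    density = 100000.0 * events / person_days if person_days else 0.0
    cum_pct = 100.0 * events / n
    if ci_method == "poisson_exact":
        ci = poisson_exact_ci(events, n, alpha)
    elif ci_method == "clopper_pearson":
        ci = clopper_pearson_ci(events, n, alpha)
    else:
        raise StructuralError(f"unknown ci_method {ci_method!r}")
    return IncidenceSummary(
        group=groups.pop(),
        mode=modes.pop(),
        outcome=outcome,
        n_subjects=n,
        events=events,
        person_days=person_days,
        incidence_density=density,
        cumulative_incidence_pct=cum_pct,
        ci95=ci,
        ci_method=ci_method,
    )


def followup_frame(records: Sequence[FollowUpRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.patient_id, r.group, r.mode, r.time_days, r.event, r.end_reason) for r in records],
        columns=["patient_id", "group", "mode", "time_days", "event", "end_reason"],
    )


def incidence_frame(summaries: Sequence[IncidenceSummary]) -> pd.DataFrame:
    """Incidence table mirroring the published layout, 2-decimal CI bounds."""
    rows = []
    for s in summaries:
        rows.append({
            "mode": s.mode,
            "group": s.group,
            "outcome": s.outcome,
            "n": s.n_subjects,
            "events": s.events,
            "person_days": s.person_days,
            "incidence_density": round(s.incidence_density, 2),
            "cumulative_incidence_pct": round(s.cumulative_incidence_pct, 2),
            "ci95_lower": round(s.ci95[0], 2),
            "ci95_upper": round(s.ci95[1], 2),
            "ci_method": s.ci_method,
        })
    return pd.DataFrame(rows)
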