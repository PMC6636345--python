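"""Config-to-outputs orchestration of the full study pipeline.

Stage order: cohort tree -> per-outcome incident subcohorts -> analysis-ready
assembly -> propensity fit + match + balance -> ITT and AT follow-up ->
incidence summaries -> KM + Cox.  Every stage writes its artifact so that any
intermediate file can be re-loaded and downstream stages reproduced.

Result CSVs are byte-deterministic for a fixed config + seed + inputs; the
manifest records a single hash over all of them (manifest and log themselves
carry wall-clock timings and are excluded from that hash).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_builder import (
    CohortTree,
    apply_criterion,
    attrition_report,
    build_incident_subcohort,
    criterion_from_dict,
    identify_new_users,
    render_tree,
)
from .covariate_mapper import assemble, specs_from_config
from .emr_model import StudyConfig, Tables, code_matches, write_tables
from .errors import ConfigError, ConvergenceError, SeparationError
from .followup import (
    build_episodes,
    build_followup,
    first_outcome,
    followup_frame,
    incidence,
    incidence_frame,
)
from .matching import balance, fit_logistic, match
from .survival_stats import cox_fit, km
from .synthetic_emr import SimulationSpec, generate, write_truth


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    software_version: str
    input_rows: dict[str, int]
    output_files: list[str]
    output_hash: str
    stage_seconds: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _config_hash(config: StudyConfig) -> str:
    blob = yaml.safe_dump(
        {k: repr(v) for k, v in sorted(vars(config).items())}, sort_keys=True
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def _hash_files(paths: list[Path]) -> str:
    digest = hashlib.sha256()
    for path in sorted(paths, key=lambda p: p.name):
        digest.update(path.name.encode())
        digest.update(path.read_bytes())
    return digest.hexdigest()


class _StageLog:
    """Structured stage log without timestamps (keeps reruns comparable)."""

    def __init__(self) -> None:
        self.lines: list[str] = []

    def stage(self, name: str, **counts) -> None:
        detail = " ".join(f"{k}={v}" for k, v in counts.items())
        self.lines.append(f"[{name}] {detail}".rstrip())

    def write(self, path: Path) -> None:
        path.write_text("\n".join(self.lines) + "\n")


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")


def run_study(
    config: StudyConfig,
    tables: Tables,
    out_dir: str | Path,
    seed: int | None = None,
) -> RunManifest:
    """Execute the full study and write all artifacts to ``out_dir``.

    A Cox fit that cannot be estimated (no events, or monotone likelihood)
    is recorded in the results table with an explanatory note instead of
    aborting, since sparse-event strata are an expected outcome of the
    design; all other stage failures propagate with the stage name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    log = _StageLog()
    timings: dict[str, float] = {}
    outputs: list[Path] = []

    # fail-fast: parse all covariate/criterion specs before any computation
    # (code-set name consistency was already validated at config build time)
    specs = specs_from_config(config)
    criteria = [criterion_from_dict(raw) for raw in config.criteria]

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                return False
        return _T()

    # ---- stage: cohort tree --------------------------------------------
    with timed("cohort_tree"):
        tree = CohortTree()
        index, tree = identify_new_users(
            tables, config.exposure_sets, config.study_window,
            config.washout_days, tree,
        )
        node = tree.leaf()
        for criterion in criteria:
            node = apply_criterion(tree, node, criterion, tables, index)
        main_cohort = node
    for n in tree:
        log.stage("cohort_tree", label=n.label, n_in=n.n_in,
                  n_dropped=n.n_dropped, n_out=n.n_out)

    treated, comparator = config.treated_group, config.comparator_group

    cov_names_base = ["age_years", "sex"]
    incidence_rows = []
    cox_rows = []
    km_frames = []

    exposure_class = {g: cs for g, cs in config.exposure_sets.items()}
    rx_by_patient: dict[str, list] = {}
    for rx in tables.prescriptions:
        rx_by_patient.setdefault(rx.patient_id, []).append(rx)
    dx_by_patient: dict[str, list] = {}
    for rec in tables.diagnoses:
        dx_by_patient.setdefault(rec.patient_id, []).append(rec)

    for outcome_name, outcome_set in config.outcome_sets.items():
        # ---- stage: incident subcohort ---------------------------------
        with timed(f"subcohort_{outcome_name}"):
            if outcome_name in config.incident_exclusion_sets:
                sub = build_incident_subcohort(
                    tree, main_cohort, outcome_name,
                    config.incident_exclusion_sets[outcome_name],
                    config.lookback_days, tables, index,
                )
            else:
                sub = main_cohort
        log.stage(f"subcohort_{outcome_name}", n_in=sub.n_in,
                  n_dropped=sub.n_dropped, n_out=sub.n_out)

        # ---- stage: analysis-ready assembly ----------------------------
        with timed(f"assemble_{outcome_name}"):
            rows = assemble(sub, index, tables, specs, treated)
        path = out_dir / f"analysis_ready_{outcome_name}.csv"
        _write_csv(rows, path)
        outputs.append(path)
        log.stage(f"assemble_{outcome_name}", n_rows=len(rows))

        covariates = cov_names_base + [s.name for s in specs if s.source != "demographic"]
        covariates = [c for c in covariates if rows[c].nunique() > 1]

        # ---- stage: propensity + matching + balance --------------------
        with timed(f"match_{outcome_name}"):
            fit = fit_logistic(rows, covariates)
            groups = pd.Series(
                rows["group"].to_numpy(), index=rows["patient_id"].to_numpy()
            )
            matched = match(fit.scores, groups, config.caliper,
                            config.caliper_scale, seed)
            bal = balance(rows, covariates, matched, config.smd_threshold)
        path = out_dir / f"matches_{outcome_name}.csv"
        _write_csv(matched.to_frame(), path)
        outputs.append(path)
        path = out_dir / f"balance_{outcome_name}.csv"
        _write_csv(bal, path)
        outputs.append(path)
        log.stage(f"match_{outcome_name}", n_pairs=matched.n_pairs,
                  caliper_used=round(matched.caliper_used, 6),
                  ps_converged=fit.converged)

        matched_ids = {pid for t, c, _ in matched.pairs for pid in (t, c)}
        cohort_rows = rows[rows["patient_id"].isin(matched_ids)]

        # ---- stage: follow-up + incidence ------------------------------
        with timed(f"followup_{outcome_name}"):
            data_end = {p.patient_id: p.data_end_date for p in tables.patients}
            fu_records = []
            for pid in sorted(matched_ids):
                assign = index[pid]
                cls = exposure_class[assign.index_group]
                own_rx = [r for r in rx_by_patient.get(pid, [])
                          if code_matches(r.drug_code, cls)]
                episodes = build_episodes(own_rx, config.gap_days)
                outcome_date = first_outcome(
                    dx_by_patient.get(pid, []), outcome_set, assign.index_date
                )
                for mode in ("ITT", "AT"):
                    fu_records.append(build_followup(
                        pid, assign.index_group, mode, assign.index_date,
                        episodes, outcome_date, config.max_followup_days,
                        data_end[pid],
                    ))
        fu_frame = followup_frame(fu_records)
        path = out_dir / f"followup_{outcome_name}.csv"
        _write_csv(fu_frame, path)
        outputs.append(path)

        for mode in ("ITT", "AT"):
            for grp in (comparator, treated):
                recs = [r for r in fu_records if r.mode == mode and r.group == grp]
                if recs:
                    incidence_rows.append(
                        incidence(recs, outcome_name, config.ci_method, config.alpha)
                    )

        # ---- stage: survival -------------------------------------------
        with timed(f"survival_{outcome_name}"):
            surv = fu_frame.merge(
                cohort_rows[["patient_id", "group"] + [c for c in covariates]],
                on="patient_id", suffixes=("_name", ""),
            )
            for mode in ("ITT", "AT"):
                sub_mode = surv[(surv["mode"] == mode) & (surv["time_days"] > 0)]
                for grp_name, grp_bin in ((comparator, 0), (treated, 1)):
                    part = sub_mode[sub_mode["group"] == grp_bin]
                    if len(part):
                        curve = km(part["time_days"].to_numpy(),
                                   part["event"].to_numpy())
                        frame = curve.to_frame(group=grp_name)
                        frame.insert(0, "outcome", outcome_name)
                        frame.insert(0, "mode", mode)
                        km_frames.append(frame)
                ev_ref = int(sub_mode[sub_mode["group"] == 0]["event"].sum())
                ev_trt = int(sub_mode[sub_mode["group"] == 1]["event"].sum())
                model_covs = ["group"] + [
                    c for c in covariates if sub_mode[c].nunique() > 1
                ]
                row = {
                    "mode": mode, "outcome": outcome_name, "group": treated,
                    "events_reference": ev_ref, "events_treated": ev_trt,
                }
                try:
                    cfit = cox_fit(sub_mode, model_covs)
                    k = 0  # treatment indicator is the first model covariate
                    lo, hi = cfit.ci95[k]
                    row.update({
                        "hazard_ratio": round(float(cfit.hazard_ratios[k]), 2),
                        "p_value": round(float(cfit.p_values[k]), 4),
                        "ci95_lower": round(lo, 2),
                        "ci95_upper": round(hi, 2),
                        "unstable": cfit.unstable,
                        "note": "se>2: estimate unstable" if cfit.unstable else "",
                    })
                except (ConfigError, ConvergenceError, SeparationError) as exc:
                    row.update({
                        "hazard_ratio": "", "p_value": "", "ci95_lower": "",
                        "ci95_upper": "", "unstable": True,
                        "note": f"not estimable: {exc}",
                    })
                cox_rows.append(row)
        log.stage(f"survival_{outcome_name}", models=2)

    # ---- consolidated outputs ------------------------------------------
    att = attrition_report(tree)  # after subcohort nodes joined the tree
    path = out_dir / "attrition.csv"
    _write_csv(att, path)
    outputs.append(path)
    (out_dir / "attrition.txt").write_text(render_tree(tree))
    outputs.append(out_dir / "attrition.txt")

    path = out_dir / "incidence.csv"
    _write_csv(incidence_frame(incidence_rows), path)
    outputs.append(path)

    path = out_dir / "km_curve.csv"
    km_all = (pd.concat(km_frames, ignore_index=True) if km_frames
              else pd.DataFrame(columns=["mode", "outcome", "group", "time",
                                         "n_risk", "n_event", "survival", "se"]))
    _write_csv(km_all, path)
    outputs.append(path)

    path = out_dir / "cox_results.csv"
    _write_csv(pd.DataFrame(cox_rows), path)
    outputs.append(path)

    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=seed,
        software_version=__version__,
        input_rows={
            "patients": len(tables.patients),
            "diagnoses": len(tables.diagnoses),
            "prescriptions": len(tables.prescriptions),
        },
        output_files=sorted(p.name for p in outputs),
        output_hash=_hash_files(outputs),
        stage_seconds=timings,
    )
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
    log.write(out_dir / "run.log")
    return manifest


def simulate_and_run(
    spec: SimulationSpec,
    config: StudyConfig,
    out_dir: str | Path,
) -> tuple[RunManifest, dict]:
    """Generate synthetic EMR, run the study, and report truth recovery.

    The pipeline sees only the three EMR tables; the latent truth table is
    written beside the outputs for the comparison report only.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables, truth = generate(spec)
    write_tables(tables, out_dir / "inputs")
    write_truth(truth, out_dir / "inputs")

    manifest = run_study(config, tables, out_dir)

    cox = pd.read_csv(out_dir / "cox_results.csv")
    recovery: dict = {"true_log_hr": {}, "estimated": {}}
    for om in spec.outcome_models:
        recovery["true_log_hr"][om.name] = om.treatment_log_hr
        est = {}
        for _, row in cox[cox["outcome"] == om.name].iterrows():
            hr = row["hazard_ratio"]
            est[row["mode"]] = {
                "hazard_ratio": None if pd.isna(hr) else float(hr),
                "log_hr": None if pd.isna(hr) or float(hr) <= 0 else float(np.log(hr)),
                "note": "" if pd.isna(row.get("note")) else str(row.get("note")),
            }
        recovery["estimated"][om.name] = est

    bal_files = sorted(out_dir.glob("balance_*.csv"))
    post = pd.concat([pd.read_csv(p) for p in bal_files], ignore_index=True)
    post = post[post["phase"] == "after"]
    recovery["post_match_max_smd"] = (
        float(post["smd"].max()) if len(post) else None
    )
    (out_dir / "recovery.json").write_text(json.dumps(recovery, indent=2) + "\n")
    return manifest, recovery
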