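import datetime as dt

import pytest

from cohortwatch.cohort_builder import (
    CohortTree,
    Criterion,
    apply_criterion,
    attrition_report,
    build_incident_subcohort,
    criterion_from_dict,
    identify_new_users,
    render_tree,
    _age_at,
)
from cohortwatch.emr_model import (
    CodeSet,
    DiagnosisRecord,
    PatientRecord,
    PrescriptionRecord,
    Tables,
)
from cohortwatch.errors import ConfigError, StructuralError

D = dt.date
WINDOW = (D(2010, 1, 1), D(2015, 12, 31))
EXPOSURE = {
    "noac": CodeSet("noac", frozenset({"NOAC"}), "prefix"),
    "warfarin": CodeSet("warfarin", frozenset({"WARF"}), "exact"),
}


def patient(pid, birth=D(1950, 1, 1)):
    return PatientRecord(pid, birth, "female", D(2015, 12, 31))


def tables(patients, diagnoses=(), prescriptions=()):
    return Tables(list(patients), list(diagnoses), list(prescriptions))


def new_users(tbl, washout=365):
    return identify_new_users(tbl, EXPOSURE, WINDOW, washout, CohortTree())


class TestIdentifyNewUsers:
    def test_prior_use_before_window_excluded(self):
        tbl = tables(
            [patient("A")],
            prescriptions=[
                PrescriptionRecord("A", "NOAC_D", D(2009, 6, 1), 30),
                PrescriptionRecord("A", "NOAC_D", D(2010, 3, 1), 30),
            ],
        )
        assignments, tree = new_users(tbl)
        assert assignments == {}
        washout_node = next(n for n in tree
                            if n.label == "no prior exposure within washout")
        assert washout_node.n_dropped == 1

    def test_clean_new_user_indexed_at_first_start(self):
        tbl = tables(
            [patient("A")],
            prescriptions=[PrescriptionRecord("A", "WARF", D(2011, 5, 2), 30)],
        )
        assignments, _ = new_users(tbl)
        assert assignments["A"].index_date == D(2011, 5, 2)
        assert assignments["A"].index_group == "warfarin"

    def test_dual_exposure_on_index_excluded(self):
        tbl = tables(
            [patient("A")],
            prescriptions=[
                PrescriptionRecord("A", "WARF", D(2010, 5, 1), 30),
                PrescriptionRecord("A", "NOAC_R", D(2010, 5, 1), 30),
            ],
        )
        assignments, tree = new_users(tbl)
        assert assignments == {}
        dual_node = next(n for n in tree
                         if n.label == "single exposure group on index date")
        assert dual_node.n_dropped == 1

    def test_prior_use_outside_washout_not_excluded(self):
        tbl = tables(
            [patient("A")],
            prescriptions=[
                PrescriptionRecord("A", "WARF", D(2009, 1, 1), 30),
                PrescriptionRecord("A", "WARF", D(2011, 1, 1), 30),
            ],
        )
        assignments, _ = new_users(tbl)
        assert "A" in assignments  # 731-day gap exceeds the washout

    def test_infinite_washout_is_all_history(self):
        tbl = tables(
            [patient("A")],
            prescriptions=[
                PrescriptionRecord("A", "WARF", D(2005, 1, 1), 30),
                PrescriptionRecord("A", "WARF", D(2011, 1, 1), 30),
            ],
        )
        assignments, _ = identify_new_users(
            tbl, EXPOSURE, WINDOW, float("inf"), CohortTree())
        assert assignments == {}

    def test_no_exposure_never_indexed(self):
        tbl = tables([patient("A")])
        assignments, tree = new_users(tbl)
        assert assignments == {}
        node = next(n for n in tree
                    if n.label == "exposure prescription within study window")
        assert node.n_dropped == 1

    def test_empty_exposure_sets_rejected(self):
        with pytest.raises(ConfigError):
            identify_new_users(tables([patient("A")]), {}, WINDOW, 365)


class TestApplyCriterion:
    def _indexed(self, tbl):
        return new_users(tbl)

    def test_exclude_diagnosis_drops_exactly_matches(self):
        tbl = tables(
            [patient("A"), patient("B")],
            diagnoses=[DiagnosisRecord("A", D(2010, 12, 1), "CANCER", "inpatient")],
            prescriptions=[
                PrescriptionRecord("A", "WARF", D(2011, 1, 1), 30),
                PrescriptionRecord("B", "WARF", D(2011, 1, 1), 30),
            ],
        )
        assignments, tree = self._indexed(tbl)
        criterion = Criterion("no cancer", "exclude_diagnosis",
                              CodeSet("ca", frozenset({"CANCER"})), (-365, 0))
        node = apply_criterion(tree, tree.leaf(), criterion, tbl, assignments)
        assert node.members == ("B",)

    def test_age_exactly_at_threshold_retained(self):
        # born 1991-01-01, index 2011-01-01: aged exactly 20 -> "at least" keeps
        tbl = tables(
            [patient("A", birth=D(1991, 1, 1))],
            prescriptions=[PrescriptionRecord("A", "WARF", D(2011, 1, 1), 30)],
        )
        assignments, tree = self._indexed(tbl)
        criterion = Criterion("age", "age_at_least", threshold=20)
        node = apply_criterion(tree, tree.leaf(), criterion, tbl, assignments)
        assert node.members == ("A",)

    def test_one_day_under_threshold_dropped(self):
        tbl = tables(
            [patient("A", birth=D(1991, 1, 2))],
            prescriptions=[PrescriptionRecord("A", "WARF", D(2011, 1, 1), 30)],
        )
        assignments, tree = self._indexed(tbl)
        criterion = Criterion("age", "age_at_least", threshold=20)
        node = apply_criterion(tree, tree.leaf(), criterion, tbl, assignments)
        assert node.members == ()

    def test_require_on_empty_node_is_vacuous(self):
        tbl = tables(
            [patient("A")],
            prescriptions=[PrescriptionRecord("A", "OTHER", D(2011, 1, 1), 30)],
        )
        assignments, tree = self._indexed(tbl)
        assert tree.leaf().members == ()
        criterion = Criterion("af", "require_diagnosis",
                              CodeSet("af", frozenset({"AF"})), (-365, 0))
        node = apply_criterion(tree, tree.leaf(), criterion, tbl, assignments)
        assert node.n_in == 0 and node.n_out == 0

    def test_min_count_respected(self):
        tbl = tables(
            [patient("A")],
            diagnoses=[DiagnosisRecord("A", D(2010, 11, 1), "AF", "outpatient")],
            prescriptions=[PrescriptionRecord("A", "WARF", D(2011, 1, 1), 30)],
        )
        assignments, tree = self._indexed(tbl)
        criterion = Criterion("af x2", "require_diagnosis",
                              CodeSet("af", frozenset({"AF"})), (-365, 0), min_count=2)
        node = apply_criterion(tree, tree.leaf(), criterion, tbl, assignments)
        assert node.members == ()

    def test_settings_filter(self):
        tbl = tables(
            [patient("A")],
            diagnoses=[DiagnosisRecord("A", D(2010, 11, 1), "AF", "outpatient")],
            prescriptions=[PrescriptionRecord("A", "WARF", D(2011, 1, 1), 30)],
        )
        assignments, tree = self._indexed(tbl)
        criterion = Criterion("af inpatient only", "require_diagnosis",
                              CodeSet("af", frozenset({"AF"})), (-365, 0),
                              settings=("inpatient",))
        node = apply_criterion(tree, tree.leaf(), criterion, tbl, assignments)
        assert node.members == ()

    def test_criterion_from_dict(self):
        c = criterion_from_dict({
            "label": "no cancer", "kind": "exclude_diagnosis",
            "codes": ["C00"], "match_mode": "prefix", "window": [-365, 0],
        })
        assert c.code_set.match_mode == "prefix"
        assert c.window == (-365, 0)


class TestIncidentSubcohort:
    def _setup(self, dx_date):
        tbl = tables(
            [patient("A")],
            diagnoses=[DiagnosisRecord("A", dx_date, "TIA", "emergency")],
            prescriptions=[PrescriptionRecord("A", "WARF", D(2011, 1, 1), 30)],
        )
        assignments, tree = new_users(tbl)
        node = build_incident_subcohort(
            tree, tree.leaf(), "stroke",
            CodeSet("hx", frozenset({"STROKE", "TIA"})), 365, tbl, assignments,
        )
        return node

    def test_prior_event_dropped(self):
        assert self._setup(D(2010, 9, 23)).members == ()  # index - 100 days

    def test_event_on_index_date_retained(self):
        # [index - 365, index) excludes the index day itself
        assert self._setup(D(2011, 1, 1)).members == ("A",)

    def test_no_history_subcohort_equals_parent(self):
        assert self._setup(D(2005, 1, 1)).members == ("A",)


class TestTreeStructure:
    def test_monotone_membership_and_telescoping(self, fixture_tables, fixture_config):
        tree = CohortTree()
        assignments, tree = identify_new_users(
            fixture_tables, fixture_config.exposure_sets,
            fixture_config.study_window, fixture_config.washout_days, tree)
        nodes = list(tree)
        for parent, child in zip(nodes, nodes[1:]):
            assert set(child.members) <= set(parent.members)
            assert child.n_out == child.n_in - child.n_dropped
        # telescoping along the chain
        total_dropped = sum(n.n_dropped for n in nodes)
        assert total_dropped == nodes[0].n_in - nodes[-1].n_out
        # every member appears in the patients table
        pids = fixture_tables.patient_ids()
        for n in nodes:
            assert set(n.members) <= pids

    def test_exclusions_commute_on_membership(self):
        tbl = tables(
            [patient("A"), patient("B"), patient("C")],
            diagnoses=[
                DiagnosisRecord("A", D(2010, 12, 1), "CANCER", "inpatient"),
                DiagnosisRecord("B", D(2010, 12, 1), "DIALYSIS", "outpatient"),
            ],
            prescriptions=[
                PrescriptionRecord(p, "WARF", D(2011, 1, 1), 30)
                for p in ("A", "B", "C")
            ],
        )
        ca = Criterion("no cancer", "exclude_diagnosis",
                       CodeSet("ca", frozenset({"CANCER"})), (-365, 0))
        di = Criterion("no dialysis", "exclude_diagnosis",
                       CodeSet("di", frozenset({"DIALYSIS"})), (-365, 0))

        def leaf_for(order):
            assignments, tree = new_users(tbl)
            node = tree.leaf()
            for c in order:
                node = apply_criterion(tree, node, c, tbl, assignments)
            return set(node.members)

        assert leaf_for([ca, di]) == leaf_for([di, ca]) == {"C"}

    def test_growing_membership_rejected(self):
        tree = CohortTree()
        root = tree.add("root", ["A"])
        with pytest.raises(StructuralError):
            tree.add("child", ["A", "B"], parent=root)

    def test_attrition_report_rows_chain(self, fixture_tables, fixture_config):
        tree = CohortTree()
        identify_new_users(
            fixture_tables, fixture_config.exposure_sets,
            fixture_config.study_window, fixture_config.washout_days, tree)
        report = attrition_report(tree)
        for i in range(len(report) - 1):
            assert report.loc[i, "n_out"] == report.loc[i + 1, "n_in"]

    def test_single_node_tree(self):
        tree = CohortTree()
        tree.add("root", ["A", "B"])
        report = attrition_report(tree)
        assert len(report) == 1
        assert report.loc[0, "n_dropped"] == 0

    def test_render_tree_is_indented(self, fixture_tables, fixture_config):
        tree = CohortTree()
        identify_new_users(
            fixture_tables, fixture_config.exposure_sets,
            fixture_config.study_window, fixture_config.washout_days, tree)
        text = render_tree(tree)
        assert "all patients" in text
        assert text.count("\n") == len(tree)


def test_age_at_completed_years():
    assert _age_at(D(1990, 3, 10), D(2010, 3, 10)) == 20
    assert _age_at(D(1990, 3, 10), D(2010, 3, 9)) == 19
    assert _age_at(D(1990, 3, 10), D(2010, 12, 1)) == 20
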