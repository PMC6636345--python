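import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from cohortwatch.errors import ConfigError, RankDeficiencyError, SeparationError
from cohortwatch.matching import MatchedSet, balance, fit_logistic, match
from cohortwatch.synthetic_emr import (
    CovariateDef,
    OutcomeModel,
    SimulationSpec,
    generate,
)


def frame(y, **covs):
    n = len(y)
    data = {"patient_id": [f"P{i:03d}" for i in range(n)], "group": y}
    data.update(covs)
    return pd.DataFrame(data)


class TestFitLogistic:
    def test_intercept_only_equals_logit_of_fraction(self):
        y = [1] * 30 + [0] * 70
        fit = fit_logistic(frame(y), [])
        expected = np.log(0.3 / 0.7)
        assert fit.converged
        assert fit.coefficients["intercept"] == pytest.approx(expected, abs=1e-6)

    def test_two_by_two_slope_is_log_odds_ratio(self):
        # treated/covariate cross-table a=30, b=20, c=10, d=40
        y = [1] * 50 + [0] * 50
        x = [1] * 30 + [0] * 20 + [1] * 10 + [0] * 40
        fit = fit_logistic(frame(y, x=x), ["x"])
        assert fit.coefficients["x"] == pytest.approx(np.log(6.0), abs=1e-6)

    def test_scores_are_local_maximum(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=80)
        y = (rng.random(80) < 1 / (1 + np.exp(-0.5 * x))).astype(int)
        rows = frame(y, x=x)
        fit = fit_logistic(rows, ["x"])

        X = np.column_stack([np.ones(80), x])

        def ll(beta):
            eta = X @ beta
            return float(np.sum(y * eta - np.logaddexp(0, eta)))

        beta_hat = np.array([fit.coefficients["intercept"], fit.coefficients["x"]])
        base = ll(beta_hat)
        for k in range(2):
            for delta in (1e-3, -1e-3):
                perturbed = beta_hat.copy()
                perturbed[k] += delta
                assert ll(perturbed) < base

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_numeric_maximizer(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.4).astype(float)
        eta = -0.3 + 0.8 * x1 - 0.5 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        rows = frame(y, x1=x1, x2=x2)
        fit = fit_logistic(rows, ["x1", "x2"])

        X = np.column_stack([np.ones(n), x1, x2])

        def nll(beta):
            e = X @ beta
            return -float(np.sum(y * e - np.logaddexp(0, e)))

        res = minimize(nll, np.zeros(3), method="BFGS", tol=1e-12)
        got = [fit.coefficients["intercept"], fit.coefficients["x1"],
               fit.coefficients["x2"]]
        assert np.allclose(got, res.x, atol=1e-6)

    def test_separation_detected(self):
        y = [0, 0, 0, 1, 1, 1, 0, 1]
        x = [0, 1, 2, 10, 11, 12, 0.5, 10.5]
        with pytest.raises(SeparationError):
            fit_logistic(frame(y, x=x), ["x"])

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        rows = frame(y, x=x, x_copy=2 * x)
        with pytest.raises(RankDeficiencyError):
            fit_logistic(rows, ["x", "x_copy"])

    def test_needs_two_per_group(self):
        with pytest.raises(ConfigError):
            fit_logistic(frame([1, 0, 0, 0]), [])

    def test_scores_in_open_interval(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=100)
        y = (rng.random(100) < 0.5).astype(int)
        fit = fit_logistic(frame(y, x=x), ["x"])
        assert ((fit.scores > 0) & (fit.scores < 1)).all()


def series(ids, values):
    return pd.Series(values, index=ids, dtype=float)


class TestMatch:
    def test_identical_scores_exhaust_controls(self):
        ids = [f"T{i}" for i in range(3)] + [f"C{i}" for i in range(2)]
        scores = series(ids, [0.5] * 5)
        groups = series(ids, [1, 1, 1, 0, 0])
        m = match(scores, groups, caliper=0.1, caliper_scale="raw", seed=0)
        assert m.n_pairs == 2
        assert all(d == 0 for _, _, d in m.pairs)
        assert len(m.unmatched_treated) == 1

    def test_nearest_within_raw_caliper(self):
        ids = ["T1", "C1", "C2", "C3"]
        scores = series(ids, [0.30, 0.10, 0.28, 0.50])
        groups = series(ids, [1, 0, 0, 0])
        m = match(scores, groups, caliper=0.05, caliper_scale="raw", seed=0)
        assert m.pairs == [("T1", "C2", pytest.approx(0.02))]
        assert set(m.unmatched_control) == {"C1", "C3"}

    def test_caliper_binds(self):
        ids = ["T1", "C1"]
        scores = series(ids, [0.9, 0.1])
        groups = series(ids, [1, 0])
        m = match(scores, groups, caliper=0.05, caliper_scale="raw", seed=0)
        assert m.n_pairs == 0
        assert m.unmatched_treated == ["T1"]

    def test_tie_broken_by_smallest_control_id(self):
        ids = ["T1", "C2", "C1"]
        scores = series(ids, [0.5, 0.4, 0.6])  # equidistant
        groups = series(ids, [1, 0, 0])
        m = match(scores, groups, caliper=0.5, caliper_scale="raw", seed=0)
        assert m.pairs[0][1] == "C1"

    def test_invariant_to_input_row_order(self):
        rng = np.random.default_rng(3)
        ids = [f"P{i:02d}" for i in range(20)]
        scores = rng.uniform(0.2, 0.8, 20)
        groups = rng.integers(0, 2, 20)
        while groups.sum() < 2 or groups.sum() > 18:
            groups = rng.integers(0, 2, 20)
        s1 = series(ids, scores)
        g1 = series(ids, groups)
        perm = rng.permutation(20)
        s2 = s1.iloc[perm]
        g2 = g1.iloc[perm]
        m1 = match(s1, g1, 0.2, "logit_sd", seed=5)
        m2 = match(s2, g2, 0.2, "logit_sd", seed=5)
        assert m1.pairs == m2.pairs

    def test_every_distance_within_caliper(self):
        rng = np.random.default_rng(8)
        ids = [f"P{i:03d}" for i in range(100)]
        scores = series(ids, rng.uniform(0.05, 0.95, 100))
        groups = series(ids, rng.integers(0, 2, 100))
        m = match(scores, groups, 0.2, "logit_sd", seed=1)
        assert all(d <= m.caliper_used for _, _, d in m.pairs)
        # no id appears twice
        used = [pid for t, c, _ in m.pairs for pid in (t, c)]
        assert len(used) == len(set(used))

    def test_logit_sd_caliper_value(self):
        rng = np.random.default_rng(2)
        ids = [f"P{i:03d}" for i in range(50)]
        s = rng.uniform(0.2, 0.8, 50)
        scores = series(ids, s)
        groups = series(ids, rng.integers(0, 2, 50))
        m = match(scores, groups, 0.2, "logit_sd", seed=0)
        logit = np.log(s / (1 - s))
        assert m.caliper_used == pytest.approx(0.2 * np.std(logit, ddof=1))

    def test_bad_caliper(self):
        ids = ["T1", "C1"]
        with pytest.raises(ConfigError):
            match(series(ids, [0.5, 0.5]), series(ids, [1, 0]), caliper=0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_greedy_equals_exhaustive_oracle_small(self, seed):
        # independent oracle: process treated in the same seed order, scanning
        # every remaining control exhaustively for the nearest within caliper
        rng = np.random.default_rng(seed)
        n = 12
        ids = [f"P{i:02d}" for i in range(n)]
        s = rng.uniform(0.1, 0.9, n)
        g = np.array([1] * 5 + [0] * 7)
        rng.shuffle(g)
        if g.sum() < 1 or g.sum() == n:
            pytest.skip("degenerate draw")
        scores, groups = series(ids, s), series(ids, g)
        caliper = 0.15
        m = match(scores, groups, caliper, "raw", seed=seed)

        treated = sorted(i for i in ids if groups[i] == 1)
        controls = {i for i in ids if groups[i] == 0}
        order = np.random.default_rng(seed).permutation(len(treated))
        expected = []
        for k in order:
            tid = treated[k]
            best, best_d = None, None
            for cid in sorted(controls):
                d = abs(scores[tid] - scores[cid])
                if d <= caliper and (best_d is None or d < best_d):
                    best, best_d = cid, d
            if best is not None:
                controls.discard(best)
                expected.append((tid, best, pytest.approx(best_d)))
        expected.sort(key=lambda p: p[0])
        assert m.pairs == expected


class TestBalance:
    def _rows(self, y, **covs):
        return frame(y, **covs)

    def test_equal_prevalence_smd_zero(self):
        rows = self._rows([1, 1, 0, 0], x=[1, 0, 1, 0])
        tab = balance(rows, ["x"])
        assert tab.loc[0, "smd"] == 0

    def test_binary_smd_formula(self):
        # p1 = 0.5, p0 = 0.3 -> 0.2 / sqrt((0.25 + 0.21)/2)
        y = [1] * 10 + [0] * 10
        x = [1] * 5 + [0] * 5 + [1] * 3 + [0] * 7
        tab = balance(self._rows(y, x=x), ["x"])
        assert tab.loc[0, "smd"] == pytest.approx(0.2 / np.sqrt(0.23), abs=1e-12)

    def test_continuous_smd_uses_sample_variance(self):
        y = [1, 1, 1, 0, 0, 0]
        x = [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]
        tab = balance(self._rows(y, x=x), ["x"])
        assert tab.loc[0, "smd"] == pytest.approx(1.0 / np.sqrt(1.0), abs=1e-12)

    def test_zero_variance_unequal_means_is_inf(self):
        y = [1, 1, 0, 0]
        x = [1.0, 1.0, 0.0, 0.0]  # binary {0,1}: both prevalences degenerate
        tab = balance(self._rows(y, x=x), ["x"])
        assert tab.loc[0, "smd"] == np.inf

    def test_perfect_self_match_smds_zero(self):
        y = [1, 1, 0, 0]
        x = [1, 0, 1, 0]
        rows = self._rows(y, x=x)
        matched = MatchedSet(
            pairs=[("P000", "P002", 0.0), ("P001", "P003", 0.0)],
            caliper_used=0.1, scale="raw",
            unmatched_treated=[], unmatched_control=[],
        )
        tab = balance(rows, ["x"], matched)
        after = tab[tab["phase"] == "after"]
        assert (after["smd"] == 0).all()


class TestConfoundedRecovery:
    def test_matching_improves_balance(self):
        # moderate confounding at n=2000: post-match mean |SMD| drops and
        # >=90% of covariates land under 0.1
        spec = SimulationSpec(
            n_patients=2000,
            covariate_defs=(
                CovariateDef("c1", prevalence=0.35),
                CovariateDef("c2", prevalence=0.2),
                CovariateDef("c3", prevalence=0.5),
                CovariateDef("c4", prevalence=0.1),
            ),
            treatment_intercept=-0.4,
            treatment_coefficients={"c1": 0.7, "c2": -0.6, "c3": 0.5, "c4": 0.8},
            outcome_models=(
                OutcomeModel("o", "EV_O", baseline_hazard=1e-4),
            ),
            seed=13,
        )
        _, truth = generate(spec)
        covs = ["c1", "c2", "c3", "c4", "age", "sex"]
        rows = truth[["patient_id", "group"] + covs].copy()
        fit = fit_logistic(rows, covs)
        groups = pd.Series(rows["group"].to_numpy(),
                           index=rows["patient_id"].to_numpy())
        m = match(fit.scores, groups, 0.2, "logit_sd", seed=3)
        tab = balance(rows, covs, m)
        before = tab[tab["phase"] == "before"]["smd"]
        after = tab[tab["phase"] == "after"]["smd"]
        assert after.mean() < before.mean()
        assert (after < 0.1).mean() >= 0.9
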