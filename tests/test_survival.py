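"""Cohort filtering, tertiles, Spearman screen, Cox models and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from stromascore import CohortSimConfig, simulate_cohort
from stromascore.survival import (
    assign_tertiles,
    cox_multivariate_backward,
    cox_univariate,
    filter_cohort,
    ph_test,
    spearman_screen,
    survival_curves,
)


def brute_force_cox_beta(time, event, x, lo=-5.0, hi=5.0, step=1e-4):
    """Independent oracle: grid maximisation of the Cox partial likelihood
    (no ties), written directly from its definition."""
    betas = np.arange(lo, hi, step)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = np.zeros_like(betas)
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += betas * x[i] - np.log(np.exp(betas[:, None] * x[None, risk]).sum(axis=1))
    return betas[np.argmax(ll)]


class TestFilterCohort:
    def _manifest(self, n_none, reasons):
        rows = [{"patient_id": f"P{i}", "exclusion_reason": "none"} for i in range(n_none)]
        for j, r in enumerate(reasons):
            rows.append({"patient_id": f"X{j}", "exclusion_reason": r})
        return pd.DataFrame(rows)

    def test_stated_exclusions_leave_86_of_111(self):
        reasons = ["misclassified"] * 10 + ["insufficient_material"] * 9 + ["poor_quality"] * 6
        manifest = self._manifest(86, reasons)
        assert len(manifest) == 111
        retained, report = filter_cohort(manifest)
        assert len(retained) == 86
        assert report["misclassified"] == 10
        assert report["insufficient_material"] == 9
        assert report["poor_quality"] == 6
        assert report["n_retained"] == 86

    def test_no_exclusions_retains_all(self):
        retained, report = filter_cohort(self._manifest(12, []))
        assert len(retained) == 12 and report["n_retained"] == 12

    def test_empty_manifest_errors(self):
        with pytest.raises(ValueError, match="empty cohort"):
            filter_cohort(pd.DataFrame(columns=["patient_id", "exclusion_reason"]))

    def test_unknown_reason_errors(self):
        with pytest.raises(ValueError, match="unknown exclusion reason"):
            filter_cohort(self._manifest(2, ["lost_slide"]))


class TestTertiles:
    @pytest.mark.parametrize(
        "n,expected", [(86, (29, 28, 29)), (3, (1, 1, 1)), (100, (34, 32, 34)), (7, (3, 1, 3))]
    )
    def test_group_sizes_follow_ceiling_rule(self, n, expected, rng):
        t = assign_tertiles(rng.permutation(np.arange(n, dtype=float)))
        assert t.sizes == expected
        assert sum(t.sizes) == n
        # outer groups take ceil(n/3) each, so for n = 3k+1 they exceed the
        # middle group by 2; otherwise sizes differ by at most 1
        assert max(t.sizes) - min(t.sizes) <= (2 if n % 3 == 1 else 1)

    def test_assignment_respects_rank_order(self):
        values = np.array([5.0, 1.0, 9.0, 3.0, 7.0, 2.0])
        t = assign_tertiles(values)
        assert list(t.index) == [1, 0, 2, 1, 2, 0]

    def test_ties_broken_by_patient_id(self):
        values = np.zeros(6)
        ids = np.array(["f", "a", "d", "b", "e", "c"])
        t = assign_tertiles(values, ids=ids)
        # ascending id order at equal value: a,b,c -> lower+middle, d,e,f -> upper
        by_id = dict(zip(ids, t.index))
        assert by_id["a"] == 0 and by_id["b"] == 0
        assert by_id["e"] == 2 and by_id["f"] == 2

    def test_too_few_values_error(self):
        with pytest.raises(ValueError, match="n >= 3"):
            assign_tertiles([1.0, 2.0])


class TestSpearman:
    def test_score_correlates_perfectly_with_itself(self):
        df = pd.DataFrame({"tbs": np.arange(10.0), "v": np.arange(10.0)})
        out = spearman_screen(df, "tbs", ["v"])
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_five_pair_hand_example(self):
        """Ranks (1..5) vs (2,1,4,3,5): sum of squared rank differences is 4,
        so rho = 1 - 6*4/(5*24) = 0.8."""
        df = pd.DataFrame({"tbs": [1.0, 2, 3, 4, 5], "v": [2.0, 1, 4, 3, 5]})
        out = spearman_screen(df, "tbs", ["v"])
        assert out.loc[0, "rho"] == pytest.approx(0.8)

    def test_independent_variable_near_zero(self, rng):
        df = pd.DataFrame({"tbs": rng.normal(size=1000), "v": rng.normal(size=1000)})
        out = spearman_screen(df, "tbs", ["v"])
        assert abs(out.loc[0, "rho"]) < 0.1

    def test_constant_variable_reported_missing_with_warning(self):
        df = pd.DataFrame({"tbs": np.arange(6.0), "v": np.ones(6)})
        with pytest.warns(UserWarning, match="constant"):
            out = spearman_screen(df, "tbs", ["v"])
        assert np.isnan(out.loc[0, "rho"])


class TestCoxUnivariate:
    def test_matches_brute_force_partial_likelihood(self, rng):
        for n in (4, 5, 6, 7, 8):
            time = rng.exponential(1.0, n)
            while len(np.unique(time)) < n:
                time = rng.exponential(1.0, n)
            event = np.ones(n, int)
            event[rng.integers(0, n)] = 0
            x = rng.normal(0, 1, n)
            df = pd.DataFrame({"time_to_recurrence": time, "event": event, "v": x})
            fit = cox_univariate(df, "v")
            oracle = brute_force_cox_beta(time, event, x)
            assert abs(fit.coef[0] - oracle) <= 1e-3

    def test_single_factor_hr_recovery(self):
        """Five replicates at n = 2000 with a true HR of 3.0 for nodal status
        recover a mean HR in the 2.6-3.5 window."""
        logs = []
        for seed in range(5):
            df = simulate_cohort(
                CohortSimConfig(
                    n_patients=2000, preset="univariate_single_factor", seed=seed
                )
            )
            fit = cox_univariate(df, "n_status")
            logs.append(np.log(fit.term_hr("n_status")))
        assert 2.6 <= np.exp(np.mean(logs)) <= 3.5

    def test_null_covariate_ci_covers_one(self):
        df = simulate_cohort(CohortSimConfig(n_patients=2000, seed=3))
        fit = cox_univariate(df, "margin")  # margin has no effect on the hazard
        assert fit.ci_lower[0] < 1.0 < fit.ci_upper[0]

    def test_no_events_errors(self):
        df = pd.DataFrame(
            {"time_to_recurrence": [1.0, 2.0, 3.0], "event": [0, 0, 0], "v": [0.0, 1, 0]}
        )
        with pytest.raises(ValueError, match="no events"):
            cox_univariate(df, "v")

    def test_wald_ci_coverage_near_nominal(self):
        """95% Wald CIs should cover the true HR in roughly 95% of fits."""
        true_log_hr = np.log(3.0)
        covered = 0
        n_rep = 200
        for seed in range(n_rep):
            df = simulate_cohort(
                CohortSimConfig(
                    n_patients=500, preset="univariate_single_factor", seed=7000 + seed
                )
            )
            fit = cox_univariate(df, "n_status")
            i = fit.terms.index("n_status")
            covered += fit.ci_lower[i] <= np.exp(true_log_hr) <= fit.ci_upper[i]
        assert covered / n_rep == pytest.approx(0.95, abs=0.05)


class TestBackwardElimination:
    def test_noise_variable_eliminated_true_factors_kept(self):
        df = simulate_cohort(
            CohortSimConfig(n_patients=2000, preset="multivariate", seed=8)
        )
        from stromascore.survival import assign_tertiles

        tert = assign_tertiles(df["tbs"].to_numpy(), ids=df["patient_id"].to_numpy())
        df["tbs_tertile_step"] = tert.index.astype(float)
        fit, trace = cox_multivariate_backward(
            df, ["tbs_tertile_step", "perineural", "n_status", "margin"]
        )
        removed = {t["removed"] for t in trace}
        assert removed == {"margin"}  # the only null factor
        assert set(fit.variable_terms) == {"tbs_tertile_step", "perineural", "n_status"}

    def test_single_significant_candidate_returned_unchanged(self):
        df = simulate_cohort(
            CohortSimConfig(n_patients=1000, preset="univariate_single_factor", seed=2)
        )
        fit, trace = cox_multivariate_backward(df, ["n_status"])
        assert trace == []
        assert fit.terms == ["n_status"]

    def test_empty_candidate_set_errors(self):
        df = simulate_cohort(CohortSimConfig(n_patients=100, seed=1))
        with pytest.raises(ValueError, match="empty candidate"):
            cox_multivariate_backward(df, [])


class TestPHDiagnostic:
    def test_residual_count_equals_event_count(self):
        df = pd.DataFrame(
            {
                "time_to_recurrence": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 0, 1, 0, 1, 0],
                "v": [1.0, 0, 1, 0, 0, 1],
            }
        )
        fit = cox_univariate(df, "v")
        # the diagnostic is built from one scaled residual per event
        diags = ph_test(fit)
        assert len(diags) == 1
        assert fit.n_events == 3

    def test_sign_flip_violation_detected(self):
        df = simulate_cohort(
            CohortSimConfig(
                n_patients=1000,
                preset="univariate_single_factor",
                seed=5,
                ph_flip_time=12.0,
            )
        )
        fit = cox_univariate(df, "n_status")
        assert ph_test(fit)[0].p < 0.01

    def test_too_few_events_errors(self):
        df = pd.DataFrame(
            {"time_to_recurrence": [1.0, 2.0, 3.0], "event": [1, 1, 0], "v": [1.0, 0, 1]}
        )
        fit = cox_univariate(df, "v")
        with pytest.raises(ValueError, match="3 events"):
            ph_test(fit)


class TestSurvivalCurves:
    def test_duplicated_group_logrank_is_null(self):
        df = simulate_cohort(CohortSimConfig(n_patients=100, seed=3))
        dup = pd.concat([df, df], ignore_index=True)
        dup["patient_id"] = [f"Q{i}" for i in range(len(dup))]
        groups = np.array(["a"] * 100 + ["b"] * 100)
        bundle = survival_curves(dup, groups)
        assert bundle.logrank_stat == pytest.approx(0.0, abs=1e-9)
        assert bundle.logrank_p == pytest.approx(1.0)

    def test_toy_logrank_matches_hand_computation(self):
        """Group A fails at 1,2,3 and B at 4,5,6 (no censoring): O_A = 3,
        E_A = 0.5 + 0.4 + 0.25 = 1.15, V = 0.25 + 0.24 + 0.1875 = 0.6775,
        chi2 = (3 - 1.15)^2 / 0.6775 = 5.0517."""
        df = pd.DataFrame(
            {
                "patient_id": list("abcdef"),
                "time_to_recurrence": [1.0, 2, 3, 4, 5, 6],
                "event": [1] * 6,
            }
        )
        bundle = survival_curves(df, np.array(["A", "A", "A", "B", "B", "B"]))
        assert bundle.logrank_stat == pytest.approx(3.4225 / 0.6775, abs=1e-6)

    def test_single_group_errors(self):
        df = simulate_cohort(CohortSimConfig(n_patients=50, seed=3))
        with pytest.raises(ValueError, match="2 groups"):
            survival_curves(df, np.zeros(50))

    def test_cox_curves_start_high_and_decrease(self):
        from stromascore.survival import assign_tertiles

        df = simulate_cohort(CohortSimConfig(n_patients=300, seed=10))
        tert = assign_tertiles(df["tbs"].to_numpy(), ids=df["patient_id"].to_numpy())
        bundle = survival_curves(df, tert)
        for _, grp in bundle.cox_curves.groupby("group"):
            s = grp.sort_values("time")["survival"].to_numpy()
            assert np.all(np.diff(s) <= 1e-12)
            assert s[0] <= 1.0 and s[-1] >= 0.0
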