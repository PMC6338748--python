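"""Cox models, hazard screen, Nelson-Aalen curves, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from filab import (ModelSpec, SimulationConfig, cumulative_hazard_by_group,
                   fit_cox, nelson_aalen_curve, per_variable_hr_screen,
                   recovery_experiment)
from filab.survival import (COVARIATE_SETS, DegenerateDesignError,
                            NoEventError)


def breslow_loglik(beta, times, events, x):
    """Independent Breslow partial log-likelihood (brute force)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def grid_maximiser(times, events, x, lo=-5, hi=5):
    """Coarse-then-fine grid search of the Breslow partial likelihood."""
    for _ in range(6):
        grid = np.linspace(lo, hi, 201)
        vals = [breslow_loglik(b, times, events, x) for b in grid]
        best = grid[int(np.argmax(vals))]
        span = (hi - lo) / 200
        lo, hi = best - 2 * span, best + 2 * span
    return best


@pytest.fixture(scope="module")
def toy():
    """Four subjects, all events, binary exposure interleaved in time.

    Interleaving matters: if both exposed subjects outlived both
    unexposed ones the partial likelihood would be monotone and the
    maximiser infinite (tested separately below).
    """
    return pd.DataFrame({
        "time": [1.0, 2.0, 3.0, 4.0],
        "event": [1, 1, 1, 1],
        "x": [0.0, 1.0, 0.0, 1.0],
    })


class TestFitCox:
    def test_toy_matches_grid_search_oracle(self, toy):
        fit = fit_cox(toy, ModelSpec(exposure="x"), ties="breslow")
        oracle = grid_maximiser(toy["time"].to_numpy(),
                                toy["event"].to_numpy(), toy["x"].to_numpy())
        assert fit.coefficients[0] == pytest.approx(oracle, abs=1e-4)

    def test_reported_optimum_is_local_maximum(self, toy):
        fit = fit_cox(toy, ModelSpec(exposure="x"))
        b = fit.coefficients[0]
        ll = breslow_loglik(b, toy["time"].to_numpy(),
                            toy["event"].to_numpy(), toy["x"].to_numpy())
        for db in (-0.01, 0.01, -0.1, 0.1):
            assert breslow_loglik(b + db, toy["time"].to_numpy(),
                                  toy["event"].to_numpy(),
                                  toy["x"].to_numpy()) <= ll

    def test_separated_exposure_has_monotone_likelihood(self):
        # both exposed subjects die last: the likelihood is monotone in
        # beta and any large negative value beats any smaller one
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        x = np.array([0.0, 0.0, 1.0, 1.0])
        lls = [breslow_loglik(b, times, events, x) for b in (-1, -5, -10)]
        assert lls[0] < lls[1] < lls[2]

    def test_log_partial_likelihood_reported(self, toy):
        fit = fit_cox(toy, ModelSpec(exposure="x"))
        expected = breslow_loglik(fit.coefficients[0],
                                  toy["time"].to_numpy(),
                                  toy["event"].to_numpy(),
                                  toy["x"].to_numpy())
        assert fit.log_partial_likelihood == pytest.approx(expected, abs=1e-6)

    def test_efron_matches_lifelines_cross_check(self, scored_cohort):
        lifelines = pytest.importorskip("lifelines")
        scored, _ = scored_cohort
        fit = fit_cox(scored, ModelSpec("frail"), ties="efron")
        cph = lifelines.CoxPHFitter()
        cph.fit(scored[["time", "event", "frail"]], "time", "event")
        assert fit.coefficients[0] == pytest.approx(
            cph.params_["frail"], abs=1e-5)

    def test_null_exposure_hr_near_one(self, rng):
        n = 3000
        df = pd.DataFrame({
            "time": rng.exponential(5, n).clip(max=4.0),
            "x": (rng.random(n) < 0.5).astype(float),
        })
        df["event"] = (df["time"] < 4.0).astype(int)
        fit = fit_cox(df, ModelSpec(exposure="x"))
        t = fit.term("x")
        assert t["ci_lower"] <= 1.0 <= t["ci_upper"]

    def test_sign_matches_concordance_direction(self, rng):
        # exposure that shortens survival must get a positive coefficient
        n = 800
        x = (rng.random(n) < 0.5).astype(float)
        times = rng.exponential(1.0 / (0.2 * np.exp(0.8 * x)))
        df = pd.DataFrame({"time": times, "event": 1, "x": x})
        assert fit_cox(df, ModelSpec(exposure="x")).coefficients[0] > 0

    def test_wald_ci_brackets_hr(self, scored_cohort):
        scored, _ = scored_cohort
        fit = fit_cox(scored, ModelSpec("frail"))
        t = fit.term("frail")
        assert t["ci_lower"] <= t["hr"] <= t["ci_upper"]

    def test_constant_exposure_rejected(self, toy):
        bad = toy.assign(x=1.0)
        with pytest.raises(DegenerateDesignError):
            fit_cox(bad, ModelSpec(exposure="x"))

    def test_zero_events_rejected(self, toy):
        with pytest.raises(NoEventError):
            fit_cox(toy.assign(event=0), ModelSpec(exposure="x"))

    def test_adjusted_models_leave_frailty_hr_stable(self, scored_cohort):
        """Independently generated covariates barely move the frailty HR."""
        scored, _ = scored_cohort
        hrs = {name: fit_cox(scored, ModelSpec("frail", name)).term("frail")["hr"]
               for name in COVARIATE_SETS}
        for name in ("model1", "model2", "model3"):
            assert hrs[name] == pytest.approx(hrs["unadjusted"], abs=0.05)

    def test_nested_covariate_sets(self):
        assert set(COVARIATE_SETS["model1"]) < set(COVARIATE_SETS["model2"])
        assert set(COVARIATE_SETS["model2"]) < set(COVARIATE_SETS["model3"])


class TestPerVariableScreen:
    def test_recovers_known_deficit_hazard(self, rng):
        # one variable with true HR 1.4, fitted unadjusted, many subjects
        n = 20000
        deficit = (rng.random(n) < 0.3).astype(float)
        lam = 0.15 * np.exp(np.log(1.4) * deficit)
        latent = rng.exponential(1 / lam)
        cohort = pd.DataFrame({
            "time": np.minimum(latent, 4.0),
            "event": (latent <= 4.0).astype(int),
        })
        deficits = pd.DataFrame({"var1": deficit})
        screen = per_variable_hr_screen(cohort, deficits)
        row = screen.iloc[0]
        assert row["status"] == "ok"
        assert row["hr"] == pytest.approx(1.4, rel=0.08)

    def test_screen_consistent_with_fit_cox(self, scored_cohort):
        scored, deficits = scored_cohort
        screen = per_variable_hr_screen(scored, deficits[["wbc"]])
        sub = scored[["time", "event"]].copy()
        sub["deficit"] = deficits["wbc"]
        fit = fit_cox(sub, ModelSpec(exposure="deficit"))
        assert screen.iloc[0]["hr"] == pytest.approx(
            fit.term("deficit")["hr"], abs=1e-10)

    def test_one_per_panel_variable(self, scored_cohort):
        scored, deficits = scored_cohort
        screen = per_variable_hr_screen(scored, deficits)
        assert len(screen) == 22
        assert set(screen["status"]) <= {"ok", "unstable", "not_estimable"}

    def test_rare_deficit_flagged_unstable(self):
        cohort = pd.DataFrame({
            "time": [1, 2, 3, 4, 4, 4, 4, 4.0],
            "event": [1, 1, 1, 0, 0, 0, 0, 0],
        })
        deficits = pd.DataFrame({"v": [1, 0, 0, 0, 0, 0, 0, 0.0]})
        screen = per_variable_hr_screen(cohort, deficits)
        assert screen.iloc[0]["status"] == "unstable"
        assert np.isnan(screen.iloc[0]["hr"])

    def test_constant_column_not_estimable(self):
        cohort = pd.DataFrame({"time": [1, 2, 3.0], "event": [1, 1, 1]})
        deficits = pd.DataFrame({"v": [0, 0, 0.0]})
        screen = per_variable_hr_screen(cohort, deficits)
        assert screen.iloc[0]["status"] == "not_estimable"


class TestNelsonAalen:
    def test_hand_computed_three_subject_example(self):
        curve = nelson_aalen_curve(np.array([1.0, 2.0, 3.0]),
                                   np.array([1, 1, 1]))
        assert curve["time"].tolist() == [0.0, 1.0, 2.0, 3.0]
        assert curve["cumhaz"].to_numpy() == pytest.approx(
            [0.0, 1 / 3, 1 / 3 + 1 / 2, 1 / 3 + 1 / 2 + 1.0])

    def test_non_decreasing_from_zero(self, cohort):
        curve = nelson_aalen_curve(cohort["time"].to_numpy(),
                                   cohort["event"].to_numpy())
        ch = curve["cumhaz"].to_numpy()
        assert ch[0] == 0.0 and np.all(np.diff(ch) >= 0)

    def test_invariant_to_record_duplication(self, cohort):
        t = cohort["time"].to_numpy()
        e = cohort["event"].to_numpy()
        a = nelson_aalen_curve(t, e)
        b = nelson_aalen_curve(np.repeat(t, 2), np.repeat(e, 2))
        assert np.allclose(a["cumhaz"], b["cumhaz"])

    def test_no_events_rejected(self):
        with pytest.raises(NoEventError):
            nelson_aalen_curve(np.array([1.0, 2.0]), np.array([0, 0]))

    def test_matches_lifelines_unsmoothed(self, cohort):
        lifelines = pytest.importorskip("lifelines")
        naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(cohort["time"], cohort["event"])
        ours = nelson_aalen_curve(cohort["time"].to_numpy(),
                                  cohort["event"].to_numpy())
        theirs = naf.cumulative_hazard_.iloc[:, 0]
        # compare at each of our event times
        for t, ch in zip(ours["time"][1:], ours["cumhaz"][1:]):
            assert ch == pytest.approx(theirs.loc[t], abs=1e-10)

    def test_plot_helper_renders_both_scales(self, scored_cohort, tmp_path):
        import matplotlib.pyplot as plt
        scored, _ = scored_cohort
        curves = cumulative_hazard_by_group(scored, "frail")
        from filab.survival import plot_cumulative_hazard
        for loglog, name in ((False, "linear.png"), (True, "loglog.png")):
            fig = plot_cumulative_hazard(curves, str(tmp_path / name),
                                         loglog=loglog)
            assert (tmp_path / name).exists()
            plt.close(fig)

    def test_group_curves(self, scored_cohort):
        scored, _ = scored_cohort
        curves = cumulative_hazard_by_group(scored, "frail")
        assert set(curves) == {"0.0", "1.0"}
        # frail group should accumulate hazard faster on this cohort
        final = {k: v["cumhaz"].iloc[-1] for k, v in curves.items()}
        assert final["1.0"] > 0 and final["0.0"] > 0


class TestRecoveryExperiment:
    def test_small_recovery_run_is_unbiased(self):
        cfg = SimulationConfig(n_subjects=736)
        rs = recovery_experiment(cfg, n_reps=40, seed=99)
        assert abs(rs.bias_log_hr) < 3 * rs.se_mean_log_hr
        assert 0.80 <= rs.ci_coverage <= 1.0

    def test_bias_shrinks_with_sample_size(self):
        small = recovery_experiment(
            SimulationConfig(n_subjects=150), n_reps=25, seed=5)
        large = recovery_experiment(
            SimulationConfig(n_subjects=8000), n_reps=8, seed=5)
        assert abs(large.bias_log_hr) < 3 * large.se_mean_log_hr
        assert large.sd_log_hr < small.sd_log_hr

    def test_needs_two_reps(self):
        with pytest.raises(ValueError):
            recovery_experiment(SimulationConfig(), n_reps=1, seed=1)
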