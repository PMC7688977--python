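import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from fedsurv import SimConfig, build_federation, generate_cohort
from fedsurv.fed_cox import (
    EventGrid,
    FitOptions,
    build_event_grid,
    fit_federated_cox,
    format_hr_table,
    hazard_ratios,
    local_aggregates,
    newton_step,
    partial_loglik,
    sum_aggregates,
)
from fedsurv.fed_infra import FederationError
from fedsurv.registry_model import build_design_matrix, multivariable_spec

from conftest import pooled, split_sites
from oracle import centralized_breslow_fit

# three subjects: events at 1.0 and 2.0 years, one censored at 3.0;
# a single binary covariate z = (1, 0, 1)
TOY_TIMES = np.array([1.0, 2.0, 3.0])
TOY_EVENTS = np.array([1, 1, 0])
TOY_Z = np.array([[1.0], [0.0], [1.0]])
TOY_GRID = EventGrid((10, 20))


class TestEventGrid:
    def test_union_across_sites(self):
        tabs = {
            "A": pd.DataFrame({"time": [0.5, 1.2, 4.0], "event": [1, 1, 0]}),
            "B": pd.DataFrame({"time": [1.2, 3.0], "event": [1, 1]}),
        }
        server = build_federation(tabs)
        grid = build_event_grid(server)
        assert list(grid.times) == [0.5, 1.2, 3.0]

    def test_single_site_grid_is_its_own_event_times(self):
        tabs = {"A": pd.DataFrame({"time": [0.5, 1.2, 4.0], "event": [1, 1, 0]})}
        grid = build_event_grid(build_federation(tabs))
        assert list(grid.times) == [0.5, 1.2]

    def test_all_censored_federation_is_an_error(self):
        tabs = {"A": pd.DataFrame({"time": [0.5, 1.2], "event": [0, 0]})}
        with pytest.raises(FederationError, match="no events"):
            build_event_grid(build_federation(tabs))


class TestLocalAggregates:
    def test_toy_risk_set_sums_at_zero(self):
        agg = local_aggregates(TOY_TIMES, TOY_EVENTS, TOY_Z, TOY_GRID, [0.0])
        # risk sets: {1,2,3} at t=1.0 and {2,3} at t=2.0
        assert np.allclose(agg.S0, [3.0, 2.0])
        assert np.allclose(agg.d, [1.0, 1.0])
        assert np.allclose(agg.s.ravel(), [1.0, 0.0])
        assert np.allclose(agg.S1.ravel(), [2.0, 1.0])
        assert np.allclose(agg.S2.ravel(), [2.0, 1.0])

    def test_beta_zero_S0_is_count_at_risk(self, small_cohorts, small_spec):
        table = small_cohorts["NL"]
        X, _ = build_design_matrix(table, small_spec)
        t = table["time"].to_numpy()
        grid = EventGrid(tuple(np.unique(np.rint(
            t[table["event"] == 1] * 10).astype(int))))
        agg = local_aggregates(t, table["event"].to_numpy(), X, grid, np.zeros(X.shape[1]))
        for k, gt in enumerate(grid.times):
            assert agg.S0[k] == (t >= gt - 1e-9).sum()

    def test_site_past_its_last_follow_up_contributes_zero(self):
        grid = EventGrid((5, 12))
        agg = local_aggregates([0.5, 0.9], [1, 0], [[1.0], [0.0]], grid, [0.0])
        assert agg.S0[1] == 0.0 and np.all(agg.S1[1] == 0) and agg.d[1] == 0

    def test_overflowing_linear_predictor_reports_magnitude(self):
        with pytest.raises(FederationError, match="overflow"):
            local_aggregates(TOY_TIMES, TOY_EVENTS, TOY_Z, TOY_GRID, [800.0])


class TestNewtonStep:
    def test_hand_computed_scalar_step(self):
        # at beta=0: U = (1 - 2/3) + (0 - 1/2) = -1/6
        #            I = (2/3 - 4/9) + (1/2 - 1/4) = 17/36
        agg = local_aggregates(TOY_TIMES, TOY_EVENTS, TOY_Z, TOY_GRID, [0.0])
        beta_new, U, I = newton_step(agg, [0.0])
        assert U[0] == pytest.approx(-1.0 / 6.0, abs=1e-12)
        assert I[0, 0] == pytest.approx(17.0 / 36.0, abs=1e-12)
        assert beta_new[0] == pytest.approx(-(1.0 / 6.0) / (17.0 / 36.0), abs=1e-12)

    def test_additivity_duplicated_data_equals_doubled_site(self):
        one = local_aggregates(TOY_TIMES, TOY_EVENTS, TOY_Z, TOY_GRID, [0.3])
        summed = sum_aggregates([one, one])
        times2 = np.concatenate([TOY_TIMES, TOY_TIMES])
        events2 = np.concatenate([TOY_EVENTS, TOY_EVENTS])
        Z2 = np.vstack([TOY_Z, TOY_Z])
        doubled = local_aggregates(times2, events2, Z2, TOY_GRID, [0.3])
        b1, _, _ = newton_step(summed, [0.3])
        b2, _, _ = newton_step(doubled, [0.3])
        assert np.allclose(b1, b2, atol=1e-14)

    def test_singular_information_names_collinear_columns(self):
        Z = np.array([[1.0, 1.0], [0.0, 0.0], [1.0, 1.0]])
        agg = local_aggregates(TOY_TIMES, TOY_EVENTS, Z, TOY_GRID, [0.0, 0.0])
        with pytest.raises(FederationError, match="collinear"):
            newton_step(agg, [0.0, 0.0])


class TestPartialLoglik:
    def test_toy_closed_form_at_zero(self):
        agg = local_aggregates(TOY_TIMES, TOY_EVENTS, TOY_Z, TOY_GRID, [0.0])
        assert partial_loglik(agg, [0.0]) == pytest.approx(-(np.log(3) + np.log(2)), abs=1e-14)

    def test_zero_beta_equals_minus_sum_d_log_risk_count(self, small_cohorts, small_spec):
        table = small_cohorts["TW"]
        X, _ = build_design_matrix(table, small_spec)
        t, e = table["time"].to_numpy(), table["event"].to_numpy()
        grid = EventGrid(tuple(np.unique(np.rint(t[e == 1] * 10).astype(int))))
        agg = local_aggregates(t, e, X, grid, np.zeros(X.shape[1]))
        expected = -sum(
            agg.d[k] * np.log((t >= gt - 1e-9).sum()) for k, gt in enumerate(grid.times)
        )
        assert partial_loglik(agg, np.zeros(X.shape[1])) == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_partitioning(self, small_cohorts, small_spec):
        table = pooled(small_cohorts)
        X, _ = build_design_matrix(table, small_spec)
        t, e = table["time"].to_numpy(), table["event"].to_numpy()
        grid = EventGrid(tuple(np.unique(np.rint(t[e == 1] * 10).astype(int))))
        beta = np.full(X.shape[1], 0.2)
        whole = local_aggregates(t, e, X, grid, beta)
        parts = sum_aggregates(
            [
                local_aggregates(t[i::3], e[i::3], X[i::3], grid, beta)
                for i in range(3)
            ]
        )
        assert partial_loglik(whole, beta) == pytest.approx(partial_loglik(parts, beta), abs=1e-9)


class TestFederatedFit:
    def test_single_site_equals_centralized_oracle(self, small_cohorts, small_spec):
        # country is constant within one site, so the single-site model
        # carries only the within-site covariates
        from fedsurv.registry_model import ModelSpec

        small_spec = ModelSpec(
            tuple(b for b in small_spec.covariate_blocks if b.variable != "country")
        )
        table = small_cohorts["NL"]
        server = build_federation({"NL": table})
        fit = fit_federated_cox(server, small_spec)
        X, _ = build_design_matrix(table, small_spec)
        ref = centralized_breslow_fit(table["time"], table["event"], X)
        assert np.abs(fit.beta - ref["beta"]).max() < 1e-6
        assert np.abs(fit.se - ref["se"]).max() < 1e-6
        assert fit.loglik == pytest.approx(ref["loglik"], abs=1e-6)
        assert fit.loglik_null == pytest.approx(ref["loglik_null"], abs=1e-9)

    def test_two_site_fit_matches_pooled_oracle(self, small_cohorts, small_spec):
        server = build_federation(small_cohorts)
        fit = fit_federated_cox(server, small_spec)
        table = pooled(small_cohorts)
        X, _ = build_design_matrix(table, small_spec)
        ref = centralized_breslow_fit(table["time"], table["event"], X)
        assert np.abs(fit.beta - ref["beta"]).max() < 1e-6
        assert np.abs(fit.se - ref["se"]).max() < 1e-6

    def test_matches_r_survival_breslow(self, tmp_path, small_cohorts, small_spec):
        table = pooled(small_cohorts)
        X, labels = build_design_matrix(table, small_spec)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        df["time"], df["event"] = table["time"], table["event"]
        csv = tmp_path / "pooled.csv"
        df.to_csv(csv, index=False)
        rscript = (
            f'd <- read.csv("{csv}"); library(survival); '
            f'f <- coxph(Surv(time, event) ~ x0 + x1 + x2 + x3, data=d, ties="breslow"); '
            f'cat(sprintf("%.12f ", coef(f)), "\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        r_beta = np.array([float(v) for v in out.stdout.split()])
        fit = fit_federated_cox(build_federation(small_cohorts), small_spec)
        assert np.abs(fit.beta - r_beta).max() < 1e-6

    @pytest.mark.parametrize("n_sites", [1, 2, 3, 5])
    def test_partition_invariance(self, small_cohorts, small_spec, n_sites):
        table = pooled(small_cohorts)
        reference = fit_federated_cox(build_federation({"all": table}), small_spec)
        sites = split_sites(table, n_sites, seed=7)
        sites = {k: v for k, v in sites.items() if len(v)}
        fit = fit_federated_cox(build_federation(sites), small_spec)
        assert np.abs(fit.beta - reference.beta).max() < 1e-9
        assert np.abs(fit.covariance - reference.covariance).max() < 1e-9
        assert fit.loglik == pytest.approx(reference.loglik, abs=1e-9)

    def test_fit_diagnostics(self, small_cohorts, small_spec):
        fit = fit_federated_cox(build_federation(small_cohorts), small_spec)
        assert fit.converged and fit.iterations <= 10
        assert fit.loglik >= fit.loglik_null
        assert np.allclose(fit.covariance, fit.covariance.T)
        assert np.all(np.linalg.eigvalsh(fit.covariance) > 0)
        assert fit.trace[-1]["max_score"] < 1e-6 or fit.trace[-1]["gap"] < 1e-8

    def test_max_delta_criterion_agrees(self, small_cohorts, small_spec):
        server = build_federation(small_cohorts)
        a = fit_federated_cox(server, small_spec, options=FitOptions(criterion="hr_sum"))
        b = fit_federated_cox(server, small_spec, options=FitOptions(criterion="max_delta"))
        assert np.abs(a.beta - b.beta).max() < 1e-8

    def test_null_covariate_estimate_near_zero(self):
        # a covariate permuted independently of outcome has true log-HR 0
        rng = np.random.default_rng(42)
        n = 4000
        t = np.floor(rng.exponential(5.0, n) * 10 + 0.5) / 10
        e = (rng.uniform(size=n) < 0.7).astype(int)
        z = rng.integers(0, 2, n)
        tabs = {"A": pd.DataFrame({"time": t, "event": e, "z": np.where(z, "yes", "no")})}
        from fedsurv.registry_model import CovariateBlock, ModelSpec

        spec = ModelSpec((CovariateBlock("z", ("no", "yes"), "no"),))
        fit = fit_federated_cox(build_federation(tabs), spec)
        assert abs(fit.beta[0]) < 3 * fit.se[0]

    def test_nonconvergence_raises_with_trace(self, small_cohorts, small_spec):
        server = build_federation(small_cohorts)
        with pytest.raises(FederationError, match="did not converge"):
            fit_federated_cox(server, small_spec, options=FitOptions(max_iter=1))


class TestHazardRatios:
    def test_closed_form_ci(self, small_cohorts, small_spec):
        fit = fit_federated_cox(build_federation(small_cohorts), small_spec)
        table = hazard_ratios(fit)
        j = 0
        assert table.loc[j, "hr"] == pytest.approx(np.exp(fit.beta[j]), rel=1e-12)
        assert table.loc[j, "ci_low"] == pytest.approx(
            np.exp(fit.beta[j] - 1.959964 * fit.se[j]), rel=1e-12
        )
        assert table.loc[j, "ci_high"] == pytest.approx(
            np.exp(fit.beta[j] + 1.959964 * fit.se[j]), rel=1e-12
        )

    def test_reference_rows_rendered(self, small_cohorts, small_spec):
        fit = fit_federated_cox(build_federation(small_cohorts), small_spec)
        table = format_hr_table(fit, small_spec)
        ref = table[table["reference"]]
        assert set(ref["hr"]) == {"1.00"} and set(ref["ci"]) == {"–"}
        assert len(table) == sum(len(b.levels) for b in small_spec.covariate_blocks)

    def test_non_converged_fit_refused(self, small_cohorts, small_spec):
        fit = fit_federated_cox(build_federation(small_cohorts), small_spec)
        fit.converged = False
        with pytest.raises(FederationError, match="non-converged"):
            hazard_ratios(fit)
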