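"""Hierarchical estimation: Laplace objective, staged fitting, bootstrap,
shrinkage and VPC diagnostics.

Simulation sizes here are deliberately small (8-24 subjects, restricted
free-parameter sets) so the whole suite stays fast; the fuller recovery
checks run in the acceptance suite.
"""

import numpy as np
import pandas as pd
import pytest

from doxypk import Route, published_model
from doxypk.estimation import (
    EstimationError,
    PopPKModel,
    bootstrap_ci,
    build_model,
    covariate_search,
    fit,
    laplace_nll,
    marginal_ofv,
    shrinkage,
    vpc_check,
)
from doxypk.io import Dataset
from doxypk.population import ResidualModel
from doxypk.synthetic import TrialDesign, generate_trials

RICH_IV = (0.25, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)


def small_iv_model(omega_cl=0.266, extra_omega=None):
    """IV-only model: published typicals, no covariates, omega on Cl."""
    model = published_model()
    model.covariates = ()
    model.omega = {} if omega_cl is None else {"cl": omega_cl}
    if extra_omega:
        model.omega.update(extra_omega)
    model.residual = {Route.IV: ResidualModel(0.013, 0.139)}
    model.absorption = {}
    return model


def simulate_iv(model, n=10, seed=0, times=RICH_IV, bw=50.0):
    design = TrialDesign(
        "SIM", n, Route.IV, (0.0,), (8.68,), times, 1e-6,
        bw_sampler=(lambda rng, k: np.full(k, bw)) if np.isscalar(bw) else bw,
    )
    return generate_trials(model, [design], seed=seed)


class TestLaplaceMachinery:
    def test_exact_on_linear_gaussian_toy(self):
        """For y = a + b*eta + e the marginal is N(a, b^2 w^2 + s^2); the
        Laplace approximation is exact and matches the closed form to
        1e-8."""
        y, a, b, w, s = 1.3, 0.4, 0.7, 0.5, 0.2

        def joint(eta):
            e = float(eta[0]) if len(eta) else 0.0
            return 0.5 * (
                ((y - a - b * e) / s) ** 2 + np.log(2 * np.pi * s**2)
                + (e / w) ** 2 + np.log(2 * np.pi * w**2)
            )

        nll, eta_hat = laplace_nll(joint, d=1)
        var = b**2 * w**2 + s**2
        closed = 0.5 * (((y - a) ** 2) / var + np.log(2 * np.pi * var))
        assert nll == pytest.approx(closed, abs=1e-8)
        # conditional mode of the conjugate normal
        assert eta_hat[0] == pytest.approx(b * w**2 * (y - a) / var, abs=1e-6)

    def test_pooled_limit_equals_fixed_effect_m2ll(self):
        """With all omegas zero the OFV is the pooled extended least
        squares -2 log-likelihood of the fixed-effect model."""
        model = small_iv_model(omega_cl=None)
        ds = simulate_iv(model, n=4, seed=1)
        ofv = marginal_ofv(ds, model)
        manual = 0.0
        from doxypk.pk import conc_profile

        for subj in ds.subjects():
            ind = model.individual(subj.bw, subj.route)
            pred = conc_profile(ind.disposition, ind.absorption, subj.doses, subj.obs_times)
            sd = model.residual_for(Route.IV).sd(pred)
            manual += float(
                np.sum(((subj.obs_conc - pred) / sd) ** 2 + np.log(2 * np.pi * sd**2))
            )
        assert ofv == pytest.approx(manual, rel=1e-10)

    def test_truth_beats_perturbed_parameters(self):
        """Simulation oracle: the OFV at the generating parameters is lower
        than at 1.5x-perturbed clearance in nearly all replicate
        datasets."""
        model = small_iv_model()
        wins = 0
        for seed in range(15):
            ds = simulate_iv(model, n=10, seed=100 + seed)
            subjects = ds.subjects()
            at_truth = marginal_ofv(subjects, model)
            perturbed = marginal_ofv(subjects, model, thetas={"cl": model.disposition.cl * 1.5})
            wins += at_truth < perturbed
        assert wins >= 13

    def test_nonpositive_residual_sd_names_subject(self):
        """An oral observation at t=0 has zero prediction; with a purely
        proportional residual the SD is zero and the error identifies the
        subject."""
        model = published_model()
        model.covariates = ()
        model.omega = {}
        model.residual[Route.SOL_DW] = ResidualModel(0.0, 0.3)
        rows = [
            dict(subject="BAD", trial="T", route="SOL_DW", bw=30.0, time=0.0,
                 evid=1, amount=8.68, conc=np.nan, lloq=0.01),
            dict(subject="BAD", trial="T", route="SOL_DW", bw=30.0, time=0.0,
                 evid=0, amount=np.nan, conc=0.0, lloq=0.01),
            dict(subject="BAD", trial="T", route="SOL_DW", bw=30.0, time=2.0,
                 evid=0, amount=np.nan, conc=0.5, lloq=0.01),
        ]
        with pytest.raises(EstimationError, match="BAD"):
            marginal_ofv(Dataset(pd.DataFrame(rows)), model)


@pytest.fixture(scope="module")
def noiseless_fit():
    """Near-noiseless identifiability: all six disposition thetas free,
    no BSV, tiny residual."""
    truth = small_iv_model(omega_cl=None)
    truth.residual = {Route.IV: ResidualModel(1e-4, 0.0)}
    ds = simulate_iv(truth, n=8, seed=5, times=(0.1, 0.25, 0.5, 1, 2, 4, 8, 12, 24, 36.0))
    start = build_model(truth, thetas={n: v * 1.3 for n, v in [
        ("cl", 0.259), ("cl2", 1.179), ("cl3", 0.072),
        ("vc", 0.192), ("v2", 0.595), ("v3", 0.536)]})
    result = fit(
        ds, start, stage="iv_only",
        free_thetas=["cl", "cl2", "cl3", "vc", "v2", "v3"], free_omegas=[],
        method="Powell", maxiter=4000,
    )
    return truth, result


class TestFit:
    def test_noiseless_recovery_within_one_percent(self, noiseless_fit):
        truth, result = noiseless_fit
        for name in ("cl", "cl2", "cl3", "vc", "v2", "v3"):
            assert result.thetas[name] == pytest.approx(
                getattr(truth.disposition, name), rel=0.01
            ), name

    def test_aic_identity_and_monotone_history(self, noiseless_fit):
        _, result = noiseless_fit
        assert result.aic == result.ofv + 2 * result.n_params
        assert result.n_params == 6
        history = np.asarray(result.ofv_history)
        assert np.all(np.diff(history) <= 0.0)

    def test_results_surface(self, noiseless_fit):
        _, result = noiseless_fit
        summary = result.summary()
        assert (summary["parameter"] == "AIC").any()
        assert result.converged
        assert set(result.ebes) == {f"SIM-{i:03d}" for i in range(1, 9)}

    def test_unknown_stage_and_missing_prior(self):
        model = small_iv_model()
        ds = simulate_iv(model, n=3, seed=2)
        with pytest.raises(ValueError, match="stage"):
            fit(ds, model, stage="both_at_once")
        with pytest.raises(ValueError, match="prior"):
            fit(ds, model, stage="oral_given_iv")

    def test_model_results_front_door(self):
        """PopPKModel.fit returns the same results object as the
        functional interface."""
        model = small_iv_model(omega_cl=None)
        ds = simulate_iv(model, n=4, seed=8)
        wrapper = PopPKModel(ds, model, free_thetas=["cl"], free_omegas=[])
        res = wrapper.fit(stage="iv_only", method="Powell", maxiter=200)
        assert res.thetas["cl"] == pytest.approx(model.disposition.cl, rel=0.15)
        assert wrapper.ofv() == pytest.approx(marginal_ofv(ds, model))


class TestShrinkage:
    def test_limit_cases(self):
        omega = {"cl": 0.3}
        ebes_match = {f"s{i}": {"cl": v} for i, v in enumerate(np.array([-0.3, 0.3, -0.3, 0.3]) * 0.7746)}
        sd = np.std([e["cl"] for e in ebes_match.values()], ddof=1)
        expect = 100 * (1 - sd / 0.3)
        assert shrinkage(ebes_match, omega)["cl"] == pytest.approx(expect)
        all_zero = {f"s{i}": {"cl": 0.0} for i in range(5)}
        assert shrinkage(all_zero, omega)["cl"] == pytest.approx(100.0)
        assert shrinkage(all_zero, {"cl": 0.0})["cl"] is None

    def test_sparse_data_shrinks_more_than_rich(self):
        """EBEs from one early observation per subject (nearly
        clearance-free information) collapse toward zero more than EBEs
        from rich profiles under the same model."""
        model = small_iv_model()
        rich = simulate_iv(model, n=14, seed=31, times=RICH_IV)
        sparse = simulate_iv(model, n=14, seed=31, times=(0.25,))
        _, ebes_rich = marginal_ofv(rich, model, return_ebes=True)
        _, ebes_sparse = marginal_ofv(sparse, model, return_ebes=True)
        sh_rich = shrinkage(ebes_rich, model.omega)["cl"]
        sh_sparse = shrinkage(ebes_sparse, model.omega)["cl"]
        assert sh_sparse > sh_rich


class TestBootstrap:
    def test_resample_preserves_size_and_strata(self):
        from doxypk.estimation import _resample_dataset

        model = small_iv_model(omega_cl=None)
        ds = simulate_iv(model, n=12, seed=3)
        rng = np.random.default_rng(0)
        resampled = _resample_dataset(ds, rng, stratify=True)
        assert resampled.n_subjects == ds.n_subjects
        assert resampled.df.groupby("route")["subject"].nunique().equals(
            ds.df.groupby("route")["subject"].nunique()
        )

    def test_strong_bw_effect_ci_excludes_zero(self):
        """Simulated exponent 0.3 on Cl, 24 subjects across 10-100 kg: the
        bootstrap 95% CI of the exponent excludes 0."""
        truth = small_iv_model(omega_cl=None)
        truth = build_model(truth, thetas={"bw_cl": 0.3})
        rng_bw = lambda rng, k: np.exp(rng.uniform(np.log(10), np.log(100), k))
        ds = simulate_iv(truth, n=24, seed=41, bw=rng_bw)
        base = small_iv_model(omega_cl=None)
        result = bootstrap_ci(
            ds, base, free_thetas=["cl", "bw_cl"], free_omegas=[],
            n_resamples=20, seed=7, method="Powell", maxiter=300,
        )
        assert result.n_success == 20
        assert result.significant("bw_cl")
        assert result.table.loc["bw_cl", "p2_5"] <= result.table.loc["bw_cl", "median"]
        assert result.table.loc["bw_cl", "median"] <= result.table.loc["bw_cl", "p97_5"]

    def test_coverage_of_clearance_ci(self):
        """True-parameter coverage of the percentile 95% CI for Cl over
        scaled-down outer replicates stays in the 80-100% band."""
        truth = small_iv_model(omega_cl=None)
        covered = 0
        n_outer = 8
        for k in range(n_outer):
            ds = simulate_iv(truth, n=12, seed=600 + k, times=(0.5, 2.0, 8.0, 24.0))
            result = bootstrap_ci(
                ds, truth, free_thetas=["cl"], free_omegas=[],
                n_resamples=14, seed=k, method="Powell", maxiter=150,
            )
            lo, hi = result.table.loc["cl", ["p2_5", "p97_5"]]
            covered += lo <= truth.disposition.cl <= hi
        assert 0.8 * n_outer <= covered <= n_outer

    def test_too_few_subjects_rejected(self):
        model = small_iv_model(omega_cl=None)
        ds = simulate_iv(model, n=4, seed=2)
        with pytest.raises(ValueError, match="at least 10"):
            bootstrap_ci(ds, model, free_thetas=["cl"], n_resamples=5, seed=0)


class TestCovariateSearch:
    def test_empty_subset_reproduces_base_aic(self):
        """The empty covariate subset is the base model: identical free
        parameters, identical AIC."""
        truth = small_iv_model(omega_cl=None)
        rng_bw = lambda rng, k: np.exp(rng.uniform(np.log(10), np.log(100), k))
        ds = simulate_iv(truth, n=10, seed=51, bw=rng_bw)
        table = covariate_search(
            ds, truth, parameters=("cl",), free_thetas=["cl", "vc"], free_omegas=[],
            method="Powell", maxiter=200,
        )
        base = fit(ds, truth, free_thetas=["cl", "vc"], free_omegas=[],
                   method="Powell", maxiter=200)
        empty_row = table[table["subset"].apply(lambda s: s == ())]
        assert empty_row["aic"].iloc[0] == pytest.approx(base.aic, abs=1e-6)
        assert empty_row["delta_aic"].iloc[0] == 0.0

    def test_constant_bw_rejected(self):
        truth = small_iv_model(omega_cl=None)
        ds = simulate_iv(truth, n=6, seed=52, bw=40.0)
        with pytest.raises(ValueError, match="constant"):
            covariate_search(ds, truth, parameters=("cl",))

    def test_base_model_with_covariates_rejected(self):
        rng_bw = lambda rng, k: np.exp(rng.uniform(np.log(10), np.log(100), k))
        ds = simulate_iv(small_iv_model(omega_cl=None), n=6, seed=53, bw=rng_bw)
        with pytest.raises(ValueError, match="without BW covariates"):
            covariate_search(ds, published_model(), parameters=("cl",))


class TestVPC:
    def test_self_consistency(self):
        """Data simulated from the model: observed quantiles fall inside
        the simulated 95% bands in at least 90% of bins."""
        model = small_iv_model()
        ds = simulate_iv(model, n=15, seed=61)
        result = vpc_check(ds, model, n_replicates=200, seed=1)
        assert result.fraction_within_bands() >= 0.90

    def test_zero_variability_quantiles_coincide(self):
        model = small_iv_model(omega_cl=None)
        model.residual = {Route.IV: ResidualModel(1e-9, 0.0)}
        ds = simulate_iv(model, n=6, seed=62)
        result = vpc_check(ds, model, n_replicates=30, quantiles=(20.0, 50.0, 80.0), seed=2)
        for q in (20.0, 50.0, 80.0):
            np.testing.assert_allclose(
                result.table[f"obs_q{q:g}"], result.table[f"sim_q{q:g}_med"],
                rtol=1e-5, atol=1e-8,
            )

    def test_alternative_quantile_set_supported(self):
        model = small_iv_model()
        ds = simulate_iv(model, n=8, seed=63)
        result = vpc_check(ds, model, n_replicates=40, quantiles=(20.0, 50.0, 80.0), seed=3)
        assert result.quantiles == (20.0, 50.0, 80.0)
        assert {"obs_q20", "sim_q20_lo", "sim_q20_hi"} <= set(result.table.columns)
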