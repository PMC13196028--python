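"""Staged fitting: residuals, parameter recovery, bootstrap, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from viralshunt.dynamics import DEFAULT_PARAMS, InitialState, simulate
from viralshunt.inference import (
    ConfigError,
    DataError,
    FitConfig,
    FitResult,
    GrowthCurveDataset,
    UsageError,
    bootstrap_cis,
    fit_diagnostics,
    fit_stage1,
    fit_stage2,
    fit_stage3,
    normalized_delta_biomass,
    run_three_stage_fit,
    weighted_log_residuals,
)
from viralshunt.synthetic import (
    BatchNoiseModel,
    MixDesign,
    generate_batch_dataset,
    generate_batch_suite,
)

TRUE = {
    "mu_g_max": 0.7, "K_S_g": 0.01, "delta": 0.9, "k": 6,
    "mu_l_max": 0.8, "K_S_l": 0.05, "epsilon": 0.4,
}


def _dataset(times, replicates, label="100WT", wt=1.0, ts=0.0, od0=0.01):
    return GrowthCurveDataset(
        mix_label=label, wt_fraction=wt, ts_fraction=ts, initial_od=od0,
        times=np.asarray(times, float), replicates=np.asarray(replicates, float),
    )


class TestWeightedLogResiduals:
    def _flat_traj(self, od, t_end=2.0):
        p = DEFAULT_PARAMS.with_(mu_g_max=0.0, mu_l_max=0.0, delta=1e-3)
        return simulate(p, InitialState(B_WT0=od, TS0=0.0, C_g0=0.0), t_end)

    def test_perfect_fit_gives_zero_residuals(self):
        traj = self._flat_traj(0.02)
        ds = _dataset([0.0, 1.0], [[0.02, 0.02], [0.02, 0.02]])
        np.testing.assert_allclose(weighted_log_residuals(ds, traj), 0.0, atol=1e-12)

    def test_small_sd_is_floored(self):
        # replicate pair with sample SD = 1e-4, well under the 1e-3 floor
        d = 1e-4 / np.sqrt(2.0)
        ds = _dataset([0.0, 1.0], [[0.02 + d, 0.02 - d], [0.02 + d, 0.02 - d]])
        traj = self._flat_traj(0.01)
        r = weighted_log_residuals(ds, traj, sd_floor=1e-3)
        np.testing.assert_allclose(r, np.log(2.0) / 1e-3, rtol=1e-6)

    def test_direct_evaluation_with_large_sd(self):
        # mean twice the model od with SD 0.1 -> ln(2)/0.1
        d = 0.1 / np.sqrt(2.0)
        ds = _dataset([0.0, 1.0], [[2.0 + d, 2.0 - d], [2.0 + d, 2.0 - d]])
        traj = self._flat_traj(1.0)
        r = weighted_log_residuals(ds, traj)
        np.testing.assert_allclose(r, np.log(2.0) / 0.1, rtol=1e-6)
        assert r[0] == pytest.approx(6.9315, rel=1e-3)

    def test_halving_sd_doubles_residuals_and_quadruples_rss(self):
        traj = self._flat_traj(0.015)
        d = 0.02 / np.sqrt(2.0)
        ds1 = _dataset([0.0, 1.0], [[0.02 + d, 0.02 - d]] * 2)
        ds2 = _dataset([0.0, 1.0], [[0.02 + d / 2, 0.02 - d / 2]] * 2)
        r1 = weighted_log_residuals(ds1, traj, sd_floor=1e-12)
        r2 = weighted_log_residuals(ds2, traj, sd_floor=1e-12)
        np.testing.assert_allclose(r2, 2 * r1, rtol=1e-9)
        assert r2 @ r2 == pytest.approx(4 * (r1 @ r1), rel=1e-9)

    def test_trajectory_must_span_observations(self):
        traj = self._flat_traj(0.01, t_end=0.5)
        ds = _dataset([0.0, 1.0], [[0.02, 0.02], [0.02, 0.02]])
        with pytest.raises(DataError):
            weighted_log_residuals(ds, traj)


class TestStage1:
    def test_noiseless_recovery_within_1pct(self, noiseless_fit):
        est = noiseless_fit.stage1.estimates
        assert est["mu_g_max"] == pytest.approx(TRUE["mu_g_max"], rel=0.01)
        assert est["K_S_g"] == pytest.approx(TRUE["K_S_g"], rel=0.01)

    def test_rejects_mixed_dataset(self, noiseless_suite):
        with pytest.raises(UsageError):
            fit_stage1(noiseless_suite["19WT-81TS"])

    def test_deterministic(self, noiseless_suite):
        a = fit_stage1(noiseless_suite["100WT"])
        b = fit_stage1(noiseless_suite["100WT"])
        assert a.estimates == b.estimates

    def test_flat_series_pins_growth_rate_low(self):
        reps = np.full((6, 3), 0.01)
        ds = _dataset(np.arange(6.0), reps)
        with pytest.raises(DataError):
            # no OD increase: initial glucose cannot be inferred
            fit_stage1(ds)
        res = fit_stage1(ds, FitConfig(c_g0=0.45))
        assert res.estimates["mu_g_max"] <= 2e-3


class TestStage2:
    def test_noiseless_recovery(self, noiseless_fit):
        est = noiseless_fit.stage2.estimates
        assert est["k"] == TRUE["k"]
        assert est["delta"] == pytest.approx(TRUE["delta"], rel=0.05)

    def test_rejects_wt_containing_dataset(self, noiseless_suite, noiseless_fit):
        with pytest.raises(UsageError):
            fit_stage2(noiseless_suite["100WT"], noiseless_fit.stage1)

    def test_requires_enough_early_points(self, noiseless_suite, noiseless_fit):
        ds = noiseless_suite["100TS"]
        short = _dataset(ds.times[:3], ds.replicates[:3], label="100TS", wt=0.0, ts=1.0)
        with pytest.raises(DataError):
            fit_stage2(short, noiseless_fit.stage1)

    def test_pure_growth_pins_delta_at_lower_bound(self, noiseless_fit):
        design = MixDesign("100TS", 0.0, 1.0, 0.01)
        ds = generate_batch_dataset(
            DEFAULT_PARAMS.with_(delta=1e-3), design, BatchNoiseModel(od_cv=0.0), seed=0
        )
        cfg = FitConfig(k_grid=(1, 2, 3))
        res = fit_stage2(ds, noiseless_fit.stage1, cfg=cfg)
        assert res.estimates["delta"] <= 1.5e-3

    def test_returned_k_minimizes_grid_rss(self, noiseless_suite, noiseless_fit):
        """The reported k must beat every other grid value's best delta."""
        cfg = FitConfig(k_grid=tuple(range(1, 11)))
        res = fit_stage2(noiseless_suite["100TS"], noiseless_fit.stage1, cfg=cfg)
        best_rss = {}
        for k in cfg.k_grid:
            single = FitConfig(k_grid=(k,))
            best_rss[k] = fit_stage2(
                noiseless_suite["100TS"], noiseless_fit.stage1, cfg=single
            ).rss
        assert res.estimates["k"] == min(best_rss, key=best_rss.get)


class TestStage3:
    def test_noiseless_recovery_within_10pct(self, noiseless_fit):
        est = noiseless_fit.stage3.estimates
        assert est["mu_l_max"] == pytest.approx(TRUE["mu_l_max"], rel=0.10)
        assert est["K_S_l"] == pytest.approx(TRUE["K_S_l"], rel=0.10)
        assert est["epsilon"] == pytest.approx(TRUE["epsilon"], rel=0.10)

    def test_rejects_monoculture(self, noiseless_suite, noiseless_fit):
        with pytest.raises(UsageError, match="100TS"):
            fit_stage3(
                [noiseless_suite["100TS"]],
                noiseless_fit.stage1,
                noiseless_fit.stage2,
            )

    def test_pooled_residual_count(self, noiseless_suite, noiseless_fit):
        n_expected = sum(
            noiseless_suite[m].times.size for m in ("73WT-27TS", "19WT-81TS")
        )
        assert noiseless_fit.stage3.n_obs == n_expected

    def test_no_recycling_data_pins_epsilon_low(self, noiseless_fit):
        p0 = DEFAULT_PARAMS.with_(epsilon=0.0)
        mixes = [
            generate_batch_dataset(
                p0, MixDesign(lbl, wt, ts, 0.01), BatchNoiseModel(od_cv=0.0), seed=0
            )
            for lbl, wt, ts in [("73WT-27TS", 0.73, 0.27), ("19WT-81TS", 0.19, 0.81)]
        ]
        res = fit_stage3(mixes, noiseless_fit.stage1, noiseless_fit.stage2)
        assert res.estimates["epsilon"] < 0.02

    def test_frozen_parameters_passed_through(self, noiseless_fit):
        assert noiseless_fit.stage3.fixed["mu_g_max"] == (
            noiseless_fit.stage1.estimates["mu_g_max"]
        )
        assert noiseless_fit.stage3.fixed["delta"] == (
            noiseless_fit.stage2.estimates["delta"]
        )


class TestRunThreeStageFit:
    def test_end_to_end_recovery(self, noiseless_fit):
        params = noiseless_fit.model_params()
        assert params.mu_g_max == pytest.approx(TRUE["mu_g_max"], rel=0.01)
        assert params.K_S_g == pytest.approx(TRUE["K_S_g"], rel=0.01)
        assert params.delta == pytest.approx(TRUE["delta"], rel=0.05)
        assert params.k == TRUE["k"]
        assert params.mu_l_max == pytest.approx(TRUE["mu_l_max"], rel=0.10)
        assert params.K_S_l == pytest.approx(TRUE["K_S_l"], rel=0.10)
        assert params.epsilon == pytest.approx(TRUE["epsilon"], rel=0.10)

    def test_missing_mix_names_what_is_absent(self, noiseless_suite):
        partial = {k: v for k, v in noiseless_suite.items() if k != "100TS"}
        with pytest.raises(DataError, match="stage 2"):
            run_three_stage_fit(partial)

    def test_rerun_is_byte_identical(self, noiseless_suite):
        t1 = run_three_stage_fit(noiseless_suite).table()
        t2 = run_three_stage_fit(noiseless_suite).table()
        assert t1.to_csv() == t2.to_csv()

    def test_estimates_respect_bounds(self, noisy_suite):
        fit = run_three_stage_fit(noisy_suite)
        for res in fit:
            for name, value in res.estimates.items():
                lo, hi = res.bounds[name]
                assert lo - 1e-12 <= value <= hi + 1e-12


class TestBootstrap:
    def test_rejects_nonpositive_n_boot(self, noiseless_suite):
        with pytest.raises(ConfigError):
            bootstrap_cis(noiseless_suite, n_boot=0)

    def test_identical_replicates_give_zero_width_cis(self, noiseless_suite):
        boot = bootstrap_cis(noiseless_suite, n_boot=3, seed=0, fix_k=True)
        for name, (lo, hi) in boot.ci95.items():
            assert lo == pytest.approx(hi, rel=1e-6)

    def test_seeded_determinism_and_ci_nesting(self, noisy_suite):
        cfg = FitConfig()
        b1 = bootstrap_cis(noisy_suite, cfg, n_boot=8, seed=11, fix_k=True)
        b2 = bootstrap_cis(noisy_suite, cfg, n_boot=8, seed=11, fix_k=True)
        assert b1.ci95 == b2.ci95
        ci90 = b1.ci(90.0)
        for name in b1.ci95:
            assert b1.ci95[name][0] <= ci90[name][0]
            assert ci90[name][1] <= b1.ci95[name][1]

    def test_cis_attach_to_stage_results(self, noisy_suite):
        boot = bootstrap_cis(noisy_suite, n_boot=5, seed=2, fix_k=True)
        fit = boot.fits_with_ci()
        assert set(fit.stage1.ci95) == {"mu_g_max", "K_S_g"}
        assert set(fit.stage3.ci95) == {"mu_l_max", "K_S_l", "epsilon"}


class TestFitDiagnostics:
    def _result(self, residuals, p):
        r = np.asarray(residuals, float)
        return FitResult(
            stage=1, estimates={}, bounds={}, rss=float(r @ r),
            n_obs=r.size, n_params=p, residuals=r,
        )

    def test_perfect_fit_formula(self):
        rss, aic, bic = fit_diagnostics(self._result(np.zeros(10), 2))
        assert rss == 0.0
        assert aic == pytest.approx(4.0)
        assert bic == pytest.approx(2 * np.log(10), rel=1e-9)

    def test_extra_parameter_costs_two_aic_points(self):
        r = [0.5, -0.2, 0.1]
        _, aic_p2, _ = fit_diagnostics(self._result(r, 2))
        _, aic_p3, _ = fit_diagnostics(self._result(r, 3))
        assert aic_p3 - aic_p2 == pytest.approx(2.0)

    @pytest.mark.parametrize("n, heavier", [(7, False), (8, True), (100, True)])
    def test_bic_penalty_exceeds_aic_beyond_e_squared(self, n, heavier):
        r = np.full(n, 0.3)
        _, aic, bic = fit_diagnostics(self._result(r, 2))
        assert (bic > aic) == heavier


class TestNormalizedDeltaBiomass:
    def test_identical_series_give_zero(self):
        ref = np.array([0.01, 0.02, 0.04])
        np.testing.assert_allclose(normalized_delta_biomass(ref, ref), 0.0)

    def test_doubled_series_gives_plus_one(self):
        ref = np.array([0.01, 0.02, 0.04])
        np.testing.assert_allclose(normalized_delta_biomass(2 * ref, ref), 1.0)

    def test_inoculum_arithmetic_for_19wt_mix(self):
        assert normalized_delta_biomass(
            np.array([0.19 * 0.01]), np.array([0.01])
        )[0] == pytest.approx(-0.81)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalized_delta_biomass(np.array([1.0]), np.array([0.0]))
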