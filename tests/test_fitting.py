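"""Parameter inference: oracle agreement, noiseless recovery, guards."""

import dataclasses

import numpy as np
import pytest

import softjam as sj
from softjam import (
    fit_clog_dynamics,
    fit_concentration_sweep,
    fit_low_pressure,
    fit_pressure_sweep,
    fit_suction,
    generate_clog_trace,
    generate_dna_curves,
    generate_frequency_curves,
    get_preset,
)
from softjam.curves import FrequencyCurve
from softjam.errors import (
    InsufficientDataError,
    InvalidParameterError,
    UnidentifiableError,
)


def _noiseless_exit(seed=0, **overrides):
    s = get_preset(
        "hiv_exit_200nm", seed=seed, noise="gaussian_relative", sigma=1e-13,
        replicates=1, **overrides,
    )
    return s, generate_frequency_curves(s)


class TestLowPressureFit:
    def test_noiseless_recovery_is_exact(self):
        s = get_preset(
            "amino_beads_200nm", seed=0, noise="gaussian_relative", sigma=1e-13,
            replicates=1,
        )
        curve = sj.generate_bead_curves(s, "amino")
        res = fit_low_pressure(curve, s.geometry, s.fluid, seed=0)
        assert res.estimates["Pc"] == pytest.approx(50.0, rel=1e-4)
        assert res.derived["kon_pore"] == pytest.approx(0.625, rel=1e-4)

    def test_grid_search_oracle_agreement(self):
        """A dense log-grid scan of the weighted chi-square must agree with
        the optimizer to within one grid cell."""
        s = get_preset(
            "amino_beads_200nm", seed=4, noise="gaussian_relative", sigma=0.05,
            replicates=1,
        )
        curve = sj.generate_bead_curves(s, "amino")
        from softjam.fitting import low_pressure_window

        sub = curve.subset(low_pressure_window(curve))
        P, C, f, sem = sub.pressures, sub.concentrations, sub.frequencies, sub.sems
        C_ref = float(np.max(C))
        # brute-force oracle: chi2 over a 200x200 (Pc, kappa) log grid
        Pc_grid = np.geomspace(5.0, 500.0, 200)
        kappa_grid = np.geomspace(1e-21, 1e-17, 200)
        chi2 = np.empty((200, 200))
        for i, Pc in enumerate(Pc_grid):
            model_unit = C * (P / Pc) * np.exp(-Pc / P)
            for j, kappa in enumerate(kappa_grid):
                chi2[i, j] = np.sum(((kappa * model_unit - f) / sem) ** 2)
        i, j = np.unravel_index(np.argmin(chi2), chi2.shape)
        res = fit_low_pressure(curve, s.geometry, s.fluid, seed=4)
        cell = Pc_grid[1] / Pc_grid[0]
        assert Pc_grid[i] / cell <= res.estimates["Pc"] <= Pc_grid[i] * cell
        kcell = kappa_grid[1] / kappa_grid[0]
        kappa_hat = res.estimates["k"] / C_ref
        assert kappa_grid[j] / kcell <= kappa_hat <= kappa_grid[j] * kcell

    def test_noisy_recovery_within_reported_band(self):
        """Mean recovered critical pressure over seeded replicates stays in
        the 50 +/- 10 Pa band (subsampled here; the acceptance run uses 100)."""
        pcs = []
        for seed in range(1, 13):
            s = get_preset(
                "hiv_exit_200nm", seed=seed, noise="gaussian_relative",
                sigma=0.05, replicates=1,
            )
            curve = generate_frequency_curves(s)
            res = fit_low_pressure(curve, s.geometry, s.fluid, seed=seed)
            pcs.append(res.estimates["Pc"])
        assert abs(np.mean(pcs) - 50.0) < 10.0

    def test_too_few_points_rejected(self, geom_200nm, water):
        curve = FrequencyCurve.from_arrays(
            np.array([10.0, 20.0, 4000.0, 5000.0, 6000.0]),
            np.full(5, 1e14),
            np.array([1e-8, 2e-8, 1e-4, 1.0e-4, 1.0e-4]),
            np.full(5, 1e-9),
            1,
        )
        with pytest.raises(InsufficientDataError):
            fit_low_pressure(curve, geom_200nm, water)


class TestPressureSweepFit:
    def test_noiseless_recovery_exact_to_optimizer_tolerance(self):
        s, curve = _noiseless_exit()
        res = fit_pressure_sweep(curve, s.geometry, s.fluid, seed=0)
        assert res.estimates["kon_pore"] == pytest.approx(s.params.kon_pore, rel=1e-6)
        assert res.estimates["koff_clog"] == pytest.approx(s.params.koff_clog, rel=1e-6)
        assert res.estimates["Kd_clog"] == pytest.approx(s.params.Kd_clog, rel=1e-6)

    def test_plateau_of_highest_curve_tracks_off_rate(self):
        s, curve = _noiseless_exit()
        res = fit_pressure_sweep(curve, s.geometry, s.fluid, seed=0)
        fitted = sj.JammingParams(**res.estimates)
        f_sat = sj.frequency(
            fitted, sj.OperatingPoint(1e7, 100 * s.params.Kd_clog), s.geometry, s.fluid
        )
        assert f_sat == pytest.approx(res.estimates["koff_clog"], rel=0.1)

    def test_stochastic_kd_recovery_median_error(self):
        """Kd is the softest direction; median relative error < 30% at 5%
        noise when the concentration grid straddles Kd (the entry-time
        saturation must be probed on both sides for Kd to be identifiable)."""
        from softjam.units import per_ml_to_per_m3

        errs = []
        for seed in range(1, 13):
            s = get_preset(
                "hiv_exit_200nm", seed=seed, noise="gaussian_relative",
                sigma=0.05, replicates=1,
            )
            s = dataclasses.replace(
                s,
                concentrations=tuple(per_ml_to_per_m3(c) for c in (1e7, 1e8, 1e9)),
            )
            curve = generate_frequency_curves(s)
            res = fit_pressure_sweep(curve, s.geometry, s.fluid, seed=seed)
            errs.append(abs(res.estimates["Kd_clog"] / s.params.Kd_clog - 1.0))
        assert np.median(errs) < 0.30

    def test_single_concentration_rejected(self):
        s, curve = _noiseless_exit()
        single = curve.subset(curve.concentrations == curve.concentrations.max())
        with pytest.raises(InsufficientDataError):
            fit_pressure_sweep(single, s.geometry, s.fluid)

    def test_fit_invariant_under_input_unit_rescaling(self):
        """Converting the table through /mL and back (the CSV round trip)
        must not change the estimates."""
        s, curve = _noiseless_exit(seed=2)
        res_si = fit_pressure_sweep(curve, s.geometry, s.fluid, seed=2)
        rescaled = FrequencyCurve.from_arrays(
            curve.pressures,
            (curve.concentrations / 1e6) * 1e6,  # /m^3 -> /mL -> /m^3
            curve.frequencies,
            curve.sems,
            1,
        )
        res_back = fit_pressure_sweep(rescaled, s.geometry, s.fluid, seed=2)
        for key in res_si.estimates:
            assert res_si.estimates[key] == pytest.approx(
                res_back.estimates[key], rel=1e-9
            )

    def test_entry_transit_separability(self):
        """Freezing the entry-time parameters at truth leaves the transit
        parameter unchanged, and vice versa — the two durations are
        independently identifiable."""
        s, curve = _noiseless_exit(seed=3)
        free = fit_pressure_sweep(curve, s.geometry, s.fluid, seed=3)
        tau1_frozen = fit_pressure_sweep(
            curve, s.geometry, s.fluid, seed=3,
            fixed={"koff_clog": s.params.koff_clog, "Kd_clog": s.params.Kd_clog},
        )
        assert tau1_frozen.estimates["kon_pore"] == pytest.approx(
            free.estimates["kon_pore"], rel=1e-5
        )
        tau2_frozen = fit_pressure_sweep(
            curve, s.geometry, s.fluid, seed=3, fixed={"kon_pore": s.params.kon_pore}
        )
        assert tau2_frozen.estimates["koff_clog"] == pytest.approx(
            free.estimates["koff_clog"], rel=1e-5
        )
        assert tau2_frozen.estimates["Kd_clog"] == pytest.approx(
            free.estimates["Kd_clog"], rel=1e-5
        )


class TestConcentrationSweepFit:
    def _sweep(self, seed, sigma=1e-13, cmin=1e12, cmax=1e16, n=9):
        s = get_preset(
            "hiv_exit_200nm", seed=seed, noise="gaussian_relative", sigma=sigma,
            replicates=1,
        )
        s = dataclasses.replace(
            s, pressures=(800.0,), concentrations=tuple(np.geomspace(cmin, cmax, n))
        )
        return s, generate_frequency_curves(s)

    def test_noiseless_recovery_exact(self):
        s, curve = self._sweep(seed=0)
        res = fit_concentration_sweep(
            curve, s.geometry, s.fluid, kon_fixed=s.params.kon_pore, seed=0
        )
        assert res.estimates["koff_clog"] == pytest.approx(s.params.koff_clog, rel=1e-6)
        assert res.estimates["Kd_clog"] == pytest.approx(s.params.Kd_clog, rel=1e-6)

    def test_noisy_recovery_stays_in_reported_decade(self):
        s, curve = self._sweep(seed=6, sigma=0.05)
        res = fit_concentration_sweep(
            curve, s.geometry, s.fluid, kon_fixed=s.params.kon_pore, seed=6
        )
        assert 0.8e-4 <= res.estimates["koff_clog"] <= 1.7e-4

    def test_all_concentrations_below_kd_unidentifiable(self):
        # grid entirely below Kd/10 ~ 9e12 m^-3
        s, curve = self._sweep(seed=1, cmin=1e9, cmax=5e11, n=6)
        with pytest.raises(UnidentifiableError):
            fit_concentration_sweep(
                curve, s.geometry, s.fluid, kon_fixed=s.params.kon_pore, seed=1
            )


class TestClogDynamicsFit:
    def test_noiseless_exponential_recovered_exactly(self):
        t = np.linspace(0.0, 300.0, 10)
        trace = generate_clog_trace(38.0, 1.0, 0.0, t, sigma=0.0, seed=0)
        res = fit_clog_dynamics(trace)
        assert res.estimates["t_clog"] == pytest.approx(38.0, rel=1e-8)

    def test_log_linear_oracle_agreement_at_low_noise(self):
        """An independent linearised estimator (regression of log-contrast
        on time) agrees with the nonlinear fit within 2% at low noise."""
        t = np.linspace(0.0, 150.0, 30)
        trace = generate_clog_trace(38.0, 1.0, 0.0, t, sigma=0.005, seed=21)
        res = fit_clog_dynamics(trace, seed=21)
        keep = trace.contrast > 0.05
        slope = np.polyfit(trace.times[keep], np.log(trace.contrast[keep]), 1)[0]
        t_oracle = -1.0 / slope
        assert res.estimates["t_clog"] == pytest.approx(t_oracle, rel=0.02)

    def test_mean_noisy_recovery_within_5s(self):
        """Subsampled replicate study; the acceptance run uses 100 traces."""
        t = np.linspace(0.0, 300.0, 30)
        recovered = [
            fit_clog_dynamics(
                generate_clog_trace(38.0, 1.0, 0.0, t, sigma=0.05, seed=seed),
                seed=seed,
            ).estimates["t_clog"]
            for seed in range(1, 16)
        ]
        assert abs(np.mean(recovered) - 38.0) < 5.0

    def test_non_decreasing_trace_rejected(self):
        t = np.linspace(0.0, 100.0, 8)
        trace = sj.ClogTrace(times=t, contrast=np.linspace(0.1, 0.9, 8),
                             f0=1.0, f_inf=0.0)
        with pytest.raises(InvalidParameterError):
            fit_clog_dynamics(trace)

    def test_out_of_band_contrast_rejected(self):
        t = np.linspace(0.0, 100.0, 8)
        trace = sj.ClogTrace(times=t, contrast=np.array([1.5, .9, .7, .5, .4, .3, .2, .1]),
                             f0=1.0, f_inf=0.0)
        with pytest.raises(InvalidParameterError):
            fit_clog_dynamics(trace)


class TestSuctionFit:
    def test_noiseless_recovery_exact(self):
        P = np.geomspace(100.0, 3e4, 12)
        naked, _ = generate_dna_curves(1037.0, 16.0, 10.0, P, sigma=1e-13, seed=0)
        res = fit_suction(naked, seed=0)
        assert res.estimates["P_suc"] == pytest.approx(1037.0, rel=1e-6)
        assert res.estimates["f_suc"] == pytest.approx(10.0, rel=1e-6)

    def test_end_to_end_half_radius_layer(self, geom_200nm, water):
        """Generating a naked/clogged pair at resistance ratio 16 and fitting
        both recovers a layer of half the pore radius."""
        P = np.geomspace(100.0, 3e5, 14)
        naked, clogged = generate_dna_curves(
            sj.p_suc_from_geometry(geom_200nm, water), 16.0, 10.0, P,
            sigma=0.05, seed=10,
        )
        rn = fit_suction(naked, seed=10)
        rc = fit_suction(clogged, seed=10)
        structure = sj.clog_thickness(
            rn.estimates["P_suc"], rc.estimates["P_suc"], geom_200nm
        )
        assert structure.relative_thickness == pytest.approx(0.5, rel=0.02)

    def test_psuc_recovery_unbiased_at_5pct_noise(self):
        """Median P_suc error < 2% (subsampled; acceptance-scale study uses
        more replicates)."""
        P = np.geomspace(100.0, 3e4, 12)
        errs = []
        for seed in range(1, 21):
            naked, _ = generate_dna_curves(1037.0, 16.0, 10.0, P, sigma=0.05, seed=seed)
            res = fit_suction(naked, seed=seed)
            errs.append(abs(res.estimates["P_suc"] / 1037.0 - 1.0))
        assert np.median(errs) < 0.02

    def test_grid_search_oracle_agreement(self):
        P = np.geomspace(100.0, 3e4, 12)
        naked, _ = generate_dna_curves(1037.0, 16.0, 10.0, P, sigma=0.05, seed=17)
        f, sem = naked.frequencies, naked.sems
        fs_grid = np.geomspace(1.0, 100.0, 200)
        ps_grid = np.geomspace(100.0, 1e4, 200)
        chi2 = np.empty((200, 200))
        for i, fs in enumerate(fs_grid):
            for j, ps in enumerate(ps_grid):
                model = fs * (P / ps) * np.exp(-ps / P)
                chi2[i, j] = np.sum(((model - f) / sem) ** 2)
        i, j = np.unravel_index(np.argmin(chi2), chi2.shape)
        res = fit_suction(naked, seed=17)
        fcell, pcell = fs_grid[1] / fs_grid[0], ps_grid[1] / ps_grid[0]
        assert fs_grid[i] / fcell <= res.estimates["f_suc"] <= fs_grid[i] * fcell
        assert ps_grid[j] / pcell <= res.estimates["P_suc"] <= ps_grid[j] * pcell


class TestCollapseMetric:
    def test_noise_free_multi_condition_collapse(self, water):
        """Several particle types and pore sizes all land on y = x.

        Grids stay in the observable window (pressures from P_c upward,
        concentrations within two decades of Kd), as in the source
        experiments; far below P_c the model frequency is exponentially
        suppressed and no instrument would record those points.
        """
        conditions = [
            (sj.PoreGeometry(40e-9, 6e-6), sj.JammingParams(0.4, 1.5e-4, 5e13)),
            (sj.PoreGeometry(100e-9, 10e-6), sj.JammingParams(0.625, 1.2e-4, 9e13)),
            (sj.PoreGeometry(200e-9, 10e-6), sj.JammingParams(0.8, 0.9e-4, 2e14)),
        ]
        pts = []
        for geom, params in conditions:
            Pc = sj.critical_pressure(params, geom, water)
            P = np.geomspace(Pc, 40 * Pc, 8)
            C = np.geomspace(params.Kd_clog / 30, 30 * params.Kd_clog, 8)
            Pg, Cg = np.meshgrid(P, C)
            f = sj.frequency_grid(params, Pg.ravel(), Cg.ravel(), geom, water)
            pts += sj.master_transform(
                Pg.ravel(), Cg.ravel(), f, params, geom, water
            )
        assert sj.collapse_metric(pts) <= 1e-12

    def test_metric_decreases_monotonically_with_noise(self, water):
        geom = sj.PoreGeometry(100e-9, 10e-6)
        params = sj.JammingParams(0.625, 1.2e-4, 9e13)
        P = np.geomspace(30, 3000, 10)
        C = np.geomspace(1e12, 1e15, 10)
        Pg, Cg = np.meshgrid(P, C)
        f = sj.frequency_grid(params, Pg.ravel(), Cg.ravel(), geom, water)
        rng = np.random.default_rng(5)
        eps = rng.standard_normal(f.shape)
        metrics = []
        for sigma in (0.10, 0.02, 0.0):
            noisy = f * (1 + sigma * eps)
            pts = sj.master_transform(Pg.ravel(), Cg.ravel(), noisy, params, geom, water)
            metrics.append(sj.collapse_metric(pts))
        assert metrics[0] > metrics[1] > metrics[2]
        assert metrics[2] <= 1e-12

    def test_single_point_on_line_scores_zero(self, water):
        geom = sj.PoreGeometry(100e-9, 10e-6)
        params = sj.JammingParams(0.625, 1.2e-4, 9e13)
        f = sj.frequency(params, sj.OperatingPoint(800.0, 1e14), geom, water)
        pts = sj.master_transform([800.0], [1e14], [f], params, geom, water)
        assert sj.collapse_metric(pts) <= 1e-14
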