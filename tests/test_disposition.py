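"""Three-compartment disposition: simulation, half-life, fitting, NCA."""

import numpy as np
import pytest

from baripbpk import (
    DispositionParams,
    NoiseSpec,
    PlasmaProfile,
    fit_disposition,
    generate_noisy_profiles,
    pk_metrics,
    simulate_disposition,
    terminal_half_life,
)
from baripbpk.disposition import MG_PER_L_TO_NG_PER_ML, _bolus_concentration


class TestSimulateDisposition:
    def test_zero_input_gives_zero_profile(self, disposition):
        prof = simulate_disposition(disposition, None, 12.0)
        assert np.all(prof.concentrations == 0.0)

    def test_iv_bolus_initial_concentration(self, disposition):
        # C(0+) = D/(Vc·BW)
        prof = simulate_disposition(disposition, None, 12.0, iv_bolus_mg=10.0)
        expected = 10.0 / (disposition.vc * disposition.body_weight)
        assert prof.concentrations[0] == pytest.approx(
            expected * MG_PER_L_TO_NG_PER_ML, rel=1e-6
        )

    def test_terminal_slope_matches_eigenvalue(self, disposition):
        t = np.linspace(0.0, 48.0, 2000)
        c = _bolus_concentration(disposition, 10.0, t)
        tail = t > 30.0
        slope, _ = np.polyfit(t[tail], np.log(c[tail]), 1)
        lam = np.log(2) / terminal_half_life(disposition)
        assert -slope == pytest.approx(lam, rel=0.01)

    def test_superposition_linearity(self, disposition):
        flux = lambda t: 5.0 * np.exp(-t)
        p1 = simulate_disposition(disposition, flux, 12.0)
        p2 = simulate_disposition(disposition, lambda t: 2 * flux(t), 12.0)
        mask = p1.concentrations > 1e-6
        ratio = p2.concentrations[mask] / p1.concentrations[mask]
        assert np.allclose(ratio, 2.0, rtol=1e-9)

    def test_auc_equals_total_input_over_clearance(self, disposition):
        # all administered drug is eventually cleared: AUC = A/(CL·BW)
        total = 10.0
        flux = lambda t: total * 2.0 * np.exp(-2.0 * t)
        t_eval = np.linspace(0.0, 96.0, 4000)
        prof = simulate_disposition(disposition, flux, 96.0, t_eval=t_eval)
        met = pk_metrics(prof)
        expected = total / (disposition.clearance * disposition.body_weight)
        assert met.auc_0_inf == pytest.approx(
            expected * MG_PER_L_TO_NG_PER_ML, rel=0.02
        )


class TestTerminalHalfLife:
    def test_vardenafil_micro_constants(self, disposition):
        assert terminal_half_life(disposition) == pytest.approx(4.43, abs=0.05)

    def test_one_compartment_closed_form(self):
        p = DispositionParams(clearance=0.925, vc=0.8)
        assert terminal_half_life(p) == pytest.approx(
            np.log(2) * 0.8 / 0.925, rel=1e-12
        )

    def test_matches_characteristic_cubic_root(self, disposition):
        # same eigenvalues as the characteristic polynomial of the rate matrix
        roots = np.roots([1.0, 7.04425, 4.9554875, 0.60703125])
        lam_min = np.min(np.abs(roots))
        assert np.log(2) / terminal_half_life(disposition) == pytest.approx(
            lam_min, rel=1e-9
        )
        assert lam_min == pytest.approx(0.1566, abs=2e-4)


class TestFitDisposition:
    TIMES = np.concatenate(
        [np.linspace(0.05, 1.0, 8), np.linspace(1.5, 12.0, 10),
         np.linspace(14.0, 36.0, 8)]
    )

    def test_recovers_noise_free_parameters(self, disposition):
        prof = generate_noisy_profiles(
            disposition, 10.0, "iv", self.TIMES, NoiseSpec(cv=0.0, lloq=0.0)
        )
        fit = fit_disposition(prof, 10.0, n_compartments=3)
        assert fit.clearance == pytest.approx(disposition.clearance, rel=0.01)
        assert fit.vc == pytest.approx(disposition.vc, rel=0.01)

    def test_median_recovery_under_10pct_noise(self, disposition):
        cls = []
        for seed in range(20):
            prof = generate_noisy_profiles(
                disposition, 10.0, "iv", self.TIMES,
                NoiseSpec(cv=10.0, lloq=0.0, seed=seed),
            )
            fit = fit_disposition(prof, 10.0, n_compartments=3)
            cls.append(fit.clearance)
        assert np.median(cls) == pytest.approx(disposition.clearance, rel=0.10)

    def test_too_few_points_rejected(self, disposition):
        prof = generate_noisy_profiles(
            disposition, 10.0, "iv", np.linspace(0.5, 6.0, 5),
            NoiseSpec(cv=0.0, lloq=0.0),
        )
        with pytest.raises(ValueError):
            fit_disposition(prof, 10.0, n_compartments=3)


class TestPkMetrics:
    def test_single_exponential_closed_form(self):
        t = np.linspace(0.0, 30.0, 3001)
        prof = PlasmaProfile(t, 100.0 * np.exp(-0.5 * t))
        met = pk_metrics(prof)
        assert met.auc_0_inf == pytest.approx(200.0, rel=0.005)
        assert met.lambda_z == pytest.approx(0.5, rel=0.01)

    def test_monotone_decreasing_peaks_at_first_point(self):
        t = np.linspace(0.1, 10.0, 100)
        prof = PlasmaProfile(t, 50.0 * np.exp(-0.3 * t))
        assert pk_metrics(prof).t_max == pytest.approx(0.1)

    def test_lambda_z_not_estimable_flags_auc_missing(self):
        prof = PlasmaProfile([0.0, 1.0, 2.0], [1.0, 5.0, 10.0])
        met = pk_metrics(prof)
        assert np.isnan(met.lambda_z) and np.isnan(met.auc_0_inf)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            PlasmaProfile([0.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            PlasmaProfile([0.0, 1.0], [1.0, -2.0])
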