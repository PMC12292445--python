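"""Speciation, pH-solubility model fitting, bile solubilization, diffusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baripbpk.physicochem import (
    IonizableGroup,
    SolubilityMeasurement,
    bile_salt_enhancement,
    diffusion_coefficient_from_mw,
    fit_solubility_model,
    fraction_ionized,
    solubility_at_ph,
)

VARDENAFIL_GROUPS = [
    IonizableGroup(4.24, "base"),
    IonizableGroup(7.76, "base"),
    IonizableGroup(8.68, "acid"),
]
VARDENAFIL_POINTS = [
    SolubilityMeasurement(1.0, 30.0),
    SolubilityMeasurement(3.0, 30.0),
    SolubilityMeasurement(5.0, 27.4),
    SolubilityMeasurement(7.0, 0.05),
]


class TestFractionIonized:
    def test_half_ionized_at_pka(self):
        frac = fraction_ionized(4.24, [IonizableGroup(4.24, "base")])
        assert frac["neutral"] == pytest.approx(0.5, abs=1e-12)
        assert frac["cation_1"] == pytest.approx(0.5, abs=1e-12)

    def test_base_fully_protonated_in_acid(self):
        # 10^(4.24-1)/(1+10^(4.24-1)) = 0.99942...
        frac = fraction_ionized(1.0, [IonizableGroup(4.24, "base")])
        assert frac["cation_1"] > 0.999

    def test_no_groups_all_neutral(self):
        assert fraction_ionized(7.0, []) == {"neutral": 1.0}

    @given(ph=st.floats(0.0, 14.0))
    @settings(max_examples=50, deadline=None)
    def test_fractions_sum_to_one(self, ph):
        frac = fraction_ionized(ph, VARDENAFIL_GROUPS)
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in frac.values())

    def test_ph_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fraction_ionized(-1.0, [])


@pytest.fixture(scope="module")
def model():
    return fit_solubility_model(VARDENAFIL_POINTS, VARDENAFIL_GROUPS)


class TestSolubilityModel:

    def test_reproduces_measured_points(self, model):
        for m in VARDENAFIL_POINTS:
            assert solubility_at_ph(model, m.pH) == pytest.approx(
                m.solubility, rel=0.25
            )

    def test_gastric_and_neutral_ph_values(self, model):
        assert solubility_at_ph(model, 1.0) == pytest.approx(30.0, rel=0.10)
        assert solubility_at_ph(model, 7.0) == pytest.approx(0.05, rel=0.20)

    def test_over_600_fold_decrease(self, model):
        assert solubility_at_ph(model, 1.0) / solubility_at_ph(model, 7.0) >= 600.0

    def test_nonincreasing_over_acid_to_neutral_range(self, model):
        ph = np.linspace(1.0, 7.0, 121)
        s = model(ph)
        assert np.all(np.diff(s) <= 1e-9 * s[:-1])

    def test_bounded_by_intrinsic_and_caps(self, model):
        ph = np.linspace(0.0, 14.0, 141)
        s = model(ph)
        s0 = model.intrinsic_solubility
        upper = s0 * (1.0 + sum(f - 1.0 for f in model.solubility_factors))
        assert np.all(s >= s0 * (1.0 - 1e-9))
        assert np.all(s <= upper * (1.0 + 1e-6))

    def test_high_ph_plateau_without_acid_group(self):
        # single basic centre: neutral species dominates at high pH
        pts = [SolubilityMeasurement(p, 0.01 * (1 + 10 ** (6.0 - p)))
               for p in [2.0, 4.0, 6.0, 8.0]]
        model = fit_solubility_model(pts, [IonizableGroup(6.0, "base")])
        assert solubility_at_ph(model, 12.0) == pytest.approx(
            model.intrinsic_solubility, rel=0.2
        )

    def test_unfitted_input_rejected(self):
        with pytest.raises(TypeError):
            solubility_at_ph(None, 7.0)

    def test_flat_profile_no_groups_gives_mean(self):
        pts = [SolubilityMeasurement(2.0, 1.0), SolubilityMeasurement(6.0, 1.0)]
        model = fit_solubility_model(pts, [])
        assert model.intrinsic_solubility == pytest.approx(1.0, rel=1e-6)

    def test_degenerate_ph_span_rejected(self):
        pts = [SolubilityMeasurement(3.0, 1.0), SolubilityMeasurement(3.5, 2.0)]
        with pytest.raises(ValueError):
            fit_solubility_model(pts, VARDENAFIL_GROUPS)

    def test_roundtrip_recovers_monoprotic_base(self):
        # forward-generate from a known capped-HH model, then refit
        s0_true, factor_true = 0.01, 1000.0
        groups = [IonizableGroup(5.0, "base")]

        def forward(ph):
            return s0_true * (1 + min(10 ** (5.0 - ph), factor_true - 1))

        pts = [SolubilityMeasurement(p, forward(p)) for p in np.arange(1.0, 7.5, 0.5)]
        model = fit_solubility_model(pts, groups)
        assert model.intrinsic_solubility == pytest.approx(s0_true, rel=0.10)
        assert model.solubility_factors[0] == pytest.approx(factor_true, rel=0.10)


class TestBileSaltEnhancement:
    def test_zero_bile_leaves_solubility_unchanged(self):
        assert bile_salt_enhancement(1.97, 0.0, 0.05) == 0.05

    def test_fasted_intestinal_bile_enhances(self):
        assert bile_salt_enhancement(1.97, 3.0, 0.05) > 0.05

    @given(c=st.floats(0.0, 20.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_bile_concentration(self, c):
        lo = bile_salt_enhancement(1.97, c, 1.0)
        hi = bile_salt_enhancement(1.97, 2 * c, 1.0)
        assert hi >= lo


class TestDiffusionCoefficient:
    def test_vardenafil_value(self):
        # power law 9.9e-5 * MW^-0.453 evaluates to 0.599e-5 at MW 488.61
        assert diffusion_coefficient_from_mw(488.61) == pytest.approx(
            0.59e-5, rel=0.05
        )
        assert diffusion_coefficient_from_mw(488.61) == pytest.approx(
            0.599e-5, rel=0.01
        )

    def test_decreasing_in_molecular_weight(self):
        assert diffusion_coefficient_from_mw(244.3) > diffusion_coefficient_from_mw(
            488.61
        )

    def test_nonpositive_mw_rejected(self):
        with pytest.raises(ValueError):
            diffusion_coefficient_from_mw(0.0)
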