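"""Gut physiology construction, the oral PBPK ODE system, and sensitivity."""

import numpy as np
import pytest

from baripbpk import (
    apply_bariatric_modifications,
    default_physiology,
    pk_metrics,
    regional_absorption,
    sensitivity_analysis,
    simulate_oral_pbpk,
)
from baripbpk.gut_model import SEGMENT_NAMES, GITract


class TestPhysiology:
    def test_healthy_defaults(self, healthy_tract):
        st = healthy_tract.stomach
        assert (st.pH, st.fluid_volume, st.transit_time) == (1.3, 50.0, 0.25)
        assert healthy_tract.dose_water_volume == 250.0
        assert len(healthy_tract.compartments) == 9
        assert [c.name for c in healthy_tract.compartments] == SEGMENT_NAMES

    def test_small_intestine_and_colon_fluid_fractions(self, healthy_tract):
        by_name = {c.name: c for c in healthy_tract.compartments}
        for seg in ("duodenum", "jejunum1", "ileum3"):
            assert by_name[seg].percent_fluid == 23.0
        for seg in ("caecum", "asc_colon"):
            assert by_name[seg].percent_fluid == 0.5

    def test_unknown_subject_rejected(self):
        with pytest.raises(ValueError):
            default_physiology("fed")

    def test_sleeve_gastrectomy_modifications(self):
        tract = apply_bariatric_modifications(default_physiology(), "SG")
        st = tract.stomach
        assert (st.pH, st.fluid_volume, st.transit_time) == (5.0, 10.0, 0.12)
        assert tract.dose_water_volume == 50.0
        assert not tract.bypassed

    def test_bypass_modifications(self):
        tract = apply_bariatric_modifications(default_physiology(), "OAGB")
        assert tract.stomach.pH == 7.0
        assert tract.bypassed == {"duodenum", "jejunum1", "jejunum2"}

    def test_double_application_rejected(self):
        tract = apply_bariatric_modifications(default_physiology(), "SG")
        with pytest.raises(ValueError):
            apply_bariatric_modifications(tract, "OAGB")

    def test_unknown_surgery_rejected(self, healthy_tract):
        with pytest.raises(ValueError):
            apply_bariatric_modifications(healthy_tract, "RYGB")

    def test_stomach_must_be_non_absorptive(self, healthy_tract):
        from dataclasses import replace

        bad = [replace(healthy_tract.stomach, absorptive=True)] + list(
            healthy_tract.compartments[1:]
        )
        with pytest.raises(ValueError):
            GITract(compartments=bad)


class TestOralSimulation:
    def test_zero_dose_gives_zero_everything(self, drug, healthy_tract):
        res = simulate_oral_pbpk(drug, healthy_tract, dose_mg=0.0, duration_h=2.0)
        assert np.all(res.plasma == 0.0) and res.fraction_absorbed == 0.0

    def test_mass_balance_every_step(self, study):
        for res in study.results.values():
            assert res.mass_balance_error() <= 1e-6

    def test_auc_identity_with_closed_form(self, study):
        # AUC(0-inf) = Fa·(1-FPE)·D/(CL·BW)
        for (scenario, dose), res in study.results.items():
            met = pk_metrics(res.plasma_profile)
            d = res.disposition
            expected = (
                res.fraction_absorbed * (1 - d.fpe) * dose
                / (d.clearance * d.body_weight) * 1000.0
            )
            assert met.auc_0_inf == pytest.approx(expected, rel=0.02)

    def test_stomach_never_absorbs(self, study):
        for res in study.results.values():
            assert np.all(res.absorbed[res.names.index("stomach")] == 0.0)

    def test_healthy_absorption_complete(self, study):
        res = study.results[("pre_surgery", 20.0)]
        assert res.fraction_absorbed >= 0.95

    def test_bypassed_segments_absorb_nothing(self, study):
        res = study.results[("post_oagb", 20.0)]
        for seg in ("duodenum", "jejunum1", "jejunum2"):
            assert np.all(res.absorbed[res.names.index(seg)] == 0.0)

    def test_distal_shift_after_bypass(self, study):
        healthy = regional_absorption(study.results[("pre_surgery", 20.0)])
        oagb = regional_absorption(study.results[("post_oagb", 20.0)])
        proximal = ["duodenum", "jejunum1", "jejunum2"]
        distal = ["caecum", "asc_colon"]
        assert healthy[proximal].sum() > oagb[proximal].sum()
        assert oagb[distal].sum() > healthy[distal].sum()

    def test_regional_sums_to_fraction_absorbed(self, study):
        for res in study.results.values():
            reg = regional_absorption(res)
            assert reg.sum() == pytest.approx(
                res.fraction_absorbed * 100.0, abs=0.1
            )

    def test_unbypassing_a_segment_never_reduces_absorption(self, drug, study):
        full = study.results[("post_oagb", 20.0)]
        partial_tract = apply_bariatric_modifications(default_physiology(), "OAGB")
        partial_tract = GITract(
            compartments=partial_tract.compartments,
            bypassed=frozenset({"duodenum", "jejunum1"}),
            dose_water_volume=partial_tract.dose_water_volume,
            surgery="OAGB",
        )
        partial = simulate_oral_pbpk(drug, partial_tract, dose_mg=20.0)
        assert partial.fraction_absorbed >= full.fraction_absorbed - 1e-9


class TestSensitivity:
    def test_precipitation_time_insensitive_over_10fold(self, drug, healthy_tract):
        tab = sensitivity_analysis(
            drug, healthy_tract, "precipitation_time", [0.1, 1.0, 10.0]
        )
        assert np.all(np.abs(tab["pct_change_c_max"]) < 10.0)
        assert np.all(np.abs(tab["pct_change_auc"]) < 10.0)

    def test_identity_multiplier_changes_nothing(self, drug, healthy_tract):
        tab = sensitivity_analysis(drug, healthy_tract, "peff", [1.0])
        assert tab["pct_change_c_max"].iloc[0] == 0.0

    def test_dose_doubling_is_linear_when_solubility_non_binding(
        self, drug, healthy_tract
    ):
        tab = sensitivity_analysis(drug, healthy_tract, "dose", [1.0, 2.0])
        auc = tab.set_index("multiplier")["auc_0_inf"]
        assert auc[2.0] / auc[1.0] == pytest.approx(2.0, rel=0.01)

    def test_unknown_parameter_rejected(self, drug, healthy_tract):
        with pytest.raises(ValueError):
            sensitivity_analysis(drug, healthy_tract, "no_such_parameter", [1.0])
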