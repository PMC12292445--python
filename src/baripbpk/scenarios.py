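"""End-to-end study pipeline: validate the drug model, then compare surgery
scenarios.

``run_study`` reproduces the full analysis: fit the drug's solubility model,
simulate the validation doses (10 and 20 mg) in the healthy pre-surgery
state and judge them against the observed clinical PK parameters, then
simulate the post-sleeve-gastrectomy and post-gastric-bypass states and
compute pre- vs. post-surgery percent changes of C_max, T_max and
AUC(0–inf), together with regional-absorption and in vivo dissolution
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .disposition import DispositionParams, PlasmaProfile, pk_metrics
from .drug import DrugSpec
from .gut_model import (
    GITract,
    SimulationResult,
    apply_bariatric_modifications,
    default_physiology,
    regional_absorption,
    simulate_oral_pbpk,
)
from .synthetic_data import observed_pk_fixture
from .validation import ScenarioDelta, ValidationReport, build_validation_report

__all__ = ["StudyConfig", "StudyReport", "run_study", "early_exposure", "SCENARIOS"]

SCENARIOS = ("pre_surgery", "post_sg", "post_oagb")
_SURGERY_OF = {"pre_surgery": None, "post_sg": "SG", "post_oagb": "OAGB"}


@dataclass
class StudyConfig:
    """What to run: drug, doses, scenarios, horizon."""

    drug: DrugSpec
    doses_mg: tuple[float, ...] = (10.0, 20.0)
    validation_doses_mg: tuple[float, ...] = (10.0, 20.0)
    scenario_doses_mg: tuple[float, ...] = (20.0,)
    scenarios: tuple[str, ...] = SCENARIOS
    duration_h: float = 24.0
    body_weight: float = 70.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses_mg):
            raise ValueError("doses must be positive")
        bad = set(self.scenarios) - set(SCENARIOS)
        if bad:
            raise ValueError(f"unknown scenarios: {sorted(bad)}")


def tract_for(scenario: str) -> GITract:
    """Build the gut physiology for a named scenario."""
    tract = default_physiology()
    surgery = _SURGERY_OF[scenario]
    return tract if surgery is None else apply_bariatric_modifications(tract, surgery)


@dataclass
class StudyReport:
    """All study outputs in machine-friendly form."""

    metrics: pd.DataFrame                      # index (scenario, dose_mg)
    regional: pd.DataFrame                     # segments × (scenario, dose)
    deltas: list[ScenarioDelta]
    validation: ValidationReport | None
    results: dict[tuple[str, float], SimulationResult] = field(repr=False)

    def deltas_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                parameter=d.parameter.split(":", 1)[1],
                scenario=d.parameter.split(":", 1)[0],
                pre=d.pre_value,
                post=d.post_value,
                percent_change=d.percent_change,
            )
            for d in self.deltas
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {
            "metrics": self.metrics.reset_index().to_dict(orient="records"),
            "deltas": self.deltas_frame().to_dict(orient="records"),
        }
        if self.validation is not None:
            out["validation"] = self.validation.to_dict()
        return out


def run_study(config: StudyConfig) -> StudyReport:
    """Run validation plus all requested scenario × dose simulations.

    An empty scenario list yields a validation-only report: the pre-surgery
    state is still simulated at the validation doses and judged against the
    observed clinical parameters, but no scenario deltas are produced.
    """
    drug = config.drug.fitted()
    disposition = DispositionParams.from_drug(drug, config.body_weight)

    run_scenarios = list(config.scenarios)
    if "pre_surgery" not in run_scenarios and config.validation_doses_mg:
        run_scenarios = ["pre_surgery"] + run_scenarios

    results: dict[tuple[str, float], SimulationResult] = {}
    rows = []
    regional_cols = {}
    for scenario in run_scenarios:
        tract = tract_for(scenario)
        doses = (
            sorted(set(config.doses_mg) | set(config.validation_doses_mg))
            if scenario == "pre_surgery"
            else config.scenario_doses_mg
        )
        for dose in doses:
            res = simulate_oral_pbpk(
                drug, tract, disposition, dose_mg=dose, duration_h=config.duration_h
            )
            results[(scenario, dose)] = res
            met = pk_metrics(res.plasma_profile)
            rows.append(
                dict(
                    scenario=scenario,
                    dose_mg=dose,
                    c_max=met.c_max,
                    t_max=met.t_max,
                    auc_0_inf=met.auc_0_inf,
                    fraction_absorbed=res.fraction_absorbed,
                    fraction_dissolved=float(res.fraction_dissolved[-1]),
                    peak_hepatic_flux=float(res.hepatic_inlet_flux.max()),
                )
            )
            regional_cols[f"{scenario}_{dose:g}mg"] = regional_absorption(res)
    if not rows:
        metrics = pd.DataFrame(
            columns=["scenario", "dose_mg", "c_max", "t_max", "auc_0_inf",
                     "fraction_absorbed", "fraction_dissolved",
                     "peak_hepatic_flux"]
        ).set_index(["scenario", "dose_mg"])
    else:
        metrics = pd.DataFrame(rows).set_index(["scenario", "dose_mg"])
    regional = pd.DataFrame(regional_cols)

    # pre- vs. post-surgery percent changes at the scenario doses
    deltas: list[ScenarioDelta] = []
    if "pre_surgery" in config.scenarios:
        for scenario in config.scenarios:
            if scenario == "pre_surgery":
                continue
            for dose in config.scenario_doses_mg:
                pre = metrics.loc[("pre_surgery", dose)]
                post = metrics.loc[(scenario, dose)]
                for par in ("c_max", "t_max", "auc_0_inf"):
                    deltas.append(
                        ScenarioDelta(
                            f"{scenario}:{par}", float(pre[par]), float(post[par])
                        )
                    )

    # validation of the pre-surgery predictions against observed clinical PK
    validation = None
    if "pre_surgery" in run_scenarios and config.validation_doses_mg:
        observed = observed_pk_fixture()
        pairs = []
        for dose in config.validation_doses_mg:
            pred = metrics.loc[("pre_surgery", dose)]
            for par in ("c_max", "t_max", "auc_0_inf"):
                pairs.append(
                    dict(
                        parameter=f"{par}_{dose:g}mg",
                        observed=float(observed.loc[(int(dose), par), "observed"]),
                        predicted=float(pred[par]),
                    )
                )
        validation = build_validation_report(pd.DataFrame(pairs), criterion=1.25)

    return StudyReport(metrics, regional, deltas, validation, results)


def early_exposure(profile: PlasmaProfile, t: float) -> float:
    """Interpolated plasma concentration (ng/mL) at post-dose time ``t`` (h).

    The clinically critical quantity for an on-demand drug: exposure shortly
    after dosing.  Raises if ``t`` lies outside the simulated span.
    """
    return profile.at(t)
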