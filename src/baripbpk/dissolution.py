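"""Particle dissolution/precipitation kinetics and an in vitro vessel simulator.

The rate law is the Nernst–Brunner/Johnson diffusion-layer form for a
monodisperse powder: total flux = 3·D·M/(ρ·h·r)·(Cs − C), with the
diffusion-layer thickness h equal to the particle radius capped at 30 µm,
and cube-root radius shrinkage as mass dissolves.  Supersaturation decays
back to solid as a first-order process with the drug's mean precipitation
time.  The vessel simulator reproduces the paddle dissolution experiments
(USP II, 250 mL, and a mini-paddle 50 mL flask used to mimic the operated
stomach), and :func:`scaled_paddle_rpm` is the equal-agitation-strength
paddle-speed calculator used to choose the mini-paddle speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .drug import DrugSpec

__all__ = [
    "ParticleState",
    "DissolutionVessel",
    "HydrodynamicSpec",
    "DIFFUSION_LAYER_CAP_UM",
    "dissolution_rate",
    "precipitation_flux",
    "simulate_invitro_dissolution",
    "scaled_paddle_rpm",
]

#: diffusion-layer thickness cap, µm (standard Johnson-model default)
DIFFUSION_LAYER_CAP_UM = 30.0
_R_MIN_CM = 1e-6  # radius floor to keep the rate law finite


@dataclass
class ParticleState:
    """Monodisperse solid drug: initial size, current radius, remaining mass."""

    initial_diameter_um: float
    current_radius_um: float
    true_density: float  # g/mL
    undissolved_mass: float  # mg

    def __post_init__(self) -> None:
        if self.current_radius_um < 0 or self.undissolved_mass < 0:
            raise ValueError("radius and mass must be nonnegative")


@dataclass
class DissolutionVessel:
    """A stirred in vitro dissolution vessel."""

    volume: float  # mL
    pH: float
    temperature: float = 37.0
    agitation_rpm: float = 100.0
    apparatus: str = "usp2_paddle"  # or "mini_paddle"

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("vessel volume must be positive")


@dataclass
class HydrodynamicSpec:
    """Paddle hydrodynamics: speed, paddle diameter, fluid volume."""

    rpm: float
    paddle_diameter: float
    fluid_volume: float

    def __post_init__(self) -> None:
        if min(self.rpm, self.paddle_diameter, self.fluid_volume) <= 0:
            raise ValueError("all hydrodynamic parameters must be positive")

    @property
    def agitation_strength(self) -> float:
        """ε ∝ RPM³·D⁵/V (arbitrary units; only ratios are meaningful)."""
        return self.rpm**3 * self.paddle_diameter**5 / self.fluid_volume


def _rate_coefficient(radius_cm: float, density_mg_ml: float, d_cm2_h: float) -> float:
    """3·D/(ρ·h·r) with h = min(r, 30 µm); mL/(mg·h)."""
    r = max(radius_cm, _R_MIN_CM)
    h = min(r, DIFFUSION_LAYER_CAP_UM * 1e-4)
    return 3.0 * d_cm2_h / (density_mg_ml * h * r)


def dissolution_rate(
    particle: ParticleState,
    local_solubility: float,
    dissolved_conc: float,
    fluid_volume: float,
    diffusion_coeff: float,
) -> float:
    """Dissolution flux (mg/h) of a monodisperse powder, never negative.

    Parameters are in mg/mL (solubility, concentration), mL, and cm²/s.
    At saturation (C = Cs) or with no solid left the flux is zero;
    supersaturation is handled by :func:`precipitation_flux`, not here.
    """
    if fluid_volume <= 0:
        raise ValueError("fluid volume must be positive")
    if min(local_solubility, dissolved_conc, diffusion_coeff) < 0:
        raise ValueError("arguments must be nonnegative")
    if particle.undissolved_mass <= 0:
        return 0.0
    k = _rate_coefficient(
        particle.current_radius_um * 1e-4,
        particle.true_density * 1000.0,
        diffusion_coeff * 3600.0,
    )
    return max(k * particle.undissolved_mass * (local_solubility - dissolved_conc), 0.0)


def precipitation_flux(
    dissolved_conc: float,
    local_solubility: float,
    precipitation_time: float,
    fluid_volume: float,
) -> float:
    """First-order return of supersaturated excess to solid, mg/h.

    ``precipitation_time`` is the mean precipitation time in seconds; the
    excess (C − Cs)·V decays with rate constant 1/τ.  Zero when C ≤ Cs.
    """
    if precipitation_time <= 0:
        raise ValueError("precipitation time must be positive")
    excess = dissolved_conc - local_solubility
    if excess <= 0:
        return 0.0
    return excess * fluid_volume * 3600.0 / precipitation_time


def simulate_invitro_dissolution(
    dose_mg: float,
    drug: DrugSpec,
    vessel: DissolutionVessel,
    duration_min: float,
    n_out: int = 181,
) -> pd.DataFrame:
    """Closed-vessel dissolution of a dose of powder/tablet (instant disintegration).

    Returns a DataFrame with columns ``time_min`` and ``percent_dissolved``.
    Mass balance (dissolved + undissolved = dose) holds at every step and
    the dissolved concentration never exceeds the saturation solubility at
    the vessel pH.
    """
    if dose_mg <= 0 or duration_min <= 0:
        raise ValueError("dose and duration must be positive")
    drug = drug.fitted()
    cs = drug.solubility(vessel.pH)
    d_cm2_h = drug.diffusion_coefficient * 3600.0
    rho = drug.particle_density * 1000.0  # mg/mL
    r0 = drug.particle_diameter_um / 2.0 * 1e-4  # cm
    v = vessel.volume

    def rhs(_t, y):
        m_solid, r = y[0], y[1]
        c = (dose_mg - m_solid) / v
        if m_solid <= 0:
            return [0.0, 0.0]
        k = _rate_coefficient(r, rho, d_cm2_h)
        flux = max(k * m_solid * (cs - c), 0.0)
        drdt = -d_cm2_h / (rho * min(max(r, _R_MIN_CM), 30e-4)) * max(cs - c, 0.0)
        return [-flux, drdt]

    t_h = duration_min / 60.0
    sol = solve_ivp(
        rhs,
        (0.0, t_h),
        [dose_mg, r0],
        method="LSODA",
        t_eval=np.linspace(0.0, t_h, n_out),
        rtol=1e-9,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"dissolution integration failed: {sol.message}")
    m_solid = np.clip(sol.y[0], 0.0, dose_mg)
    pct = (dose_mg - m_solid) / dose_mg * 100.0
    return pd.DataFrame({"time_min": sol.t * 60.0, "percent_dissolved": pct})


def scaled_paddle_rpm(
    rpm_ref: float,
    d_ref: float,
    v_ref: float,
    d_new: float,
    v_new: float,
) -> float:
    """Paddle speed preserving agitation strength ε ∝ RPM³·D⁵/V.

    Solving ε_new = ε_ref for the new speed gives
    RPM_new = RPM_ref · (D_ref⁵/D_new⁵ · V_new/V_ref)^(1/3); used to derive
    the mini-paddle speed for the 50 mL post-surgery stomach vessel from the
    100 rpm USP II reference.
    """
    if min(rpm_ref, d_ref, v_ref, d_new, v_new) <= 0:
        raise ValueError("all dimensions must be positive")
    return rpm_ref * (d_ref**5 / d_new**5 * v_new / v_ref) ** (1.0 / 3.0)
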