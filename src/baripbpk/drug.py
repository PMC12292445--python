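"""Compound-specific model inputs for the oral-absorption simulation.

One :class:`DrugSpec` collects everything the pipeline needs about the
drug: physicochemistry (MW, logP, ionizable groups, measured pH-solubility
points, particle size, precipitation time), permeability, and systemic
disposition (clearance, central volume, distribution micro-constants,
first-pass extraction).  Values mirror the vardenafil parameter table used
throughout; see :mod:`baripbpk.synthetic_data` for the canonical fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .physicochem import (
    IonizableGroup,
    SolubilityMeasurement,
    SolubilityModel,
    diffusion_coefficient_from_mw,
    fit_solubility_model,
)

__all__ = ["DrugSpec"]


@dataclass
class DrugSpec:
    """All compound-specific parameters of the PBPK model."""

    name: str
    molecular_weight: float          # g/mol
    logP: float
    groups: list[IonizableGroup]
    solubility_points: list[SolubilityMeasurement]  # measured, 37 °C, mg/mL
    peff: float                      # human effective permeability, cm/s
    particle_diameter_um: float      # monodisperse initial diameter, µm
    particle_density: float = 1.2    # true density, g/mL (not printed; config)
    precipitation_time_s: float = 900.0
    fpe: float = 0.83                # hepatic first-pass extraction fraction
    clearance: float = 0.925         # L/h/kg
    vc: float = 0.800                # central volume, L/kg
    k12: float = 3.090               # 1/h
    k21: float = 2.100
    k13: float = 0.448
    k31: float = 0.250
    blood_plasma_ratio: float = 0.83  # metadata (unused by lumped model)
    fraction_unbound: float = 0.05    # metadata (unused by lumped model)
    diffusion_coefficient: float | None = None  # cm²/s; derived if omitted
    solubility_model: SolubilityModel | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")
        if self.peff <= 0:
            raise ValueError("Peff must be positive")
        if self.particle_diameter_um <= 0 or self.particle_density <= 0:
            raise ValueError("particle size and density must be positive")
        if self.precipitation_time_s <= 0:
            raise ValueError("precipitation time must be positive")
        if not (0.0 <= self.fpe < 1.0):
            raise ValueError("FPE must lie in [0, 1)")
        for m in self.solubility_points:
            if m.solubility <= 0:
                raise ValueError("solubility points must be positive")
        for rate in (self.clearance, self.vc, self.k12, self.k21, self.k13, self.k31):
            if rate <= 0:
                raise ValueError("disposition parameters must be positive")
        if self.diffusion_coefficient is None:
            self.diffusion_coefficient = diffusion_coefficient_from_mw(
                self.molecular_weight
            )

    def fitted(self) -> "DrugSpec":
        """Return a copy with the pH-solubility model fitted (idempotent)."""
        if self.solubility_model is not None:
            return self
        model = fit_solubility_model(self.solubility_points, self.groups, self.logP)
        return replace(self, solubility_model=model)

    def solubility(self, pH: float, bile_salt_mM: float = 0.0) -> float:
        """Luminal saturation solubility (mg/mL) at ``pH`` with bile salts."""
        if self.solubility_model is None:
            raise ValueError("solubility model not fitted; call .fitted() first")
        s_aq = float(self.solubility_model(pH))
        if bile_salt_mM > 0:
            from .physicochem import bile_salt_enhancement

            return bile_salt_enhancement(self.logP, bile_salt_mM, s_aq)
        return s_aq
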