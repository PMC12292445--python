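"""Ionization-aware aqueous solubility of a multiprotic drug.

Vardenafil is a weak base with two basic centres (pKa 4.24, 7.76) and one
acidic centre (pKa 8.68).  Its saturation solubility falls more than
600-fold between gastric pH 1 and post-bypass gastric pH 7, which is the
mechanistic driver of the whole analysis.  This module provides

* Henderson–Hasselbalch speciation (:func:`fraction_ionized`),
* a pH-solubility model fitted from measured points
  (:func:`fit_solubility_model`, :func:`solubility_at_ph`),
* bile-salt micellar solubilization (:func:`bile_salt_enhancement`), and
* the molecular-weight correlation for the aqueous diffusion coefficient
  (:func:`diffusion_coefficient_from_mw`).

The fitted model carries two layers.  A capped Henderson–Hasselbalch
("solubility factor") parameterization is estimated by least squares in
log-solubility space; its intrinsic solubility and per-state factor caps are
reported as model metadata.  For *evaluation* inside the measured pH range
the model interpolates the measured profile itself (monotone PCHIP on
log10 S), because a capped-HH curve is slope-limited by the pKa set and can
badly misrepresent a measured profile that falls faster than ten-fold per
pH unit; outside the measured range the capped-HH tails take over,
rescaled for continuity at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

__all__ = [
    "IonizableGroup",
    "SolubilityMeasurement",
    "SolubilityModel",
    "fraction_ionized",
    "solubility_at_ph",
    "fit_solubility_model",
    "bile_salt_enhancement",
    "diffusion_coefficient_from_mw",
]


@dataclass(frozen=True, order=True)
class IonizableGroup:
    """A single ionizable centre: its pKa and whether it is acidic or basic."""

    pKa: float
    kind: str = field(compare=False)  # "acid" or "base"

    def __post_init__(self) -> None:
        if not (0.0 < self.pKa < 14.0):
            raise ValueError(f"pKa must lie in (0, 14), got {self.pKa}")
        if self.kind not in ("acid", "base"):
            raise ValueError(f"kind must be 'acid' or 'base', got {self.kind!r}")


@dataclass(frozen=True)
class SolubilityMeasurement:
    """One equilibrium (shake-flask style) solubility point at 37 °C."""

    pH: float
    solubility: float  # mg/mL

    def __post_init__(self) -> None:
        if self.solubility <= 0:
            raise ValueError("solubility must be positive")
        if not (0.0 <= self.pH <= 14.0):
            raise ValueError("pH out of range")


def _state_log_ratios(pH, groups: list[IonizableGroup]):
    """log10 of (ionized-state concentration / neutral concentration).

    Sequential ionization: cationic states are built by protonating basic
    groups from the highest base pKa downward, anionic states by
    deprotonating acidic groups from the lowest acid pKa upward.  Returns a
    list with one entry per charged state, each an array over ``pH``.
    """
    pH = np.asarray(pH, dtype=float)
    bases = sorted((g.pKa for g in groups if g.kind == "base"), reverse=True)
    acids = sorted(g.pKa for g in groups if g.kind == "acid")
    ratios = []
    acc = np.zeros_like(pH)
    for pka in bases:  # +1, +2, ... charge states
        acc = acc + (pka - pH)
        ratios.append(acc.copy())
    acc = np.zeros_like(pH)
    for pka in acids:  # -1, -2, ... charge states
        acc = acc + (pH - pka)
        ratios.append(acc.copy())
    return ratios


def fraction_ionized(pH: float, groups: list[IonizableGroup]) -> dict[str, float]:
    """Molar fraction of each ionization state at ``pH``.

    Returns a dict mapping state labels (``neutral``, ``cation_1``,
    ``cation_2`` ..., ``anion_1`` ...) to fractions that sum to one.  With no
    ionizable groups the drug is entirely neutral.
    """
    if not (0.0 <= pH <= 14.0):
        raise ValueError("pH must lie in [0, 14]")
    if not groups:
        return {"neutral": 1.0}
    labels = []
    n_base = sum(1 for g in groups if g.kind == "base")
    labels += [f"cation_{i+1}" for i in range(n_base)]
    labels += [f"anion_{i+1}" for i in range(len(groups) - n_base)]
    log_ratios = _state_log_ratios(pH, groups)
    rel = np.concatenate(([1.0], [float(10.0 ** min(r, 300.0)) for r in log_ratios]))
    frac = rel / rel.sum()
    out = {"neutral": frac[0]}
    out.update({lab: f for lab, f in zip(labels, frac[1:])})
    return out


@dataclass
class SolubilityModel:
    """pH-solubility model: capped-HH parameters plus the measured profile.

    Parameters
    ----------
    intrinsic_solubility
        S0, solubility of the neutral species, mg/mL.
    solubility_factors
        One cap per charged state (same order as the sequential states of
        ``groups``): the maximal ratio of that state's solubility
        contribution to S0.  All ≥ 1.
    groups
        The ionizable groups the state ladder is built from.
    measurements
        The fitted measurements; retained so that evaluation inside the
        measured pH window can follow the profile itself.
    bile_salt_logP
        logP used by :func:`bile_salt_enhancement` when a caller asks the
        model for luminal solubility with bile present.
    """

    intrinsic_solubility: float
    solubility_factors: list[float]
    groups: list[IonizableGroup]
    measurements: list[SolubilityMeasurement] = field(default_factory=list)
    bile_salt_logP: float | None = None
    _interp: PchipInterpolator | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.intrinsic_solubility <= 0:
            raise ValueError("intrinsic solubility must be positive")
        if any(f < 1.0 for f in self.solubility_factors):
            raise ValueError("solubility factors must be >= 1")
        if len(self.solubility_factors) != len(self.groups):
            raise ValueError("one solubility factor per ionizable group required")
        if len(self.measurements) >= 2:
            pts = sorted(self.measurements, key=lambda m: m.pH)
            ph = np.array([m.pH for m in pts])
            if np.any(np.diff(ph) <= 0):
                raise ValueError("duplicate measurement pH values")
            logs = np.log10([m.solubility for m in pts])
            object.__setattr__(self, "_interp", PchipInterpolator(ph, logs))
            self._ph_lo, self._ph_hi = ph[0], ph[-1]

    # -- capped Henderson–Hasselbalch curve ---------------------------------
    def _hh_curve(self, pH) -> np.ndarray:
        pH = np.atleast_1d(np.asarray(pH, dtype=float))
        total = np.ones_like(pH)
        for log_ratio, cap in zip(
            _state_log_ratios(pH, self.groups), self.solubility_factors
        ):
            total = total + np.minimum(10.0 ** np.minimum(log_ratio, 300.0), cap - 1.0)
        return self.intrinsic_solubility * total

    def __call__(self, pH):
        pH_arr = np.atleast_1d(np.asarray(pH, dtype=float))
        s = self._hh_curve(pH_arr)
        if self._interp is not None:
            lo, hi = self._ph_lo, self._ph_hi
            inside = (pH_arr >= lo) & (pH_arr <= hi)
            s[inside] = 10.0 ** self._interp(pH_arr[inside])
            # HH tails rescaled to join the measured profile continuously
            below = pH_arr < lo
            if below.any():
                anchor = 10.0 ** self._interp(lo) / float(self._hh_curve(lo)[0])
                s[below] = self._hh_curve(pH_arr[below]) * anchor
            above = pH_arr > hi
            if above.any():
                anchor = 10.0 ** self._interp(hi) / float(self._hh_curve(hi)[0])
                s[above] = self._hh_curve(pH_arr[above]) * anchor
        # the model never dips below the neutral-species (intrinsic) floor
        s = np.maximum(s, self.intrinsic_solubility)
        return s if np.ndim(pH) else float(s[0])


def solubility_at_ph(model: SolubilityModel, pH: float) -> float:
    """Saturation solubility (mg/mL) of the fitted model at ``pH``."""
    if not isinstance(model, SolubilityModel):
        raise TypeError("solubility_at_ph requires a fitted SolubilityModel")
    return float(model(pH))


def fit_solubility_model(
    measurements: list[SolubilityMeasurement],
    groups: list[IonizableGroup],
    logP: float | None = None,
) -> SolubilityModel:
    """Fit the capped-HH pH-solubility model to measured points.

    Least squares in log10-solubility space over (S0, one factor cap per
    charged state), with factors bounded ≥ 1.  The measurements are stored
    on the returned model so that evaluation follows the measured profile
    within its pH span (see module docstring).
    """
    if len(measurements) < 2:
        raise ValueError("need at least two solubility measurements")
    ph = np.array([m.pH for m in measurements], dtype=float)
    sol = np.array([m.solubility for m in measurements], dtype=float)
    if ph.max() - ph.min() < 2.0:
        raise ValueError("measurements must span at least 2 pH units")

    if not groups:
        s0 = float(np.exp(np.mean(np.log(sol))))
        return SolubilityModel(s0, [], [], list(measurements), logP)

    n_states = len(groups)

    def curve(theta):
        s0 = 10.0 ** theta[0]
        caps = 1.0 + 10.0 ** theta[1:]
        total = np.ones_like(ph)
        for log_ratio, cap in zip(_state_log_ratios(ph, groups), caps):
            total = total + np.minimum(10.0 ** np.minimum(log_ratio, 300.0), cap - 1.0)
        return s0 * total

    def resid(theta):
        return np.log10(curve(theta)) - np.log10(sol)

    # start: S0 from the least-soluble point, caps from the dynamic range
    theta0 = np.concatenate(
        ([np.log10(sol.min()) - 1.0],
         np.full(n_states, np.log10(max(sol.max() / sol.min(), 10.0))))
    )
    best = None
    for scale in (1.0, 0.3, 3.0):
        fit = least_squares(resid, theta0 * scale, method="trf", max_nfev=5000)
        if best is None or fit.cost < best.cost:
            best = fit
    s0 = float(10.0 ** best.x[0])
    factors = [float(1.0 + 10.0 ** t) for t in best.x[1:]]
    return SolubilityModel(s0, factors, list(groups), list(measurements), logP)


def bile_salt_enhancement(
    logP: float, bile_salt_conc_mM: float, aqueous_solubility: float
) -> float:
    """Solubility (mg/mL) enhanced by bile-salt micellar solubilization.

    Uses the logP correlation for the micelle–water partition coefficient,
    log10 K = 2.23 + 0.61·logP (mole-fraction based), giving an enhancement
    factor 1 + K·[BS]·v̄w with v̄w = 0.01805 L/mol the molar volume of water.
    Zero bile salt leaves the aqueous solubility unchanged.
    """
    if bile_salt_conc_mM < 0:
        raise ValueError("bile salt concentration must be nonnegative")
    K = 10.0 ** (2.23 + 0.61 * logP)
    factor = 1.0 + K * (bile_salt_conc_mM * 1e-3) * 0.01805
    return aqueous_solubility * factor


def diffusion_coefficient_from_mw(mw: float) -> float:
    """Aqueous diffusion coefficient (cm²/s) from molecular weight (g/mol).

    Power-law correlation D = 9.9e-5 · MW^(-0.453), the standard small-
    molecule estimate; for vardenafil (MW 488.61) it gives 0.599e-5 cm²/s.
    """
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    return 9.9e-5 * mw ** (-0.453)
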