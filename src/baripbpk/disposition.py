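"""Linear mammillary systemic pharmacokinetics (1-, 2- or 3-compartment).

The disposition model receives drug flux into the central compartment
(from the gut model, net of hepatic first-pass extraction), distributes it
over up to two peripheral compartments via first-order micro-constants
k12/k21/k13/k31, and eliminates it from the central compartment with
k10 = CL/Vc.  Plasma concentration is the central amount divided by
Vc·BW.  The module also provides the terminal half-life implied by the
micro-constants (smallest-magnitude eigenvalue), compartmental parameter
fitting from concentration–time data, and non-compartmental metrics
(C_max, T_max, AUC with log-linear terminal extrapolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "DispositionParams",
    "PlasmaProfile",
    "PKMetrics",
    "simulate_disposition",
    "terminal_half_life",
    "fit_disposition",
    "pk_metrics",
]

MG_PER_L_TO_NG_PER_ML = 1000.0


@dataclass
class DispositionParams:
    """Micro-constant parameterization of systemic disposition.

    CL and Vc are body-weight normalized (L/h/kg, L/kg); distribution
    micro-constants are first-order rates (1/h).  A one-compartment model is
    the k12 = k13 = 0 limit.
    """

    clearance: float          # L/h/kg
    vc: float                 # L/kg (central volume; "Vd" of the source table)
    k12: float = 0.0          # 1/h
    k21: float = 0.0
    k13: float = 0.0
    k31: float = 0.0
    fpe: float = 0.0          # hepatic first-pass extracted fraction
    body_weight: float = 70.0  # kg
    blood_plasma_ratio: float | None = None  # metadata
    fraction_unbound: float | None = None    # metadata

    def __post_init__(self) -> None:
        if self.clearance <= 0 or self.vc <= 0:
            raise ValueError("CL and Vc must be positive")
        for k in (self.k12, self.k21, self.k13, self.k31):
            if k < 0:
                raise ValueError("micro-constants must be nonnegative")
        if (self.k12 > 0) != (self.k21 > 0) or (self.k13 > 0) != (self.k31 > 0):
            raise ValueError("k_ij and k_ji must be zero or positive together")
        if not (0.0 <= self.fpe < 1.0):
            raise ValueError("FPE must lie in [0, 1)")
        if self.body_weight <= 0:
            raise ValueError("body weight must be positive")

    @property
    def k10(self) -> float:
        """Central elimination rate constant, 1/h."""
        return self.clearance / self.vc

    @property
    def n_compartments(self) -> int:
        return 1 + int(self.k12 > 0) + int(self.k13 > 0)

    def matrix(self) -> np.ndarray:
        """Rate matrix A with amounts ordered (central, periph1, periph2)."""
        return np.array(
            [
                [-(self.k10 + self.k12 + self.k13), self.k21, self.k31],
                [self.k12, -self.k21, 0.0],
                [self.k13, 0.0, -self.k31],
            ]
        )

    @classmethod
    def from_drug(cls, drug, body_weight: float = 70.0) -> "DispositionParams":
        return cls(
            clearance=drug.clearance,
            vc=drug.vc,
            k12=drug.k12,
            k21=drug.k21,
            k13=drug.k13,
            k31=drug.k31,
            fpe=drug.fpe,
            body_weight=body_weight,
            blood_plasma_ratio=drug.blood_plasma_ratio,
            fraction_unbound=drug.fraction_unbound,
        )


@dataclass
class PlasmaProfile:
    """A sampled plasma concentration–time course."""

    times: np.ndarray          # h, strictly increasing
    concentrations: np.ndarray  # ng/mL, nonnegative

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape or self.times.ndim != 1:
            raise ValueError("times and concentrations must be equal-length 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")

    def at(self, t: float) -> float:
        """Linearly interpolated concentration at time ``t`` (no extrapolation)."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"t={t} outside profile span")
        return float(np.interp(t, self.times, self.concentrations))


@dataclass
class PKMetrics:
    """Non-compartmental summary of a plasma profile."""

    c_max: float        # ng/mL
    t_max: float        # h
    auc_0_t: float      # ng·h/mL
    auc_0_inf: float    # ng·h/mL (NaN when lambda_z is not estimable)
    lambda_z: float     # 1/h (NaN when not estimable)


def _active(params: DispositionParams) -> np.ndarray:
    mask = [True, params.k12 > 0, params.k13 > 0]
    return np.where(mask)[0]


def simulate_disposition(
    params: DispositionParams,
    input_flux,
    duration: float,
    iv_bolus_mg: float = 0.0,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-10,
) -> PlasmaProfile:
    """Integrate the disposition system under a time-varying central input.

    ``input_flux`` is a callable t (h) → mg/h entering the central
    compartment systemically (i.e. already net of first-pass extraction), or
    None for no input.  ``iv_bolus_mg`` places an instantaneous dose in the
    central compartment at t = 0.
    """
    if t_eval is None:
        t_eval = np.linspace(0.0, duration, 481)
    A = params.matrix()
    flux = input_flux if input_flux is not None else (lambda t: 0.0)

    def rhs(t, y):
        dy = A @ y
        dy[0] += flux(t)
        return dy

    y0 = np.array([float(iv_bolus_mg), 0.0, 0.0])
    sol = solve_ivp(
        rhs, (0.0, duration), y0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=1e-12
    )
    if not sol.success:
        raise RuntimeError(f"disposition integration failed: {sol.message}")
    conc = sol.y[0] / (params.vc * params.body_weight) * MG_PER_L_TO_NG_PER_ML
    return PlasmaProfile(sol.t, np.maximum(conc, 0.0))


def _bolus_concentration(params: DispositionParams, dose_mg: float, t: np.ndarray):
    """Analytic IV-bolus central concentration (ng/mL) via eigendecomposition."""
    idx = _active(params)
    A = params.matrix()[np.ix_(idx, idx)]
    lam, V = np.linalg.eig(A)
    e1 = np.zeros(len(idx))
    e1[0] = dose_mg
    coef = np.linalg.solve(V, e1)
    central = (V[0, :] * coef) @ np.exp(np.outer(lam, t))
    return np.real(central) / (params.vc * params.body_weight) * MG_PER_L_TO_NG_PER_ML


def _oral_concentration(
    params: DispositionParams, fdose_mg: float, ka: float, t: np.ndarray
):
    """First-order-absorption central concentration for bioavailable dose F·D."""
    idx = _active(params)
    n = len(idx)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = params.matrix()[np.ix_(idx, idx)]
    A[n, n] = -ka
    A[0, n] = ka
    lam, V = np.linalg.eig(A)
    y0 = np.zeros(n + 1)
    y0[n] = fdose_mg
    coef = np.linalg.solve(V, y0)
    central = (V[0, :] * coef) @ np.exp(np.outer(lam, t))
    return np.real(central) / (params.vc * params.body_weight) * MG_PER_L_TO_NG_PER_ML


def terminal_half_life(params: DispositionParams) -> float:
    """Terminal elimination half-life (h): ln 2 over the slowest eigenvalue."""
    idx = _active(params)
    lam = np.linalg.eigvals(params.matrix()[np.ix_(idx, idx)])
    lam = np.real(lam)
    if np.any(lam >= 0):
        raise ValueError("disposition matrix must be strictly stable")
    return float(np.log(2) / np.min(np.abs(lam)))


def fit_disposition(
    iv_profile: PlasmaProfile,
    iv_dose_mg: float,
    oral_profile: PlasmaProfile | None = None,
    oral_dose_mg: float | None = None,
    n_compartments: int = 3,
    body_weight: float = 70.0,
) -> DispositionParams:
    """Fit compartmental disposition parameters to concentration–time data.

    Weighted least squares with 1/C weighting (residuals on log-like scale
    ``(pred − obs)/obs``) against the analytic bolus solution; when an oral
    profile is supplied, a first-order absorption rate and bioavailable
    fraction are co-estimated from it.  Raises on non-convergence with the
    best iterate attached to the exception.
    """
    if n_compartments not in (1, 2, 3):
        raise ValueError("n_compartments must be 1, 2 or 3")
    n_par = 2 * n_compartments + (2 if oral_profile is not None else 0)
    n_obs = len(iv_profile.times) + (
        len(oral_profile.times) if oral_profile is not None else 0
    )
    if len(iv_profile.times) < 2 * n_compartments + 1:
        raise ValueError(
            f"need at least {2 * n_compartments + 1} IV observations, "
            f"got {len(iv_profile.times)}"
        )
    if oral_profile is not None and oral_dose_mg is None:
        raise ValueError("oral_dose_mg required with an oral profile")

    obs_iv = iv_profile.concentrations
    pos_iv = obs_iv > 0

    # NCA-flavoured starting values
    c0 = max(obs_iv[0], 1e-9)
    vc0 = iv_dose_mg / (c0 / MG_PER_L_TO_NG_PER_ML) / body_weight
    auc0 = np.trapezoid(obs_iv, iv_profile.times) / MG_PER_L_TO_NG_PER_ML
    cl0 = iv_dose_mg / max(auc0, 1e-9) / body_weight

    def build(theta) -> tuple[DispositionParams, float, float]:
        vals = np.exp(theta)
        cl, vc = vals[0], vals[1]
        ks = [0.0, 0.0, 0.0, 0.0]
        if n_compartments >= 2:
            ks[0], ks[1] = vals[2], vals[3]
        if n_compartments == 3:
            ks[2], ks[3] = vals[4], vals[5]
        p = DispositionParams(cl, vc, *ks, body_weight=body_weight)
        if oral_profile is not None:
            ka = vals[2 * n_compartments]
            f = 1.0 / (1.0 + np.exp(-theta[2 * n_compartments + 1]))
            return p, ka, f
        return p, 0.0, 1.0

    def resid(theta):
        p, ka, f = build(theta)
        pred = _bolus_concentration(p, iv_dose_mg, iv_profile.times)
        r = (pred[pos_iv] - obs_iv[pos_iv]) / obs_iv[pos_iv]
        if oral_profile is not None:
            obs_po = oral_profile.concentrations
            pos = obs_po > 0
            pred_po = _oral_concentration(p, f * oral_dose_mg, ka, oral_profile.times)
            r = np.concatenate([r, (pred_po[pos] - obs_po[pos]) / obs_po[pos]])
        return r

    theta0 = [np.log(cl0), np.log(vc0)]
    if n_compartments >= 2:
        theta0 += [np.log(1.5), np.log(1.0)]
    if n_compartments == 3:
        theta0 += [np.log(0.4), np.log(0.2)]
    if oral_profile is not None:
        theta0 += [np.log(1.0), 0.0]
    theta0 = np.asarray(theta0)

    best = None
    for scale in (1.0, 0.5, 2.0):
        start = theta0.copy()
        start[2:2 * n_compartments] += np.log(scale) if n_compartments > 1 else 0.0
        try:
            fit = least_squares(resid, start, method="lm", max_nfev=20000)
        except Exception:
            continue
        if best is None or fit.cost < best.cost:
            best = fit
    if best is None or not np.all(np.isfinite(best.x)):
        err = RuntimeError("disposition fit did not converge")
        err.best_iterate = None if best is None else build(best.x)[0]
        raise err
    params, _ka, _f = build(best.x)
    return params


def pk_metrics(profile: PlasmaProfile) -> PKMetrics:
    """Non-compartmental C_max, T_max, AUC(0–t), λz and AUC(0–inf).

    AUC(0–t) by the linear trapezoid; λz from log-linear regression over the
    last third of the post-T_max points that lie below C_max/2 (at least
    three required, else λz and AUC(0–inf) are reported as NaN).
    """
    t, c = profile.times, profile.concentrations
    if len(t) < 3:
        raise ValueError("need at least three observations")
    i_max = int(np.argmax(c))
    c_max, t_max = float(c[i_max]), float(t[i_max])
    auc_t = float(np.trapezoid(c, t))

    tail = np.where((np.arange(len(t)) > i_max) & (c < c_max / 2.0) & (c > 0))[0]
    lam_z = np.nan
    auc_inf = np.nan
    if len(tail) >= 3:
        window = tail[-max(len(tail) // 3, 3):]
        if len(window) >= 3:
            slope, _ = np.polyfit(t[window], np.log(c[window]), 1)
            if slope < 0:
                lam_z = float(-slope)
                auc_inf = auc_t + float(c[-1]) / lam_z
    return PKMetrics(c_max, t_max, auc_t, auc_inf, lam_z)
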