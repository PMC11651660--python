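"""Apparent Kd from thermal-shift dosing curves (ThermoFluor analysis).

Given melting temperatures measured at a series of total ligand
concentrations, fit the apparent dissociation constant at a reference
temperature (default 37 C). The dosing model is the standard ThermoFluor
relation: at the melting temperature the unfolding equilibrium constant is
KU = exp(-dGu(Tm)/(R*Tm)) and the total ligand needed to produce that Tm is

    Lt = (KU - 1) * ( 1/Kb(Tm) + Pt / (2*(KU + 1)) )

where Kb(Tm) is the binding constant extrapolated from the reference
temperature by the integrated van't Hoff equation with binding enthalpy dHb
and heat-capacity change dCpb. Only ligand stabilization (Tm >= Tm_ref) is
in scope.

Covalent compounds violate the reversible model's assumptions: once the
protein is covalently saturated the dosing curve goes flat. We fit the
reversible model anyway — reporting an *apparent* Kd — and attach a
saturation diagnostic instead of a kinetic correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .melt_model import R_GAS, StabilityParams, unfolding_free_energy

__all__ = [
    "BindingThermo",
    "DosePoint",
    "KdAppResult",
    "binding_constant_at_T",
    "dosing_ligand_total",
    "tm_at_dose",
    "fit_kd_app",
    "combine_replicates",
]

T_REF_DEFAULT = 310.15  # K, 37 C
DHB_DEFAULT = -42_000.0  # J/mol, typical sulfonamide-CA binding enthalpy
DCPB_DEFAULT = -800.0  # J/(mol K)


@dataclass(frozen=True)
class BindingThermo:
    """Ligand binding thermodynamics at a reference temperature.

    Kd_ref : M, dissociation constant at T0.
    T0     : K, reference temperature (310.15 K = 37 C).
    dHb    : J/mol, binding enthalpy at T0.
    dCpb   : J/(mol K), binding heat-capacity change.
    """

    Kd_ref: float
    T0: float = T_REF_DEFAULT
    dHb: float = DHB_DEFAULT
    dCpb: float = DCPB_DEFAULT

    def __post_init__(self) -> None:
        if self.Kd_ref <= 0:
            raise ValueError("Kd_ref must be positive")
        if self.T0 <= 0:
            raise ValueError("T0 must be positive (kelvin)")


@dataclass(frozen=True)
class DosePoint:
    """One dosing observation: total ligand, observed Tm, total protein."""

    Lt: float  # M
    Tm_obs: float  # K
    Pt: float  # M

    def __post_init__(self) -> None:
        if self.Lt < 0:
            raise ValueError("Lt must be >= 0")
        if self.Pt <= 0:
            raise ValueError("Pt must be positive")


@dataclass(frozen=True)
class KdAppResult:
    Kd_app: float  # M (point estimate, or upper bound when saturated)
    ci_low: float  # M, ~95% interval
    ci_high: float
    saturation_flag: bool
    upper_bound_only: bool
    n_points_used: int
    config: dict = field(default_factory=dict)


def binding_constant_at_T(b: BindingThermo, T) -> float | np.ndarray:
    """Binding constant Kb(T) = 1/Kd(T) by van't Hoff extrapolation.

    dGb(T) = dHb + dCpb*(T - T0) - T*(dSb + dCpb*ln(T/T0)),
    dSb = (dHb - R*T0*ln Kd_ref)/T0, so that Kb(T0) = 1/Kd_ref exactly.
    """
    T = np.asarray(T, float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    dSb = (b.dHb - R_GAS * b.T0 * math.log(b.Kd_ref)) / b.T0
    dGb = b.dHb + b.dCpb * (T - b.T0) - T * (dSb + b.dCpb * np.log(T / b.T0))
    kb = np.exp(-dGb / (R_GAS * T))
    return kb if kb.ndim else float(kb)


def dosing_ligand_total(Tm_obs, s: StabilityParams, b: BindingThermo, Pt: float):
    """Total ligand that produces melting temperature Tm_obs.

    Tm_obs below the ligand-free Tm_ref (destabilization) is out of model
    scope and raises. Accepts arrays.
    """
    Tm = np.asarray(Tm_obs, float)
    if np.any(Tm < s.Tm_ref - 1e-9):
        raise ValueError("Tm_obs < Tm_ref: destabilization is out of model scope")
    ku = np.exp(-unfolding_free_energy(Tm, s) / (R_GAS * Tm))
    kb = binding_constant_at_T(b, Tm)
    lt = (ku - 1.0) * (1.0 / kb + Pt / (2.0 * (ku + 1.0)))
    lt = np.where(np.abs(Tm - s.Tm_ref) < 1e-12, 0.0, lt)
    return lt if lt.ndim else float(lt)


def tm_at_dose(
    Lt,
    s: StabilityParams,
    b: BindingThermo,
    Pt: float,
    bracket_width: float = 40.0,
    tol: float = 1e-4,
):
    """Melting temperature at total ligand Lt (inverse of the dosing relation).

    Solved by bisection on [Tm_ref, Tm_ref + bracket_width]; the dosing
    relation is strictly increasing in Tm so the root is unique. Accepts
    arrays (vectorized bisection).
    """
    Lt_arr = np.atleast_1d(np.asarray(Lt, float))
    if np.any(Lt_arr < 0):
        raise ValueError("Lt must be >= 0")
    lo = np.full_like(Lt_arr, s.Tm_ref)
    hi = np.full_like(Lt_arr, s.Tm_ref + bracket_width)
    top = dosing_ligand_total(hi, s, b, Pt)
    if np.any(top < Lt_arr):
        bad = float(np.max(Lt_arr))
        raise ValueError(
            f"no root: Lt up to {bad:.3g} M exceeds the dosing relation at "
            f"the bracket top [{s.Tm_ref:.2f}, {s.Tm_ref + bracket_width:.2f}] K"
        )
    n_iter = max(1, math.ceil(math.log2(bracket_width / tol)))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        f_mid = dosing_ligand_total(mid, s, b, Pt)
        below = f_mid < Lt_arr
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    tm = 0.5 * (lo + hi)
    tm = np.where(Lt_arr == 0.0, s.Tm_ref, tm)
    return tm if np.ndim(Lt) else float(tm[0])


def _saturation_diagnostic(
    points: list[DosePoint],
    s: StabilityParams,
    b_fit: BindingThermo,
    n_top: int = 3,
    obs_spread_max: float = 0.5,
    model_spread_min: float = 1.0,
) -> bool:
    """Covalent signature: top doses observed flat while the model predicts
    a continuing Tm rise."""
    dosed = sorted((p for p in points if p.Lt > 0), key=lambda p: p.Lt)
    if len(dosed) < n_top:
        return False
    top = dosed[-n_top:]
    obs_spread = max(p.Tm_obs for p in top) - min(p.Tm_obs for p in top)
    lts = np.array([p.Lt for p in top])
    model_tm = tm_at_dose(lts, s, b_fit, top[0].Pt)
    model_spread = float(np.max(model_tm) - np.min(model_tm))
    return obs_spread < obs_spread_max and model_spread > model_spread_min


def fit_kd_app(
    points: list[DosePoint],
    s: StabilityParams,
    dHb: float = DHB_DEFAULT,
    dCpb: float = DCPB_DEFAULT,
    T0: float = T_REF_DEFAULT,
    log10_starts: tuple[float, ...] = (-12.0, -9.0, -5.0),
    bounds_logkd: tuple[float, float] = (-13.0, -4.0),
) -> KdAppResult:
    """Fit the apparent Kd at T0 from a Tm dosing series.

    Single free parameter log10(Kd_ref); dHb and dCpb are held at configured
    values (dosing data cannot identify them). Least squares in Tm space
    with three optimizer starts spanning [1e-13, 1e-4] M. When every dosed
    point sits in the flat covalent-saturation regime, Kd is reported as an
    upper bound only.
    """
    if len(points) < 4:
        raise ValueError("need >= 4 dose points")
    if not any(p.Lt == 0 for p in points):
        raise ValueError("need a zero-ligand reference point")
    dosed = [p for p in points if p.Lt > 0]
    lts = np.array([p.Lt for p in dosed])
    tms = np.array([p.Tm_obs for p in dosed])
    pt = dosed[0].Pt

    def objective(logkd: float) -> float:
        b = BindingThermo(10.0 ** float(logkd), T0, dHb, dCpb)
        pred = tm_at_dose(lts, s, b, pt)
        return float(np.sum((pred - tms) ** 2))

    best_x, best_f = None, np.inf
    for x0 in log10_starts:
        res = minimize(
            lambda v: objective(v[0]),
            x0=[x0],
            method="Nelder-Mead",
            bounds=[bounds_logkd],
            options={"xatol": 1e-4, "fatol": 1e-12},
        )
        if res.fun < best_f:
            best_f, best_x = res.fun, float(res.x[0])

    kd = 10.0 ** best_x
    b_fit = BindingThermo(kd, T0, dHb, dCpb)

    # ~95% CI from the curvature of the chi-square surface in log10 Kd
    h = 0.05
    f0, fp, fm = best_f, objective(best_x + h), objective(best_x - h)
    curv = (fp + fm - 2 * f0) / h**2
    dof = max(len(dosed) - 1, 1)
    sigma2 = f0 / dof
    if curv > 0 and sigma2 >= 0:
        se_log = math.sqrt(2.0 * sigma2 / curv)  # 0 for a perfect fit
    else:
        se_log = float("inf")
    ci_low = 10.0 ** (best_x - 1.96 * se_log) if math.isfinite(se_log) else 0.0
    ci_high = 10.0 ** (best_x + 1.96 * se_log) if math.isfinite(se_log) else math.inf

    saturated = _saturation_diagnostic(points, s, b_fit)
    # all-points-saturated degenerate case: the whole dosed range is flat
    all_flat = (
        len(dosed) >= 3
        and float(np.max(tms) - np.min(tms)) < 0.5
        and float(np.max(tms)) > s.Tm_ref + 1.0
    )

    return KdAppResult(
        Kd_app=kd,
        ci_low=ci_low,
        ci_high=ci_high,
        saturation_flag=saturated or all_flat,
        upper_bound_only=all_flat,
        n_points_used=len(dosed),
        config={"dHb": dHb, "dCpb": dCpb, "T0": T0, "Pt": pt},
    )


def combine_replicates(kds: list[float]) -> float:
    """Geometric mean of replicate Kd estimates (order-invariant)."""
    arr = np.asarray(kds, float)
    if arr.size == 0 or np.any(arr <= 0):
        raise ValueError("replicate Kds must be positive and non-empty")
    return float(np.exp(np.mean(np.log(arr))))
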