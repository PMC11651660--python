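"""Competitive binding equilibrium and displacement-curve fitting.

A labeled probe B (here a fluorescein-labeled high-affinity tracer) and an
unlabeled competitor A bind the same site on target P. Given totals
(Pt, At, Bt) and the two dissociation constants, the mass-action system

    PA = P*A/KdA,  PB = P*B/KdB,
    P + PA + PB = Pt,  A + PA = At,  B + PB = Bt

has a unique physical solution found by monotone bisection on free P.
Depletion is modeled throughout (At and Bt are totals, not free): with an
apparent Kd well below the target concentration, the free ~= total
approximation would be badly wrong.

The measured signal is proportional to the bound-probe fraction PB/Bt with
a fitted scale and background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CompetitionSetup",
    "SpeciesState",
    "CompetitionFitResult",
    "solve_equilibrium",
    "bound_probe_single_ligand",
    "occupancy_curve",
    "fit_competitor_kd",
]


@dataclass(frozen=True)
class CompetitionSetup:
    """Assay constants: total target Pt, total probe Bt, probe KdB (all M)."""

    Pt: float
    Bt: float
    KdB: float

    def __post_init__(self) -> None:
        if min(self.Pt, self.Bt, self.KdB) <= 0:
            raise ValueError("Pt, Bt and KdB must all be positive")


@dataclass(frozen=True)
class SpeciesState:
    """Free and complexed concentrations at equilibrium (M)."""

    P: float
    A: float
    B: float
    PA: float
    PB: float


@dataclass(frozen=True)
class CompetitionFitResult:
    KdA_app: float  # M; lower bound when flagged
    ci_low: float
    ci_high: float
    scale: float
    background: float
    lower_bound_only: bool
    n_points: int
    config: dict = field(default_factory=dict)


def bound_probe_single_ligand(Pt: float, Bt: float, KdB: float) -> float:
    """Closed-form PB for the single-ligand (no competitor) quadratic."""
    b = Pt + Bt + KdB
    return 0.5 * (b - math.sqrt(b * b - 4.0 * Pt * Bt))


def solve_equilibrium(
    setup: CompetitionSetup,
    At: float,
    KdA: float,
    rel_tol: float = 1e-14,
    max_iter: int = 200,
) -> SpeciesState:
    """Unique physical equilibrium of the two-ligand competition system.

    Bisection on free P in [0, Pt]: total protein accounted for,
    f(P) = P*(1 + At/(KdA+P) + Bt/(KdB+P)) - Pt, is strictly increasing.
    """
    if At < 0:
        raise ValueError("At must be >= 0")
    if KdA <= 0:
        raise ValueError("KdA must be positive")
    pt, bt, kdb = setup.Pt, setup.Bt, setup.KdB

    def f(p: float) -> float:
        return p * (1.0 + At / (KdA + p) + bt / (kdb + p)) - pt

    lo, hi = 0.0, pt
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= rel_tol * pt:
            break
    else:
        raise RuntimeError(
            f"competition equilibrium did not converge in {max_iter} iterations"
        )
    p = 0.5 * (lo + hi)
    pa = At * p / (KdA + p)
    pb = bt * p / (kdb + p)
    return SpeciesState(P=p, A=At - pa, B=bt - pb, PA=pa, PB=pb)


def occupancy_curve(
    setup: CompetitionSetup, KdA: float, At_grid
) -> np.ndarray:
    """Bound-probe fraction PB/Bt at each competitor total dose."""
    grid = np.asarray(At_grid, float)
    if np.any(grid < 0):
        raise ValueError("competitor doses must be >= 0")
    return np.array(
        [solve_equilibrium(setup, float(a), KdA).PB / setup.Bt for a in grid]
    )


def fit_competitor_kd(
    At,
    signal,
    setup: CompetitionSetup,
    bounds_logkd: tuple[float, float] = (-12.0, -3.0),
) -> CompetitionFitResult:
    """Fit apparent competitor Kd from a probe-displacement dose curve.

    Least squares over {log10 KdA, scale, background} with the signal model
    S = background + scale * PB/Bt. Needs >= 6 doses spanning the transition
    and a zero-competitor point. A curve flat within noise yields a
    lower-bound-only result (the competitor is too weak to displace on this
    dose range).
    """
    At = np.asarray(At, float)
    sig = np.asarray(signal, float)
    if At.size != sig.size:
        raise ValueError("dose and signal lengths differ")
    if At.size < 6:
        raise ValueError("need >= 6 doses")
    if not np.any(At == 0):
        raise ValueError("need a zero-competitor point")

    # flat-curve guard: compare observed modulation against point scatter
    order = np.argsort(At)
    smooth_resid = np.std(np.diff(sig[order])) / math.sqrt(2.0)
    modulation = float(np.max(sig) - np.min(sig))
    if modulation < 3.0 * max(smooth_resid, 1e-30) or modulation == 0.0:
        kd_lb = 10.0 ** bounds_logkd[1]
        return CompetitionFitResult(
            KdA_app=kd_lb, ci_low=kd_lb, ci_high=math.inf,
            scale=float("nan"), background=float(np.mean(sig)),
            lower_bound_only=True, n_points=At.size,
            config={"Pt": setup.Pt, "Bt": setup.Bt, "KdB": setup.KdB},
        )

    occ0 = bound_probe_single_ligand(setup.Pt, setup.Bt, setup.KdB) / setup.Bt
    scale0 = (float(np.max(sig)) - float(np.min(sig))) / occ0
    bg0 = float(np.min(sig))

    def residual(theta):
        logkd, scale, bg = theta
        occ = occupancy_curve(setup, 10.0**logkd, At)
        return bg + scale * occ - sig

    x0 = np.array([math.log10(setup.KdB), scale0, bg0])
    res = least_squares(
        residual,
        x0,
        bounds=(
            [bounds_logkd[0], 0.0, -np.inf],
            [bounds_logkd[1], np.inf, np.inf],
        ),
        xtol=1e-12,
        ftol=1e-12,
    )
    logkd, scale, bg = res.x
    if logkd >= bounds_logkd[1] - 0.1:
        # optimizer pushed KdA to the weak-binding bound: no real displacement
        kd_lb = 10.0 ** bounds_logkd[1]
        return CompetitionFitResult(
            KdA_app=kd_lb, ci_low=kd_lb, ci_high=math.inf,
            scale=float(scale), background=float(bg),
            lower_bound_only=True, n_points=At.size,
            config={"Pt": setup.Pt, "Bt": setup.Bt, "KdB": setup.KdB},
        )
    # standard errors from the Jacobian (Gauss-Newton approximation)
    dof = max(At.size - 3, 1)
    sigma2 = float(np.sum(res.fun**2)) / dof
    try:
        cov = sigma2 * np.linalg.inv(res.jac.T @ res.jac)
        se_log = math.sqrt(max(cov[0, 0], 0.0))
    except np.linalg.LinAlgError:
        se_log = float("inf")
    se_log = min(se_log, 100.0)  # avoid float overflow in the CI bounds
    ci_low = 10.0 ** (logkd - 1.96 * se_log)
    ci_high = 10.0 ** (logkd + 1.96 * se_log)

    return CompetitionFitResult(
        KdA_app=10.0**logkd,
        ci_low=ci_low,
        ci_high=ci_high,
        scale=float(scale),
        background=float(bg),
        lower_bound_only=False,
        n_points=At.size,
        config={"Pt": setup.Pt, "Bt": setup.Bt, "KdB": setup.KdB},
    )
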