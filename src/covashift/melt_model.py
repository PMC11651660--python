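"""Two-state thermal unfolding of fluorescence melt curves.

The raw stage of a fluorescent thermal shift assay (FTSA / differential
scanning fluorimetry): a dye reports protein unfolding as temperature ramps
up, and the melting temperature Tm is extracted by fitting a two-state
(native <-> unfolded) model with linear pre- and post-transition baselines.

Model: the unfolding free energy at temperature T is

    dGu(T) = dHu * (1 - T/Tm) + dCpu * (T - Tm - T*ln(T/Tm))

with dHu the unfolding enthalpy at Tm and dCpu the unfolding heat-capacity
change. The folded fraction is fN(T) = 1/(1 + exp(-dGu/(R*T))) and the
signal is a baseline-weighted mix of the native and unfolded states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize as lmfit_minimize
from scipy.signal import savgol_filter

R_GAS = 8.314  # J/(mol K)

__all__ = [
    "R_GAS",
    "StabilityParams",
    "Baselines",
    "MeltCurve",
    "MeltFitResult",
    "NoTransitionError",
    "unfolding_free_energy",
    "folded_fraction",
    "simulate_melt",
    "fit_melt",
]


@dataclass(frozen=True)
class StabilityParams:
    """Two-state stability of the ligand-free protein.

    Tm_ref : K, ligand-free melting temperature.
    dHu    : J/mol, unfolding enthalpy at Tm_ref (>0).
    dCpu   : J/(mol K), unfolding heat-capacity change.
    """

    Tm_ref: float
    dHu: float
    dCpu: float = 0.0

    def __post_init__(self) -> None:
        if not (273.0 < self.Tm_ref < 373.0):
            raise ValueError("Tm_ref must be between 273 and 373 K")
        if self.dHu <= 0:
            raise ValueError("dHu must be positive")


@dataclass(frozen=True)
class Baselines:
    """Linear native/unfolded baselines, anchored at Tm_ref.

    F_native(T) = bN0 + bN1*(T - Tm_ref); likewise for unfolded.
    """

    bN0: float = 0.0
    bN1: float = 0.0
    bU0: float = 1.0
    bU1: float = 0.0


@dataclass(frozen=True)
class MeltCurve:
    """A single-well melt trace on a strictly increasing temperature grid."""

    temperatures: np.ndarray  # K
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, float)
        f = np.asarray(self.fluorescence, float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)
        if t.size != f.size:
            raise ValueError("temperature and fluorescence lengths differ")
        if t.size < 20:
            raise ValueError("melt curve needs >= 20 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(f))):
            raise ValueError("non-finite values in melt curve")


@dataclass(frozen=True)
class MeltFitResult:
    params: StabilityParams
    baselines: Baselines
    tm_stderr: float  # K; nan if not estimable
    residual_rms: float
    amplitude: float  # fitted unfolded-minus-native signal at Tm
    n_points: int


class NoTransitionError(RuntimeError):
    """The curve shows no detectable unfolding transition."""


def unfolding_free_energy(T, s: StabilityParams):
    """dGu(T) in J/mol; zero at Tm_ref by construction. Accepts arrays."""
    T = np.asarray(T, float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    g = s.dHu * (1.0 - T / s.Tm_ref) + s.dCpu * (
        T - s.Tm_ref - T * np.log(T / s.Tm_ref)
    )
    return g if g.ndim else float(g)


def folded_fraction(T, s: StabilityParams):
    """Native fraction 1/(1 + exp(-dGu/(R T))); 0.5 exactly at Tm_ref."""
    T = np.asarray(T, float)
    g = unfolding_free_energy(T, s)
    f = 1.0 / (1.0 + np.exp(-np.clip(g / (R_GAS * T), -700, 700)))
    return f if f.ndim else float(f)


def simulate_melt(
    s: StabilityParams,
    baselines: Baselines | None = None,
    t_grid: np.ndarray | None = None,
) -> MeltCurve:
    """Noise-free melt curve from the two-state model.

    Default grid is 25-90 C at 1 C spacing (the standard thermocycler ramp).
    """
    if baselines is None:
        baselines = Baselines()
    if t_grid is None:
        t_grid = np.arange(25.0, 90.0 + 0.5, 1.0) + 273.15
    T = np.asarray(t_grid, float)
    fN = folded_fraction(T, s)
    dT = T - s.Tm_ref
    signal = (baselines.bN0 + baselines.bN1 * dT) * fN + (
        baselines.bU0 + baselines.bU1 * dT
    ) * (1.0 - fN)
    return MeltCurve(T, signal)


def _initial_tm(curve: MeltCurve) -> float:
    """Tm guess from the maximum of the smoothed derivative |dF/dT|."""
    f = curve.fluorescence
    window = min(11, f.size - (1 - f.size % 2))
    smooth = savgol_filter(f, window_length=max(window, 5), polyorder=3)
    dfdt = np.gradient(smooth, curve.temperatures)
    return float(curve.temperatures[np.argmax(np.abs(dfdt))])


def fit_melt(curve: MeltCurve, dCpu: float = 17_000.0) -> MeltFitResult:
    """Fit Tm, dHu and linear baselines to a melt curve.

    dCpu is held fixed (a single curve cannot identify it); default
    17 kJ/(mol K), typical for a ~30 kDa globular domain. Raises
    :class:`NoTransitionError` when the transition amplitude is below three
    times the residual noise.
    """
    T, F = curve.temperatures, curve.fluorescence
    n_edge = max(3, T.size // 10)
    f_lo, f_hi = F[:n_edge], F[-n_edge:]
    amp_guess = float(np.mean(f_hi) - np.mean(f_lo))
    scale = max(abs(amp_guess), np.ptp(F), 1e-12)

    tm0 = _initial_tm(curve)
    tm0 = float(np.clip(tm0, T[0] + 1.0, T[-1] - 1.0))

    p = Parameters()
    p.add("Tm", value=tm0, min=T[0] - 10.0, max=T[-1] + 10.0)
    p.add("dHu", value=4e5, min=1e4, max=5e6)
    p.add("bN0", value=float(np.mean(f_lo)))
    p.add("bN1", value=0.0)
    p.add("bU0", value=float(np.mean(f_hi)))
    p.add("bU1", value=0.0)

    def residual(pars):
        s = StabilityParams(pars["Tm"].value, pars["dHu"].value, dCpu)
        bl = Baselines(pars["bN0"].value, pars["bN1"].value,
                       pars["bU0"].value, pars["bU1"].value)
        model = simulate_melt(s, bl, T).fluorescence
        return (model - F) / scale

    out = lmfit_minimize(residual, p, method="leastsq")
    pb = out.params
    s_fit = StabilityParams(pb["Tm"].value, pb["dHu"].value, dCpu)
    bl_fit = Baselines(pb["bN0"].value, pb["bN1"].value,
                       pb["bU0"].value, pb["bU1"].value)
    resid_rms = float(np.sqrt(np.mean((out.residual * scale) ** 2)))
    dTm = s_fit.Tm_ref - s_fit.Tm_ref  # 0; amplitude evaluated at Tm
    amplitude = float((bl_fit.bU0 + bl_fit.bU1 * dTm) - (bl_fit.bN0 + bl_fit.bN1 * dTm))

    if abs(amplitude) < 3.0 * max(resid_rms, 1e-15) or not (
        T[0] < s_fit.Tm_ref < T[-1]
    ):
        raise NoTransitionError(
            f"no transition detected: amplitude {amplitude:.3g} vs "
            f"residual rms {resid_rms:.3g}, Tm {s_fit.Tm_ref:.1f} K"
        )

    stderr = pb["Tm"].stderr
    return MeltFitResult(
        params=s_fit,
        baselines=bl_fit,
        tm_stderr=float(stderr) if stderr is not None else float("nan"),
        residual_rms=resid_rms,
        amplitude=amplitude,
        n_points=T.size,
    )
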