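"""Seeded generators emulating every input the analysis modules consume.

Each generator reproduces the wet-lab layout behind the corresponding
assay — serial-dilution dose grids, 25-90 C melt ramps, probe-displacement
plates, deconvoluted peak lists, covalent-modification time courses — with
configurable noise, and returns a machine-readable truth record alongside
the data so every downstream fitter has a recovery test.

Default noise levels: fluorescence sigma 1% of amplitude, Tm sigma 0.2 K,
mass error 20 ppm, competition signal CV 5%. Identical config (including
seed) gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .melt_model import Baselines, MeltCurve, StabilityParams, simulate_melt
from .ftsa_dosing import BindingThermo, tm_at_dose
from .competition_binding import CompetitionSetup, occupancy_curve
from .covalent_kinetics import RateConstants, fraction_modified, simulate

__all__ = [
    "GeneratorConfig",
    "gen_dose_grid",
    "gen_ftsa_tm_series",
    "gen_ftsa_plate",
    "gen_competition_plate",
    "gen_ms_peaklist",
    "gen_kinetics_timecourse",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed and noise model for all synthetic generators."""

    seed: int = 0
    fluor_sigma_frac: float = 0.01  # fraction of melt amplitude
    tm_sigma: float = 0.2  # K
    mass_ppm_sigma: float = 20.0
    signal_cv: float = 0.05

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_dose_grid(
    scheme: str = "twofold-8",
    stock: float = 10e-3,
    buffer_dilution: float = 12.5,
    mix_dilution: float = 2.0,
) -> np.ndarray:
    """Final assay concentrations of a serial-dilution scheme.

    Serial dilution in DMSO from the stock, then dilution into assay buffer
    (default 12.5x) and 1:1 mixing with the protein solution (2x). The
    default "twofold-8" gives 8 doses topping out at 400 uM from a 10 mM
    stock; "one-and-half-fold-12" gives 12 doses at ratio 1.5. A final
    zero-ligand point is appended.
    """
    if stock <= 0:
        raise ValueError("stock must be positive")
    if scheme == "twofold-8":
        n, ratio = 8, 2.0
    elif scheme == "one-and-half-fold-12":
        n, ratio = 12, 1.5
    else:
        raise ValueError(f"unknown dilution scheme: {scheme!r}")
    top = stock / buffer_dilution / mix_dilution
    doses = top / ratio ** np.arange(n)
    return np.append(doses, 0.0)


def gen_ftsa_tm_series(
    kd_ref: float,
    s: StabilityParams,
    b_template: BindingThermo | None = None,
    grid: np.ndarray | None = None,
    Pt: float = 5e-6,
    cfg: GeneratorConfig | None = None,
    covalent_plateau: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-dose melting temperatures for a dosing series (Tm level).

    The forward model inverts the ThermoFluor dosing relation per dose.
    With ``covalent_plateau`` the series instead mimics instantaneous
    complete covalent modification: every dosed well above the protein
    concentration shows the same maximal shift (a flat dosing curve, the
    covalent saturation signature).
    """
    cfg = cfg or GeneratorConfig()
    rng = cfg.rng()
    if grid is None:
        grid = gen_dose_grid()
    b = BindingThermo(
        kd_ref,
        *( (b_template.T0, b_template.dHb, b_template.dCpb)
           if b_template is not None else (310.15, -42_000.0, -800.0) ),
    )
    grid = np.asarray(grid, float)
    if covalent_plateau:
        top_tm = tm_at_dose(float(np.max(grid)), s, b, Pt)
        tm_true = np.where(grid >= Pt, top_tm, s.Tm_ref)
        tm_true = np.where(grid == 0.0, s.Tm_ref, tm_true)
    else:
        tm_true = np.array([tm_at_dose(float(lt), s, b, Pt) for lt in grid])
    noise = rng.normal(0.0, cfg.tm_sigma, size=grid.size) if cfg.tm_sigma > 0 else 0.0
    df = pd.DataFrame(
        {
            "well_id": [f"W{i+1:02d}" for i in range(grid.size)],
            "Lt_M": grid,
            "Tm_C": tm_true + noise - 273.15,
            "Pt_M": Pt,
        }
    )
    truth = {
        "kd_ref_M": kd_ref,
        "Tm_true_K": tm_true.tolist(),
        "stability": asdict(s),
        "binding": asdict(b),
        "Pt_M": Pt,
        "config": asdict(cfg),
    }
    return df, truth


def gen_ftsa_plate(
    kd_ref: float,
    s: StabilityParams,
    b_template: BindingThermo | None = None,
    grid: np.ndarray | None = None,
    Pt: float = 5e-6,
    cfg: GeneratorConfig | None = None,
    baselines: Baselines | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full raw plate: per-well melt curves on the 25-90 C, 1 C/min ramp.

    Returns (long-format melt curves, per-well metadata, truth record).
    Each well's curve is the two-state model at that well's true Tm (the
    ligand-shifted stability), plus Gaussian fluorescence noise.
    """
    cfg = cfg or GeneratorConfig()
    rng = cfg.rng()
    if grid is None:
        grid = gen_dose_grid()
    tm_df, truth = gen_ftsa_tm_series(
        kd_ref, s, b_template, grid, Pt,
        GeneratorConfig(cfg.seed, cfg.fluor_sigma_frac, 0.0,
                        cfg.mass_ppm_sigma, cfg.signal_cv),
    )
    baselines = baselines or Baselines(bN0=1000.0, bN1=-2.0, bU0=9000.0, bU1=-8.0)
    t_grid = np.arange(25.0, 90.0 + 0.5, 1.0) + 273.15
    amp = abs(baselines.bU0 - baselines.bN0)
    rows = []
    for well, tm_k in zip(tm_df["well_id"], np.array(truth["Tm_true_K"])):
        s_well = StabilityParams(float(tm_k), s.dHu, s.dCpu)
        curve = simulate_melt(s_well, baselines, t_grid)
        noisy = curve.fluorescence + rng.normal(
            0.0, cfg.fluor_sigma_frac * amp, size=t_grid.size
        )
        rows.append(
            pd.DataFrame(
                {
                    "well_id": well,
                    "temperature_C": t_grid - 273.15,
                    "fluorescence": noisy,
                }
            )
        )
    curves = pd.concat(rows, ignore_index=True)
    meta = tm_df.rename(columns={"Tm_C": "Tm_true_C"})
    truth["config"] = asdict(cfg)
    return curves, meta, truth


def gen_competition_plate(
    kda: float,
    setup: CompetitionSetup,
    grid: np.ndarray | None = None,
    cfg: GeneratorConfig | None = None,
    scale: float = 1000.0,
    background: float = 50.0,
) -> tuple[pd.DataFrame, dict]:
    """Probe-displacement dose-response plate.

    The default grid spans the full displacement transition for competitor
    affinities from tens of pM to tens of nM against a 10 nM / 150 pM
    probe: 12 fourfold dilutions from a 100 uM top dose (the concentration
    at which every tested compound completely outcompetes the probe), plus
    a no-competitor well. Signal = background + scale * PB/Bt with
    multiplicative noise. The narrow 80 nM serial-dilution layout used for
    plate preparation is available through :func:`gen_dose_grid`.
    """
    cfg = cfg or GeneratorConfig()
    rng = cfg.rng()
    if grid is None:
        grid = np.append(100e-6 / 4.0 ** np.arange(12), 0.0)
    grid = np.asarray(grid, float)
    occ = occupancy_curve(setup, kda, grid)
    clean = background + scale * occ
    noisy = clean * (1.0 + rng.normal(0.0, cfg.signal_cv, size=grid.size)) \
        if cfg.signal_cv > 0 else clean.copy()
    df = pd.DataFrame(
        {
            "well_id": [f"C{i+1:02d}" for i in range(grid.size)],
            "competitor_total_M": grid,
            "signal": noisy,
            "replicate": 1,
        }
    )
    truth = {
        "kda_M": kda,
        "scale": scale,
        "background": background,
        "setup": asdict(setup),
        "occupancy_true": occ.tolist(),
        "config": asdict(cfg),
    }
    return df, truth


def gen_ms_peaklist(
    base_mass: float,
    shift: float,
    occupancies,
    cfg: GeneratorConfig | None = None,
    base_intensity: float = 100.0,
) -> tuple[pd.DataFrame, dict]:
    """Deconvoluted peak list for a protein with 0..k covalent adducts.

    ``occupancies`` are the modified-site fractions (k=1, 2, ...); the
    unmodified peak carries the remainder. Masses get ppm-scale jitter.
    """
    cfg = cfg or GeneratorConfig()
    rng = cfg.rng()
    occ = np.asarray(occupancies, float)
    if np.any(occ < 0) or occ.sum() > 1.0 + 1e-12:
        raise ValueError("occupancies must be >= 0 and sum to <= 1")
    fractions = np.concatenate([[1.0 - occ.sum()], occ])
    masses = base_mass + shift * np.arange(fractions.size)
    jitter = (
        rng.normal(0.0, cfg.mass_ppm_sigma * 1e-6, size=masses.size) * masses
        if cfg.mass_ppm_sigma > 0
        else 0.0
    )
    df = pd.DataFrame(
        {
            "mass_da": masses + jitter,
            "intensity": base_intensity * fractions,
        }
    )
    df = df[df["intensity"] > 0].reset_index(drop=True)
    truth = {
        "base_mass_da": base_mass,
        "shift_da": shift,
        "occupancies": occ.tolist(),
        "true_masses_da": masses.tolist(),
        "config": asdict(cfg),
    }
    return df, truth


def gen_kinetics_timecourse(
    rates: RateConstants,
    E0: float,
    I0: float,
    t_grid=None,
    cfg: GeneratorConfig | None = None,
    noise_sigma: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Noisy covalently-modified-fraction time series plus truth."""
    cfg = cfg or GeneratorConfig()
    rng = cfg.rng()
    if t_grid is None:
        t_grid = np.linspace(0.0, 7200.0, 49)
    t_grid = np.asarray(t_grid, float)
    states = simulate(rates, E0, I0, t_grid)
    frac = fraction_modified(states)
    noisy = np.clip(frac + rng.normal(0.0, noise_sigma, size=frac.size), 0.0, 1.0) \
        if noise_sigma > 0 else frac.copy()
    df = pd.DataFrame({"t_s": t_grid, "fraction_modified": noisy})
    truth = {
        "rates": asdict(rates),
        "E0_M": E0,
        "I0_M": I0,
        "fraction_true": frac.tolist(),
        "config": asdict(cfg),
    }
    return df, truth
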