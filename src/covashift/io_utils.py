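"""Shared I/O plumbing: CSV readers, JSON writers, TOML config, fixtures.

Unit conventions at the file boundary: concentrations in molar,
temperatures in Celsius; the analysis code works in kelvin internally.
Every analysis result JSON embeds the resolved configuration and the
package version, so numbers are reproducible from the output alone.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import asdict, is_dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .formula_mass import CompoundRecord, MassPeak, parse_formula

__all__ = [
    "load_fixture_compounds",
    "read_peaks_csv",
    "read_tm_csv",
    "read_melt_csv",
    "read_competition_csv",
    "load_config",
    "write_result_json",
]

CELSIUS_OFFSET = 273.15


def load_fixture_compounds() -> list[CompoundRecord]:
    """Packaged compound table: formula, leaving group, warhead class.

    Compound ids are the study's compound numbers where the pairing with a
    synthesis code is supported; otherwise the synthesis code serves as id.
    """
    src = resources.files("covashift").joinpath("data/compounds.csv")
    with resources.as_file(src) as path:
        df = pd.read_csv(path, dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        lg = parse_formula(row["leaving_group_formula"]) if row["leaving_group_formula"] else None
        records.append(
            CompoundRecord(
                id=row["id"] or row["code"],
                code=row["code"],
                formula=parse_formula(row["formula"]),
                leaving_group=lg,
                warhead_class=row["warhead_class"] or "none",
            )
        )
    if not records:
        raise RuntimeError("compound fixture is empty")
    return records


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required columns {missing}")


def read_peaks_csv(path) -> list[MassPeak]:
    """Two-column peak list: mass_da, intensity (header required)."""
    df = pd.read_csv(path)
    _require_columns(df, ["mass_da", "intensity"], str(path))
    return [MassPeak(float(m), float(i)) for m, i in zip(df["mass_da"], df["intensity"])]


def read_tm_csv(path) -> pd.DataFrame:
    """Per-well Tm table: well_id, Lt_M, Tm_C, Pt_M."""
    df = pd.read_csv(path)
    _require_columns(df, ["well_id", "Lt_M", "Tm_C", "Pt_M"], str(path))
    return df


def read_melt_csv(path) -> pd.DataFrame:
    """Long-format melt curves: well_id, temperature_C, fluorescence."""
    df = pd.read_csv(path)
    _require_columns(df, ["well_id", "temperature_C", "fluorescence"], str(path))
    return df


def read_competition_csv(path) -> pd.DataFrame:
    """Displacement plate: well_id, competitor_total_M, signal[, replicate]."""
    df = pd.read_csv(path)
    _require_columns(df, ["well_id", "competitor_total_M", "signal"], str(path))
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return df


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _jsonify(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if isinstance(obj, float) and not math.isfinite(obj):  # NaN/inf
        return None
    return obj


def write_result_json(payload: dict, path=None, config: dict | None = None) -> str:
    """Serialize a result with the config echo and package version."""
    doc = {"covashift_version": __version__, "config": _jsonify(config or {})}
    doc.update(_jsonify(payload))
    text = json.dumps(doc, indent=2, allow_nan=False)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
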