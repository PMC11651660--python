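"""Molecular-formula mass arithmetic and covalent-adduct peak matching.

This module does the mass bookkeeping for a covalent inhibitor campaign:

* parse Hill-notation molecular formulas ("C23H28F3N3O6S2");
* exact (monoisotopic) and average masses, and m/z of singly charged ions;
* predicted protein mass shift of a covalent adduct — the inhibitor loses
  its ester/carbamate leaving group by beta-elimination before bonding, so
  the shift is compound mass minus leaving-group mass (a vinylsulfone
  warhead adds its whole mass);
* matching observed deconvoluted protein mass differences against candidate
  compounds.

Deconvoluted intact-protein spectra live on the average-mass scale, so peak
matching uses average shifts; small-molecule HRMS lines use monoisotopic
masses.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from ._elements import ELEMENTS, PROTON_MASS, SODIUM_CATION_MASS

__all__ = [
    "ElementComposition",
    "IonSpecies",
    "CompoundRecord",
    "MassPeak",
    "ShiftMatch",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "average_mass",
    "ion_mz",
    "adduct_shift",
    "predict_modified_masses",
    "match_shift",
    "PROTON_MASS",
    "SODIUM_CATION_MASS",
]


class FormulaError(ValueError):
    """Raised for malformed formulas or unknown element symbols."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementComposition:
    """Element -> count mapping for a neutral molecule or fragment."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for sym, n in self.counts.items():
            if sym not in ELEMENTS:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {sym} must be a positive integer, got {n!r}")

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementComposition(merged)

    def __sub__(self, other: "ElementComposition") -> "ElementComposition":
        if not other.issubset(self):
            raise FormulaError(
                f"{other.hill()} is not a sub-composition of {self.hill()}"
            )
        diff = {s: n - other.counts.get(s, 0) for s, n in self.counts.items()}
        return ElementComposition({s: n for s, n in diff.items() if n > 0})

    def issubset(self, other: "ElementComposition") -> bool:
        return all(other.counts.get(s, 0) >= n for s, n in self.counts.items())

    def hill(self) -> str:
        """Canonical Hill-order formula string (C, H, then alphabetical)."""
        parts: list[str] = []
        order: list[str]
        if "C" in self.counts:
            order = ["C"] + (["H"] if "H" in self.counts else [])
            order += sorted(s for s in self.counts if s not in ("C", "H"))
        else:
            order = sorted(self.counts)
        for sym in order:
            n = self.counts[sym]
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


@dataclass(frozen=True)
class IonSpecies:
    """A singly charged (or neutral) ion species label."""

    label: str  # "[M+H]+", "[M-H]-", "[M+Na]+", "neutral"
    charge: int

    _ALLOWED = {"[M+H]+": 1, "[M-H]-": -1, "[M+Na]+": 1, "neutral": 0}

    def __post_init__(self) -> None:
        if self.label not in self._ALLOWED:
            raise ValueError(f"unsupported ion species: {self.label!r}")
        if self.charge != self._ALLOWED[self.label]:
            raise ValueError(
                f"charge {self.charge} inconsistent with species {self.label}"
            )

    @classmethod
    def from_label(cls, label: str) -> "IonSpecies":
        norm = {
            "M+H": "[M+H]+", "[M+H]+": "[M+H]+",
            "M-H": "[M-H]-", "[M-H]-": "[M-H]-",
            "M+Na": "[M+Na]+", "[M+Na]+": "[M+Na]+",
            "neutral": "neutral",
        }
        if label not in norm:
            raise ValueError(f"unsupported ion species: {label!r}")
        lab = norm[label]
        return cls(lab, cls._ALLOWED[lab])


@dataclass(frozen=True)
class CompoundRecord:
    """A candidate covalent compound: formula, leaving group, warhead class."""

    id: str
    formula: ElementComposition
    leaving_group: ElementComposition | None = None
    warhead_class: str = "none"  # ester | carbamate | vinylsulfone | none
    code: str = ""

    def __post_init__(self) -> None:
        if self.warhead_class not in ("ester", "carbamate", "vinylsulfone", "none"):
            raise ValueError(f"unknown warhead class: {self.warhead_class!r}")
        if self.warhead_class in ("ester", "carbamate"):
            if self.leaving_group is None:
                raise ValueError(
                    f"{self.id}: {self.warhead_class} warhead requires a leaving group"
                )
            if not self.leaving_group.issubset(self.formula):
                raise FormulaError(
                    f"{self.id}: leaving group {self.leaving_group.hill()} is not "
                    f"a sub-composition of {self.formula.hill()}"
                )


@dataclass(frozen=True)
class MassPeak:
    """A deconvoluted neutral protein mass peak."""

    mass: float  # Da
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("peak mass must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be >= 0")


@dataclass(frozen=True)
class ShiftMatch:
    """Result of matching one observed mass shift to a candidate adduct."""

    peak: MassPeak
    observed_shift: float  # Da, peak mass minus base mass
    candidate_id: str  # "" when unmatched
    predicted_shift: float = math.nan
    error_da: float = math.nan  # observed - predicted
    error_ppm: float = math.nan  # relative to the predicted modified mass

    @property
    def matched(self) -> bool:
        return bool(self.candidate_id)


def parse_formula(text: str) -> ElementComposition:
    """Parse a Hill-style molecular formula string.

    An omitted count means 1 ("C" -> {C: 1}); repeated symbols accumulate.
    Raises :class:`FormulaError` for unknown symbols, explicit zero counts,
    or any unparseable residue.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    s = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in ELEMENTS:
            raise FormulaError(f"unknown element symbol: {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(f"zero/negative count for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return ElementComposition(counts)


def monoisotopic_mass(comp: ElementComposition) -> float:
    """Exact mass (Da) summing most-abundant-isotope masses."""
    return sum(ELEMENTS[s][0] * n for s, n in comp.counts.items())


def average_mass(comp: ElementComposition) -> float:
    """Average molecular mass (Da) summing standard atomic weights."""
    return sum(ELEMENTS[s][1] * n for s, n in comp.counts.items())


def ion_mz(comp: ElementComposition, species: IonSpecies | str) -> float:
    """m/z of a singly charged ion (or the neutral monoisotopic mass).

    [M+H]+ adds and [M-H]- subtracts the proton mass (electron mass
    accounted for); [M+Na]+ adds the sodium cation mass.
    """
    if isinstance(species, str):
        species = IonSpecies.from_label(species)
    m = monoisotopic_mass(comp)
    if species.label == "neutral":
        return m
    if species.label == "[M+H]+":
        return m + PROTON_MASS
    if species.label == "[M-H]-":
        return m - PROTON_MASS
    return m + SODIUM_CATION_MASS


def adduct_shift(compound: CompoundRecord) -> tuple[float, float]:
    """Predicted (monoisotopic, average) protein mass shift of the adduct.

    Ester/carbamate pre-warheads eliminate their leaving group before the
    covalent bond forms, so the protein gains compound minus leaving group.
    A vinylsulfone adds the full molecule. Compounds with no warhead have no
    defined shift.
    """
    if compound.warhead_class == "vinylsulfone":
        return monoisotopic_mass(compound.formula), average_mass(compound.formula)
    if compound.leaving_group is None:
        raise ValueError(
            f"{compound.id}: no leaving group and not a vinylsulfone; "
            "adduct shift undefined"
        )
    adduct = compound.formula - compound.leaving_group
    return monoisotopic_mass(adduct), average_mass(adduct)


def predict_modified_masses(base: float, shift: float, max_sites: int) -> list[float]:
    """Masses of the protein with 0..max_sites adducts: base + k*shift."""
    if max_sites < 1:
        raise ValueError("max_sites must be >= 1")
    return [base + k * shift for k in range(max_sites + 1)]


def match_shift(
    peaks: list[MassPeak],
    base: float,
    candidates: list[CompoundRecord],
    tol: float = 1.0,
    max_sites: int = 1,
) -> list[ShiftMatch]:
    """Match observed protein mass shifts to candidate adducts.

    For each peak the observed shift is ``peak.mass - base``. Every
    candidate contributes predicted average shifts ``k * adduct`` for
    ``k = 1..max_sites`` (multiply modified protein); the candidate/site
    combination minimizing the absolute error wins, and the match is kept
    only if ``|error| <= tol`` Da. Peaks with no candidate within tolerance
    (including the base peak itself) are returned unmatched.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not candidates:
        raise ValueError("empty candidate list")

    predictions: list[tuple[str, float]] = []
    for cand in candidates:
        _, avg = adduct_shift(cand)
        for k in range(1, max_sites + 1):
            label = cand.id if k == 1 else f"{cand.id} x{k}"
            predictions.append((label, k * avg))

    out: list[ShiftMatch] = []
    for peak in peaks:
        obs = peak.mass - base
        best_id, best_pred, best_err = "", math.nan, math.inf
        for cid, pred in predictions:
            err = obs - pred
            if abs(err) < abs(best_err):
                best_id, best_pred, best_err = cid, pred, err
        if abs(best_err) <= tol:
            ppm = best_err / (base + best_pred) * 1e6
            out.append(ShiftMatch(peak, obs, best_id, best_pred, best_err, ppm))
        else:
            out.append(ShiftMatch(peak, obs, ""))
    return out
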