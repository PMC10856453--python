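"""Molecular-formula chemistry for negative-mode PFAS screening.

Everything downstream — suspect matching, ppm errors, Kendrick mass-defect
filtering, CF2 homologue detection — rests on the exact masses defined here.
The element table is deliberately small: PFAS formulas in suspect lists are
built from C, H, N, O, F, P, S and Cl, and restricting the alphabet lets the
parser reject typos loudly instead of silently accepting exotic symbols.

Conventions
-----------
* Deprotonation: m/z([M-H]-) = M - 1.00727646 Da, i.e. a proton is removed
  and the electron mass stays with the ion.  This is the convention that
  reproduces curated PFAS mass errors in negative-mode Orbitrap data.
* Kendrick rescaling uses the exact monoisotopic CF2 mass 49.9968064 Da
  against a nominal repeat-unit mass of 50, so CF2 homologues share a
  Kendrick mass defect to numerical precision.  Fluorine-rich ions come out
  slightly negative; hydrogen-rich organics positive.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "CF2_EXACT_MASS",
    "CF2_NOMINAL_MASS",
    "ElementComposition",
    "FormulaError",
    "KendrickResult",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "deprotonated_mz",
    "ppm_error",
    "kendrick",
]

#: Exact monoisotopic masses (Da) of the supported elements.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984032,
    "P": 30.97376151,
    "S": 31.97207069,
    "Cl": 34.96885271,
}

#: Mass of a proton (Da); removed on deprotonation.
PROTON_MASS = 1.00727646

#: Exact monoisotopic mass of one CF2 repeat unit (C + 2 F).
CF2_EXACT_MASS = MONOISOTOPIC_MASS["C"] + 2 * MONOISOTOPIC_MASS["F"]  # 49.9968064

#: Nominal (integer) mass of the CF2 repeat unit.
CF2_NOMINAL_MASS = 50

# Hill order: C first, H second, remaining elements alphabetical.
_HILL_ORDER = ("C", "H", "Cl", "F", "N", "O", "P", "S")

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_MARKUP_RE = re.compile(r"[_\s]+")


class FormulaError(ValueError):
    """Raised when a molecular-formula string cannot be interpreted."""


@dataclass(frozen=True)
class ElementComposition:
    """Immutable element -> count map for a neutral molecular formula.

    Counts are strictly positive; absent elements are simply not present in
    the mapping.  Only the elements in :data:`MONOISOTOPIC_MASS` are allowed.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise FormulaError("empty composition is invalid")
        clean = {}
        for sym, n in self.counts.items():
            if sym not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unsupported element symbol: {sym!r}")
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {sym} must be a positive integer, got {n!r}")
            clean[sym] = n
        object.__setattr__(self, "counts", dict(clean))

    def __getitem__(self, sym: str) -> int:
        return self.counts.get(sym, 0)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementComposition):
            return dict(self.counts) == dict(other.counts)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementComposition(merged)

    def hill_formula(self) -> str:
        """Canonical Hill-order formula string (C, H, then alphabetical)."""
        parts = []
        for sym in _HILL_ORDER:
            n = self[sym]
            if n == 1:
                parts.append(sym)
            elif n > 1:
                parts.append(f"{sym}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill_formula()


@dataclass(frozen=True)
class KendrickResult:
    """Kendrick mass and mass defect of one m/z value.

    ``kmd = kendrick_mass - round(kendrick_mass)`` lies in (-0.5, +0.5];
    members of a CF2 homologous series share the same kmd.
    """

    kendrick_mass: float
    kmd: float


def parse_formula(text: str) -> ElementComposition:
    """Parse a molecular formula string into an :class:`ElementComposition`.

    Underscores and whitespace (subscript markup artifacts such as
    ``C_8_HF_17_O_3_S``) are stripped before tokenizing.  Unknown element
    symbols and malformed tokens raise :class:`FormulaError` naming the
    offending token and its position.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("formula string is empty")
    clean = _MARKUP_RE.sub("", text)
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(clean):
        m = _TOKEN_RE.match(clean, pos)
        if m is None or not m.group(1):
            raise FormulaError(
                f"malformed token at position {pos} in {clean!r}: {clean[pos:pos + 2]!r}"
            )
        sym, digits = m.groups()
        if sym not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unsupported element symbol {sym!r} in {clean!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {sym!r} at position {pos} in {clean!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return ElementComposition(counts)


def monoisotopic_mass(comp: ElementComposition) -> float:
    """Neutral monoisotopic mass (Da) of a composition."""
    return sum(MONOISOTOPIC_MASS[sym] * n for sym, n in comp.counts.items())


def adduct_mz(neutral_mass: float, adduct: str = "[M-H]-") -> float:
    """m/z of the given adduct of a neutral molecule.

    Only the deprotonated ion ``[M-H]-`` is supported: the proton is removed
    and the electron retained, so m/z = M - 1.00727646.
    """
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if adduct != "[M-H]-":
        raise ValueError(f"unsupported adduct {adduct!r}; only '[M-H]-' is implemented")
    return neutral_mass - PROTON_MASS


def deprotonated_mz(comp: ElementComposition) -> float:
    """Theoretical [M-H]- m/z of a composition.

    Compositions without hydrogen (e.g. perfluorinated esters) still return
    M - proton, matching how such species are reported in negative mode, but
    a warning is emitted because a genuine deprotonation site is absent.
    """
    if comp["H"] == 0:
        warnings.warn(
            f"composition {comp.hill_formula()} has no hydrogen; "
            "[M-H]- m/z computed as M - proton regardless",
            stacklevel=2,
        )
    return adduct_mz(monoisotopic_mass(comp))


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical_mz}")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


def kendrick(
    mz: float,
    base_nominal: int = CF2_NOMINAL_MASS,
    base_exact: float = CF2_EXACT_MASS,
) -> KendrickResult:
    """Kendrick mass and mass defect of an m/z value on a CF2 basis.

    ``kendrick_mass = mz * base_nominal / base_exact`` rescales the mass
    axis so the repeat unit has integer mass; the defect is the signed
    distance to the nearest integer.  Round-half-to-even at the .5 boundary
    follows :func:`round`.
    """
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    if base_exact <= 0 or base_nominal <= 0:
        raise ValueError("Kendrick base masses must be positive")
    km = mz * base_nominal / base_exact
    kmd = km - round(km)
    # round() guarantees |kmd| <= 0.5; normalize the -0.5 edge into (+0.5].
    if math.isclose(kmd, -0.5):
        kmd = 0.5
    return KendrickResult(kendrick_mass=km, kmd=kmd)
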