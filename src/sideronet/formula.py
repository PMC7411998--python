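"""Exact-mass arithmetic on small-molecule formulas.

Provides :class:`MolecularFormula` (element counts + charge), adduct m/z,
signed ppm errors, ring-plus-double-bond equivalents (RDBE), and bounded
CHNO formula enumeration for assigning formulas to accurate masses.

All masses come from :mod:`sideronet.constants`.  By default, m/z of charged
species is computed with the proton counted as a neutral hydrogen atom (no
electron-mass correction), the convention under which printed "calculated
[M+H]+" values in natural-product papers are reproduced to four decimals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .constants import ELECTRON_MASS, MONOISOTOPIC_MASS

__all__ = [
    "MolecularFormula",
    "AdductSpec",
    "MassTolerance",
    "M_PLUS_H",
    "M_PLUS_NA",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "rdbe",
    "enumerate_formulas",
]

_HILL_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _hill_order(element: str) -> tuple[int, str]:
    # Hill convention: C first, H second, all other elements alphabetical.
    return {"C": (0, ""), "H": (1, "")}.get(element, (2, element))


@dataclass(frozen=True)
class MolecularFormula:
    """Immutable element-count vector with an integer charge.

    ``counts`` maps element symbols to non-negative integers; zero counts are
    dropped on construction.  Arithmetic is element-wise and charge-aware.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for element, n in self.counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element: {element!r}")
            if n < 0:
                raise ValueError(f"negative count for {element}: {n}")
            if int(n) != n:
                raise ValueError(f"non-integer count for {element}: {n}")
            if n:
                clean[element] = int(n)
        object.__setattr__(self, "counts", dict(sorted(clean.items())))

    # -- construction -----------------------------------------------------
    @classmethod
    def from_string(cls, text: str, charge: int = 0) -> "MolecularFormula":
        """Parse Hill-notation text such as ``"C27H50N6O6"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _HILL_TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
            pos = match.end()
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
        return cls(counts, charge)

    def to_string(self) -> str:
        """Serialize in Hill notation; round-trips exactly via from_string."""
        parts = []
        for element in sorted(self.counts, key=_hill_order):
            n = self.counts[element]
            parts.append(element + (str(n) if n != 1 else ""))
        return "".join(parts)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.counts)
        for element, n in other.counts.items():
            counts[element] = counts.get(element, 0) + n
        return MolecularFormula(counts, self.charge + other.charge)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.counts)
        for element, n in other.counts.items():
            new = counts.get(element, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction would give negative {element} count "
                    f"({self.to_string()} - {other.to_string()})"
                )
            counts[element] = new
        return MolecularFormula(counts, self.charge - other.charge)

    def __mul__(self, k: int) -> "MolecularFormula":
        if k < 0:
            raise ValueError("cannot multiply formula by a negative integer")
        return MolecularFormula({e: n * k for e, n in self.counts.items()}, self.charge * k)

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.to_string()

    def __hash__(self) -> int:
        return hash((tuple(self.counts.items()), self.charge))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return self.counts == other.counts and self.charge == other.charge

    def replace_charge(self, charge: int) -> "MolecularFormula":
        return MolecularFormula(self.counts, charge)


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: a formula delta plus a charge delta."""

    name: str
    delta: MolecularFormula
    charge_delta: int

    def apply(self, neutral: MolecularFormula) -> MolecularFormula:
        if neutral.charge != 0:
            raise ValueError("adducts apply to neutral formulas only")
        ion = neutral + self.delta
        ion = ion.replace_charge(neutral.charge + self.charge_delta)
        if ion.charge == 0:
            raise ValueError(f"adduct {self.name} yields an uncharged species")
        return ion


M_PLUS_H = AdductSpec("[M+H]+", MolecularFormula({"H": 1}), +1)
M_PLUS_NA = AdductSpec("[M+Na]+", MolecularFormula({"Na": 1}), +1)

ADDUCTS: dict[str, AdductSpec] = {a.name: a for a in (M_PLUS_H, M_PLUS_NA)}


@dataclass(frozen=True)
class MassTolerance:
    """A mass tolerance, either relative (ppm) or absolute (Da)."""

    value: float
    unit: str = "ppm"

    def __post_init__(self) -> None:
        if self.unit not in ("ppm", "Da"):
            raise ValueError(f"tolerance unit must be 'ppm' or 'Da', got {self.unit!r}")
        if self.value <= 0:
            raise ValueError("tolerance must be positive")

    def halfwidth_da(self, at_mz: float) -> float:
        """Absolute half-width in Da at the given m/z."""
        if self.unit == "Da":
            return self.value
        return self.value * 1e-6 * at_mz


def monoisotopic_mass(f: MolecularFormula, electron_correction: bool = False) -> float:
    """Monoisotopic mass in Da (sum over most-abundant-isotope masses).

    With ``electron_correction`` the electron mass is subtracted per positive
    charge (added per negative charge); off by default so that calculated
    [M+H]+ values match the proton-as-neutral-H convention.
    """
    mass = sum(MONOISOTOPIC_MASS[e] * n for e, n in f.counts.items())
    if electron_correction:
        mass -= f.charge * ELECTRON_MASS
    return mass


def adduct_mz(
    neutral: MolecularFormula,
    adduct: AdductSpec = M_PLUS_H,
    electron_correction: bool = False,
) -> float:
    """m/z of the adduct ion of a neutral formula."""
    ion = adduct.apply(neutral)
    return monoisotopic_mass(ion, electron_correction) / abs(ion.charge)


def ppm_error(observed: float, calculated: float) -> float:
    """Signed relative error in ppm; the calculated mass is the denominator."""
    if calculated <= 0:
        raise ValueError("calculated mass must be positive")
    return 1e6 * (observed - calculated) / calculated


def rdbe(f: MolecularFormula) -> float:
    """Ring-plus-double-bond equivalents: C - (H + Na)/2 + N/2 + 1.

    Monovalent Na is counted like H.  The result may be half-integral for
    odd-electron/odd-nitrogen species; a valid even-electron neutral CHNO
    molecule has an integer RDBE >= 0.
    """
    return f["C"] - (f["H"] + f["Na"]) / 2 + f["N"] / 2 + 1


#: Default element bounds for formula enumeration (min, max).
DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {
    "C": (0, 40),
    "H": (0, 80),
    "N": (0, 10),
    "O": (0, 12),
}


def _ratio_sane(f: MolecularFormula) -> bool:
    c = f["C"]
    if c == 0:
        return False
    hc = f["H"] / c
    return 0.5 <= hc <= 3.0 and f["N"] <= c and f["O"] <= c


def enumerate_formulas(
    target_mz: float,
    adduct: AdductSpec = M_PLUS_H,
    tol: MassTolerance = MassTolerance(5.0, "ppm"),
    bounds: Mapping[str, tuple[int, int]] | None = None,
    require_integer_rdbe: bool = False,
    require_ratio_sanity: bool = False,
) -> list[MolecularFormula]:
    """Exhaustively enumerate neutral CHNO(Na) formulas matching a target m/z.

    Nested loops run over C, N, O (and Na when bounded above zero); the H
    count is solved from the residual mass window, which makes the search
    exact and fast at desk scale.  Results are sorted by ``|ppm error|`` with
    ties broken by lower RDBE and then by element counts.

    Optional chemical filters: integer-valued RDBE >= 0 (nitrogen rule for
    even-electron neutrals) and elemental-ratio sanity (H/C in [0.5, 3],
    N <= C, O <= C).
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    for element in bounds:
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element in bounds: {element!r}")
    lo = {e: bounds.get(e, (0, 0))[0] for e in ("C", "H", "N", "O", "Na")}
    hi = {e: bounds.get(e, (0, 0))[1] for e in ("C", "H", "N", "O", "Na")}

    ion_charge = abs(adduct.charge_delta)
    delta_mass = monoisotopic_mass(adduct.delta)
    half = tol.halfwidth_da(target_mz) * ion_charge
    # neutral-mass window implied by the target ion m/z
    neutral_target = target_mz * ion_charge - delta_mass

    m = MONOISOTOPIC_MASS
    out: list[MolecularFormula] = []
    for c in range(lo["C"], hi["C"] + 1):
        mass_c = c * m["C"]
        if mass_c - half > neutral_target:
            break
        for n in range(lo["N"], hi["N"] + 1):
            mass_cn = mass_c + n * m["N"]
            if mass_cn - half > neutral_target:
                break
            for o in range(lo["O"], hi["O"] + 1):
                mass_cno = mass_cn + o * m["O"]
                if mass_cno - half > neutral_target:
                    break
                for na in range(lo["Na"], hi["Na"] + 1):
                    residual = neutral_target - mass_cno - na * m["Na"]
                    h_center = residual / m["H"]
                    for h in {int(h_center), int(h_center) + 1}:
                        if h < lo["H"] or h > hi["H"] or h < 0:
                            continue
                        counts = {"C": c, "H": h, "N": n, "O": o, "Na": na}
                        f = MolecularFormula(counts)
                        if not f:
                            continue
                        mz = adduct_mz(f, adduct)
                        if abs(mz - target_mz) > tol.halfwidth_da(target_mz):
                            continue
                        if require_integer_rdbe:
                            r = rdbe(f)
                            if r < 0 or r != int(r):
                                continue
                        if require_ratio_sanity and not _ratio_sane(f):
                            continue
                        out.append(f)

    def sort_key(f: MolecularFormula):
        return (
            abs(ppm_error(target_mz, adduct_mz(f, adduct))),
            rdbe(f),
            tuple(sorted(f.counts.items())),
        )

    out.sort(key=sort_key)
    return out
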