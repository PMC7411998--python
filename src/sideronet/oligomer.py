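"""Desferrioxamine-type oligomer assembly and in-silico amide fragmentation.

Hydroxamate siderophores of the desferrioxamine family are condensation
oligomers of four biosynthetic building blocks: an acetyl cap (acetic acid),
a succinyl unit (succinic acid), cadaverine (1,5-diaminopentane, from lysine
decarboxylation) and N-hydroxy-cadaverine.  Each amide bond between an acid
carbonyl and a diamine nitrogen condenses out one water.  This module
assembles candidate structures from those blocks, computes their molecular
formulas, enumerates all structures consistent with an observed precursor
m/z, and generates the singly-charged b-type (acylium) / y-type (protonated
amine) fragments expected from cleavage of each amide bond.

N-hydroxylation is modelled as a per-diamine-unit decoration: in a
hydroxamate the hydroxylated nitrogen is the acylated one, so carrying the
flag on the diamine unit distinguishes the positional isomers that matter
for dehydroxylated congeners while keeping the combinatorics small.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .constants import MASS_H, MASS_H2O
from .formula import (
    AdductSpec,
    M_PLUS_H,
    MassTolerance,
    MolecularFormula,
    adduct_mz,
    monoisotopic_mass,
    ppm_error,
)

__all__ = [
    "BuildingBlock",
    "BLOCKS",
    "OligomerStructure",
    "Fragment",
    "assemble_formula",
    "enumerate_candidates",
    "in_silico_fragments",
    "candidate_report",
]

_F = MolecularFormula.from_string


@dataclass(frozen=True)
class BuildingBlock:
    """A biosynthetic monomer in its free (uncondensed) form."""

    name: str
    formula: MolecularFormula
    kind: str  # "cap" (monoacid), "diacid", or "diamine"
    n_hydroxylated: bool = False

    @property
    def is_acid(self) -> bool:
        return self.kind in ("cap", "diacid")


#: The bundled block registry.  Free formulas are the uncondensed acids /
#: amines; every amide condensation removes one H2O.
BLOCKS: dict[str, BuildingBlock] = {
    "Ac": BuildingBlock("Ac", _F("C2H4O2"), "cap"),
    "succ": BuildingBlock("succ", _F("C4H6O4"), "diacid"),
    "cad": BuildingBlock("cad", _F("C5H14N2"), "diamine"),
    "cad(OH)": BuildingBlock("cad(OH)", _F("C5H14N2O"), "diamine", n_hydroxylated=True),
}

H2O = _F("H2O")
OH = _F("HO")
H = _F("H")


class InvalidStructureError(ValueError):
    pass


@dataclass(frozen=True)
class OligomerStructure:
    """An ordered chain (or cycle) of building blocks joined by amide bonds.

    Valid structures alternate acid units (caps/diacids) with diamine units;
    caps may appear only at the termini of linear chains.  A linear chain of
    n blocks has n-1 amide bonds, a cycle of n blocks has n bonds.
    """

    blocks: tuple[str, ...]
    topology: str = "linear"  # or "cyclic"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "cyclic"):
            raise InvalidStructureError(f"unknown topology {self.topology!r}")
        if not self.blocks:
            raise InvalidStructureError("empty structure")
        for b in self.blocks:
            if b not in BLOCKS:
                raise InvalidStructureError(f"unknown building block {b!r}")
        n = len(self.blocks)
        pairs = list(zip(range(n - 1), range(1, n)))
        if self.topology == "cyclic":
            if n < 2 or n % 2:
                raise InvalidStructureError("cyclic structures need an even block count")
            if any(BLOCKS[b].kind == "cap" for b in self.blocks):
                raise InvalidStructureError("cyclic structures cannot contain caps")
            pairs.append((n - 1, 0))
        else:
            for i, b in enumerate(self.blocks):
                if BLOCKS[b].kind == "cap" and i not in (0, n - 1):
                    raise InvalidStructureError(f"cap {b!r} at interior position {i}")
        for i, j in pairs:
            a, b = BLOCKS[self.blocks[i]], BLOCKS[self.blocks[j]]
            if a.is_acid == b.is_acid:
                raise InvalidStructureError(
                    f"invalid junction {self.blocks[i]}-{self.blocks[j]} "
                    f"at bond {i}: amides form between an acid and a diamine"
                )

    # -- basic properties ---------------------------------------------------
    @property
    def n_bonds(self) -> int:
        return len(self.blocks) - (1 if self.topology == "linear" else 0)

    @property
    def n_oh(self) -> int:
        return sum(1 for b in self.blocks if BLOCKS[b].n_hydroxylated)

    @property
    def skeleton(self) -> tuple[str, ...]:
        """Block sequence with N-OH decorations stripped."""
        return tuple("cad" if b == "cad(OH)" else b for b in self.blocks)

    def to_string(self) -> str:
        body = "|".join(self.blocks)
        return f"cyclo[{body}]" if self.topology == "cyclic" else body

    @classmethod
    def from_string(cls, text: str) -> "OligomerStructure":
        topology = "linear"
        if text.startswith("cyclo[") and text.endswith("]"):
            topology, text = "cyclic", text[6:-1]
        return cls(tuple(text.split("|")), topology)

    def canonical(self) -> "OligomerStructure":
        """Canonical representative under reading-direction / rotation symmetry.

        Linear chains are read in the lexicographically smaller direction;
        cycles take the minimal sequence over all rotations and reflections.
        """
        if self.topology == "linear":
            rev = tuple(reversed(self.blocks))
            return self if self.blocks <= rev else OligomerStructure(rev, "linear")
        best = None
        n = len(self.blocks)
        for seq in (self.blocks, tuple(reversed(self.blocks))):
            for r in range(n):
                rot = seq[r:] + seq[:r]
                if best is None or rot < best:
                    best = rot
        return OligomerStructure(best, "cyclic")


def assemble_formula(s: OligomerStructure) -> MolecularFormula:
    """Neutral molecular formula: sum of free blocks minus one H2O per bond."""
    total = MolecularFormula()
    for b in s.blocks:
        total = total + BLOCKS[b].formula
    return total - s.n_bonds * H2O


@dataclass(frozen=True)
class Fragment:
    """A singly-charged in-silico cleavage fragment."""

    formula: MolecularFormula  # ion formula (charge +1)
    mz: float
    ion_type: str  # "b" (acylium) or "y" (protonated amine)
    cleavage: str  # human-readable cleavage-site description


def _linear_fragments(blocks: Sequence[str], tag: str = "") -> list[Fragment]:
    out = []
    n = len(blocks)
    prefix_sums: list[MolecularFormula] = []
    acc = MolecularFormula()
    for b in blocks:
        acc = acc + BLOCKS[b].formula
        prefix_sums.append(acc)
    total = prefix_sums[-1]
    for i in range(n - 1):
        # neutral acid piece / neutral amine piece of the cleaved amide
        left = prefix_sums[i] - i * H2O
        right = (total - prefix_sums[i]) - (n - 2 - i) * H2O
        left_is_acyl = BLOCKS[blocks[i]].is_acid
        acyl, amine = (left, right) if left_is_acyl else (right, left)
        side = "prefix" if left_is_acyl else "suffix"
        where = f"{tag}bond{i}:{blocks[i]}-{blocks[i + 1]}"
        b_ion = (acyl - OH).replace_charge(+1)
        y_ion = (amine + H).replace_charge(+1)
        out.append(Fragment(b_ion, monoisotopic_mass(b_ion), "b", f"b/{side}@{where}"))
        out.append(Fragment(y_ion, monoisotopic_mass(y_ion), "y", f"y@{where}"))
    return out


def _internal_fragments(blocks: Sequence[str]) -> list[Fragment]:
    """Double-cleavage (internal) ions of a linear chain.

    A contiguous interior run of blocks, released by cleaving the amide on
    each side, is observed as an acylium when it retains a carbonyl end
    (neutral piece minus OH) or as the protonated free amine when both ends
    are diamine nitrogens — e.g. protonated cadaverine at m/z 103.123, a
    hallmark ion of desferrioxamine-type spectra.
    """
    out: list[Fragment] = []
    n = len(blocks)
    for i in range(1, n - 1):
        piece_sum = MolecularFormula()
        for j in range(i, n - 1):
            piece_sum = piece_sum + BLOCKS[blocks[j]].formula
            piece = piece_sum - (j - i) * H2O
            left_acyl = BLOCKS[blocks[i]].is_acid
            right_acyl = BLOCKS[blocks[j]].is_acid
            where = f"internal@{i}-{j}:{'|'.join(blocks[i:j + 1])}"
            if left_acyl or right_acyl:
                ion = (piece - OH).replace_charge(+1)
                out.append(Fragment(ion, monoisotopic_mass(ion), "internal-b", where))
            else:
                ion = (piece + H).replace_charge(+1)
                out.append(Fragment(ion, monoisotopic_mass(ion), "internal-y", where))
    return out


def in_silico_fragments(
    s: OligomerStructure,
    adduct: AdductSpec = M_PLUS_H,
    deduplicate: bool = True,
    water_loss: bool = False,
    internal: bool = False,
) -> list[Fragment]:
    """b/y fragments from cleaving each amide bond of a (protonated) oligomer.

    For each bond, the acyl side yields a b-type acylium (neutral acid minus
    OH) and the amine side a y-type protonated amine (neutral plus H), both
    singly charged, with m/z under the no-electron-correction convention.
    Cyclic structures are ring-opened at each amide in turn and the resulting
    linear chains fragmented; the union is returned.  When ``deduplicate`` is
    set (the default), fragments are unique by ion formula; pass False to see
    every cleavage channel, e.g. to weight positions fed by several channels.

    With ``water_loss`` each b/y ion carrying at least two oxygens also
    yields its -H2O satellite (ubiquitous in collision-induced dissociation
    of hydroxamates/amides); with ``internal`` linear chains additionally
    yield double-cleavage internal ions.  Both are off by default so that the
    minimal single-cleavage b/y set remains the reference fragment chemistry
    for annotation; the synthetic-spectra generator switches them on to match
    the richness of real spectra.
    """
    if adduct is not M_PLUS_H:
        raise NotImplementedError("fragments are modelled for [M+H]+ precursors only")
    if s.topology == "linear":
        raw = _linear_fragments(s.blocks)
        if internal:
            raw.extend(_internal_fragments(s.blocks))
    else:
        raw = []
        n = len(s.blocks)
        for r in range(n):
            rotated = s.blocks[r:] + s.blocks[:r]
            raw.extend(_linear_fragments(rotated, tag=f"open{r}/"))
    if water_loss:
        satellites = []
        for frag in raw:
            if frag.formula["O"] >= 2:
                ion = frag.formula - H2O.replace_charge(0)
                satellites.append(
                    Fragment(
                        ion,
                        monoisotopic_mass(ion),
                        frag.ion_type + "-H2O",
                        frag.cleavage + "-H2O",
                    )
                )
        raw = raw + satellites
    if not deduplicate:
        return raw
    seen: dict[MolecularFormula, Fragment] = {}
    for frag in raw:
        seen.setdefault(frag.formula, frag)
    return sorted(seen.values(), key=lambda f: f.mz)


def _mask_placements(n_diamines: int, n_oh: int) -> Iterable[tuple[bool, ...]]:
    from itertools import combinations

    for idx in combinations(range(n_diamines), n_oh):
        mask = [False] * n_diamines
        for i in idx:
            mask[i] = True
        yield tuple(mask)


def _decorate(skeleton: Sequence[str], mask: Sequence[bool]) -> tuple[str, ...]:
    out, d = [], 0
    for b in skeleton:
        if b == "cad":
            out.append("cad(OH)" if mask[d] else "cad")
            d += 1
        else:
            out.append(b)
    return tuple(out)


def enumerate_candidates(
    target_mz: float,
    adduct: AdductSpec = M_PLUS_H,
    tol: MassTolerance = MassTolerance(10.0, "ppm"),
    max_blocks: int = 12,
) -> list[OligomerStructure]:
    """All linear/cyclic block assemblies whose adduct m/z matches a target.

    Structures are unique up to symmetry (canonical reading direction /
    rotation) and are returned sorted by |ppm error| of their calculated
    adduct m/z, then by structure string.  Every N-OH placement consistent
    with the mass is reported as a distinct candidate.
    """
    if max_blocks > 12:
        raise ValueError("max_blocks > 12 is outside the supported desk scale")
    half = tol.halfwidth_da(target_mz)
    m_cad = monoisotopic_mass(BLOCKS["cad"].formula)
    m_succ = monoisotopic_mass(BLOCKS["succ"].formula)
    m_ac = monoisotopic_mass(BLOCKS["Ac"].formula)
    m_o = monoisotopic_mass(MolecularFormula({"O": 1}))
    delta_mass = monoisotopic_mass(adduct.delta)
    charge = abs(adduct.charge_delta)

    found: set[OligomerStructure] = set()

    def mass_ok(n_cad: int, n_succ: int, n_ac: int, n_oh: int, n_bonds: int) -> bool:
        neutral = (
            n_cad * m_cad + n_succ * m_succ + n_ac * m_ac + n_oh * m_o - n_bonds * MASS_H2O
        )
        mz = (neutral + delta_mass) / charge
        return abs(mz - target_mz) <= half

    # linear skeletons: diamines alternate with diacids, so the diacid count
    # is d-1, d, or d+1; acetyl caps may occupy free amine termini.
    for d in range(1, max_blocks + 1):
        for a in (d - 1, d, d + 1):
            if a < 0:
                continue
            free_amine_ends = {d - 1: 2, d: 1, d + 1: 0}[a]
            for caps in range(free_amine_ends + 1):
                n_blocks = d + a + caps
                if n_blocks > max_blocks or n_blocks < 2:
                    continue
                for n_oh in range(d + 1):
                    if not mass_ok(d, a, caps, n_oh, n_blocks - 1):
                        continue
                    for skeleton in _linear_skeletons(d, a, caps):
                        for mask in _mask_placements(d, n_oh):
                            s = OligomerStructure(_decorate(skeleton, mask), "linear")
                            found.add(s.canonical())

    # cyclic skeletons: equal counts, no caps
    for k in range(1, max_blocks // 2 + 1):
        skeleton = ("succ", "cad") * k
        for n_oh in range(k + 1):
            if not mass_ok(k, k, 0, n_oh, 2 * k):
                continue
            for mask in _mask_placements(k, n_oh):
                s = OligomerStructure(_decorate(skeleton, mask), "cyclic")
                found.add(s.canonical())

    def sort_key(s: OligomerStructure):
        err = abs(ppm_error(target_mz, adduct_mz(assemble_formula(s), adduct)))
        return (err, s.to_string())

    return sorted(found, key=sort_key)


def _linear_skeletons(d: int, a: int, caps: int) -> list[tuple[str, ...]]:
    """Undecorated linear block orders for given diamine/diacid/cap counts."""
    if a == d - 1:
        core = ("cad",) + ("succ", "cad") * (d - 1)
        if caps == 0:
            return [core]
        if caps == 1:
            return [("Ac",) + core]
        return [("Ac",) + core + ("Ac",)]
    if a == d:
        core = ("succ", "cad") * d  # acid terminus on the left
        if caps == 0:
            return [core]
        return [core + ("Ac",)]  # cap on the single free amine terminus
    core = ("succ", "cad") * d + ("succ",)
    return [core]


def candidate_report(
    target_mz: float,
    candidates: Sequence[OligomerStructure],
    adduct: AdductSpec = M_PLUS_H,
):
    """Tabulate candidates as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for s in candidates:
        f = assemble_formula(s)
        mz = adduct_mz(f, adduct)
        rows.append(
            {
                "structure": s.to_string(),
                "formula": f.to_string(),
                "calc_mz": round(mz, 4),
                "ppm": round(ppm_error(target_mz, mz), 2),
                "n_oh": s.n_oh,
                "topology": s.topology,
            }
        )
    return pd.DataFrame(
        rows, columns=["structure", "formula", "calc_mz", "ppm", "n_oh", "topology"]
    )
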