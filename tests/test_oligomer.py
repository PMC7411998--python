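"""Building-block assembly, candidate enumeration, and in-silico
amide-cleavage fragmentation."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from sideronet.constants import MASS_H, MASS_O
from sideronet.formula import (
    M_PLUS_H,
    MassTolerance,
    MolecularFormula,
    adduct_mz,
    monoisotopic_mass,
)
from sideronet.oligomer import (
    BLOCKS,
    InvalidStructureError,
    OligomerStructure,
    assemble_formula,
    enumerate_candidates,
    in_silico_fragments,
)

F = MolecularFormula.from_string
S = OligomerStructure.from_string

SPEIBONOXAMINE = S("Ac|cad|succ|cad|succ|cad|Ac")
DESOXY_DFO_D1 = S("Ac|cad|succ|cad(OH)|succ|cad(OH)|Ac")
DFO_D1 = S("Ac|cad(OH)|succ|cad(OH)|succ|cad(OH)|Ac")
NOCARDAMINE = S("cyclo[cad(OH)|succ|cad(OH)|succ|cad(OH)|succ]")


class TestRegistry:
    def test_bundled_blocks(self):
        assert BLOCKS["Ac"].formula == F("C2H4O2")
        assert BLOCKS["succ"].formula == F("C4H6O4")
        assert BLOCKS["cad"].formula == F("C5H14N2")
        assert BLOCKS["cad(OH)"].formula == F("C5H14N2O")
        assert BLOCKS["cad(OH)"].n_hydroxylated


class TestAssembly:
    @pytest.mark.parametrize(
        "structure, expected",
        [
            # di-acetyl series: 0..3 N-OH
            ("Ac|cad|succ|cad|succ|cad|Ac", "C27H50N6O6"),
            ("Ac|cad|succ|cad|succ|cad(OH)|Ac", "C27H50N6O7"),
            ("Ac|cad|succ|cad(OH)|succ|cad(OH)|Ac", "C27H50N6O8"),
            ("Ac|cad(OH)|succ|cad(OH)|succ|cad(OH)|Ac", "C27H50N6O9"),
            # mono-acetyl (free amine) series
            ("Ac|cad(OH)|succ|cad(OH)|succ|cad(OH)", "C25H48N6O8"),
            ("Ac|cad(OH)|succ|cad(OH)|succ|cad", "C25H48N6O7"),
            # cyclic trimer series
            ("cyclo[cad|succ|cad(OH)|succ|cad(OH)|succ]", "C27H48N6O8"),
            ("cyclo[cad(OH)|succ|cad(OH)|succ|cad(OH)|succ]", "C27H48N6O9"),
        ],
    )
    def test_known_compositions(self, structure, expected):
        assert assemble_formula(S(structure)) == F(expected)

    def test_bond_count(self):
        assert SPEIBONOXAMINE.n_bonds == 6
        assert NOCARDAMINE.n_bonds == 6

    @pytest.mark.parametrize(
        "blocks, topology",
        [
            (("Ac", "succ", "cad"), "linear"),  # acid-acid junction
            (("cad", "cad"), "linear"),  # amine-amine junction
            (("Ac", "cad", "Ac", "cad"), "linear"),  # interior cap
            (("succ", "cad", "succ"), "cyclic"),  # odd cycle
            (("Ac", "cad"), "cyclic"),  # cap in cycle
        ],
    )
    def test_invalid_structures_rejected(self, blocks, topology):
        with pytest.raises(InvalidStructureError):
            OligomerStructure(blocks, topology)

    def test_invalid_junction_is_named(self):
        with pytest.raises(InvalidStructureError, match="bond 0"):
            OligomerStructure(("succ", "Ac"), "linear")

    def test_n_oh_monotonicity(self):
        base = assemble_formula(SPEIBONOXAMINE)
        one_oh = assemble_formula(S("Ac|cad(OH)|succ|cad|succ|cad|Ac"))
        assert one_oh - base == F("O")
        assert monoisotopic_mass(one_oh) - monoisotopic_mass(base) == pytest.approx(
            MASS_O, abs=1e-9
        )


class TestCanonicalization:
    def test_linear_reading_direction(self):
        a = S("Ac|cad(OH)|succ|cad|succ|cad|Ac")
        b = S("Ac|cad|succ|cad|succ|cad(OH)|Ac")
        assert a.canonical() == b.canonical()

    def test_cyclic_rotation_reflection(self):
        seqs = [
            ("succ", "cad", "succ", "cad(OH)", "succ", "cad(OH)"),
            ("cad(OH)", "succ", "cad", "succ", "cad(OH)", "succ"),
        ]
        canon = {OligomerStructure(s, "cyclic").canonical() for s in seqs}
        assert len(canon) == 1


class TestEnumeration:
    def test_didesoxy_dfo_d1_target(self):
        hits = enumerate_candidates(571.3807, M_PLUS_H, MassTolerance(10, "ppm"))
        d1_skeleton = [
            s for s in hits if s.skeleton == SPEIBONOXAMINE.skeleton and s.n_oh == 1
        ]
        assert d1_skeleton
        assert all(assemble_formula(s) == F("C27H50N6O7") for s in d1_skeleton)

    def test_desoxy_dfo_b_target(self):
        hits = enumerate_candidates(545.3654, M_PLUS_H, MassTolerance(10, "ppm"))
        mono_acetyl = [
            s
            for s in hits
            if sorted(s.skeleton).count("Ac") == 1 and s.n_oh == 2
        ]
        assert mono_acetyl
        assert all(assemble_formula(s) == F("C25H48N6O7") for s in mono_acetyl)

    def test_below_assemblable_mass(self):
        assert enumerate_candidates(100.0, M_PLUS_H, MassTolerance(10, "ppm")) == []

    @pytest.mark.parametrize(
        "structure",
        [
            "Ac|cad|succ|cad|succ|cad|Ac",
            "Ac|cad(OH)|succ|cad(OH)|succ|cad(OH)",
            "cyclo[cad(OH)|succ|cad(OH)|succ|cad(OH)|succ]",
            "Ac|cad",
            "succ|cad|succ",
        ],
    )
    def test_round_trip_recovery(self, structure):
        s = S(structure).canonical()
        target = adduct_mz(assemble_formula(s), M_PLUS_H)
        hits = enumerate_candidates(target, M_PLUS_H, MassTolerance(1, "ppm"))
        assert s in hits

    def test_desk_scale_guard(self):
        with pytest.raises(ValueError):
            enumerate_candidates(555.0, max_blocks=13)


class TestFragmentation:
    def test_diagnostic_fragment_in_speibonoxamine(self):
        frags = {f.formula: f for f in in_silico_fragments(SPEIBONOXAMINE)}
        diag = F("C20H35N4O5").replace_charge(+1)
        assert diag in frags
        assert abs(frags[diag].mz - 411.2596) < 2e-3
        assert frags[diag].ion_type == "b"

    def test_diagnostic_fragment_absent_in_desoxy_dfo_d1(self):
        formulas = {f.formula for f in in_silico_fragments(DESOXY_DFO_D1)}
        assert F("C20H35N4O5").replace_charge(+1) not in formulas
        # any 2-of-3 hydroxylation placement lacks the unmodified acylium
        for mask in itertools.combinations(range(3), 2):
            blocks = list(SPEIBONOXAMINE.blocks)
            diamine_positions = [i for i, b in enumerate(blocks) if b == "cad"]
            for d in mask:
                blocks[diamine_positions[d]] = "cad(OH)"
            formulas = {
                f.formula
                for f in in_silico_fragments(OligomerStructure(tuple(blocks)))
            }
            assert F("C20H35N4O5").replace_charge(+1) not in formulas

    def test_single_amide_gives_two_fragments(self):
        frags = in_silico_fragments(S("Ac|cad"))
        assert len(frags) == 2
        assert {f.ion_type for f in frags} == {"b", "y"}

    @pytest.mark.parametrize(
        "structure",
        [
            "Ac|cad|succ|cad|succ|cad|Ac",
            "Ac|cad(OH)|succ|cad(OH)|succ|cad(OH)",
            "succ|cad|succ",
            "Ac|cad",
        ],
    )
    def test_by_pair_conservation(self, structure):
        # for every cleavage, mass(b) + mass(y) = mass([M+H]+) + mass(H)
        s = S(structure)
        precursor = adduct_mz(assemble_formula(s), M_PLUS_H)
        frags = in_silico_fragments(s, deduplicate=False)
        by_bond: dict[str, dict[str, float]] = {}
        for f in frags:
            bond = f.cleavage.split("@")[1].removesuffix("-H2O")
            by_bond.setdefault(bond, {})[f.ion_type] = f.mz
        assert by_bond
        for bond, ions in by_bond.items():
            assert ions["b"] + ions["y"] == pytest.approx(
                precursor + MASS_H, abs=1e-9
            ), bond

    def test_cyclic_fragments_require_ring_opening(self):
        frags = in_silico_fragments(NOCARDAMINE)
        assert frags
        # every fragment is strictly lighter than the precursor
        precursor = adduct_mz(assemble_formula(NOCARDAMINE))
        assert all(f.mz < precursor for f in frags)

    def test_water_loss_satellites(self):
        base = {f.formula for f in in_silico_fragments(SPEIBONOXAMINE)}
        with_sat = {
            f.formula for f in in_silico_fragments(SPEIBONOXAMINE, water_loss=True)
        }
        assert base < with_sat
        diag = F("C20H35N4O5").replace_charge(+1)
        assert (diag - F("H2O")) in with_sat

    def test_internal_fragments_include_protonated_cadaverine(self):
        frags = in_silico_fragments(SPEIBONOXAMINE, internal=True)
        cad_h = F("C5H15N2").replace_charge(+1)
        by_formula = {f.formula: f for f in frags}
        assert cad_h in by_formula
        assert by_formula[cad_h].mz == pytest.approx(103.1230, abs=1e-3)


@given(st.integers(1, 3), st.integers(0, 3))
def test_assembled_mass_matches_block_sum(n_units, n_oh_limit):
    # cyclic (succ|cad)xk assembly equals explicit block arithmetic
    k = n_units
    n_oh = min(n_oh_limit, k)
    blocks = []
    for i in range(k):
        blocks += ["succ", "cad(OH)" if i < n_oh else "cad"]
    s = OligomerStructure(tuple(blocks), "cyclic")
    expected = (
        k * monoisotopic_mass(F("C4H6O4"))
        + (k - n_oh) * monoisotopic_mass(F("C5H14N2"))
        + n_oh * monoisotopic_mass(F("C5H14N2O"))
        - 2 * k * monoisotopic_mass(F("H2O"))
    )
    assert monoisotopic_mass(assemble_formula(s)) == pytest.approx(expected, rel=1e-12)
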