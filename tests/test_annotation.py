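"""Formula assignment, dereplication, delta-edge labelling, diagnostic
fragments, and analogue proposals."""

import networkx as nx
import pytest

from sideronet.annotation import (
    DEFAULT_DELTA_RULES,
    DIAGNOSTIC_FRAGMENT,
    annotate_edges,
    assign_formula,
    dereplicate,
    diagnostic_fragment_test,
    load_compound_library,
    propose_analogues,
)
from sideronet.formula import M_PLUS_H, MassTolerance, MolecularFormula, adduct_mz
from sideronet.oligomer import OligomerStructure, assemble_formula, in_silico_fragments
from sideronet.spectra import Peak, Spectrum

from conftest import make_spectrum

F = MolecularFormula.from_string


def spectrum_of(structure_text, id="node", jitter_ppm=0.0, extra_peaks=()):
    s = OligomerStructure.from_string(structure_text)
    mh = adduct_mz(assemble_formula(s))
    frags = in_silico_fragments(s, water_loss=True, internal=True)
    peaks = [Peak(f.mz, 100.0) for f in frags] + [Peak(m, i) for m, i in extra_peaks]
    return Spectrum(
        id=id, precursor_mz=mh * (1 + jitter_ppm * 1e-6), peaks=tuple(peaks)
    )


class TestAssignFormula:
    @pytest.mark.parametrize(
        "precursor, expected",
        [
            (555.3857, "C27H50N6O6"),
            (545.3654, "C25H48N6O7"),
            (529.3702, "C25H48N6O6"),
        ],
    )
    def test_reported_assignments(self, precursor, expected):
        node = make_spectrum(id="n", precursor=precursor)
        rec = assign_formula(node, tol=MassTolerance(10, "ppm"), prefer_assemblable=True)
        assert rec.formula == F(expected)
        assert abs(rec.ppm) < 5

    def test_no_candidate_leaves_formula_unset(self):
        node = make_spectrum(id="n", precursor=555.3857)
        rec = assign_formula(node, bounds={"C": (0, 2), "H": (0, 4)}, tol=MassTolerance(5, "ppm"))
        assert rec.formula is None


class TestDereplicate:
    def test_nocardamine_by_exact_mass(self):
        rec = assign_formula(make_spectrum(id="n", precursor=601.3552))
        rec = dereplicate(rec)
        assert rec.library_match is not None
        assert rec.library_match.name == "nocardamine"
        assert rec.library_match.formula == F("C27H48N6O9")

    def test_diketopiperazine_by_exact_mass(self):
        rec = assign_formula(make_spectrum(id="n", precursor=261.1237))
        rec = dereplicate(rec)
        assert rec.library_match is not None
        assert rec.library_match.formula == F("C14H16N2O3")

    def test_unmatched_mass_returns_record_unchanged(self):
        rec = assign_formula(make_spectrum(id="n", precursor=999.9))
        out = dereplicate(rec)
        assert out.library_match is None
        assert out == rec

    def test_proposed_entries_excluded_by_default(self):
        # 571.3807 is the tentative network-proposed congener, not a known
        rec = assign_formula(make_spectrum(id="n", precursor=571.3807))
        assert dereplicate(rec).library_match is None
        assert (
            dereplicate(rec, include_proposed=True).library_match.name
            == "didesoxy-desferrioxamine D1"
        )

    def test_bundled_library_contents(self):
        lib = load_compound_library()
        names = {e.name for e in lib}
        assert {"speibonoxamine", "nocardamine", "desferrioxamine B", "ferrioxamine E"} <= names
        structured = [e for e in lib if e.structure is not None]
        assert all(assemble_formula(e.structure) == e.formula for e in structured)
        assert all(e.structure.n_oh == e.n_oh for e in structured)


class TestDeltaEdges:
    def build_graph(self, masses):
        g = nx.Graph()
        for name, mz in masses.items():
            g.add_node(name, precursor_mz=mz)
        names = list(masses)
        for i in range(len(names) - 1):
            g.add_edge(names[i], names[i + 1])
        return g

    def test_oxygen_and_h2_labels(self):
        g = self.build_graph(
            {
                "d1": adduct_mz(F("C27H50N6O9")),
                "desoxy": adduct_mz(F("C27H50N6O8")),
                "cyclic": adduct_mz(F("C27H48N6O8")),
            }
        )
        annotate_edges(g)
        assert g.edges["d1", "desoxy"]["delta_label"] == "±O"
        assert g.edges["d1", "desoxy"]["delta_nominal"] == 16
        assert g.edges["desoxy", "cyclic"]["delta_label"] == "±H2"
        assert g.edges["desoxy", "cyclic"]["delta_nominal"] == 2

    def test_zero_delta_gets_no_label(self):
        g = self.build_graph({"a": 555.387, "b": 555.387})
        annotate_edges(g)
        assert "delta_label" not in g.edges["a", "b"]

    def test_rule_table_values(self):
        by_label = {r.label: r.delta for r in DEFAULT_DELTA_RULES}
        assert by_label["±O"] == pytest.approx(15.9949, abs=1e-4)
        assert by_label["±H2"] == pytest.approx(2.0157, abs=1e-4)
        assert by_label["±H2O"] == pytest.approx(18.0106, abs=1e-4)
        assert by_label["±C2H2O"] == pytest.approx(42.0106, abs=1e-4)
        assert by_label["±(Na-H)"] == pytest.approx(21.9819, abs=1e-4)


class TestDiagnosticFragment:
    def test_presence_pattern_across_congeners(self):
        nodes = [
            spectrum_of("Ac|cad|succ|cad|succ|cad|Ac", id="speibonoxamine"),
            spectrum_of("Ac|cad|succ|cad|succ|cad(OH)|Ac", id="didesoxy_d1"),
            spectrum_of("Ac|cad|succ|cad(OH)|succ|cad(OH)|Ac", id="desoxy_d1"),
            make_spectrum(id="empty", peaks=()),
        ]
        table = diagnostic_fragment_test(nodes, DIAGNOSTIC_FRAGMENT)
        assert table == {
            "speibonoxamine": True,
            "didesoxy_d1": True,
            "desoxy_d1": False,
            "empty": False,
        }

    def test_noise_level_peak_is_not_called(self):
        from sideronet.formula import monoisotopic_mass

        target = monoisotopic_mass(DIAGNOSTIC_FRAGMENT)
        s = make_spectrum(
            id="noisy", peaks=((100.0, 500.0), (target, 1.0))
        )
        assert diagnostic_fragment_test([s])["noisy"] is False


class TestProposals:
    def build_annotated_pair(self, known_text, known_name, unknown_text):
        known = spectrum_of(known_text, id="known")
        unknown = spectrum_of(unknown_text, id="unknown")
        g = nx.Graph()
        for s in (known, unknown):
            g.add_node(s.id, precursor_mz=s.precursor_mz)
        g.add_edge("known", "unknown", cosine=0.9, matched_peaks=10,
                   delta_mz=known.precursor_mz - unknown.precursor_mz)
        annotate_edges(g)
        records = {
            "known": dereplicate(assign_formula(known, prefer_assemblable=True)),
            "unknown": assign_formula(unknown, prefer_assemblable=True),
        }
        assert records["known"].library_match is not None, "fixture must dereplicate"
        spectra = {"known": known, "unknown": unknown}
        return propose_analogues(g, spectra, records)

    def test_didesoxy_d1_proposed_from_desoxy_d1(self):
        records = self.build_annotated_pair(
            "Ac|cad|succ|cad(OH)|succ|cad(OH)|Ac",  # compound 2, library known
            "desoxy-desferrioxamine D1",
            "Ac|cad|succ|cad|succ|cad(OH)|Ac",  # the unknown congener
        )
        proposals = records["unknown"].proposals
        assert proposals
        structures = {p.structure.to_string() for p in proposals}
        assert "Ac|cad|succ|cad|succ|cad(OH)|Ac" in structures
        assert all(p.formula == F("C27H50N6O7") for p in proposals)
        assert all(abs(p.ppm) < 10 for p in proposals)
        # the diagnostic 411 ion is present in the unknown's spectrum, so the
        # middle-hydroxylated isomer (which cannot produce it) is rejected
        assert "Ac|cad|succ|cad(OH)|succ|cad|Ac" not in structures

    def test_desoxy_dfo_b_proposed_from_dfo_b(self):
        records = self.build_annotated_pair(
            "Ac|cad(OH)|succ|cad(OH)|succ|cad(OH)",  # desferrioxamine B
            "desferrioxamine B",
            "Ac|cad(OH)|succ|cad(OH)|succ|cad",  # desoxy congener
        )
        proposals = records["unknown"].proposals
        structures = {p.structure.to_string() for p in proposals}
        assert "Ac|cad(OH)|succ|cad(OH)|succ|cad" in structures
        assert all(p.formula == F("C25H48N6O7") for p in proposals)

    def test_node_without_labelled_edges_gets_no_proposal(self):
        known = spectrum_of("Ac|cad|succ|cad(OH)|succ|cad(OH)|Ac", id="known")
        unknown = make_spectrum(id="unknown", precursor=700.0)
        g = nx.Graph()
        g.add_node("known", precursor_mz=known.precursor_mz)
        g.add_node("unknown", precursor_mz=700.0)
        g.add_edge("known", "unknown", cosine=0.8, matched_peaks=5, delta_mz=0.0)
        annotate_edges(g)
        records = {
            "known": dereplicate(assign_formula(known, prefer_assemblable=True)),
            "unknown": assign_formula(unknown),
        }
        out = propose_analogues(g, {"known": known, "unknown": unknown}, records)
        assert out["unknown"].proposals == ()

    def test_every_proposal_reproduces_precursor_mass(self):
        records = self.build_annotated_pair(
            "Ac|cad|succ|cad(OH)|succ|cad(OH)|Ac",
            "desoxy-desferrioxamine D1",
            "Ac|cad|succ|cad|succ|cad(OH)|Ac",
        )
        for p in records["unknown"].proposals:
            assert abs(p.ppm) <= 10
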