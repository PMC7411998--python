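"""Turning a molecular network into chemistry.

Per-node molecular-formula assignment, dereplication against a bundled
candidate library, interpretation of precursor mass differences along
network edges (the classic 16 Da hydroxylation / 2 Da cyclization deltas),
diagnostic-fragment presence tests, and structure proposals for unannotated
nodes by combining the building-block grammar with the evidence on their
edges — the inference chain by which new dehydroxylated desferrioxamine
congeners are recognized from a network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import networkx as nx

from .formula import (
    AdductSpec,
    M_PLUS_H,
    MassTolerance,
    MolecularFormula,
    adduct_mz,
    enumerate_formulas,
    monoisotopic_mass,
    ppm_error,
)
from .oligomer import OligomerStructure, assemble_formula, enumerate_candidates, in_silico_fragments
from .spectra import Spectrum

__all__ = [
    "DeltaRule",
    "DEFAULT_DELTA_RULES",
    "DIAGNOSTIC_FRAGMENT",
    "AnnotationRecord",
    "LibraryEntry",
    "load_compound_library",
    "assign_formula",
    "dereplicate",
    "annotate_edges",
    "diagnostic_fragment_test",
    "propose_analogues",
    "Proposal",
]

_F = MolecularFormula.from_string


@dataclass(frozen=True)
class DeltaRule:
    """An interpretable precursor mass difference."""

    label: str
    delta: float  # exact monoisotopic mass difference, Da
    meaning: str


def _mass(text: str) -> float:
    return monoisotopic_mass(_F(text))


DEFAULT_DELTA_RULES: tuple[DeltaRule, ...] = (
    DeltaRule("±O", _mass("O"), "hydroxylation / desoxy congener"),
    DeltaRule("±H2", _mass("H2"), "saturation change, e.g. acyclic vs cyclic"),
    DeltaRule("±H2O", _mass("H2O"), "condensation / hydrolysis"),
    DeltaRule("±C2H2O", _mass("C2H2O"), "acetylation"),
    DeltaRule("±(Na-H)", _mass("Na") - _mass("H"), "sodiated vs protonated adduct"),
)

#: The hydroxamate-series diagnostic acylium: present when the two diamine
#: units flanking the cleaved succinyl carry no N-OH.
DIAGNOSTIC_FRAGMENT = _F("C20H35N4O5")


@dataclass(frozen=True)
class LibraryEntry:
    id: str
    name: str
    formula: MolecularFormula
    topology: str
    n_oh: int
    structure: OligomerStructure | None
    status: str  # isolated | network_identified | network_proposed


def load_compound_library(path: str | Path | None = None) -> list[LibraryEntry]:
    """Load the dereplication library (bundled TSV by default).

    The bundled table carries the named compounds of the reference
    desferrioxamine panel (name, neutral formula, topology, N-OH count and,
    where the compound is a building-block oligomer, its structure string).
    Users may point ``path`` at their own TSV with the same columns.
    """
    import pandas as pd

    if path is None:
        source = resources.files("sideronet.data").joinpath("compound_library.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    entries = []
    for row in df.itertuples(index=False):
        structure = None
        if isinstance(row.structure, str) and row.structure.strip():
            structure = OligomerStructure.from_string(row.structure).canonical()
        entries.append(
            LibraryEntry(
                id=str(row.id),
                name=row.name,
                formula=_F(row.formula),
                topology=row.topology,
                n_oh=int(row.n_oh),
                structure=structure,
                status=row.status,
            )
        )
    return entries


@dataclass(frozen=True)
class Proposal:
    structure: OligomerStructure
    formula: MolecularFormula
    calc_mz: float
    ppm: float
    coverage: float
    via_node: str
    delta_label: str


@dataclass(frozen=True)
class AnnotationRecord:
    """Accumulated evidence for one network node."""

    node_id: str
    precursor_mz: float
    formula: MolecularFormula | None = None
    ppm: float | None = None
    library_match: LibraryEntry | None = None
    library_ppm: float | None = None
    analogue_of: str | None = None
    delta_label: str | None = None
    observed_delta: float | None = None
    diagnostics: tuple[tuple[str, bool], ...] = ()
    proposals: tuple[Proposal, ...] = ()


def assign_formula(
    node: Spectrum,
    bounds=None,
    tol: MassTolerance = MassTolerance(10.0, "ppm"),
    adduct: AdductSpec = M_PLUS_H,
    prefer_assemblable: bool = False,
    max_blocks: int = 12,
) -> AnnotationRecord:
    """Assign a molecular formula to a node from its precursor m/z.

    Candidates come from bounded CHNO enumeration with the nitrogen-rule and
    elemental-ratio filters, ranked by |ppm error|.  With
    ``prefer_assemblable`` the first candidate that can be assembled from the
    building-block grammar wins (mirroring series-based reasoning in
    siderophore dereplication, where accurate mass alone can be closer to a
    chemically senseless formula); otherwise the |ppm|-best candidate is
    recorded.
    """
    candidates = enumerate_formulas(
        node.precursor_mz,
        adduct=adduct,
        tol=tol,
        bounds=bounds,
        require_integer_rdbe=True,
        require_ratio_sanity=True,
    )
    best = None
    if candidates:
        best = candidates[0]
        if prefer_assemblable:
            assemblable = {
                assemble_formula(s)
                for s in enumerate_candidates(node.precursor_mz, adduct, tol, max_blocks)
            }
            for cand in candidates:
                if cand in assemblable:
                    best = cand
                    break
    return AnnotationRecord(
        node_id=node.id,
        precursor_mz=node.precursor_mz,
        formula=best,
        ppm=None if best is None else ppm_error(node.precursor_mz, adduct_mz(best, adduct)),
    )


def dereplicate(
    record: AnnotationRecord,
    library: list[LibraryEntry] | None = None,
    tol: MassTolerance = MassTolerance(10.0, "ppm"),
    adduct: AdductSpec = M_PLUS_H,
    include_proposed: bool = False,
) -> AnnotationRecord:
    """Attach the best library match whose adduct m/z agrees with the node.

    Entries flagged ``network_proposed`` (tentative structures, not reference
    knowns) are skipped unless ``include_proposed`` is set.  The record is
    returned unchanged when nothing matches.
    """
    if library is None:
        library = load_compound_library()
    best: tuple[float, LibraryEntry] | None = None
    for entry in library:
        if entry.status == "network_proposed" and not include_proposed:
            continue
        err = ppm_error(record.precursor_mz, adduct_mz(entry.formula, adduct))
        if abs(err) * 1e-6 * record.precursor_mz > tol.halfwidth_da(record.precursor_mz):
            continue
        if best is None or abs(err) < abs(best[0]):
            best = (err, entry)
    if best is None:
        return record
    return replace(record, library_match=best[1], library_ppm=best[0])


def annotate_edges(
    graph: nx.Graph,
    rules: tuple[DeltaRule, ...] = DEFAULT_DELTA_RULES,
    tol: float = 0.01,
) -> nx.Graph:
    """Label network edges whose precursor mass difference matches a rule.

    Each labelled edge gains ``delta_label`` plus ``delta_nominal`` (the
    integer-rounded difference, matching how such deltas are quoted).  The
    label depends only on |delta|, hence is symmetric in the two nodes.
    """
    for u, v, data in graph.edges(data=True):
        delta = abs(
            graph.nodes[u]["precursor_mz"] - graph.nodes[v]["precursor_mz"]
        )
        data["delta_nominal"] = round(delta)
        for rule in rules:
            if abs(delta - rule.delta) <= tol:
                data["delta_label"] = rule.label
                data["delta_meaning"] = rule.meaning
                break
    return graph


def _peak_present(s: Spectrum, target_mz: float, tol: float, min_rel_intensity: float) -> bool:
    if not s.peaks:
        return False
    floor = min_rel_intensity * max(p.intensity for p in s.peaks)
    return any(
        abs(p.mz - target_mz) <= tol and p.intensity >= floor for p in s.peaks
    )


def diagnostic_fragment_test(
    nodes: list[Spectrum],
    fragment: MolecularFormula = DIAGNOSTIC_FRAGMENT,
    tol: float = 0.005,
    min_rel_intensity: float = 0.02,
) -> dict[str, bool]:
    """Per node: is a peak present within ``tol`` Da of the fragment's m/z?

    The fragment formula is the singly charged ion; its m/z is the plain
    monoisotopic mass under the no-electron-correction convention.  To count,
    a peak must also reach ``min_rel_intensity`` of the base peak — a
    diagnostic ion call requires the signal to stand above the noise floor.
    """
    target = monoisotopic_mass(fragment)
    return {
        s.id: _peak_present(s, target, tol, min_rel_intensity) for s in nodes
    }


def _skeleton_consistent(
    candidate: OligomerStructure,
    neighbor: OligomerStructure,
    label: str,
    node_heavier: bool,
) -> bool:
    if label == "±O":
        want = neighbor.n_oh + (1 if node_heavier else -1)
        return (
            candidate.skeleton == neighbor.skeleton
            and candidate.topology == neighbor.topology
            and candidate.n_oh == want
        )
    if label == "±H2":
        # acyclic vs cyclic reading: same block alternation, different closure
        return candidate.topology != neighbor.topology
    if label == "±C2H2O":
        a = sorted(candidate.skeleton)
        b = sorted(neighbor.skeleton)
        shorter, longer = (a, b) if len(a) < len(b) else (b, a)
        return (
            candidate.n_oh == neighbor.n_oh
            and len(longer) - len(shorter) == 1
            and sorted(longer) == sorted(shorter + ["Ac"])
        )
    return True


def _oh_mask(s: OligomerStructure) -> tuple[bool, ...]:
    return tuple(b == "cad(OH)" for b in s.blocks if b.startswith("cad"))


def _placement_distance(candidate: OligomerStructure, neighbor: OligomerStructure) -> int:
    if candidate.skeleton != neighbor.skeleton:
        return len(candidate.blocks)
    a = _oh_mask(candidate)
    options = [_oh_mask(neighbor), tuple(reversed(_oh_mask(neighbor)))]
    return min(sum(x != y for x, y in zip(a, opt)) for opt in options)


def _fragment_coverage(
    s: Spectrum, structure: OligomerStructure, tol: float
) -> float:
    if not s.peaks:
        return 0.0
    mzs = sorted(f.mz for f in in_silico_fragments(structure))
    hit = 0
    for p in s.peaks:
        if any(abs(p.mz - m) <= tol for m in mzs):
            hit += 1
    return hit / len(s.peaks)


def propose_analogues(
    graph: nx.Graph,
    spectra: dict[str, Spectrum],
    records: dict[str, AnnotationRecord],
    tol: MassTolerance = MassTolerance(10.0, "ppm"),
    adduct: AdductSpec = M_PLUS_H,
    frag_tol: float = 0.005,
    diagnostics: tuple[MolecularFormula, ...] = (DIAGNOSTIC_FRAGMENT,),
    min_rel_intensity: float = 0.02,
    max_blocks: int = 12,
    max_rounds: int = 3,
) -> dict[str, AnnotationRecord]:
    """Propose building-block structures for unannotated network nodes.

    For every node without a library match that is adjacent, via a
    delta-labelled edge, to a node of known structure, candidate structures
    are enumerated at the node's precursor mass and kept when (i) they are
    consistent with the delta rule relative to the neighbour's structure and
    (ii) their in-silico fragment set accounts for every diagnostic fragment
    actually observed in the node's spectrum (observed presence is strong
    evidence; absence is not used to reject, since real spectra are
    incomplete).  Candidates are ranked by the fraction of the node's peaks
    explained by their fragments, ties broken by the fewest N-OH placement
    changes relative to the neighbour, then by structure string.

    Proposals propagate: once a node has a top-ranked proposal it can serve
    as the structure-known neighbour in a later round (up to ``max_rounds``),
    which is how a chain such as known -> analogue -> analogue-of-analogue is
    resolved.  Returns updated records (proposal tuples filled in).
    """
    records = dict(records)
    known: dict[str, OligomerStructure] = {}
    for node_id, rec in records.items():
        if rec.library_match is not None and rec.library_match.structure is not None:
            known[node_id] = rec.library_match.structure

    diag_mzs = [(f, monoisotopic_mass(f)) for f in diagnostics]

    for _ in range(max_rounds):
        new_known: dict[str, OligomerStructure] = {}
        for node_id in sorted(graph.nodes):
            if node_id in known or node_id not in records:
                continue
            if records[node_id].proposals:
                continue
            spectrum = spectra[node_id]
            proposals: list[Proposal] = []
            for other in sorted(graph.neighbors(node_id)):
                if other not in known:
                    continue
                data = graph.edges[node_id, other]
                label = data.get("delta_label")
                if label is None:
                    continue
                neighbor = known[other]
                node_heavier = (
                    graph.nodes[node_id]["precursor_mz"]
                    > graph.nodes[other]["precursor_mz"]
                )
                candidates = enumerate_candidates(
                    spectrum.precursor_mz, adduct, tol, max_blocks
                )
                for cand in candidates:
                    if not _skeleton_consistent(cand, neighbor, label, node_heavier):
                        continue
                    frag_formulas = {f.formula for f in in_silico_fragments(cand)}
                    rejected = False
                    for diag_formula, diag_mz in diag_mzs:
                        present = _peak_present(
                            spectrum, diag_mz, frag_tol, min_rel_intensity
                        )
                        ion = diag_formula.replace_charge(+1)
                        if present and ion not in frag_formulas:
                            rejected = True
                            break
                    if rejected:
                        continue
                    f = assemble_formula(cand)
                    mz = adduct_mz(f, adduct)
                    proposals.append(
                        Proposal(
                            structure=cand,
                            formula=f,
                            calc_mz=mz,
                            ppm=ppm_error(spectrum.precursor_mz, mz),
                            coverage=_fragment_coverage(spectrum, cand, frag_tol),
                            via_node=other,
                            delta_label=label,
                        )
                    )
            if not proposals:
                continue
            # dedup by structure, keep best-covered occurrence
            by_structure: dict[str, Proposal] = {}
            for p in proposals:
                key = p.structure.to_string()
                if key not in by_structure or p.coverage > by_structure[key].coverage:
                    by_structure[key] = p
            ranked = sorted(
                by_structure.values(),
                key=lambda p: (
                    -p.coverage,
                    _placement_distance(p.structure, known.get(p.via_node))
                    if p.via_node in known
                    else 0,
                    p.structure.to_string(),
                ),
            )
            records[node_id] = replace(records[node_id], proposals=tuple(ranked))
            new_known[node_id] = ranked[0].structure
        if not new_known:
            break
        known.update(new_known)
    return records
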