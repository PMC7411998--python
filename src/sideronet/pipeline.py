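"""End-to-end orchestration: spectra in, annotated network and reports out.

Stage order follows the molecular-networking workflow: read MGF inputs,
drop blank-derived spectra, apply the precursor-window and top-k-per-window
peak filters, score all pairs and build the network, dereplicate nodes
against the compound library, label interpretable precursor mass differences
on the edges, propose structures for unannotated nodes, and write the
reports (GraphML, TSV tables, JSON run log carrying the config hash).

All outputs are deterministic functions of (inputs, config): rerunning with
the same inputs and config produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from . import __version__
from .annotation import (
    DEFAULT_DELTA_RULES,
    AnnotationRecord,
    annotate_edges,
    assign_formula,
    dereplicate,
    diagnostic_fragment_test,
    DIAGNOSTIC_FRAGMENT,
    load_compound_library,
    propose_analogues,
)
from .formula import MassTolerance
from .network import build_network, write_edge_tsv, write_node_tsv
from .processing import remove_precursor_window, subtract_blanks, window_filter_top_k
from .spectra import Spectrum, read_mgf

__all__ = ["PipelineConfig", "PipelineResult", "run"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """All workflow parameters.

    Defaults reproduce the standard molecular-networking settings: +/-17 Da
    precursor window removal, top-6 peaks per +/-50 Da window, 0.02 Da
    fragment and precursor tolerances, edge cosine > 0.7 with > 3 matched
    peaks, mutual top-10 rule, molecular families capped at 100 nodes, and
    library matches at cosine > 0.7 with >= 3 matched peaks.
    """

    precursor_window_da: float = 17.0
    window_top_k: int = 6
    window_halfwidth_da: float = 50.0
    frag_tol_da: float = 0.02
    precursor_tol_da: float = 0.02
    edge_cosine: float = 0.7
    edge_min_matched: int = 4
    library_cosine: float = 0.7
    library_min_matched: int = 3
    top_k: int = 10
    family_cap: int = 100
    sqrt_intensity: bool = True  # GNPS-style sqrt intensity scaling
    allow_shift: bool = True
    blank_ppm_tol: float = 10.0
    formula_tol_ppm: float = 10.0
    formula_bounds: tuple[tuple[str, tuple[int, int]], ...] = (
        ("C", (0, 40)),
        ("H", (0, 80)),
        ("N", (0, 10)),
        ("O", (0, 12)),
    )
    delta_tol_da: float = 0.01
    diagnostic_tol_da: float = 0.005
    max_blocks: int = 12
    library_path: str | None = None
    seed: int = 1

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    graph: nx.Graph
    records: dict[str, AnnotationRecord]
    diagnostics: dict[str, bool]
    n_input: int = 0
    n_after_blanks: int = 0
    outdir: Path | None = None


def _annotation_table(result: PipelineResult):
    import pandas as pd

    rows = []
    for node_id in sorted(result.records):
        rec = result.records[node_id]
        top = rec.proposals[0] if rec.proposals else None
        rows.append(
            {
                "node": node_id,
                "precursor_mz": round(rec.precursor_mz, 4),
                "formula": rec.formula.to_string() if rec.formula else "",
                "ppm": round(rec.ppm, 2) if rec.ppm is not None else "",
                "library_match": rec.library_match.name if rec.library_match else "",
                "library_ppm": round(rec.library_ppm, 2)
                if rec.library_ppm is not None
                else "",
                "diagnostic_fragment": result.diagnostics.get(node_id, ""),
                "proposal": top.structure.to_string() if top else "",
                "proposal_via": top.via_node if top else "",
                "proposal_delta": top.delta_label if top else "",
                "proposal_coverage": round(top.coverage, 3) if top else "",
                "n_proposals": len(rec.proposals),
            }
        )
    return pd.DataFrame(rows)


def run(
    config: PipelineConfig,
    spectra: list[Spectrum] | None = None,
    input_mgfs: list[str | Path] | None = None,
    outdir: str | Path | None = None,
    log=print,
) -> PipelineResult:
    """Run the full workflow on in-memory spectra and/or MGF files.

    Blank spectra are recognized by their ``SOURCE`` label.  When ``outdir``
    is given, writes network.graphml, edges.tsv, nodes.tsv, annotations.tsv
    and run.json there.
    """
    spectra = list(spectra or [])
    for path in input_mgfs or []:
        try:
            spectra.extend(read_mgf(path))
        except Exception as exc:
            raise PipelineError("read", str(exc)) from exc
    if not spectra:
        raise PipelineError("read", "no input spectra")
    n_input = len(spectra)
    log(f"read: {n_input} spectra ({sum(s.is_blank for s in spectra)} blanks)")

    if any(s.is_blank for s in spectra):
        kept, report = subtract_blanks(spectra, ppm_tol=config.blank_ppm_tol)
        log(f"blank subtraction: dropped {len(report.dropped)} -> {len(kept)} spectra")
    else:
        kept = spectra
        log("blank subtraction: no blanks provided, skipped")
    if not kept:
        raise PipelineError("blank_subtraction", "all spectra matched blanks")

    processed = [
        window_filter_top_k(
            remove_precursor_window(s, config.precursor_window_da),
            config.window_top_k,
            config.window_halfwidth_da,
        )
        for s in kept
    ]
    log(f"filters: precursor +/-{config.precursor_window_da} Da, "
        f"top-{config.window_top_k} per +/-{config.window_halfwidth_da} Da")

    graph = build_network(
        processed,
        edge_threshold=config.edge_cosine,
        min_matched=config.edge_min_matched,
        top_k=config.top_k,
        family_cap=config.family_cap,
        frag_tol=config.frag_tol_da,
        allow_shift=config.allow_shift,
        sqrt_intensity=config.sqrt_intensity,
    )
    log(f"network: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges, "
        f"{graph.graph['n_pairs_scored']} pairs scored")

    library = load_compound_library(config.library_path)
    bounds = dict(config.formula_bounds)
    tol = MassTolerance(config.formula_tol_ppm, "ppm")
    records: dict[str, AnnotationRecord] = {}
    for s in processed:
        rec = assign_formula(
            s, bounds=bounds, tol=tol, prefer_assemblable=True, max_blocks=config.max_blocks
        )
        records[s.id] = dereplicate(rec, library, tol=tol)
    n_matched = sum(r.library_match is not None for r in records.values())
    log(f"dereplication: {n_matched}/{len(records)} nodes matched the library")

    annotate_edges(graph, DEFAULT_DELTA_RULES, tol=config.delta_tol_da)
    diagnostics = diagnostic_fragment_test(
        processed, DIAGNOSTIC_FRAGMENT, tol=config.diagnostic_tol_da
    )
    records = propose_analogues(
        graph,
        {s.id: s for s in processed},
        records,
        tol=tol,
        frag_tol=config.diagnostic_tol_da,
        max_blocks=config.max_blocks,
    )
    n_proposed = sum(bool(r.proposals) for r in records.values())
    log(f"proposals: structures proposed for {n_proposed} unannotated nodes")

    result = PipelineResult(
        graph=graph,
        records=records,
        diagnostics=diagnostics,
        n_input=n_input,
        n_after_blanks=len(kept),
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nx.write_graphml(graph, outdir / "network.graphml")
        write_edge_tsv(graph, outdir / "edges.tsv")
        write_node_tsv(graph, outdir / "nodes.tsv")
        _annotation_table(result).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        run_log = {
            "sideronet_version": __version__,
            "config": dataclasses.asdict(config),
            "config_hash": config.hash(),
            "n_input_spectra": n_input,
            "n_after_blank_subtraction": len(kept),
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_library_matched": n_matched,
            "n_proposed": n_proposed,
        }
        (outdir / "run.json").write_text(json.dumps(run_log, indent=2, default=str))
        result.outdir = outdir
        log(f"outputs written to {outdir} (config hash {config.hash()})")
    return result
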