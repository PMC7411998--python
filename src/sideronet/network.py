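"""Modified-cosine spectral similarity and molecular-network construction.

The modified cosine pairs fragment peaks either directly (within a fragment
tolerance) or offset by the difference of the two precursor masses, so that
structural analogues whose fragment ladders are shifted by a substituent
mass still align.  Peak pairs are scored by the product of L2-normalized
intensities and a one-to-one matching is chosen greedily by descending pair
score, which is deterministic and, on non-degenerate instances, optimal.

A molecular network keeps an edge between two spectra when the score and the
matched-peak count clear their thresholds, both nodes appear in each other's
top-k most similar spectra, and the resulting connected component (the
"molecular family") is pruned to a maximum size by iteratively removing its
lowest-scoring edges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .spectra import Spectrum

__all__ = [
    "MatchResult",
    "modified_cosine",
    "build_network",
    "library_search",
    "LibraryMatch",
    "write_edge_tsv",
    "write_node_tsv",
]


@dataclass(frozen=True)
class MatchResult:
    score: float
    matched_count: int
    pairs: tuple[tuple[int, int], ...]  # (index in a, index in b)


def _normalized(s: Spectrum, sqrt_intensity: bool) -> np.ndarray:
    v = s.intensity
    if sqrt_intensity:
        v = np.sqrt(v)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float = 0.02,
    allow_shift: bool = True,
    sqrt_intensity: bool = False,
) -> MatchResult:
    """Greedy modified-cosine similarity between two spectra.

    Candidate peak pairs satisfy ``|mz_a - mz_b| <= frag_tol`` or, when
    ``allow_shift``, ``|mz_a - (mz_b + d)| <= frag_tol`` with ``d`` the
    precursor m/z difference (a - b).  With ``allow_shift=False`` this is the
    plain cosine.  Returns the score (in [0, 1]), the number of matched peak
    pairs, and the pairs themselves.
    """
    if not a.peaks or not b.peaks:
        return MatchResult(0.0, 0, ())
    va, vb = _normalized(a, sqrt_intensity), _normalized(b, sqrt_intensity)
    mza, mzb = a.mz, b.mz
    shift = a.precursor_mz - b.precursor_mz

    candidates: dict[tuple[int, int], float] = {}
    shifts = (0.0, shift) if (allow_shift and abs(shift) > frag_tol) else (0.0,)
    for offset in shifts:
        # two-pointer sweep over sorted arrays
        j0 = 0
        for i in range(len(mza)):
            target = mza[i] - offset
            while j0 < len(mzb) and mzb[j0] < target - frag_tol:
                j0 += 1
            j = j0
            while j < len(mzb) and mzb[j] <= target + frag_tol:
                candidates[(i, j)] = va[i] * vb[j]
                j += 1

    # greedy one-to-one matching: descending pair score, ties by lower m/z
    order = sorted(
        candidates.items(), key=lambda kv: (-kv[1], mza[kv[0][0]], mzb[kv[0][1]])
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    score = 0.0
    for (i, j), s in order:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
        score += s
    return MatchResult(min(float(score), 1.0), len(pairs), tuple(pairs))


def build_network(
    spectra: list[Spectrum],
    edge_threshold: float = 0.7,
    min_matched: int = 4,
    top_k: int = 10,
    family_cap: int = 100,
    frag_tol: float = 0.02,
    allow_shift: bool = True,
    sqrt_intensity: bool = False,
) -> nx.Graph:
    """Score all spectrum pairs and assemble the molecular network.

    Stages: (i) all n(n-1)/2 pairwise modified cosines; (ii) edges kept when
    ``score > edge_threshold`` and ``matched_count >= min_matched``;
    (iii) mutual top-k rule (an edge survives only if each endpoint ranks the
    other among its ``top_k`` highest-scoring retained neighbours);
    (iv) components larger than ``family_cap`` lose their lowest-scoring edge
    (deterministic tie-break on the node-id pair), repeatedly, until every
    family is small enough.

    Node attributes: ``precursor_mz``, ``source``.  Edge attributes:
    ``cosine``, ``matched_peaks``, ``delta_mz`` (precursor difference).
    ``graph.graph["n_pairs_scored"]`` records the number of scored pairs.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    ids = [s.id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate spectrum ids")
    g = nx.Graph()
    for s in spectra:
        g.add_node(s.id, precursor_mz=s.precursor_mz, source=s.source)

    n_pairs = 0
    for a, b in itertools.combinations(spectra, 2):
        n_pairs += 1
        res = modified_cosine(a, b, frag_tol, allow_shift, sqrt_intensity)
        if res.score > edge_threshold and res.matched_count >= min_matched:
            g.add_edge(
                a.id,
                b.id,
                cosine=res.score,
                matched_peaks=res.matched_count,
                delta_mz=a.precursor_mz - b.precursor_mz,
            )
    g.graph["n_pairs_scored"] = n_pairs

    # mutual top-k: rank retained neighbours by score (ties by neighbour id)
    ranks: dict[str, dict[str, int]] = {}
    for node in g.nodes:
        neighbours = sorted(
            g[node].items(), key=lambda kv: (-kv[1]["cosine"], kv[0])
        )
        ranks[node] = {other: r for r, (other, _) in enumerate(neighbours)}
    for u, v in list(g.edges):
        if ranks[u][v] >= top_k or ranks[v][u] >= top_k:
            g.remove_edge(u, v)

    # family-size pruning
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > family_cap]
        if not oversized:
            break
        for comp in oversized:
            sub_edges = g.subgraph(comp).edges(data=True)
            worst = min(
                sub_edges, key=lambda e: (e[2]["cosine"], tuple(sorted((e[0], e[1]))))
            )
            g.remove_edge(worst[0], worst[1])
    return g


@dataclass(frozen=True)
class LibraryMatch:
    library_id: str
    score: float
    matched_count: int


def library_search(
    query: Spectrum,
    library: list[Spectrum],
    score_threshold: float = 0.7,
    min_matched: int = 3,
    frag_tol: float = 0.02,
    allow_shift: bool = True,
) -> list[LibraryMatch]:
    """Match a query spectrum against a spectral library.

    Entries must score above ``score_threshold`` with at least
    ``min_matched`` matched peaks; results are sorted by descending score
    (ties by library id).
    """
    if not library:
        raise ValueError("empty spectral library")
    out = []
    for entry in library:
        res = modified_cosine(query, entry, frag_tol, allow_shift)
        if res.score > score_threshold and res.matched_count >= min_matched:
            out.append(LibraryMatch(entry.id, res.score, res.matched_count))
    out.sort(key=lambda m: (-m.score, m.library_id))
    return out


def write_edge_tsv(g: nx.Graph, path) -> None:
    import pandas as pd

    rows = [
        {
            "node1": u,
            "node2": v,
            "cosine": round(d["cosine"], 6),
            "matched_peaks": d["matched_peaks"],
            "delta_mz": round(d["delta_mz"], 4),
            **{k: v2 for k, v2 in d.items() if k not in ("cosine", "matched_peaks", "delta_mz")},
        }
        for u, v, d in sorted(g.edges(data=True), key=lambda e: tuple(sorted(e[:2])))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_node_tsv(g: nx.Graph, path) -> None:
    import pandas as pd

    rows = [
        {"id": n, **{k: (round(v, 6) if isinstance(v, float) else v) for k, v in d.items()}}
        for n, d in sorted(g.nodes(data=True))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
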