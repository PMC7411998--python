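"""Run the full molecular-networking pipeline on the simulated panel.

Reads results/panel/panel.mgf (run 01_simulate_panel.py first), applies the
blank subtraction and spectrum filters, builds the modified-cosine network,
dereplicates nodes against the bundled compound library, labels the
interpretable mass-difference edges, and proposes structures for the
unannotated nodes.  All reports land in results/network/.
"""

from pathlib import Path

import networkx as nx

from sideronet.pipeline import PipelineConfig, run

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    mgf = BASE / "panel" / "panel.mgf"
    if not mgf.exists():
        raise SystemExit("run analysis/01_simulate_panel.py first")
    config = PipelineConfig(seed=SEED)
    result = run(config, input_mgfs=[mgf], outdir=BASE / "network")

    g = result.graph
    print("\nmolecular families:")
    for comp in nx.connected_components(g):
        members = sorted(comp)
        print(" ", " - ".join(members))
    print("\ndelta-labelled edges:")
    for u, v, d in sorted(g.edges(data=True)):
        label = d.get("delta_label", "-")
        print(f"  {u} <-> {v}  cosine {d['cosine']:.3f}  "
              f"delta {d['delta_mz']:+.4f} ({label})")


if __name__ == "__main__":
    main()
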