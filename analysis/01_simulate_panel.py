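"""Generate the synthetic desferrioxamine MS/MS panel used by the analysis.

Writes the panel spectra (plus three solvent blanks) as MGF and the
ground-truth table as TSV under results/panel/.  One spectrum per compound:
the non-hydroxylated, partially and fully hydroxylated linear congeners, the
desferrioxamine-B series, and the two cyclic nocardamines.
"""

from pathlib import Path

from sideronet.spectra import write_mgf
from sideronet.synth import PanelSpec, generate_blanks, generate_panel

OUT = Path(__file__).resolve().parent.parent / "results" / "panel"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = PanelSpec(seed=SEED)
    spectra, truth = generate_panel(spec)
    blanks = generate_blanks(3, seed=SEED + 10_000)
    write_mgf(spectra + blanks, OUT / "panel.mgf")
    truth.to_csv(OUT / "ground_truth.tsv", sep="\t", index=False)

    print(f"panel: {len(spectra)} compounds + {len(blanks)} blanks (seed {SEED})")
    print(f"precursors span {min(s.precursor_mz for s in spectra):.4f}"
          f"-{max(s.precursor_mz for s in spectra):.4f} m/z")
    print(truth.to_string(index=False))
    print(f"\nwrote {OUT/'panel.mgf'} and {OUT/'ground_truth.tsv'}")


if __name__ == "__main__":
    main()
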