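# Methods

## Exact-mass arithmetic

All masses derive from one pinned table of monoisotopic atomic masses
(`sideronet.constants`, version 2024.1): C 12 (exact), H 1.0078250319,
N 14.0030740052, O 15.9949146221, Na 22.98976928, and Fe 55.9349375 (Fe is
carried only so the iron-bound ferrioxamine library entries can be
mass-checked; enumeration is CHNO-only). Calculated m/z of charged species
adds the adduct atoms as neutrals and does **not** subtract the electron
mass; this is the convention under which printed "calculated [M+H]⁺" values
in the dereplication literature are reproduced to four decimals (e.g.
555.3870 for protonated C₂₇H₅₀N₆O₆). The physically exact value (0.00055 Da
lower per positive charge) is available via `electron_correction=True`.
ppm errors are signed, with the calculated mass as denominator.

Formula enumeration runs nested loops over C, N, O (and Na if bounded above
zero) and solves H from the residual mass window — exhaustive and exact at
desk scale. Ranking is by |ppm error|, ties broken by lower RDBE then element
counts. Two optional chemical filters, both applied by the pipeline: integer
RDBE ≥ 0 (the nitrogen rule for even-electron neutrals) and elemental-ratio
sanity (H/C ∈ [0.5, 3], N ≤ C, O ≤ C). Default bounds C ≤ 40, H ≤ 80,
N ≤ 10, O ≤ 12.

**Why |ppm|-best is not enough.** Within ±5 ppm of an observed hydroxamate
mass, blind CHNO enumeration regularly contains a chemically senseless
formula closer to the measurement than the true one (at 555.3857,
C₂₆H₅₄N₂O₁₀ sits 0.05 ppm away while the true C₂₇H₅₀N₆O₆ is 2.3 ppm away).
The pipeline therefore prefers, among in-tolerance candidates, a formula
assemblable from the building-block grammar, falling back to the |ppm|-best
candidate. This mirrors how series membership, not accurate mass alone,
fixes the formula in siderophore dereplication. `assign_formula` exposes the
behaviour as `prefer_assemblable` (off by default at the library level).

## Oligomer grammar

Building blocks (free forms): acetyl cap C₂H₄O₂, succinyl diacid C₄H₆O₄,
cadaverine diamine C₅H₁₄N₂, N-hydroxy-cadaverine C₅H₁₄N₂O. Valid structures
alternate acid and diamine units; caps only at linear termini; a linear
chain of n blocks has n−1 amide bonds, a cycle n. Formula = Σ free blocks −
(bonds × H₂O). N-hydroxylation is a per-diamine-unit flag (in a hydroxamate
the hydroxylated nitrogen is the acylated one), which is exactly the
resolution needed to distinguish the positional isomers of dehydroxylated
congeners; enumeration reports every mass-consistent placement as a distinct
candidate. Symmetry is removed by canonicalization: linear chains read in
the lexicographically smaller direction, cycles by minimal
rotation/reflection.

Candidate enumeration over (diamine count d, diacid count a ∈ {d−1, d, d+1},
caps on free amine termini, N-OH placements), linear and cyclic, up to 12
blocks; masses are checked per composition before placements are expanded,
so the search is fast.

## In-silico fragmentation

Each amide cleavage of a protonated precursor yields a b-type acylium
(neutral acid fragment minus OH) and a y-type protonated amine (neutral
amine fragment plus H), both singly charged. For every cleavage,
mass(b) + mass(y) = mass([M+H]⁺) + mass(H) — asserted as a property test.
Cyclic precursors are ring-opened at each amide and the resulting chains
fragmented (two cleavages per observed fragment); the union is reported,
deduplicated by ion formula.

The minimal b/y set is the reference chemistry used for annotation: it is
sufficient to explain the diagnostic C₂₀H₃₅N₄O₅ acylium (calculated
411.2607, 1.1 mDa above the reported ion at 411.2596; the ion exists in the
fragment set exactly when both diamines flanking the cleaved succinyl carry
no N-OH). Two optional extensions reproduce the richness of real
collision-induced dissociation spectra of this compound class and are used
by the synthetic generator: water-loss satellites (for ions with ≥ 2
oxygens) and internal double-cleavage ions (e.g. protonated cadaverine at
m/z 103.123). Ion types are recorded per fragment; the diagnostic ion is a
b-type acylium — an interpretation, since no ion type is attached to the
reported value.

## Spectrum processing and similarity

Filters follow the standard molecular-networking recipe with all defaults in
one config block: fragment ions within ±17 Da of the precursor removed
(closed interval); a peak retained only if it is among the 6 most intense in
its own ±50 Da neighbourhood (sliding per-peak rule, intensity ties broken
toward lower m/z); blank subtraction at precursor level (10 ppm, optional
retention-time gate). Both peak filters are idempotent and never add peaks.

Modified cosine: candidate peak pairs match directly (|Δm/z| ≤ 0.02 Da) or
shifted by the precursor mass difference; pairs are scored by the product of
L2-normalized intensities and a one-to-one matching is chosen greedily by
descending pair score (ties toward lower m/z) — deterministic, and bounded
above by the exhaustive optimal matching (property-tested; equal whenever
the pair graph is itself a matching). Scores agree with an independent
implementation of the same statistic (matchms) to machine precision.
Network rules: edges need score > 0.7 and ≥ 4 matched peaks ("more than
three"); mutual top-10; oversized families (> 100 nodes) repeatedly lose
their lowest-scoring edge (deterministic tie-break on the node-id pair).
Library search uses ≥ 3 matched peaks ("at least three") — the two
matched-peak conventions are deliberately distinct and each configurable.

Intensity scaling: the library-level default scores raw intensities; the
pipeline default applies square-root scaling, matching the workflow the
panel emulates. Raw scoring lets a single dominant fragment carry most of
the score, which is exactly the failure mode sqrt scaling damps; both are
exposed everywhere as a flag.

## Dereplication library and Δ-mass annotation

A bundled TSV carries the reference desferrioxamine panel: name, neutral
formula, topology, N-OH count, block structure where the compound is an
oligomer, and a status column. `isolated` and `network_identified` entries
participate in dereplication; `network_proposed` entries (tentative congener
structures) are excluded by default so that the proposal machinery — not a
lookup — is what annotates them. Two named compounds of the original panel
are omitted because no verifiable formula was available; the TSV is
user-extensible. Ferrioxamine entries are the [desferrioxamine + Fe − 3H]
complexes.

Edges are labelled when |Δ precursor| matches a rule within 0.01 Da:
±O 15.9949 (hydroxylation/desoxy), ±H₂ 2.0157 (cyclic vs. acyclic),
±H₂O 18.0106, ±C₂H₂O 42.0106 (acetylation), ±(Na−H) 21.9819. The nominal
(integer-rounded) delta is reported alongside, matching how such differences
are quoted.

Diagnostic-fragment calls require a peak within 0.005 Da **and** at least 2%
of the base-peak intensity — a noise blip at the right mass is not evidence.

## Structure proposals

For an unannotated node adjacent to a structure-known node via a labelled
edge: enumerate candidates at the node's precursor mass, keep those
consistent with the Δ rule (±O: same skeleton and topology, N-OH count ±1;
±acetyl: one cap difference at equal N-OH; ±H₂: opposite topology), then
reject candidates whose fragment set cannot produce a diagnostic ion that is
*observed* in the node's spectrum. Observed presence is treated as strong
evidence; absence is never used to reject, because real spectra are
incomplete. Ranking: fraction of the node's peaks explained by the
candidate's b/y fragments (0.005 Da), then fewest N-OH placement changes
relative to the neighbour, then structure string. Proposals propagate for up
to three rounds, so a chain known → analogue → analogue-of-analogue
resolves even when only the first member is in the library.

## Synthetic panel: what it emulates, and what it does not

One spectrum per panel compound: precursor at the theoretical [M+H]⁺ with
ppm jitter, the compound's fragment ladder (b/y + water-loss satellites +
internal ions), and Poisson(10) low-intensity noise peaks uniform over
[80, precursor − 20] m/z.

- **Mass error**: N(0, 3 ppm) truncated at ±4.5 ppm, per ion — the bounded
  error of a calibrated Orbitrap-class instrument. Truncation matters: the
  recovery guarantee "every node's formula within 5 ppm" cannot hold for any
  seed under an unbounded error model.
- **Intensities**: each cleavage site carries a log-normal propensity
  (σ = 1.0, spanning the ~2 orders of magnitude of real relative
  abundances), drawn once per run and keyed by ion type plus the fragment's
  CHN skeleton, so corresponding fragments of desoxy/hydroxy analogues share
  their propensity — cleavage chemistry is conserved across a congener
  series. Each spectrum multiplies it by log-normal replicate noise
  (σ = 0.2, ~20% CV, instrument-level variation). Symmetry-degenerate
  cleavage channels feeding one m/z sum their contributions, so symmetric
  oligomers show fewer, proportionally stronger peaks, as their degenerate
  ladders do in reality.
- **Peak loss**: each spectrum keeps its most intense 80% of ladder
  positions (detection censoring). Modelling loss as independent random
  dropout instead provably caps the expected modified cosine of analogue
  pairs near the sampling fraction and makes analogue-pair scores coin-flips
  around the 0.7 network threshold; detection-limit censoring is both the
  physically correct mechanism and the reason real analogues lose
  *corresponding* weak fragments.
- **Determinism**: one seed drives everything; identical seeds give
  byte-identical MGF output.

What passing tests on this panel do **not** show about real data: intensity
patterns here are stylized (no collision-energy dependence, no rearrangement
chemistry); chromatography, adduct clusters and isotope envelopes are not
simulated; and cyclic compounds share no single-cleavage fragments with
linear ones under the b/y model, so the cyclic family connects to the linear
family only through precursor-mass reasoning, not spectral similarity —
real spectra, whose ring-opened internal ions overlap the linear series,
may do better.

## Numerical and degenerate-input choices

Duplicate centroids at 6-decimal m/z resolution merge by intensity sum on
spectrum construction. Empty spectra score 0 against anything and match no
library entry. Enumeration with empty bounds returns an empty list; a target
below any assemblable mass returns an empty candidate list, and proposals
for nodes without labelled edges are empty with the record left intact.
MGF serialization is deterministic (fixed field order, 6-decimal m/z,
4-significant-digit intensities), so file-level reproducibility is a
testable contract. Problem sizes throughout (9-compound panel, 5–10 seeds,
≤ 12 blocks) are desk-scale by design: every quantity in the acceptance
report recomputes in seconds.

## Known limitations

Single charge state only; CHNO(+Na) chemistry only; no isotope-pattern
scoring (the nitrogen rule and ratio filters stand in); the bundled library
is a small open reference set, not a comprehensive database; proposal
ranking by fragment coverage is a heuristic — on the synthetic panel it
recovers the true structure in the candidate set in 10/10 seeds, but
positional N-OH isomers that produce identical fragment formulas remain
genuinely indistinguishable by MS/MS alone, and are reported as co-ranked
candidates rather than resolved.
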