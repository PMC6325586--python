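# Methods

## Model

The screen treats a protein structure as a set of ordered Cα traces, one
per polypeptide chain, and asks whether two *distinct* chains run nearly
parallel over a sufficiently long fragment. That is the trace-level
signature of the cross-β stack: in a fibril, neighbouring chains are
hydrogen-bonded β-strands about 4.8 Å apart, so the per-residue minimum
inter-chain Cα distance is nearly constant over the strand.

For an ordered chain pair (A, B) the distance profile is
`C(A)_dist[i] = min_j ‖Cα_i(A) − Cα_j(B)‖`. A fragment F of A passes when

* **(a)** every profile value in F lies in [2, 15] Å and the standard
  deviation of the values is ≤ 1.5 Å, F being inclusion-maximal;
* **(b)** the pseudo-bond angles θ(i) at the interior Cα vertices of F
  (angle at Cα_i between rays to Cα_{i−1} and Cα_{i+1}), averaged over F,
  lie in [110°, 180°];
* **(c)** len(F) ≥ len(A)/7.

The structure verdict is positive iff any ordered pair of sheet-qualifying
chains yields at least one passing fragment. The distance profile is
directional, so both (A, B) and (B, A) are evaluated; the same residue
range found against two targets is reported twice, which keeps the
per-pair diagnostics faithful.

Rule (a) separates parallel from converging/diverging chains; rule (b)
removes locally parallel but curved arrangements, most importantly helix
bundles, whose vertex angles sit near 90° against ~127° for extended
strands; rule (c) prevents a short accidental contact on a long chain from
flagging the structure. The distinct-chain requirement encodes the
biology: a fibril is an aggregate, so single-chain entries — including
β-barrels, which are parallel to themselves — are negative regardless of
geometry.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `sigma_max` | 1.5 Å | max standard deviation of the fragment's profile |
| `d_min`, `d_max` | 2, 15 Å | allowed range of profile values |
| `theta_min`, `theta_max` | 110°, 180° | allowed mean pseudo-bond angle |
| `length_ratio_divisor` | 7 | fragment must cover ≥ 1/divisor of the chain |
| `min_fragment_residues` | 3 | floor so rule (b) has ≥ 1 interior vertex |
| `max_gap` | 4.5 Å | Cα–Cα distance treated as a chain break |
| `sample_std` | off | use n−1 instead of n in the deviation (sensitivity) |

All intervals are treated as closed. "Between 2 and 15 Å" and
"between 110° and 180°" are read inclusively, and the standard deviation
is the population form (divide by n): σ with no qualifier is most commonly
the population deviation, and the n-form is defined and stable for the
shortest (3-residue) windows. Both choices are surfaced as switches so a
sensitivity sweep needs no code changes.

## Reading structures

gemmi parses PDB and mmCIF. Only the first model of a multi-model (NMR)
file is screened — fibril depositions carry near-identical models and one
screening per entry is intended. Only ATOM records of the 20 standard
amino acids contribute (a configurable allowlist admits modified residues
such as MSE); for altloc'd CA atoms the highest occupancy wins, ties by
file order; chains without CA atoms (waters, ligands, nucleic acids) are
dropped. `len(A)` in rule (c) counts residues with a deposited Cα:
unresolved residues cannot contribute geometry, so they do not count.
The deposited asymmetric unit is screened as-is, with no
biological-assembly expansion.

Chains are split wherever consecutive Cα atoms are more than 4.5 Å apart
(trans Cα–Cα is ≈ 3.8 Å), and windows are confined to one segment so
neither the deviation of rule (a) nor the angle average of rule (b) spans
missing density. Rule (c) still divides by the full chain length, since
the length condition is about the chain, not the segment.

## β-sheet chain triage

Which chains count as "β-sheet chains" is genuinely open: deposited
annotation is authoritative when present but many solid-state NMR entries
lack it, and any geometric assignment from Cα alone is approximate. The
default mode uses SHEET/struct_sheet_range annotation when the file has
it and otherwise falls back to a Cα-only geometric call in the spirit of
P-SEA: an interior residue is extended iff its pseudo-bond angle lies in
[100°, 155°] and the pseudo-dihedral of the surrounding four Cα has
absolute value ≥ 90° (helices fall near +50°); terminal residues inherit
their nearest interior neighbour's flag. A chain qualifies when ≥ 25% of
residues are extended — deliberately permissive, because the triage should
not pre-empt rules (a)–(c). Modes `annotation`, `geometric` and `none`
(no triage) are selectable so all hypotheses can be tested against real
accession lists.

## Maximal-window search

The deviation constraint is not monotone under extension — adding a
residue can *lower* σ — so "maximal" means inclusion-maximal (no strict
superwindow qualifies), not globally longest, and maximal windows may
overlap. The implementation computes window deviations in O(1) from
prefix sums, finds for each start the longest qualifying end, and removes
dominated windows with a prefix-maximum scan; a shorter window at the same
start is always contained in the longest one, so this enumerates exactly
the inclusion-maximal set. The tests compare it, window for window,
against an independent O(n³) enumeration oracle on 1000 random profiles
plus property-based cases.

Angles are computed with a clamped arccos for stability near collinearity;
coincident points raise rather than return NaN. Degenerate inputs —
single-residue chains, empty window sets, profiles entirely out of bounds
— yield empty results, not errors.

## Synthetic structures

The generators produce the three decision-boundary archetypes with known
labels: cross-β stacks (planar zig-zag strands, 3.8 Å Cα step, 3.4 Å rise
— which together fix a ~127° vertex angle — stacked 4.8 Å apart, optional
per-chain twist and Gaussian coordinate noise), parallel ideal α-helices
(1.5 Å rise, 100°/residue, 2.3 Å radius, 10 Å apart), and a single chain
threading extended strands around a cylinder as a β-barrel (optionally
re-emitted as separate chains to show that only the distinct-chain rule,
not geometry, excludes barrels). The constants are textbook strand/helix
geometry, chosen so noise-free fixtures sit far from every rule boundary;
noise of σ = 6 Å destroys the parallel geometry and flips the label.

What the fixtures do *not* emulate: real fibril twist profiles, missing
density, sequence register, side-chain packing, or annotation quirks of
real depositions. Passing the offline suite therefore demonstrates the
rule engine's correctness on controlled geometry; verdicts on real
deposited entries are exercised by the accession tests, which need access
to the RCSB archive.

## Problem sizes

The randomised cross-checks use 1000 profiles of up to 50 residues for the
window oracle, 20 random seeds for the noise experiment, and fixture sizes
of 14–28 residues per chain — small enough that the whole suite runs in
seconds while still crossing every rule boundary.

## Known limitations

* The screen sees only Cα geometry: a pair of chains held parallel by
  crystal packing rather than hydrogen bonding will pass.
* Any single pair of chains suffices; no consistency across multiple
  neighbours (as in a real fibril lattice) is demanded.
* The β-sheet triage is heuristic at both ends: annotation can be absent
  or conservative, and the Cα-only geometric call cannot see hydrogen
  bonds (no DSSP-style assignment is attempted).
* The asymmetric unit is screened as deposited; a fibril represented by a
  single chain plus symmetry operators will be missed.
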