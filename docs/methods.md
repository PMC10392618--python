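# Methods

## The QTY substitution model

The package treats "making a membrane protein water-soluble" as a pure
sequence operation with fixed scope: inside each annotated transmembrane
(TM) segment, apply the mapping L→Q, I→T, V→T, F→Y; everywhere else,
change nothing. The mapping is total and context-free — no positional
exceptions, no substitution of M, W or A — because the code is defined by
side-chain shape equivalence (L/Q, I·V/T, F/Y pairs have near-identical
volumes and helix propensities) rather than by local environment. Two
consequences are treated as invariants throughout: the operation is
idempotent (Q, T, Y are not in its domain), and it is length-preserving,
so native/variant comparisons are positional and never need an alignment
algorithm.

Variation rates are reported as `100·|events|/L` (overall) and
`100·|events|/n_TM` (transmembrane), rounded half-up to two decimals,
matching the convention of published per-protein percentages. Before
rounding the two rates satisfy the exact identity
`overall·L = TM·n_TM = 100·|events|`, which the tests check in rational
arithmetic.

Hydrogen-bond capacity gain assigns 4 water H-bonds per introduced Q
(amide: two donors, two acceptors) and 3 per introduced T or Y (hydroxyl:
one donor, two acceptors); the replaced aliphatic/aromatic side chains
count 0.

## Topology

Coordinates are 1-based inclusive everywhere (the UniProt TRANSMEM
convention); conversion to 0-based slices happens only at array
boundaries. When an annotation table is supplied it always wins;
prediction is a fallback flagged `source="predicted"`.

The predictor is a Kyte–Doolittle sliding-window scan (window 19,
threshold 1.6 — the classical TM-detection setting; both overridable). A
residue is marked TM when *any* window containing it scores above
threshold, i.e. above-threshold window centres are expanded by half a
window to each side. This windows-union rule is what makes a 21-residue
hydrophobic block detectable at all under the 15-residue minimum length:
the run of above-threshold centres for such a block is only ~13 residues
wide, while the union covers the block plus at most half a window of
overhang on each side. Marked runs separated by ≤ 3 residues are merged,
then runs shorter than 15 are discarded, in that order. No HMM, signal
peptide or loop-orientation modelling is attempted.

## Sequence properties

- **Molecular weight**: sum of average-isotopic residue masses plus one
  water (18.0153 Da), the Expasy-style convention; the mass table is in
  `tables.py`. Average rather than monoisotopic masses because the
  published comparisons use the Expasy service.
- **Isoelectric point**: Henderson–Hasselbalch net charge over the
  termini and the ionizable side chains D, E, C, Y, H, K, R with the
  Bjellqvist pKa set (including its residue-specific N-terminal and
  terminal-D/E values; identical constants to Biopython's
  implementation, which the tests use as an independent cross-check).
  The zero crossing is found by bisection on [0, 14] to a pH bracket of
  1e-4. A charge-magnitude early exit exists but is off by default: on
  sequences with few ionizable groups the charge curve is nearly flat
  and a loose charge tolerance would cost pH accuracy. The classical
  EMBOSS set is selectable for sensitivity checks; having no
  terminal-specific pKas it is strictly composition-based, and the
  permutation-invariance test uses it for exactly that reason.
  Cysteines are treated as free (no disulfide correction). Because Y is
  ionizable, F→Y events can shift the pI slightly; variants without F→Y
  events have exactly the native pI.
- **GRAVY / profiles**: mean Kyte–Doolittle value and centred
  window means. Every QTY event strictly decreases hydropathy (all four
  mapped pairs drop by ≥ 4.1 units), so GRAVY(variant) < GRAVY(native)
  whenever at least one event occurred — asserted as a property.

## Superposition

`kabsch_superpose` is the closed-form least-squares rigid fit via SVD of
the 3×3 covariance matrix, with the reflection excluded by flipping the
smallest singular direction when the determinant is negative. Collinear
inputs (second singular value ≈ 0) are flagged degenerate but still
solved; the returned RMSD is well-defined even though the rotation is
not unique. Alpha-carbon-only RMSD is the default metric, the usual
convention for predicted-model comparison.

`refine_superpose` emulates viewer-style refinement: fit on kept pairs,
drop pairs whose deviation lies more than `sigma_cutoff` (default 2.0)
standard deviations *above the mean* deviation, repeat up to `cycles`
(default 5) times or until nothing is dropped. The cutoff is
mean + k·σ rather than k·σ alone because deviations are norms of 3-D
displacements (Maxwell-like, σ ≈ 0.42·mean): a threshold of 2σ absolute
would sit below the mean and reject most of a perfectly clean set. A
1e-6 Å floor and a σ < 1e-8 convergence guard keep identical inputs from
tripping the rejector on float noise. Both `rmsd_all` (final transform
applied to every pair) and `rmsd_refined` (kept pairs) are always
reported, since published RMSDs do not state which convention they use.

Residue pairing for native-vs-QTY models defaults to `by_sequence`
(positional), because QTY preserves length and numbering while changing
identity; pairing never inspects residue identity. `by_resnum` handles
models with missing residues.

## Surface hydrophobicity

Shrake–Rupley SASA: each atom's solvent-expanded sphere
(r_vdW + 1.4 Å probe) carries a deterministic golden-ratio spiral point
set (default 960 points; no randomness, hence bit-stable results);
points inside any neighbour's expanded sphere are removed and the
surviving fraction scales the sphere area. Neighbour search uses a
KD-tree. Radii: C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å;
unknown elements 1.70 Å with a warning. CA-only models fall back to one
3.0 Å bead per residue and the result is flagged `coarse`.

The hydrophobic surface fraction divides the SASA of residues in a set
by the total. The default set is exactly {L, I, V, F} — the residues the
QTY code replaces — so the metric measures precisely what the design
changes; a broader {L,I,V,F,A,M,W} set is available by flag. Two
numerical caveats are deliberate: the quadrature converges to ~1%
between 960 and 3840 points, and because the point set has a fixed lab
frame orientation, rigid-body rotation invariance holds only to
quadrature accuracy (tested at 0.01 absolute on the fraction).

## Synthetic fixtures

`synthetic_transporter` emulates a 12-TM transporter only at the level
that the statistics need: alternating polar loops (default 10 residues)
and hydrophobic-biased TM blocks (default 21 residues, matching a
membrane-spanning helix), drawn from fixed composition tables. The TM
composition places 48% of its mass on L/I/V/F so that synthetic TM
variation rates land in the ~44–50% band observed for real transporter
designs; the loop table contains no L/I/V/F at all, which makes the
post-QTY hydrophobic fraction of a synthetic bundle exactly zero (real
proteins keep hydrophobic loop residues, so theirs is reduced but
nonzero). Structures are ideal alpha-helix CA traces (rise 1.5 Å, twist
100°, radius 2.3 Å — consecutive-CA distance 3.83 Å) and Gaussian
perturbations with per-axis σ, for which the expected post-superposition
RMSD is σ√3. All generators take explicit seeds; there is no global
random state.

What passing tests on these fixtures show: the substitution logic,
rate arithmetic, superposition and SASA machinery are correct under
known ground truth. What they do not show: behaviour on real folds
(helix packing, inverted-repeat architecture, loops with hydrophobic
residues) or agreement with any particular published RMSD, which
depends on downloaded crystal structures and deposited predicted models
(`qty fetch` exists for that reproduction mode and requires network
access).

## Problem sizes

Default test and acceptance runs use 382-residue transporters (12×21 TM
+ 13×10 loop), 20-transporter ensembles for rate recovery (standard
error ~0.7 points at 252 TM residues each), 100-residue helices with 5
planted 10 Å outliers for rejection checks, 500-residue helices for the
σ√3 recovery, and 100 random sequences for the pI oracle comparison —
sizes at which every statistical tolerance in the tests is comfortably
wider than the corresponding sampling noise.

## Known limitations

- The TM predictor is a plain hydropathy scan; it under-segments
  borderline amphiphilic helices and is a fallback, not a topology
  method.
- pI is a composition-plus-termini model; it ignores local
  electrostatics and disulfides, like the service convention it follows.
- SASA in coarse CA mode is a one-bead approximation suitable for
  fractions and comparisons, not for absolute areas.
- Whole-sequence substitution (`whole_sequence=True`) exists for
  experimentation but is off by default; published designs substitute
  only within TM helices.
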