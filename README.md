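# qtykit

Designing water-soluble variants of multispan transmembrane helical
proteins with the **QTY code**, and quantifying how little the design
changes everything else.

Integral membrane proteins — glucose transporters (GLUTs) and other
12-transmembrane-helix carriers among them — expose leucine (L),
isoleucine (I), valine (V) and phenylalanine (F) side chains to the lipid
bilayer, which makes them aggregate in water and forces detergent-based
workflows. The QTY code is a deterministic substitution scheme that swaps
those four hydrophobic residues, *within the transmembrane helices only*,
for hydrophilic residues of near-identical side-chain shape:

```
L → Q (glutamine)     I → T (threonine)
V → T (threonine)     F → Y (tyrosine)
```

Q, T and Y introduce no charge, only water hydrogen-bonding capacity (the
Q amide forms 4 water H-bonds, the T/Y hydroxyls 3 each), so the variant
keeps its helical geometry, molecular weight and isoelectric point almost
unchanged while its lipid-facing surface becomes hydrophilic.

`qtykit` implements the code and the full comparison pipeline around it:

- **Sequence/topology I/O** — FASTA, a simple TM-range TSV, UniProt
  `FT TRANSMEM` lines, and a Kyte–Doolittle sliding-window TM predictor
  as fallback (window 19, threshold 1.6).
- **QTY engine** — substitution events, overall and transmembrane
  variation rates (`100·|events|/L` and `100·|events|/n_TM`), and the
  hydrogen-bond capacity gained.
- **Sequence properties** — average-mass MW, Bjellqvist-model pI by
  bisection, GRAVY and hydropathy profiles.
- **Alignment rendering** — the annotated native-vs-variant block
  alignment (`|` identical, `*` substituted, `=` helix track).
- **Structure comparison** — PDB reading (gemmi), Kabsch superposition
  with proper-rotation correction, and iterative outlier-rejection
  refinement reporting both all-pair and refined RMSD.
- **Surface hydrophobicity** — Shrake–Rupley SASA on a deterministic
  golden-spiral point set and the hydrophobic surface fraction (share of
  SASA from {L,I,V,F}), the numeric proxy for a hydrophobic patch.
- **Fixtures** — seeded synthetic 12-TM transporters and ideal-helix
  coordinate builders, so every analysis is testable offline.

## Worked example

Generate a synthetic 12-TM transporter and run the pipeline:

```bash
qty fixtures --out fx --seed 3
qty run --fasta fx/transporter.fasta --tm-table fx/transporter.tm.tsv --out out
cat out/properties.tsv
```

```
id	length	MW_native	MW_QTY	pI_native	pI_QTY	overall_pct	TM_pct
synthetic_3	382	41653.17	42470.41	5.61	5.61	33.51	50.79
```

Reading the row: the QTY variant differs from the native sequence at
33.51% of all positions and 50.79% of transmembrane positions, yet the
molecular weight moves by only ~817 Da (the added –OH/–NH₂ groups) and
the pI does not move at all here — Q and T are non-ionizable, so only
F→Y events can shift it. The same contrast drives real transporter
designs, where TM variation of ~44–50% leaves MW and pI nearly intact.

A small alignment rendering (`qty render`):

```
            =========
toy      MKKLLIVFLIVFAKDE  16
         |||*********||||
toy_QTY  MKKQQTTYQTTYAKDE  16
```

Structural comparison and surface hydrophobicity:

```bash
qty superpose fx/transporter_ca.pdb fx/transporter_ca.pdb
# rmsd_all  rmsd_refined  n_paired  n_kept
# 0.000     0.000         382       382
qty sasa fx/transporter_ca.pdb
# total_sasa  hydrophobic_sasa  hydrophobic_fraction  mode
# 24378.7     8086.9            0.3317                coarse_ca
```

After QTY relabelling, the hydrophobic fraction of the same geometry
drops to 0 — the quantitative form of "the hydrophobic patch is
reduced".

An optional `qty fetch <accession>` helper downloads a UniProt entry
(FASTA + TRANSMEM table) for reproducing published designs from real
sequences such as GLUT1 (P11166) or GLUT3 (P11169); it needs network
access and nothing else in the package depends on it.

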