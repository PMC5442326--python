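# tetrahelix

Sequence and structure analysis of **AGCGA-quadruplexes** — a tetrahelical
DNA family built from four 5′-AGCGA-3′ tracts and stabilized by G-A and G-C
base pairs that assemble into GAGA- and GCGC-quartets, rather than the
G-quartets of canonical G-quadruplexes.

The package is aimed at structural bioinformaticians and NMR
spectroscopists working on non-canonical DNA. It covers the computational
side of characterizing these folds:

* **Consensus scanning** (`tetrahelix.seqscan`) — find
  5′-AGCGA(N₁₋₂₀)AGCGA(N₁₋₂₀)AGCGA(N₁₋₂₀)AGCGA-3′ motifs and the
  G-quadruplex consensus 5′-GGG(N₁₋₇)GGG(N₁₋₇)GGG(N₁₋₇)GGG-3′ in FASTA
  input, on both strands, with BED6/TSV output; plus the nearest-neighbour
  260 nm extinction coefficient.
* **Ensemble I/O** (`tetrahelix.structio`) — validated multi-model
  PDB/mmCIF reading and writing for DA/DC/DG/DT/DI nucleotides (gemmi
  backend), hydrogens retained.
* **Pairing** (`tetrahelix.pairing`) — hydrogen-bond detection and
  classification of Watson-Crick G-C pairs, G-G pairs in N1-carbonyl
  symmetric geometry, G-A pairs in N1-N7 carbonyl-amino geometry, Hoogsteen
  G-I pairs; assembly of GAGA-, GGGG- and minor/major-groove GCGC-quartets;
  crisscross-topology detection (stacked pair couples with inter-pair twist
  ≥ 35°).
* **Geometry** (`tetrahelix.geometry`) — standard base reference frames by
  template fitting; intra-pair (shear/stretch/stagger/buckle/propeller/
  opening) and inter-step (shift/slide/rise/tilt/roll/twist) parameters via
  the mid-frame (CEHS-style) construction; quartet non-planarity; backbone
  torsions, glycosidic χ classes (syn/anti/high-anti) and
  Altona–Sundaralingam sugar puckers; groove widths from cross-strand P–P
  distances.
* **Restraints** (`tetrahelix.restraints`) — NOE volume calibration
  (intra-nucleotide H8-H1′ of *anti* residues referenced to 3.9 Å),
  isolated-spin-pair r = 3.9·(V_ref/V)^(1/6) distance estimates binned as
  strong (1.8–3.6 Å), medium (2.6–5.0 Å), weak (3.5–6.5 Å) and very weak
  (4.5–7.5 Å); χ torsion, hydrogen-bond and planarity restraints with
  conventional force constants (20 / 200 / 50 kcal mol⁻¹).
* **Synthetic fixtures** (`tetrahelix.synthetic`) — ground-truth quartet
  stacks with controllable rise/twist/buckle/propeller and noise, planted
  consensus motifs, and r⁻⁶ NOE volume tables, all fully seeded.
* **Pipeline + CLI** (`tetrahelix.pipeline`, `tetrahelix` command) —
  one-call structure reports with ensemble consensus and an overall
  topology call (TYPE 1: stacked GAGA + GCGC quartet core; TYPE 2: central
  G-C pairs with peripheral G-A pairs).

## Worked example

```python
import tetrahelix as tx

# VK34, the 15-mer d(GCGAGGGAGCGAGGG)
vk34 = tx.NucleotideSequence("VK34", "GCGAGGGAGCGAGGG")
tx.extinction_260(vk34)          # 155200.0  (M^-1 cm^-1)

# 4VK34: four VK34 units joined by single adenines -> 63 nt
four = tx.NucleotideSequence("4VK34", "A".join(["GCGAGGGAGCGAGGG"] * 4))
summary = tx.classify_sequence(four)
summary["n_agcga_repeats"]       # 7
summary["dual_consensus"]        # True: matches both consensus motifs
```

The sequence satisfies the G-quadruplex consensus *and* the
AGCGA-quadruplex consensus (`dual_consensus=True`) — the situation where
these sequences fold into AGCGA-quadruplexes instead of G-quadruplexes.

```python
from tetrahelix import StackSpec, build_quartet_stack, analyze_structure

# a tetramer-like core: GCGC / GGGG / GAGA / GAGA / GGGG / GCGC
spec = StackSpec(
    layer_classes=["GCGC_MAJOR", "GGGG", "GAGA", "GAGA", "GGGG", "GCGC_MAJOR"],
    rise=3.4, twist=[0, 20, 25, 25, 25, 20],
)
ens, truth = build_quartet_stack(spec)
report = analyze_structure(ens)
report.topology                  # 'TYPE 1'
```

The report's quartet table recovers the constructed stack exactly:

```
       residues      class  quartet_buckle
A:1+B:1+C:1+D:1 GCGC_MAJOR            0.00
A:2+B:2+C:2+D:2       GGGG            0.01
A:3+B:3+C:3+D:3       GAGA            0.00
A:4+B:4+C:4+D:4       GAGA            0.00
A:5+B:5+C:5+D:5       GGGG            0.01
A:6+B:6+C:6+D:6 GCGC_MAJOR            0.00
```

and the step between the two core GAGA-quartets reads twist 25.0°, rise
3.40 Å — the injected construction parameters, and the values typical of
the distinctive large-twist GAGA-quartet stacking in these folds.

The same analyses are available from the shell:

```sh
tetrahelix synth stack --out core            # writes core.pdb + truth JSON
tetrahelix analyze --structure core.pdb --out report
tetrahelix scan --fasta genes.fa --motif both --out hits
```

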