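# Methods

This note documents the models, conventions and numerical choices behind
`tetrahelix`, what the synthetic fixtures do and do not demonstrate, and
the design decisions taken where more than one convention is defensible.

## Consensus scanning

The AGCGA-quadruplex consensus is four literal 5′-AGCGA-3′ repeats with
three spacers of `min_spacer..max_spacer` residues (defaults 1 and 20); the
G-quadruplex folding consensus uses GGG tracts with spacers of 1–7.
Repeat occurrences may overlap in the occurrence index, but the repeat
blocks of a single match never overlap (spacer ≥ 0 is enforced through
`min_spacer`). `min_spacer=0` is exposed because merged-repeat variants
(AGCG·AGCGA, an adenine deletion between tandem repeats) occur in real
regulatory sequences.

Two reporting modes exist. `all` enumerates every valid decomposition into
four repeats. `minimal` returns non-overlapping matches chosen by leftmost
start, then shortest end, then lexicographically smallest repeat starts —
a total order, so output is deterministic. Minus-strand hits are found by
scanning the reverse complement and reported in plus-strand coordinates.
Coordinates are 0-based half-open internally and in BED output.

Note that joining repeat units with single adenines can create *new*
repeat occurrences spanning the junctions (an A before GCGA... yields
AGCGA); the scanner treats these like any other occurrence, and the
minimal decomposition may therefore use shorter spacers than the unit
length suggests. The brute-force oracle in the test suite pins this
behaviour down.

The 260 nm molar extinction coefficient uses the nearest-neighbour method,
ε = Σ ε(dinucleotide) − Σ ε(interior mononucleotide), with the
Cantor–Warshaw–Shapiro coefficient table shipped as versioned data
(`data/extinction_nn.tsv`, citation recorded in the file). For the VK34
15-mer d(GCGAGGGAGCGAGGG) this evaluates to 155,200 M⁻¹ cm⁻¹ exactly.
Residues without table entries (N, I) raise an explicit error rather than
guessing.

## Base templates and reference frames

Idealized nucleotide geometry comes from the PDB chemical component
dictionary (bundled with biotite, exported at build time into
`data/base_templates.json`). Each base is superposed via its ring atoms
onto the standard nucleic-acid base reference frame (Olson et al. 2001),
so templates lie in the z = 0 plane with the conventional in-plane
orientation; ring-fit RMSDs of the anchoring are 0.02–0.07 Å.
Hypoxanthine (DI) has no published standard-frame entry and is anchored on
the guanine ring through the nine shared purine ring atom names.

A residue's frame is the proper rotation + translation that carries its
template onto the observed ring atoms (Kabsch superposition). The fit
residual is reported; above 0.5 Å the base is flagged distorted.

## Pair and step parameters

Intra-pair and inter-step parameters use the mid-frame (CEHS-style)
construction: the two frames are rotated by ± half the angle between their
normals about the hinge axis, twist (or opening) is the in-plane angle
between the aligned frames, and the remaining rotation is decomposed along
the mid-frame x and y axes into tilt/roll (steps) or buckle/propeller
(pairs). Translations are expressed in the mid-frame. The anti-oriented
partner of a pair is flipped 180° about its own x axis first. Parameters
are therefore comparable with mainstream helical-analysis tools; signed
values and magnitudes are both reported, since the sign convention depends
on strand ordering.

**Unit frames.** The frame of a pair or quartet used for step parameters
takes its normal from the mean of the (sign-aligned) base normals and its
in-plane orientation from the first base's x axis projected onto the mean
plane. A quaternion average is *not* used: the bases of a quartet are
related by in-plane rotations approaching 180°, where quaternion means are
degenerate and can tilt the mean normal by tens of degrees. The chosen
construction is rigid-motion equivariant and recovers generator-injected
step parameters exactly. A consequence worth knowing: step twist between
two units of the *same* class is directly interpretable (and is what the
package reports for, e.g., GAGA/GAGA steps), whereas twist between units
of different classes contains a class-dependent in-plane offset.

**Quartet buckle** is defined here as the angle between the best-fit
planes of the two constituent base pairs (range 0–90°), with the deviation
of all ring atoms from a single common plane reported alongside
(`plane_rmsd`). This is an interpretation — the quantity is not given a
formal definition in the structural literature on these folds — and it is
the definition the synthetic generator injects, so the two are consistent
by construction.

## Torsions, χ classes, puckers, grooves

Backbone torsions α…ζ and glycosidic χ (O4′-C1′-N9-C4 for purines,
O4′-C1′-N1-C2 for pyrimidines) use IUPAC atom quadruples and are reported
in [0, 360). Terminal residues yield absent (None) values for angles that
span a missing neighbour. Sugar pucker uses the Altona–Sundaralingam
pseudorotation phase from the five endocyclic torsions; North is
P ∈ [324°, 36°], South is P ∈ [108°, 180°].

χ classes partition [0, 360): anti = [170°, 280°] (the conventional NMR
restraint window for purines), high-anti = (280°, 320°), syn =
[320°, 360°) ∪ [0°, 90°], other = (90°, 170°). The anti window is also
what the χ restraint generator emits (purines 170–280°, pyrimidines
170–310°, force constant 200 kcal mol⁻¹ rad⁻²).

Groove widths are cross-strand P–P distances minus 5.8 Å (the conventional
phosphate-radius correction). For an antiparallel strand pair the package
reports, per residue, the minimal corrected distance to partner-strand
phosphates within six registers on the 5′ side and on the 3′ side
separately; on a canonical B-form duplex these two directional minima are
the minor- and major-groove widths (≈ 5.9 and ≈ 11 Å). Labels: narrow
< 4 Å, medium 4–9 Å, wide > 9 Å (configurable).

## Hydrogen bonds and pairing classes

Donors are base N/O atoms carrying a hydrogen (each hydrogen is attached
to its nearest heavy atom — robust under coordinate noise, unlike a fixed
covalent-distance cutoff); acceptors are base N/O atoms of other residues.
Criteria: donor–acceptor distance ≤ 3.5 Å and donor-H-acceptor angle
≥ 120° (config-exposed). For models without hydrogens a fallback uses a
per-residue-type donor table and requires the acceptor on the outward side
of the donor. Bonds are reported in a deterministic order.

Pair classification matches observed bonds against an editable pattern
table (`data/pair_patterns.tsv`): WC_GC (three canonical bonds),
GG_N1_CARBONYL (reciprocal N1-H···O6), GA_N1N7_CARBONYLAMINO
(G N1-H···A N7 + A N6-H···G O6), and G_I_HOOGSTEEN. A classified pair
needs at least two matching bonds; bonded but unmatched pairs are OTHER.
For the G-I Hoogsteen pair the table uses the G-quartet-like arrangement —
guanine WC edge donating into the hypoxanthine Hoogsteen face
(G N1-H···I O6 and G N2-H···I N7) — because hypoxanthine's own WC edge has
a single donor and could not satisfy the two-bond requirement.

Quartets: GAGA = two G-A pairs cross-linked by A N6-H···G N7;
GCGC_MINOR/_MAJOR = two WC G-C pairs cross-linked through G N2-H···C O2
(minor-groove edges) or C N4-H···G O6 (major-groove edges); GGGG = a
directed 4-cycle of guanine N1/N2 → O6/N7 bonds. Candidates are accepted
greedily by descending total hydrogen-bond count (ties: lowest residue
indices), each residue joining at most one quartet per model.

Crisscross topology: two classified pairs joining the same two strands,
stacked (inter-pair rise ≤ 6 Å) with |inter-pair twist| ≥ 35° — capturing
the distinctive 40–60° twists of crisscross G-G pair couples.

Ensemble aggregation reports per-model tables plus a consensus of items
present in ≥ 50% of models (configurable). The overall topology call —
TYPE 1 (≥ 2 GAGA-quartets plus ≥ 1 GCGC-quartet) versus TYPE 2 (≥ 4
central G-C pairs, no GAGA-quartets, peripheral G-A pairs) versus
neither — uses config-exposed thresholds, since only prose definitions of
the two fold types exist.

## NOE restraints

The reference volume is the arithmetic mean of intra-nucleotide H8-H1′
cross-peak volumes of residues known to be *anti*, mapped to 3.9 Å.
Distances are estimated with the isolated-spin-pair relation
r̂ = 3.9·(V_ref/V)^(1/6) and binned: strong (1.8–3.6 Å), medium
(2.6–5.0 Å), weak (3.5–6.5 Å), very weak (4.5–7.5 Å). Because the bins
overlap, the class-assignment cutoffs cannot be inferred from the bounds
alone; the package uses r̂ < 3.0 / 4.2 / 5.5 Å near the bin midpoints,
config-exposed. Distance restraints carry force constant 20 kcal mol⁻¹ Å⁻²;
hydrogen-bond restraints use heavy-atom bounds 2.7–3.1 Å per classified
bond; planarity groups (force constant 50 kcal mol⁻¹ rad⁻²) are emitted
for GAGA-quartets and N1-carbonyl G-G pairs only. Restraint counts from
any particular spectral dataset are provenance metadata, not reproducible
targets. Serialization is TSV or fixed-width flat list; both round-trip.

## Synthetic fixtures: what they show and what they do not

The stack generator solves, once per layer class, the in-plane pose of
rigid idealized bases that satisfies the class's hydrogen-bond pattern
(least squares on donor–acceptor distance 2.9 Å and near-linear hydrogen
placement, with a clash penalty; deterministic multi-start). Layers are
then stacked by exact rigid transforms: rise along and twist about the
stack axis between layers, buckle as a symmetric split between the layer's
two halves, propeller within each pair. Because the injections are exact
transforms of otherwise identical layers, recovered step parameters equal
the injected ones to ≈ 0.01 units, which is what the injection-recovery
tests assert (tolerance 0.1).

Backbone attachment mode adds the template sugar-phosphate rigidly per
base. Intra-residue quantities (χ, δ, pucker) are then well-defined;
inter-residue backbone connectivity is *not* maintained between layers, so
α/β/ε/ζ across layer boundaries are not meaningful in generated stacks,
and generated NOE tables exclude proton pairs closer than 2 Å (geminal
contacts and backbone-boundary artifacts are not usable cross-peaks).

Sequence planting places non-overlapping consensus motifs with spacers
drawn uniformly from the requested range into uniform-random background;
the truth table lists exact repeat coordinates. NOE simulation follows
V = scale·r⁻⁶·exp(ε), ε ~ N(0, cv), with distances averaged over models.

Passing on these fixtures demonstrates correctness of the detection and
parameter machinery under controlled geometry. It does not demonstrate
performance on experimental ensembles, where bases are internally
distorted, hydrogen-bond geometry is irregular, spectra are incomplete,
and conformational heterogeneity couples parameters; deposited NMR
ensembles (e.g. PDB 5M1L, 5M2L, 5M4W) remain the appropriate validation
inputs where available. With thresholded bond detection, class recovery
under coordinate noise is near-certain but not guaranteed: at σ = 0.15 Å
each bond retains a sub-percent chance of crossing the distance or angle
cutoff, so seeded tests assert exact recovery while the acceptance script
reports recovery averaged over ten noise draws.

## Problem sizes and defaults

Default study-scale parameters: scanner validation on 1000 random
sequences of length ≤ 500 nt; quartet stacks of 1–6 layers at rise
2.5–5.5 Å, twist −60°…60°, buckle −40°…40°; coordinate noise σ ≤ 0.15 Å;
NOE tables of ~300 proton pairs with 20% multiplicative noise. Hydrogen
bond defaults 3.5 Å / 120°; crisscross threshold 35°; consensus fraction
0.5. All defaults live in `tetrahelix.config.Config`, are printable with
`tetrahelix --dump-config`, and every report records the config hash.

## Known limitations

* No curvilinear-axis analysis; parameters are local (mid-frame), so
  strongly bent stacks are described stepwise, not globally.
* Pair classification covers the classes above plus OTHER; it is not a
  full 12-family edge-interaction taxonomy.
* The TYPE 1/TYPE 2 topology call is heuristic (prose-derived thresholds)
  and is best treated as a label for downstream human inspection.
* Groove widths assume an antiparallel register between the two strands
  of each requested pair.
* The generator's backbone mode is rigid and idealized; it supports
  torsion/pucker plumbing tests, not backbone conformational realism.
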