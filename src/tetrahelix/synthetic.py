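"""Ground-truth fixture generation.

Three generators make every analysis stage testable without any downloads:

* :func:`build_quartet_stack` constructs coordinate models of stacked
  base-pair / quartet layers from idealized base templates.  Hydrogen-bond
  geometry within a layer is solved by least squares against the same
  donor/acceptor pattern tables the detector uses, and inter-layer rise,
  twist, buckle and propeller are injected as exact rigid transforms, so
  the construction parameters are recoverable ground truth.
* :func:`plant_sequence_motifs` writes random sequences with AGCGA-consensus
  motifs planted at known coordinates, together with a truth table.
* :func:`simulate_noe_volumes` emits NOE volume tables following the
  inverse-sixth-power distance law with optional multiplicative log-normal
  noise.

All randomness is driven by explicit integer seeds via numpy's Generator,
so identical specs give byte-identical outputs.
"""
from __future__ import annotations

import copy
import functools
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .geometry import base_templates, rotation_about
from .pairing import pattern_table
from .seqscan import AGCGA_REPEAT, MotifMatch, NucleotideSequence
from .structio import (AtomRecord, Chain, Model, Residue, StructureEnsemble)

_BACKBONE_NAMES = {"P", "OP1", "OP2", "OP3"}


def _is_base_atom(name: str) -> bool:
    return "'" not in name and name not in _BACKBONE_NAMES


def _template_arrays(resname: str, backbone: bool) -> tuple[list[str], list[str], np.ndarray]:
    tpl = base_templates()[resname]
    keep = [
        i for i, name in enumerate(tpl["atoms"])
        if backbone or _is_base_atom(name)
    ]
    names = [tpl["atoms"][i] for i in keep]
    elements = [tpl["elements"][i] for i in keep]
    coords = tpl["coords"][keep].copy()
    return names, elements, coords


def _donor_hydrogens(names: Sequence[str], coords: np.ndarray, donor: str) -> list[int]:
    di = names.index(donor)
    return [
        i for i, n in enumerate(names)
        if n.startswith("H") and np.linalg.norm(coords[i] - coords[di]) < 1.25
    ]


@dataclass
class _Base:
    resname: str
    names: list[str]
    elements: list[str]
    coords: np.ndarray

    def copy(self) -> "_Base":
        return _Base(self.resname, list(self.names), list(self.elements),
                     self.coords.copy())

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "_Base":
        out = self.copy()
        out.coords = (R @ self.coords.T).T + t
        return out

    def coord(self, atom: str) -> np.ndarray:
        return self.coords[self.names.index(atom)]


def _make_base(resname: str, backbone: bool) -> _Base:
    return _Base(resname, *_template_arrays(resname, backbone))


_FLIP = np.diag([1.0, -1.0, -1.0])  # 180 deg about x: anti-orient a partner

_HB_TARGET = 2.90   # heavy donor-acceptor distance, A
_HH_TARGET = 1.92   # hydrogen-acceptor distance for a linear bond, A
_CLASH_DIST = 2.6   # non-bonded heavy-heavy distances below this are penalized


def _bond_residuals(bases: Sequence[_Base], bonds) -> list[float]:
    """Residuals of hydrogen-bond geometry for (donor_base_idx, donor_atom,
    acceptor_base_idx, acceptor_atom) tuples."""
    res = []
    for bi, datom, bj, aatom in bonds:
        D = bases[bi].coord(datom)
        A = bases[bj].coord(aatom)
        res.append(float(np.linalg.norm(D - A)) - _HB_TARGET)
        hs = _donor_hydrogens(bases[bi].names, bases[bi].coords, datom)
        if hs:
            dh = min(float(np.linalg.norm(bases[bi].coords[h] - A)) for h in hs)
            res.append(dh - _HH_TARGET)
    return res


def _clash_penalty(bases: Sequence[_Base]) -> float:
    """Penalty for inter-base heavy-atom contacts closer than _CLASH_DIST
    (hydrogen-bond donor/acceptor targets sit above the threshold)."""
    total = 0.0
    for a, b in itertools.combinations(bases, 2):
        ca = a.coords[[i for i, e in enumerate(a.elements) if e != "H"]]
        cb = b.coords[[i for i, e in enumerate(b.elements) if e != "H"]]
        d = np.sqrt(((ca[:, None, :] - cb[None, :, :]) ** 2).sum(-1))
        total += float(np.clip(_CLASH_DIST - d, 0.0, None).sum())
    return 5.0 * total


def _solve_inplane(cost, x0_grid: Sequence[Sequence[float]]):
    """Deterministic multi-start in-plane least squares."""
    best = None
    for x0 in x0_grid:
        sol = least_squares(cost, x0, method="lm", max_nfev=200)
        if best is None or sol.cost < best.cost:
            best = sol
    return best.x, best.cost


# ---------------------------------------------------------------------------
# pair and quartet layer construction
# ---------------------------------------------------------------------------

#: pair layer classes -> classification pattern name
_PAIR_OF = {"GG_PAIR": "GG_N1_CARBONYL", "GC_PAIR": "WC_GC", "GA_PAIR":
            "GA_N1N7_CARBONYLAMINO", "GI_PAIR": "G_I_HOOGSTEEN"}

#: quartet classes built from two pairs + cross-links
_QUARTET_PAIR = {
    "GAGA": ("GA_PAIR", ("N6", "DA", "N7", "DG")),
    "GCGC_MINOR": ("GC_PAIR", ("N2", "DG", "O2", "DC")),
    "GCGC_MAJOR": ("GC_PAIR", ("N4", "DC", "O6", "DG")),
}

LAYER_CLASSES = ("GAGA", "GGGG", "GCGC_MINOR", "GCGC_MAJOR", "GG_PAIR",
                 "GC_PAIR", "GA_PAIR", "GI_PAIR")


@functools.cache
def _build_pair_cached(layer_class: str, backbone: bool) -> tuple[_Base, _Base]:
    """Two coplanar bases positioned so the class's hydrogen-bond pattern is
    satisfied; the in-plane pose of the partner is solved by least squares.

    Both the antiparallel (partner flipped about x) and parallel (C2 about
    the plane normal) orientations are tried and the better fit is kept.
    """
    pattern = pattern_table()[_PAIR_OF[layer_class]]
    b1_name, b2_name = pattern["bases"]
    base1 = _make_base(b1_name, backbone)
    base2_raw = _make_base(b2_name, backbone)

    bonds = [
        (0 if dr == 1 else 1, da, 0 if ar == 1 else 1, aa)
        for dr, da, ar, aa in pattern["bonds"]
    ]
    grid = [
        (th, tx, ty)
        for th in np.radians([0, 45, 90, 135, 180, 225, 270, 315])
        for tx in (-3.0, 0.0, 3.0)
        for ty in (-4.0, 0.0, 4.0)
    ]

    best = None
    for flip in (True, False):
        def placed(params, flip=flip):
            th, tx, ty = params
            R = rotation_about([0, 0, 1], math.degrees(th))
            if flip:
                R = R @ _FLIP
            return base2_raw.transformed(R, np.array([tx, ty, 0.0]))

        def cost(params, placed=placed):
            pair = [base1, placed(params)]
            return _bond_residuals(pair, bonds) + [_clash_penalty(pair)]

        x, c = _solve_inplane(cost, grid)
        if best is None or c < best[1]:
            best = ((base1, placed(x)), c)
    return best[0]


def _build_pair(layer_class: str, backbone: bool) -> list[_Base]:
    return [b.copy() for b in _build_pair_cached(layer_class, backbone)]


@functools.cache
def _build_two_pair_quartet_cached(layer_class: str, backbone: bool) -> tuple[_Base, ...]:
    """Quartet = pair + its C2 copy (180 deg about z through a solved centre),
    with the class's cross-link bonds enforced."""
    pair_class, (datom, dbase, aatom, abase) = _QUARTET_PAIR[layer_class]
    pair1 = _build_pair(pair_class, backbone)

    def placed(params):
        cx, cy = params
        R = rotation_about([0, 0, 1], 180.0)
        t = np.array([2 * cx, 2 * cy, 0.0])
        # rotation about the point (cx, cy): p -> R p + (I - R) c
        return [b.transformed(R, t) for b in pair1]

    def cross_bonds(pair2):
        # donor of dbase type in one pair, acceptor of abase in the other
        bonds = []
        for pi, pj in ((0, 1), (1, 0)):
            src = pair1 if pi == 0 else pair2
            dst = pair2 if pi == 0 else pair1
            for a, b in itertools.product(range(2), range(2)):
                if src[a].resname == dbase and dst[b].resname == abase:
                    bonds.append((a if pi == 0 else 2 + a, datom,
                                  2 + b if pi == 0 else b, aatom))
        return bonds

    def cost(params):
        pair2 = placed(params)
        allb = pair1 + pair2
        res = []
        for bi, da, bj, aa in cross_bonds(pair2):
            D, A = allb[bi].coord(da), allb[bj].coord(aa)
            res.append(float(np.linalg.norm(D - A)) - _HB_TARGET)
            hs = _donor_hydrogens(allb[bi].names, allb[bi].coords, da)
            if hs:
                dh = min(float(np.linalg.norm(allb[bi].coords[h] - A)) for h in hs)
                res.append(dh - _HH_TARGET)
        res.append(_clash_penalty(allb))
        return res

    grid = [(cx, cy) for cx in np.arange(-6, 6.1, 2.0) for cy in np.arange(-6, 6.1, 2.0)]
    best_x, best_cost = None, None
    for x0 in grid:
        sol = least_squares(cost, x0, method="lm", max_nfev=200)
        if best_cost is None or sol.cost < best_cost:
            best_x, best_cost = sol.x, sol.cost
    return tuple(pair1 + placed(best_x))


def _build_two_pair_quartet(layer_class: str, backbone: bool) -> list[_Base]:
    return [b.copy() for b in _build_two_pair_quartet_cached(layer_class, backbone)]


@functools.cache
def _build_gggg_cached(backbone: bool) -> tuple[_Base, ...]:
    """Cyclic G-quartet: one guanine pose replicated by C4 symmetry about z,
    solved so that N1->O6 and N2->N7 bonds close around the cycle."""
    g0 = _make_base("DG", backbone)

    def placed(params):
        th, tx, ty = params
        R0 = rotation_about([0, 0, 1], math.degrees(th))
        b0 = g0.transformed(R0, np.array([tx, ty, 0.0]))
        return [
            b0.transformed(rotation_about([0, 0, 1], 90.0 * k), np.zeros(3))
            for k in range(4)
        ]

    def cost(params):
        bases = placed(params)
        bonds = [(k, "N1", (k + 1) % 4, "O6") for k in range(4)]
        bonds += [(k, "N2", (k + 1) % 4, "N7") for k in range(4)]
        return _bond_residuals(bases, bonds) + [_clash_penalty(bases)]

    grid = [
        (th, tx, ty)
        for th in np.radians([0, 45, 90, 135, 180, 225, 270, 315])
        for tx in (2.0, 4.0)
        for ty in (-3.0, 0.0, 3.0)
    ]
    x, _ = _solve_inplane(cost, grid)
    return tuple(placed(x))


def _build_gggg(backbone: bool) -> list[_Base]:
    return [b.copy() for b in _build_gggg_cached(backbone)]


def _build_layer(layer_class: str, backbone: bool) -> list[_Base]:
    if layer_class in _PAIR_OF:
        return _build_pair(layer_class, backbone)
    if layer_class in _QUARTET_PAIR:
        return _build_two_pair_quartet(layer_class, backbone)
    if layer_class == "GGGG":
        return _build_gggg(backbone)
    raise ValueError(
        f"unknown layer class {layer_class!r}; supported: {LAYER_CLASSES}"
    )


# ---------------------------------------------------------------------------
# stack assembly
# ---------------------------------------------------------------------------


@dataclass
class StackSpec:
    """Recipe for a stack of quartet/pair layers.

    rise/twist are applied stepwise between consecutive layers; buckle and
    propeller are intra-layer deformations.  Scalars broadcast over layers.
    """

    layer_classes: Sequence[str]
    rise: float | Sequence[float] = 3.4        # A, step i-1 -> i
    twist: float | Sequence[float] = 25.0      # deg
    buckle: float | Sequence[float] = 0.0      # deg, between layer halves
    propeller: float | Sequence[float] = 0.0   # deg, within each pair
    noise_sigma: float = 0.0                   # A, isotropic Gaussian
    seed: int = 0
    backbone: bool = False

    def __post_init__(self):
        if len(self.layer_classes) < 1:
            raise ValueError("at least one layer required")
        for c in self.layer_classes:
            if c not in LAYER_CLASSES:
                raise ValueError(f"unknown layer class {c!r}")

    def per_layer(self, value) -> list[float]:
        n = len(self.layer_classes)
        if np.isscalar(value):
            return [float(value)] * n
        value = list(value)
        if len(value) != n:
            raise ValueError("per-layer parameter length mismatch")
        return [float(v) for v in value]


_CHAIN_IDS = "ABCD"


def build_quartet_stack(spec: StackSpec) -> tuple[StructureEnsemble, dict]:
    """Construct the ensemble and its machine-readable truth labels."""
    rises = spec.per_layer(spec.rise)
    twists = spec.per_layer(spec.twist)
    buckles = spec.per_layer(spec.buckle)
    propellers = spec.per_layer(spec.propeller)

    placed_layers: list[list[_Base]] = []
    truth_layers = []
    z_total, twist_total = 0.0, 0.0
    for li, cls in enumerate(spec.layer_classes):
        bases = [b.copy() for b in _build_layer(cls, spec.backbone)]
        # centre the layer in xy so injected twists do not couple into rise
        centre = np.mean([b.coords.mean(axis=0) for b in bases], axis=0)
        centre[2] = 0.0
        bases = [b.transformed(np.eye(3), -centre) for b in bases]
        # intra-layer deformations: buckle splits the two halves about x,
        # propeller counter-rotates the two bases of each pair about y
        half = len(bases) // 2
        if buckles[li] != 0.0:
            Rp = rotation_about([1, 0, 0], +buckles[li] / 2.0)
            Rm = rotation_about([1, 0, 0], -buckles[li] / 2.0)
            bases = [
                b.transformed(Rm if i < half else Rp, np.zeros(3))
                for i, b in enumerate(bases)
            ]
        if propellers[li] != 0.0:
            Rp = rotation_about([0, 1, 0], +propellers[li] / 2.0)
            Rm = rotation_about([0, 1, 0], -propellers[li] / 2.0)
            bases = [
                b.transformed(Rm if i % 2 == 0 else Rp, np.zeros(3))
                for i, b in enumerate(bases)
            ]
        if li > 0:
            z_total += rises[li]
            twist_total += twists[li]
        R = rotation_about([0, 0, 1], twist_total)
        t = np.array([0.0, 0.0, z_total])
        bases = [b.transformed(R, t) for b in bases]
        placed_layers.append(bases)
        truth_layers.append({
            "layer": li, "class": cls, "rise": rises[li] if li > 0 else None,
            "twist": twists[li] if li > 0 else None,
            "buckle": buckles[li], "propeller": propellers[li],
        })

    n_pos = max(len(layer) for layer in placed_layers)
    chains = {cid: Chain(id=cid) for cid in _CHAIN_IDS[:n_pos]}
    truth_pairs, truth_residues = [], []
    for li, (cls, bases) in enumerate(zip(spec.layer_classes, placed_layers)):
        keys = []
        for pos, base in enumerate(bases):
            cid = _CHAIN_IDS[pos]
            res = Residue(name=base.resname, number=li + 1, chain_id=cid)
            for name, elem, xyz in zip(base.names, base.elements, base.coords):
                res.add(AtomRecord(name=name, element=elem, xyz=xyz))
            chains[cid].residues.append(res)
            keys.append(res.key)
        truth_layers[li]["residues"] = keys
        truth_residues.extend(keys)
        pair_class = _PAIR_OF.get(cls)
        if cls in _QUARTET_PAIR:
            pair_class = _PAIR_OF[_QUARTET_PAIR[cls][0]]
        if pair_class is not None:
            for a in range(0, len(keys) - 1, 2):
                truth_pairs.append({"residues": (keys[a], keys[a + 1]),
                                    "class": pair_class, "layer": li})

    model = Model(index=1, chains=[chains[c] for c in sorted(chains)])
    ens = StructureEnsemble(models=[model], provenance={
        "synthetic": True,
        "layer_classes": list(spec.layer_classes),
        "seed": spec.seed,
    })
    if spec.noise_sigma > 0:
        ens = perturb_coordinates(ens, spec.noise_sigma, spec.seed)
    truth = {"layers": truth_layers, "pairs": truth_pairs,
             "spec": spec, "residues": truth_residues}
    return ens, truth


def perturb_coordinates(ens: StructureEnsemble, sigma: float, seed: int) -> StructureEnsemble:
    """Isotropic Gaussian coordinate noise; sigma = 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = copy.deepcopy(ens)
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for model in out.models:
        for res in model.residues():
            for atom in res.atoms:
                atom.xyz = atom.xyz + rng.normal(0.0, sigma, size=3)
    return out


# ---------------------------------------------------------------------------
# planted sequence motifs
# ---------------------------------------------------------------------------


@dataclass
class PlantSpec:
    n_sequences: int = 10
    sequence_length: int = 500
    n_planted: int = 1            # motifs per sequence
    min_spacer: int = 1
    max_spacer: int = 20
    background: str = "ACGT"      # symbols drawn uniformly for background
    mutation_rate: float = 0.0    # per-base substitution rate inside repeats
    seed: int = 0


def plant_sequence_motifs(
    spec: PlantSpec,
) -> tuple[list[NucleotideSequence], list[MotifMatch]]:
    """Random sequences with AGCGA-consensus motifs planted at known spots."""
    rng = np.random.default_rng(spec.seed)
    word = AGCGA_REPEAT
    seqs, truth = [], []
    for si in range(spec.n_sequences):
        bg = rng.choice(list(spec.background), size=spec.sequence_length)
        seq = list("".join(bg))
        placed = []
        for _ in range(spec.n_planted):
            spacers = rng.integers(spec.min_spacer, spec.max_spacer + 1, size=3)
            motif_len = 4 * len(word) + int(spacers.sum())
            if motif_len > spec.sequence_length:
                raise ValueError("motif does not fit in sequence_length")
            for _attempt in range(200):
                start = int(rng.integers(0, spec.sequence_length - motif_len + 1))
                if all(start + motif_len <= s or start >= e for s, e, *_ in placed):
                    break
            else:
                raise ValueError("could not pack motifs without overlap")
            starts = []
            pos = start
            for k in range(4):
                starts.append(pos)
                motif = list(word)
                for ci in range(len(motif)):
                    if rng.random() < spec.mutation_rate:
                        motif[ci] = str(rng.choice(list("ACGT")))
                seq[pos : pos + len(word)] = motif
                if k < 3:
                    pos += len(word) + int(spacers[k])
            placed.append((start, start + motif_len))
            truth.append(MotifMatch(
                seq_id=f"synth{si}", start=start, end=start + motif_len,
                strand="+", motif_class="AGCGA_QUAD",
                repeat_starts=tuple(starts),
                spacer_lengths=tuple(int(s) for s in spacers),
            ))
        seqs.append(NucleotideSequence(f"synth{si}", "".join(seq)))
    return seqs, truth


def write_fasta(seqs: Sequence[NucleotideSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


# ---------------------------------------------------------------------------
# NOE volume simulation
# ---------------------------------------------------------------------------


def simulate_noe_volumes(
    ens: StructureEnsemble,
    proton_pairs: Sequence[tuple[tuple[str, int], str, tuple[str, int], str]] | None = None,
    scale: float = 1.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    d_max: float = 6.0,
    d_min: float = 2.0,
) -> list[tuple[tuple[str, int], str, tuple[str, int], str, float, float]]:
    """Volumes V = scale * r^-6 * exp(eps), eps ~ Normal(0, noise_cv).

    Distances are averaged over models.  Returns (res_i, atom_i, res_j,
    atom_j, volume, true_distance) tuples; when ``proton_pairs`` is None all
    hydrogen pairs with ensemble-mean distance in [d_min, d_max] are
    enumerated (the lower cutoff drops geminal contacts, which are not
    usable NOE cross-peaks).
    """
    rng = np.random.default_rng(seed)

    def mean_distance(ri, ai, rj, aj) -> float:
        ds = []
        for model in ens.models:
            ci = model.residue(*ri).coord(ai)
            cj = model.residue(*rj).coord(aj)
            if ci is None or cj is None:
                raise KeyError(f"missing proton {ri}:{ai} or {rj}:{aj}")
            ds.append(float(np.linalg.norm(ci - cj)))
        return float(np.mean(ds))

    if proton_pairs is None:
        model = ens.models[0]
        protons = [
            (res.key, a.name)
            for res in model.residues()
            for a in res.atoms
            if a.element == "H"
        ]
        proton_pairs = []
        for (ri, ai), (rj, aj) in itertools.combinations(protons, 2):
            if d_min <= mean_distance(ri, ai, rj, aj) <= d_max:
                proton_pairs.append((ri, ai, rj, aj))

    out = []
    for ri, ai, rj, aj in proton_pairs:
        r = mean_distance(ri, ai, rj, aj)
        if r <= 1e-6:
            raise ValueError(f"zero distance between {ri}:{ai} and {rj}:{aj}")
        eps = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
        out.append((ri, ai, rj, aj, scale * r ** -6.0 * math.exp(eps), r))
    return out


def write_peaks_tsv(peaks, path: str | Path) -> None:
    """TSV with columns chain_i, res_i, atom_i, chain_j, res_j, atom_j, volume."""
    with open(path, "w") as fh:
        fh.write("chain_i\tres_i\tatom_i\tchain_j\tres_j\tatom_j\tvolume\n")
        for ri, ai, rj, aj, vol, _r in peaks:
            fh.write(f"{ri[0]}\t{ri[1]}\t{ai}\t{rj[0]}\t{rj[1]}\t{aj}\t{vol!r}\n")
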