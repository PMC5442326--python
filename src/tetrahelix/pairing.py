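"""Hydrogen-bond detection and classification of base pairs, quartets and
crisscross topologies.

Pair classes cover the vocabulary of AGCGA-quadruplex structures: canonical
Watson-Crick G-C pairs, G-G pairs in N1-carbonyl symmetric geometry
(reciprocal N1-H...O6), G-A pairs in N1-N7 carbonyl-amino geometry, and
Hoogsteen G-I pairs; everything else hydrogen-bonded is OTHER.  Quartets are
two base pairs joined by class-specific cross-links (GAGA, minor/major
groove GCGC) or a cyclic arrangement of four guanines (GGGG).  Crisscross
topology is a stacked couple of pairs on the same two strands with an
unusually large inter-pair twist.
"""
from __future__ import annotations

import functools
import math
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .geometry import BaseFrame, fit_base_frame, pair_mid_frame, step_params, unit_frame
from .structio import Model, Residue

# donor heavy atoms per residue type, for models without explicit hydrogens
_FALLBACK_DONORS = {
    "DG": ("N1", "N2"),
    "DA": ("N6",),
    "DC": ("N4",),
    "DT": ("N3",),
    "DI": ("N1",),
}
# base N/O acceptors per residue type
_ACCEPTORS = {
    "DG": ("N3", "N7", "O6"),
    "DA": ("N1", "N3", "N7"),
    "DC": ("O2", "N3"),
    "DT": ("O2", "O4"),
    "DI": ("N3", "N7", "O6"),
}

_COVALENT_H_MAX = 1.6  # A, sanity cap when attaching H to its nearest heavy atom


def _is_base_atom(name: str) -> bool:
    return "'" not in name and name not in ("P", "OP1", "OP2", "OP3")


@dataclass(frozen=True)
class HydrogenBond:
    donor_res: tuple[str, int]
    donor_atom: str
    acceptor_res: tuple[str, int]
    acceptor_atom: str
    hydrogen_atom: str | None
    d_DA: float
    theta: float | None  # donor-H-acceptor angle, deg

    @property
    def key(self):
        return (self.donor_res, self.donor_atom, self.acceptor_res, self.acceptor_atom)


def find_hbonds(
    model: Model,
    d_max: float = 3.5,
    theta_min: float = 120.0,
    base_only: bool = True,
) -> list[HydrogenBond]:
    """Geometric hydrogen bonds between N/O donors (with attached H) and N/O
    acceptors of different residues.

    When a residue carries no hydrogens at all (heavy-atom-only models), a
    fallback applies: donors come from a per-residue-type table and the
    angle criterion is replaced by requiring the acceptor on the outward
    side of the donor (antecedent-donor-acceptor angle >= 90 deg).
    """
    residues = list(model.residues())
    donors = []  # (res, heavy AtomRecord, H AtomRecord or None)
    acceptors = []  # (res, AtomRecord)
    for res in residues:
        has_h = any(a.element == "H" for a in res.atoms)
        heavy = [a for a in res.atoms if a.element in ("N", "O")]
        if base_only:
            heavy = [a for a in heavy if _is_base_atom(a.name)]
        for atom in heavy:
            acceptors.append((res, atom))
        if has_h:
            # attach each hydrogen to its nearest heavy atom (robust under
            # coordinate noise, unlike a fixed covalent-distance cutoff)
            all_heavy = [a for a in res.atoms if a.element != "H"]
            for h in (a for a in res.atoms if a.element == "H"):
                dists = [float(np.linalg.norm(h.xyz - a.xyz)) for a in all_heavy]
                nearest = all_heavy[int(np.argmin(dists))]
                if min(dists) > _COVALENT_H_MAX:
                    continue
                for atom in heavy:
                    if atom is nearest:
                        donors.append((res, atom, h))
        else:
            for atom in heavy:
                if atom.name in _FALLBACK_DONORS.get(res.name, ()):
                    donors.append((res, atom, None))

    bonds = []
    for dres, datom, h in donors:
        for ares, aatom in acceptors:
            if ares.key == dres.key:
                continue
            if aatom.name not in _ACCEPTORS.get(ares.name, ()) and not (
                aatom.element == "O" and _is_base_atom(aatom.name)
            ):
                continue
            d = float(np.linalg.norm(datom.xyz - aatom.xyz))
            if d > d_max:
                continue
            if h is not None:
                v1 = datom.xyz - h.xyz
                v2 = aatom.xyz - h.xyz
                cosang = float(
                    np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)
                )
                theta = math.degrees(math.acos(cosang))
                if theta < theta_min:
                    continue
            else:
                # donor-geometry heuristic: acceptor must be on the outward side
                neighbours = [
                    a for a in dres.atoms
                    if a.element == "C" and np.linalg.norm(a.xyz - datom.xyz) < 1.6
                ]
                theta = None
                if neighbours:
                    v1 = datom.xyz - neighbours[0].xyz
                    v2 = aatom.xyz - datom.xyz
                    cosang = float(
                        np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)
                    )
                    if math.degrees(math.acos(cosang)) > 90.0:
                        continue
            bonds.append(HydrogenBond(
                donor_res=dres.key, donor_atom=datom.name,
                acceptor_res=ares.key, acceptor_atom=aatom.name,
                hydrogen_atom=None if h is None else h.name,
                d_DA=d, theta=theta,
            ))
    # deterministic order; keep the best (shortest) bond per donor/acceptor pair
    best: dict[tuple, HydrogenBond] = {}
    for b in bonds:
        cur = best.get(b.key)
        if cur is None or b.d_DA < cur.d_DA:
            best[b.key] = b
    return sorted(best.values(), key=lambda b: b.key)


# ---------------------------------------------------------------------------
# pair classification
# ---------------------------------------------------------------------------


@functools.cache
def pattern_table() -> dict[str, dict]:
    """Pair-class hydrogen-bond patterns, loaded from shipped TSV data."""
    text = resources.files("tetrahelix.data").joinpath("pair_patterns.tsv").read_text()
    table: dict[str, dict] = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("class\t"):
            continue
        cls, b1, b2, drole, datom, arole, aatom = line.split("\t")
        entry = table.setdefault(cls, {"bases": (b1, b2), "bonds": []})
        entry["bonds"].append((int(drole), datom, int(arole), aatom))
    return table


@dataclass(frozen=True)
class BasePair:
    res_i: tuple[str, int]
    res_j: tuple[str, int]
    geometry_class: str
    hbonds: tuple[HydrogenBond, ...]
    strand_relation: str  # parallel / antiparallel / intramolecular

    @property
    def residues(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.res_i, self.res_j)

    @property
    def n_hbonds(self) -> int:
        return len(self.hbonds)


def _strand_relation(res_i: Residue, res_j: Residue,
                     frames: dict[tuple[str, int], BaseFrame] | None) -> str:
    if res_i.chain_id == res_j.chain_id:
        return "intramolecular"
    if frames is None:
        return "antiparallel"
    zi = frames[res_i.key].z
    zj = frames[res_j.key].z
    return "parallel" if zi @ zj >= 0 else "antiparallel"


def classify_pair(
    res_i: Residue,
    res_j: Residue,
    hbonds: Sequence[HydrogenBond],
    frames: dict[tuple[str, int], BaseFrame] | None = None,
) -> BasePair:
    """Classify one hydrogen-bonded residue pair against the pattern table.

    Symmetric in its two residue arguments; the stored pair is canonically
    ordered by (chain, residue number).
    """
    a, b = sorted([res_i, res_j], key=lambda r: r.key)
    mine = tuple(
        hb for hb in hbonds
        if {hb.donor_res, hb.acceptor_res} == {a.key, b.key}
    )
    observed = {
        (hb.donor_res, hb.donor_atom, hb.acceptor_res, hb.acceptor_atom) for hb in mine
    }
    best_class, best_score = "OTHER", 0
    for cls, entry in pattern_table().items():
        b1, b2 = entry["bases"]
        for first, second in (((a, b)), ((b, a))):
            if (first.name, second.name) != (b1, b2):
                continue
            role = {1: first, 2: second}
            matched = sum(
                (role[dr].key, da, role[ar].key, aa) in observed
                for dr, da, ar, aa in entry["bonds"]
            )
            if matched >= 2 and matched > best_score:
                best_class, best_score = cls, matched
    return BasePair(
        res_i=a.key, res_j=b.key,
        geometry_class=best_class if len(mine) >= 2 else "OTHER",
        hbonds=mine,
        strand_relation=_strand_relation(a, b, frames),
    )


def find_pairs(
    model: Model,
    hbonds: Sequence[HydrogenBond] | None = None,
    frames: dict[tuple[str, int], BaseFrame] | None = None,
    d_max: float = 3.5,
    theta_min: float = 120.0,
) -> list[BasePair]:
    """All residue pairs joined by >=2 hydrogen bonds, classified."""
    if hbonds is None:
        hbonds = find_hbonds(model, d_max=d_max, theta_min=theta_min)
    by_pair: dict[frozenset, list[HydrogenBond]] = defaultdict(list)
    for hb in hbonds:
        by_pair[frozenset((hb.donor_res, hb.acceptor_res))].append(hb)
    index = {r.key: r for r in model.residues()}
    pairs = []
    for key, bonds in by_pair.items():
        if len(bonds) < 2:
            continue
        ri, rj = sorted(key)
        pairs.append(classify_pair(index[ri], index[rj], bonds, frames))
    return sorted(pairs, key=lambda p: (p.res_i, p.res_j))


# ---------------------------------------------------------------------------
# quartets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Quartet:
    residues: tuple[tuple[str, int], ...]  # ordered 4-cycle
    quartet_class: str  # GGGG / GAGA / GCGC_MINOR / GCGC_MAJOR
    constituent_pairs: tuple[BasePair, ...] | None
    cross_links: tuple[HydrogenBond, ...]

    @property
    def n_hbonds(self) -> int:
        n = len(self.cross_links)
        if self.constituent_pairs:
            n += sum(p.n_hbonds for p in self.constituent_pairs)
        return n


#: cross-link bond patterns joining the two pairs of a quartet:
#: (pair class, donor base, donor atom, acceptor base, acceptor atom)
_CROSS_LINKS = {
    "GAGA": ("GA_N1N7_CARBONYLAMINO", "DA", "N6", "DG", "N7"),
    "GCGC_MINOR": ("WC_GC", "DG", "N2", "DC", "O2"),
    "GCGC_MAJOR": ("WC_GC", "DC", "N4", "DG", "O6"),
}


def _cross_bonds(
    pair_a: BasePair, pair_b: BasePair, hbonds: Sequence[HydrogenBond],
    donor_base: str, donor_atom: str, acceptor_base: str, acceptor_atom: str,
    index: dict[tuple[str, int], Residue],
) -> list[HydrogenBond]:
    set_a, set_b = set(pair_a.residues), set(pair_b.residues)
    out = []
    for hb in hbonds:
        if hb.donor_atom != donor_atom or hb.acceptor_atom != acceptor_atom:
            continue
        if index[hb.donor_res].name != donor_base:
            continue
        if index[hb.acceptor_res].name != acceptor_base:
            continue
        if (hb.donor_res in set_a and hb.acceptor_res in set_b) or (
            hb.donor_res in set_b and hb.acceptor_res in set_a
        ):
            out.append(hb)
    return out


def _gggg_quartets(
    model: Model, hbonds: Sequence[HydrogenBond]
) -> list[Quartet]:
    """Cyclic donor->acceptor arrangements of four guanines."""
    index = {r.key: r for r in model.residues()}
    edges: dict[tuple[str, int], set[tuple[str, int]]] = defaultdict(set)
    bond_lookup: dict[tuple, list[HydrogenBond]] = defaultdict(list)
    for hb in hbonds:
        if index[hb.donor_res].name != "DG" or index[hb.acceptor_res].name != "DG":
            continue
        if hb.donor_atom in ("N1", "N2") and hb.acceptor_atom in ("O6", "N7"):
            edges[hb.donor_res].add(hb.acceptor_res)
            bond_lookup[(hb.donor_res, hb.acceptor_res)].append(hb)
    cycles = set()
    nodes = sorted(edges)
    for a in nodes:
        for b in edges[a]:
            for c in edges.get(b, ()):
                if c == a:
                    continue
                for d in edges.get(c, ()):
                    if d in (a, b):
                        continue
                    if a in edges.get(d, ()):
                        cyc = min(
                            [(a, b, c, d), (b, c, d, a), (c, d, a, b), (d, a, b, c)]
                        )
                        cycles.add(cyc)
    out = []
    for cyc in sorted(cycles):
        links = []
        for k in range(4):
            links.extend(bond_lookup[(cyc[k], cyc[(k + 1) % 4])])
        out.append(Quartet(residues=cyc, quartet_class="GGGG",
                           constituent_pairs=None, cross_links=tuple(links)))
    return out


def assemble_quartets(
    pairs: Sequence[BasePair],
    hbonds: Sequence[HydrogenBond],
    model: Model,
) -> list[Quartet]:
    """Detect GAGA, minor/major-groove GCGC and GGGG quartets.

    Candidates are scored by total hydrogen-bond count and accepted greedily
    so that each residue belongs to at most one quartet (ties broken by
    lowest residue indices, making the output deterministic).
    """
    index = {r.key: r for r in model.residues()}
    candidates: list[Quartet] = list(_gggg_quartets(model, hbonds))
    for i, pa in enumerate(pairs):
        for pb in pairs[i + 1:]:
            if set(pa.residues) & set(pb.residues):
                continue
            for qclass, (pcls, db, da, ab, aa) in _CROSS_LINKS.items():
                if pa.geometry_class != pcls or pb.geometry_class != pcls:
                    continue
                links = _cross_bonds(pa, pb, hbonds, db, da, ab, aa, index)
                if len(links) < 2:
                    continue
                order = (pa.res_i, pa.res_j, pb.res_i, pb.res_j)
                candidates.append(Quartet(
                    residues=order, quartet_class=qclass,
                    constituent_pairs=(pa, pb), cross_links=tuple(links),
                ))
    candidates.sort(key=lambda q: (-q.n_hbonds, q.residues))
    used: set[tuple[str, int]] = set()
    chosen = []
    for q in candidates:
        if used & set(q.residues):
            continue
        used |= set(q.residues)
        chosen.append(q)
    return sorted(chosen, key=lambda q: q.residues)


# ---------------------------------------------------------------------------
# crisscross topology
# ---------------------------------------------------------------------------


def detect_crisscross(
    pairs: Sequence[BasePair],
    frames: dict[tuple[str, int], BaseFrame],
    twist_min: float = 35.0,
    rise_max: float = 6.0,
) -> list[tuple[BasePair, BasePair]]:
    """Stacked couples of pairs joining the same two strands whose inter-pair
    twist magnitude is at least ``twist_min`` degrees."""
    out = []
    for i, pa in enumerate(pairs):
        for pb in pairs[i + 1:]:
            if set(pa.residues) & set(pb.residues):
                continue
            chains_a = {pa.res_i[0], pa.res_j[0]}
            chains_b = {pb.res_i[0], pb.res_j[0]}
            if chains_a != chains_b:
                continue
            fa = pair_mid_frame(frames[pa.res_i], frames[pa.res_j])
            fb = pair_mid_frame(frames[pb.res_i], frames[pb.res_j])
            sp = step_params(fa, fb)
            if 0.0 < abs(sp.rise) <= rise_max and abs(sp.twist) >= twist_min:
                out.append((pa, pb))
    return out


# ---------------------------------------------------------------------------
# per-model convenience and ensemble consensus
# ---------------------------------------------------------------------------


def model_frames(model: Model) -> dict[tuple[str, int], BaseFrame]:
    return {res.key: fit_base_frame(res) for res in model.residues()}


def consensus(
    per_model_items: Sequence[Sequence],
    key,
    fraction: float = 0.5,
) -> list:
    """Items (pairs or quartets) present in >= fraction of models.

    ``key`` maps an item to its identity across models; one representative
    item (from the first model containing it) is returned per identity.
    """
    n_models = len(per_model_items)
    counts: dict = {}
    rep: dict = {}
    for items in per_model_items:
        seen = set()
        for it in items:
            k = key(it)
            if k in seen:
                continue
            seen.add(k)
            counts[k] = counts.get(k, 0) + 1
            rep.setdefault(k, it)
    threshold = fraction * n_models
    return [rep[k] for k in sorted(rep) if counts[k] >= threshold]
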