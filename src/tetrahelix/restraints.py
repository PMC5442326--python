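"""NMR-style restraint generation.

NOE cross-peak volumes are calibrated against the averaged intra-nucleotide
H8-H1' volume of clearly *anti* residues, mapped to a reference distance of
3.9 A, and converted to distance estimates with the isolated-spin-pair
inverse-sixth-power relation r = r_ref * (V_ref / V)^(1/6).  Estimates fall
into the four conventional bins strong (1.8-3.6 A), medium (2.6-5.0 A),
weak (3.5-6.5 A) and very weak (4.5-7.5 A).  Glycosidic torsion restraints
for *anti* residues span 170-280 deg (purines) or 170-310 deg (pyrimidines);
hydrogen-bond distance restraints and planarity groups are derived from
classified pairs and quartets.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .pairing import BasePair, Quartet
from .structio import PURINES

REFERENCE_DISTANCE = 3.9  # A

#: class -> (lower, upper) distance bounds in A
CLASS_BOUNDS = {
    "strong": (1.8, 3.6),
    "medium": (2.6, 5.0),
    "weak": (3.5, 6.5),
    "very_weak": (4.5, 7.5),
}
#: r-hat cutoffs separating the classes (config-exposed; bins overlap, so
#: assignment cutoffs sit near the bin midpoints)
DEFAULT_CUTOFFS = (3.0, 4.2, 5.5)

DISTANCE_FORCE_CONSTANT = 20.0   # kcal/mol/A^2
TORSION_FORCE_CONSTANT = 200.0   # kcal/mol/rad^2
PLANARITY_FORCE_CONSTANT = 50.0  # kcal/mol/rad^2

HBOND_BOUNDS = (2.7, 3.1)  # heavy-atom bounds for hydrogen-bond restraints, A


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class NOEPeak:
    res_i: tuple[str, int]
    atom_i: str
    res_j: tuple[str, int]
    atom_j: str
    volume: float

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError(f"NOE peak volume must be positive, got {self.volume}")

    @property
    def intranucleotide(self) -> bool:
        return self.res_i == self.res_j


@dataclass(frozen=True)
class DistanceRestraint:
    atom_i: str  # "chain:number:atom"
    atom_j: str
    lower: float
    upper: float
    restraint_class: str
    force_constant: float = DISTANCE_FORCE_CONSTANT


@dataclass(frozen=True)
class TorsionRestraint:
    residue: str
    angle_name: str
    lower: float
    upper: float
    force_constant: float = TORSION_FORCE_CONSTANT

    def __post_init__(self):
        if not (0 <= self.lower < self.upper <= 360):
            raise ValueError(f"invalid torsion bounds ({self.lower}, {self.upper})")


@dataclass(frozen=True)
class PlanarityGroup:
    label: str
    atoms: tuple[str, ...]
    force_constant: float = PLANARITY_FORCE_CONSTANT


@dataclass
class RestraintSet:
    distance: list[DistanceRestraint] = field(default_factory=list)
    torsion: list[TorsionRestraint] = field(default_factory=list)
    hbond: list[DistanceRestraint] = field(default_factory=list)
    planarity: list[PlanarityGroup] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {
            "distance": len(self.distance),
            "torsion": len(self.torsion),
            "hbond": len(self.hbond),
            "planarity": len(self.planarity),
        }


def _atom_id(res: tuple[str, int], atom: str) -> str:
    return f"{res[0]}:{res[1]}:{atom}"


# ---------------------------------------------------------------------------
# NOE volume calibration and classification
# ---------------------------------------------------------------------------


def calibrate_reference(
    peaks: Iterable[NOEPeak], anti_residues: Sequence[tuple[str, int]]
) -> float:
    """Reference volume: arithmetic mean of intra-nucleotide H8-H1' volumes
    of the given *anti* residues; this volume corresponds to 3.9 A."""
    anti = set(anti_residues)
    vols = [
        p.volume
        for p in peaks
        if p.intranucleotide
        and p.res_i in anti
        and {p.atom_i, p.atom_j} == {"H8", "H1'"}
    ]
    if not vols:
        raise CalibrationError(
            "no intra-nucleotide H8-H1' peaks among the given anti residues; "
            "check residue identifiers and that H8/H1' assignments are present"
        )
    return sum(vols) / len(vols)


def estimate_distance(volume: float, reference_volume: float,
                      reference_distance: float = REFERENCE_DISTANCE) -> float:
    """Isolated-spin-pair estimate r = r_ref * (V_ref / V)^(1/6)."""
    if volume <= 0 or reference_volume <= 0:
        raise ValueError("volumes must be positive")
    return reference_distance * (reference_volume / volume) ** (1.0 / 6.0)


def classify_noe(
    peak: NOEPeak,
    reference_volume: float,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    reference_distance: float = REFERENCE_DISTANCE,
) -> DistanceRestraint:
    """Convert one NOE peak into a classed distance restraint."""
    r = estimate_distance(peak.volume, reference_volume, reference_distance)
    c1, c2, c3 = cutoffs
    if r < c1:
        cls = "strong"
    elif r < c2:
        cls = "medium"
    elif r < c3:
        cls = "weak"
    else:
        cls = "very_weak"
    lo, hi = CLASS_BOUNDS[cls]
    return DistanceRestraint(
        atom_i=_atom_id(peak.res_i, peak.atom_i),
        atom_j=_atom_id(peak.res_j, peak.atom_j),
        lower=lo, upper=hi, restraint_class=cls,
    )


# ---------------------------------------------------------------------------
# torsion / hydrogen-bond / planarity restraints
# ---------------------------------------------------------------------------


def chi_restraints(
    residues: Iterable[tuple[str, tuple[str, int], str]],
) -> list[TorsionRestraint]:
    """Chi torsion restraints for *anti* residues.

    ``residues`` yields (residue type, (chain, number), chi_class).  Anti
    purines get (170, 280), anti pyrimidines (170, 310); syn and other
    residues produce no restraint.
    """
    out = []
    for resname, key, cls in residues:
        if cls != "anti":
            continue
        upper = 280.0 if resname in PURINES else 310.0
        out.append(TorsionRestraint(
            residue=f"{key[0]}:{key[1]}", angle_name="chi",
            lower=170.0, upper=upper,
        ))
    return out


def hbond_restraints(pairs: Iterable[BasePair]) -> list[DistanceRestraint]:
    """One heavy-atom distance restraint per hydrogen bond of every
    classified (non-OTHER) pair."""
    out = []
    for pair in pairs:
        if pair.geometry_class == "OTHER":
            continue
        for hb in pair.hbonds:
            out.append(DistanceRestraint(
                atom_i=_atom_id(hb.donor_res, hb.donor_atom),
                atom_j=_atom_id(hb.acceptor_res, hb.acceptor_atom),
                lower=HBOND_BOUNDS[0], upper=HBOND_BOUNDS[1],
                restraint_class="hbond",
            ))
    return out


def planarity_restraints(
    quartets: Iterable[Quartet] = (),
    gg_pairs: Iterable[BasePair] = (),
) -> list[PlanarityGroup]:
    """Planarity groups for GAGA-quartets and N1-carbonyl symmetric G-G
    pairs (the classes conventionally kept planar during refinement)."""
    out = []
    for q in quartets:
        if q.quartet_class != "GAGA":
            continue
        out.append(PlanarityGroup(
            label="GAGA:" + "+".join(f"{c}:{n}" for c, n in q.residues),
            atoms=tuple(f"{c}:{n}:base" for c, n in q.residues),
        ))
    for p in gg_pairs:
        if p.geometry_class != "GG_N1_CARBONYL":
            continue
        out.append(PlanarityGroup(
            label="GG:" + "+".join(f"{c}:{n}" for c, n in p.residues),
            atoms=tuple(f"{c}:{n}:base" for c, n in p.residues),
        ))
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["type", "atom_i", "atom_j_or_angle", "lower", "upper", "class",
                "force_constant"]


def _rows(rset: RestraintSet) -> list[dict]:
    rows = []
    for r in rset.distance:
        rows.append(dict(type="distance", atom_i=r.atom_i, atom_j_or_angle=r.atom_j,
                         lower=r.lower, upper=r.upper, **{"class": r.restraint_class},
                         force_constant=r.force_constant))
    for t in rset.torsion:
        rows.append(dict(type="torsion", atom_i=t.residue, atom_j_or_angle=t.angle_name,
                         lower=t.lower, upper=t.upper, **{"class": "torsion"},
                         force_constant=t.force_constant))
    for r in rset.hbond:
        rows.append(dict(type="hbond", atom_i=r.atom_i, atom_j_or_angle=r.atom_j,
                         lower=r.lower, upper=r.upper, **{"class": r.restraint_class},
                         force_constant=r.force_constant))
    for p in rset.planarity:
        rows.append(dict(type="planarity", atom_i=p.label,
                         atom_j_or_angle="|".join(p.atoms),
                         lower=0.0, upper=0.0, **{"class": "planarity"},
                         force_constant=p.force_constant))
    return rows


def write_restraints(rset: RestraintSet, path: str | Path,
                     dialect: str = "tsv") -> None:
    """Serialize a restraint set as TSV or fixed-width flat list."""
    rows = _rows(rset)
    path = Path(path)
    if dialect == "tsv":
        df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "flat_list":
        with open(path, "w") as fh:
            for row in rows:
                fh.write(
                    f"{row['type']:<10s}{row['atom_i']:<28s}"
                    f"{row['atom_j_or_angle']:<40s}"
                    f"{row['lower']:>8.2f}{row['upper']:>8.2f}"
                    f"{row['class']:>12s}{row['force_constant']:>8.1f}\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_restraints(path: str | Path, dialect: str = "tsv") -> RestraintSet:
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        rows = df.to_dict("records")
    elif dialect == "flat_list":
        rows = []
        for line in path.read_text().splitlines():
            rows.append({
                "type": line[0:10].strip(),
                "atom_i": line[10:38].strip(),
                "atom_j_or_angle": line[38:78].strip(),
                "lower": float(line[78:86]),
                "upper": float(line[86:94]),
                "class": line[94:106].strip(),
                "force_constant": float(line[106:114]),
            })
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    rset = RestraintSet()
    for row in rows:
        kind = row["type"]
        if kind in ("distance", "hbond"):
            r = DistanceRestraint(
                atom_i=row["atom_i"], atom_j=row["atom_j_or_angle"],
                lower=float(row["lower"]), upper=float(row["upper"]),
                restraint_class=row["class"],
                force_constant=float(row["force_constant"]),
            )
            (rset.distance if kind == "distance" else rset.hbond).append(r)
        elif kind == "torsion":
            rset.torsion.append(TorsionRestraint(
                residue=row["atom_i"], angle_name=row["atom_j_or_angle"],
                lower=float(row["lower"]), upper=float(row["upper"]),
                force_constant=float(row["force_constant"]),
            ))
        elif kind == "planarity":
            rset.planarity.append(PlanarityGroup(
                label=row["atom_i"],
                atoms=tuple(row["atom_j_or_angle"].split("|")),
                force_constant=float(row["force_constant"]),
            ))
    return rset


def read_peaks_tsv(path: str | Path) -> list[NOEPeak]:
    """Read peaks from TSV columns chain_i, res_i, atom_i, chain_j, res_j,
    atom_j, volume."""
    df = pd.read_csv(path, sep="\t")
    return [
        NOEPeak(
            res_i=(str(row.chain_i), int(row.res_i)), atom_i=str(row.atom_i),
            res_j=(str(row.chain_j), int(row.res_j)), atom_j=str(row.atom_j),
            volume=float(row.volume),
        )
        for row in df.itertuples()
    ]
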