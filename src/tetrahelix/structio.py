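"""Reading and writing multi-model nucleic-acid coordinate files.

A thin, validated data model (ensemble -> model -> chain -> residue -> atom)
over gemmi's PDB/mmCIF parsers.  NMR-style multi-model files keep all models
and all hydrogens; altlocs are resolved to the highest-occupancy conformer.
Supported residue types are the five 2'-deoxynucleotides DA, DC, DG, DT and
DI (deoxyinosine, hypoxanthine base).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

SUPPORTED_RESIDUES = ("DA", "DC", "DG", "DT", "DI")

PURINES = {"DA", "DG", "DI"}
PYRIMIDINES = {"DC", "DT"}

#: base ring atoms that every residue of a given type must carry
RING_ATOMS = {
    "DA": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
    "DG": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
    "DI": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
    "DC": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "DT": ("N1", "C2", "N3", "C4", "C5", "C6"),
}


class StructureValidationError(ValueError):
    pass


@dataclass
class AtomRecord:
    name: str
    element: str
    xyz: np.ndarray  # (3,) Angstrom

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise StructureValidationError(f"atom {self.name}: non-finite coordinates")


@dataclass
class Residue:
    name: str          # DA/DC/DG/DT/DI
    number: int        # author numbering, kept as-is
    chain_id: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self):
        self._index: dict[str, AtomRecord] = {a.name: a for a in self.atoms}

    def add(self, atom: AtomRecord) -> None:
        self.atoms.append(atom)
        self._index[atom.name] = atom

    def atom(self, name: str) -> AtomRecord | None:
        return self._index.get(name)

    def coord(self, name: str) -> np.ndarray | None:
        a = self._index.get(name)
        return None if a is None else a.xyz

    @property
    def is_purine(self) -> bool:
        return self.name in PURINES

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.number)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.name}{self.number}"


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Model:
    index: int
    chains: list[Chain] = field(default_factory=list)

    def residues(self) -> Iterator[Residue]:
        for ch in self.chains:
            yield from ch.residues

    def residue(self, chain_id: str, number: int) -> Residue:
        for ch in self.chains:
            if ch.id == chain_id:
                for res in ch.residues:
                    if res.number == number:
                        return res
        raise KeyError(f"no residue {chain_id}:{number}")

    def topology(self) -> list[tuple[str, str, int, tuple[str, ...]]]:
        return [
            (r.chain_id, r.name, r.number, tuple(sorted(a.name for a in r.atoms)))
            for r in self.residues()
        ]


@dataclass
class StructureEnsemble:
    models: list[Model]
    provenance: dict = field(default_factory=dict)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def validate(self) -> None:
        if not self.models:
            raise StructureValidationError("ensemble contains no models")
        ref = self.models[0].topology()
        for model in self.models:
            for res in model.residues():
                if res.name not in SUPPORTED_RESIDUES:
                    raise StructureValidationError(
                        f"model {model.index}, {res.label}: unsupported residue "
                        f"type {res.name!r} (supported: {', '.join(SUPPORTED_RESIDUES)})"
                    )
                missing = [a for a in RING_ATOMS[res.name] if res.atom(a) is None]
                if missing:
                    raise StructureValidationError(
                        f"model {model.index}, {res.label}: missing base ring "
                        f"atoms {missing}"
                    )
            topo = model.topology()
            if [(t[0], t[1], t[2]) for t in topo] != [(t[0], t[1], t[2]) for t in ref]:
                raise StructureValidationError(
                    f"model {model.index}: residue topology differs from model "
                    f"{self.models[0].index}"
                )


# ---------------------------------------------------------------------------
# gemmi conversion
# ---------------------------------------------------------------------------

_FORMATS = {
    "PDB": gemmi.CoorFormat.Pdb,
    "mmCIF": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def _pick_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve altlocs to the highest-occupancy conformer per atom name."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        cur = best.get(atom.name)
        if cur is None or atom.occ > cur.occ:
            best[atom.name] = atom
    return [best[name] for name in dict.fromkeys(a.name for a in res) if name in best]


def read_structure(path: str | Path, format: str = "auto") -> StructureEnsemble:
    """Read a PDB or mmCIF file into a validated :class:`StructureEnsemble`.

    All MODEL blocks and all hydrogens are retained; HETATM nucleotides are
    accepted; TER records are optional.
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=_FORMATS[format])
    models = []
    for mi, gm in enumerate(st, start=1):
        model = Model(index=mi)
        for gch in gm:
            chain = Chain(id=gch.name)
            for gres in gch:
                res = Residue(name=gres.name.strip(), number=gres.seqid.num,
                              chain_id=gch.name)
                for atom in _pick_altloc(gres):
                    name = atom.name.replace("′", "'").replace("*", "'")
                    res.add(AtomRecord(name=name, element=atom.element.name,
                                       xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
                chain.residues.append(res)
            model.chains.append(chain)
        models.append(model)
    ens = StructureEnsemble(
        models=models, provenance={"source": str(path), "format": format}
    )
    ens.validate()
    return ens


def to_gemmi(ens: StructureEnsemble, name: str = "tetrahelix") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for model in ens.models:
        gm = gemmi.Model(model.index)
        for chain in model.chains:
            gch = gemmi.Chain(chain.id)
            for res in chain.residues:
                gres = gemmi.Residue()
                gres.name = res.name
                gres.seqid = gemmi.SeqId(res.number, " ")
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.xyz)
                    ga.occ = 1.0
                    gres.add_atom(ga)
                gch.add_residue(gres)
            gm.add_chain(gch)
        st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(ens: StructureEnsemble, path: str | Path, format: str = "auto") -> None:
    """Write the ensemble as PDB or mmCIF; ``auto`` picks by file suffix.

    Chain identifiers longer than one character cannot be encoded in PDB
    columns, so such ensembles fall back to mmCIF naming automatically.
    """
    if not ens.models:
        raise StructureValidationError("refusing to write an empty ensemble")
    path = Path(path)
    if format == "auto":
        format = "mmCIF" if path.suffix.lower() in (".cif", ".mmcif") else "PDB"
    if format == "PDB" and any(
        len(ch.id) > 1 for m in ens.models for ch in m.chains
    ):
        format = "mmCIF"
    st = to_gemmi(ens)
    if format == "PDB":
        st.write_pdb(str(path))
    elif format == "mmCIF":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def ensembles_equal(a: StructureEnsemble, b: StructureEnsemble, decimals: int = 3) -> bool:
    """True if both ensembles have identical topology and coordinates agree
    to ``decimals`` decimal places."""
    if a.n_models != b.n_models:
        return False
    for ma, mb in zip(a.models, b.models):
        ra, rb = list(ma.residues()), list(mb.residues())
        if len(ra) != len(rb):
            return False
        for x, y in zip(ra, rb):
            if (x.name, x.number, x.chain_id) != (y.name, y.number, y.chain_id):
                return False
            if [a_.name for a_ in x.atoms] != [a_.name for a_ in y.atoms]:
                return False
            ca = np.array([a_.xyz for a_ in x.atoms])
            cb = np.array([a_.xyz for a_ in y.atoms])
            if not np.allclose(np.round(ca, decimals), np.round(cb, decimals),
                               atol=1.5 * 10 ** -decimals):
                return False
    return True
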