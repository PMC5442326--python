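"""Base reference frames and helical/torsional parameters.

Frames are obtained by least-squares superposition of an idealized base onto
the observed base ring atoms; the idealized bases are stored in the standard
nucleic-acid base reference frame (origin near the ring centre, base in the
xy plane, y axis running toward C1').  Intra-pair (shear, stretch, stagger,
buckle, propeller, opening) and inter-step (shift, slide, rise, tilt, roll,
twist) parameters follow the mid-frame (CEHS-style) construction, so values
are comparable with mainstream helical-analysis tools.  Sugar pucker uses
the Altona-Sundaralingam pseudorotation formalism; glycosidic torsions are
classified into syn / anti / high-anti windows anchored to the conventional
NMR restraint ranges.
"""
from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structio import Model, Residue, RING_ATOMS, StructureEnsemble

# ---------------------------------------------------------------------------
# idealized base templates
# ---------------------------------------------------------------------------


@functools.cache
def base_templates() -> dict:
    """Idealized nucleotide geometry in the standard base reference frame.

    Shipped as package data; see the 'provenance' key of the returned dict.
    """
    text = resources.files("tetrahelix.data").joinpath("base_templates.json").read_text()
    raw = json.loads(text)
    out = {"provenance": raw["provenance"]}
    for name, entry in raw["residues"].items():
        out[name] = {
            "atoms": list(entry["atoms"]),
            "elements": list(entry["elements"]),
            "coords": np.asarray(entry["coords"], dtype=float),
        }
    return out


def template_coords(resname: str, atom_names: Sequence[str]) -> np.ndarray:
    tpl = base_templates()[resname]
    idx = {a: i for i, a in enumerate(tpl["atoms"])}
    missing = [a for a in atom_names if a not in idx]
    if missing:
        raise KeyError(f"{resname} template lacks atoms {missing}")
    return tpl["coords"][[idx[a] for a in atom_names]]


# ---------------------------------------------------------------------------
# rotations, frames
# ---------------------------------------------------------------------------


def rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Proper rotation R and translation t minimizing |R p + t - q|, with RMSD."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt((((R @ P.T).T + t - Q) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


@dataclass
class BaseFrame:
    """Right-handed orthonormal frame (columns of ``axes`` are x, y, z)."""

    origin: np.ndarray
    axes: np.ndarray
    rmsd: float = 0.0
    distorted: bool = False

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-6):
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame axes are left-handed")

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]

    def flipped(self) -> "BaseFrame":
        """Frame rotated 180 deg about its own x axis (z and y negated)."""
        return BaseFrame(self.origin, self.axes @ np.diag([1.0, -1.0, -1.0]),
                         self.rmsd, self.distorted)


DISTORTION_RMSD = 0.5  # A; above this the fitted base is flagged distorted


def fit_base_frame(residue: Residue) -> BaseFrame:
    """Fit the idealized base of the residue's type onto its ring atoms."""
    ring = RING_ATOMS[residue.name]
    obs = np.array([residue.coord(a) for a in ring])
    if any(residue.coord(a) is None for a in ring):
        raise ValueError(f"{residue.label}: missing ring atoms")
    tpl = template_coords(residue.name, ring)
    R, t, rmsd = kabsch(tpl, obs)
    return BaseFrame(origin=t, axes=R, rmsd=rmsd, distorted=rmsd > DISTORTION_RMSD)


def unit_frame(frames: Sequence[BaseFrame]) -> BaseFrame:
    """Average frame of a base pair or quartet.

    The unit normal is the mean of the base normals (sign-aligned to the
    first frame), and the in-plane orientation is carried by the first
    frame's x axis projected onto the mean plane.  A plain quaternion mean
    is ill-conditioned here because the bases of a quartet are related by
    in-plane rotations approaching 180 degrees; this construction stays
    well-defined and is equivariant under rigid motions.
    """
    ref = frames[0]
    zs = [f.z if f.z @ ref.z >= 0 else -f.z for f in frames]
    z = np.mean(zs, axis=0)
    z /= np.linalg.norm(z)
    x = ref.x - (ref.x @ z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    origin = np.mean([f.origin for f in frames], axis=0)
    return BaseFrame(origin=origin, axes=np.column_stack([x, y, z]))


# ---------------------------------------------------------------------------
# mid-frame parameter computation
# ---------------------------------------------------------------------------


@dataclass
class PairParams:
    shear: float
    stretch: float
    stagger: float
    buckle: float
    propeller: float
    opening: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class StepParams:
    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _signed_angle(a: np.ndarray, b: np.ndarray, about: np.ndarray) -> float:
    return math.degrees(math.atan2(np.cross(a, b) @ about, a @ b))


def _mid_frame_params(f1: BaseFrame, f2: BaseFrame) -> tuple[np.ndarray, float, float, float, BaseFrame]:
    """Mid-frame decomposition between two same-orientation frames.

    Returns (translation in mid-frame, rotation about mid-x, rotation about
    mid-y, rotation about mid-z) plus the mid frame itself.  For a base-pair
    step these are (shift, slide, rise), tilt, roll, twist.
    """
    z1, z2 = f1.z, f2.z
    cosg = float(np.clip(z1 @ z2, -1.0, 1.0))
    gamma = math.degrees(math.acos(cosg))
    hinge = np.cross(z1, z2)
    if np.linalg.norm(hinge) < 1e-12:
        hinge_u = f1.x
        gamma = 0.0
    else:
        hinge_u = hinge / np.linalg.norm(hinge)
    R_half_p = rotation_about(hinge_u, +gamma / 2.0)
    R_half_m = rotation_about(hinge_u, -gamma / 2.0)
    A1 = R_half_p @ f1.axes
    A2 = R_half_m @ f2.axes
    zm = A1[:, 2] + A2[:, 2]
    zm /= np.linalg.norm(zm)
    omega = _signed_angle(A1[:, 1], A2[:, 1], zm)
    xm = A1[:, 0] + A2[:, 0]
    xm -= (xm @ zm) * zm
    xm /= np.linalg.norm(xm)
    ym = np.cross(zm, xm)
    mid = BaseFrame(origin=(f1.origin + f2.origin) / 2.0,
                    axes=np.column_stack([xm, ym, zm]))
    dr = f2.origin - f1.origin
    trans = np.array([dr @ xm, dr @ ym, dr @ zm])
    rot_x = gamma * float(hinge_u @ xm)
    rot_y = gamma * float(hinge_u @ ym)
    return trans, rot_x, rot_y, omega, mid


def pair_params(frame_i: BaseFrame, frame_j: BaseFrame) -> PairParams:
    """Intra-pair parameters; frame_j (the anti-oriented partner) is flipped
    about its x axis before the mid-frame decomposition."""
    f2 = frame_j.flipped() if frame_j.z @ frame_i.z < 0 else frame_j
    trans, rot_x, rot_y, omega, _ = _mid_frame_params(frame_i, f2)
    return PairParams(shear=trans[0], stretch=trans[1], stagger=trans[2],
                      buckle=rot_x, propeller=rot_y, opening=omega)


def pair_mid_frame(frame_i: BaseFrame, frame_j: BaseFrame) -> BaseFrame:
    f2 = frame_j.flipped() if frame_j.z @ frame_i.z < 0 else frame_j
    return _mid_frame_params(frame_i, f2)[4]


def step_params(frame_i: BaseFrame, frame_j: BaseFrame) -> StepParams:
    """Local step parameters between two stacked unit frames."""
    trans, rot_x, rot_y, omega, _ = _mid_frame_params(frame_i, frame_j)
    return StepParams(shift=trans[0], slide=trans[1], rise=trans[2],
                      tilt=rot_x, roll=rot_y, twist=omega)


# ---------------------------------------------------------------------------
# quartet parameters
# ---------------------------------------------------------------------------


@dataclass
class QuartetParams:
    plane_rmsd: float
    quartet_buckle: float  # angle between mean planes of the two pairs, deg


def _plane_normal(points: np.ndarray) -> tuple[np.ndarray, float]:
    c = points.mean(axis=0)
    _, _, Vt = np.linalg.svd(points - c)
    normal = Vt[2]
    rmsd = float(np.sqrt((((points - c) @ normal) ** 2).mean()))
    return normal, rmsd


def _ring_points(residues: Iterable[Residue]) -> np.ndarray:
    pts = []
    for res in residues:
        for a in RING_ATOMS[res.name]:
            pts.append(res.coord(a))
    return np.array(pts)


def quartet_params(pair_a: Sequence[Residue], pair_b: Sequence[Residue]) -> QuartetParams:
    """Non-planarity of a quartet given its two constituent base pairs.

    quartet_buckle is the angle between the best-fit planes through the ring
    atoms of each pair (in [0, 90]); plane_rmsd is the deviation from a
    single best-fit plane through all ring atoms.
    """
    na, _ = _plane_normal(_ring_points(pair_a))
    nb, _ = _plane_normal(_ring_points(pair_b))
    cosang = abs(float(np.clip(na @ nb, -1.0, 1.0)))
    buckle = math.degrees(math.acos(cosang))
    _, rmsd = _plane_normal(_ring_points(list(pair_a) + list(pair_b)))
    return QuartetParams(plane_rmsd=rmsd, quartet_buckle=buckle)


# ---------------------------------------------------------------------------
# torsions and sugar pucker
# ---------------------------------------------------------------------------


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle in degrees, in [0, 360)."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1u) * b1u
    w = b2 - (b2 @ b1u) * b1u
    ang = math.degrees(math.atan2(np.cross(v, w) @ b1u, v @ w))
    return ang % 360.0


SUGAR_RING = ("C4'", "O4'", "C1'", "C2'", "C3'")

#: endocyclic torsions nu0..nu4 as atom quadruples around the furanose ring
_NU_ATOMS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)


def pseudorotation(nu: Sequence[float]) -> tuple[float, float]:
    """Altona-Sundaralingam pseudorotation phase P and amplitude tau_m from
    the five endocyclic torsions nu0..nu4 (degrees)."""
    v = [((x + 180.0) % 360.0) - 180.0 for x in nu]  # signed torsions
    num = (v[4] + v[1]) - (v[3] + v[0])
    den = 2.0 * v[2] * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))
    P = math.degrees(math.atan2(num, den))
    if v[2] < 0:
        # atan2 with signed denominator already handles the quadrant
        pass
    P %= 360.0
    tau_m = v[2] / math.cos(math.radians(P)) if abs(math.cos(math.radians(P))) > 1e-9 else abs(num) / (
        2.0 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))
    )
    return P, abs(tau_m)


def pucker_class(P: float) -> str:
    if P >= 324.0 or P <= 36.0:
        return "North"
    if 108.0 <= P <= 180.0:
        return "South"
    return "other"


def chi_class(chi: float) -> str:
    """syn / anti / high_anti / other windows on the glycosidic torsion.

    anti is the conventional NMR restraint window [170, 280]; high_anti
    extends to 320; syn covers the window around 0 ([320, 360) U [0, 90]).
    """
    chi %= 360.0
    if 170.0 <= chi <= 280.0:
        return "anti"
    if 280.0 < chi < 320.0:
        return "high_anti"
    if chi <= 90.0 or chi >= 320.0:
        return "syn"
    return "other"


@dataclass
class TorsionProfile:
    residue_label: str
    alpha: float | None
    beta: float | None
    gamma: float | None
    delta: float | None
    epsilon: float | None
    zeta: float | None
    chi: float | None
    chi_class: str | None
    pucker_phase: float | None
    pucker_amplitude: float | None
    pucker_class: str | None

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _tors(res_atoms: Sequence[tuple[Residue, str]]) -> float | None:
    coords = []
    for res, name in res_atoms:
        if res is None:
            return None
        c = res.coord(name)
        if c is None:
            return None
        coords.append(c)
    return dihedral(*coords)


def torsion_profile(
    residue: Residue,
    prev_residue: Residue | None = None,
    next_residue: Residue | None = None,
) -> TorsionProfile:
    """Backbone/glycosidic torsions and sugar pucker of one nucleotide.

    Angles whose atoms span a missing neighbour (alpha/beta at the 5'
    terminus, epsilon/zeta at the 3' terminus) are reported as None.
    """
    missing_sugar = [a for a in SUGAR_RING if residue.coord(a) is None]
    if missing_sugar:
        raise ValueError(f"{residue.label}: missing sugar atoms {missing_sugar}")
    r, p, n = residue, prev_residue, next_residue
    alpha = _tors([(p, "O3'"), (r, "P"), (r, "O5'"), (r, "C5'")])
    beta = _tors([(r, "P"), (r, "O5'"), (r, "C5'"), (r, "C4'")])
    gamma = _tors([(r, "O5'"), (r, "C5'"), (r, "C4'"), (r, "C3'")])
    delta = _tors([(r, "C5'"), (r, "C4'"), (r, "C3'"), (r, "O3'")])
    epsilon = _tors([(r, "C4'"), (r, "C3'"), (r, "O3'"), (n, "P")])
    zeta = _tors([(r, "C3'"), (r, "O3'"), (n, "P"), (n, "O5'")])
    if r.is_purine:
        chi = _tors([(r, "O4'"), (r, "C1'"), (r, "N9"), (r, "C4")])
    else:
        chi = _tors([(r, "O4'"), (r, "C1'"), (r, "N1"), (r, "C2")])
    nu = [_tors([(r, a) for a in quad]) for quad in _NU_ATOMS]
    P, tau = pseudorotation(nu)
    return TorsionProfile(
        residue_label=r.label,
        alpha=alpha, beta=beta, gamma=gamma, delta=delta,
        epsilon=epsilon, zeta=zeta,
        chi=chi, chi_class=chi_class(chi) if chi is not None else None,
        pucker_phase=P, pucker_amplitude=tau, pucker_class=pucker_class(P),
    )


def model_torsions(model: Model) -> pd.DataFrame:
    """Torsion profiles for every residue of a model (per chain, in order)."""
    rows = []
    for chain in model.chains:
        for i, res in enumerate(chain.residues):
            prev_res = chain.residues[i - 1] if i > 0 else None
            next_res = chain.residues[i + 1] if i + 1 < len(chain.residues) else None
            prof = torsion_profile(res, prev_res, next_res)
            row = {"chain": chain.id, "residue": res.name, "number": res.number}
            row.update(prof.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# groove widths
# ---------------------------------------------------------------------------


def groove_widths(
    model: Model,
    strand_pairs: Sequence[tuple[str, str]],
    pp_offset: float = 5.8,
    narrow: float = 4.0,
    wide: float = 9.0,
    max_register: int = 6,
) -> pd.DataFrame:
    """Cross-strand P-P groove widths for antiparallel strand pairs.

    For each residue i of strand A (paired antiparallel with strand B), the
    width on either side of the pairing register is the minimum P-P distance
    to B residues within ``max_register`` steps 5' (``width_5p``) or 3'
    (``width_3p``) of the partner, minus ``pp_offset`` (the conventional
    correction for the phosphate van der Waals radii).  ``width`` is the
    smaller of the two and carries the narrow/medium/wide label.
    """
    chains = {c.id: c for c in model.chains}
    rows = []
    for a_id, b_id in strand_pairs:
        ca, cb = chains[a_id], chains[b_id]
        pa = [r.coord("P") for r in ca.residues]
        pb = [r.coord("P") for r in cb.residues]
        n = len(cb.residues)
        for i, res in enumerate(ca.residues):
            if pa[i] is None:
                continue
            j0 = n - 1 - i  # antiparallel pairing register
            d5, d3 = math.inf, math.inf
            for k in range(1, max_register + 1):
                for sign, store in ((-1, "5p"), (1, "3p")):
                    j = j0 + sign * k
                    if 0 <= j < n and pb[j] is not None:
                        d = float(np.linalg.norm(pa[i] - pb[j]))
                        if store == "5p":
                            d5 = min(d5, d)
                        else:
                            d3 = min(d3, d)
            w5 = d5 - pp_offset if math.isfinite(d5) else None
            w3 = d3 - pp_offset if math.isfinite(d3) else None
            widths = [w for w in (w5, w3) if w is not None]
            width = min(widths) if widths else None
            if width is None:
                label = None
            elif width < narrow:
                label = "narrow"
            elif width > wide:
                label = "wide"
            else:
                label = "medium"
            rows.append({
                "strand_a": a_id, "strand_b": b_id, "residue": res.label,
                "width_5p": w5, "width_3p": w3, "width": width, "label": label,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ensemble statistics
# ---------------------------------------------------------------------------


def ensemble_stats(per_model: pd.DataFrame, value_cols: Sequence[str],
                   key_cols: Sequence[str]) -> pd.DataFrame:
    """Mean and SD over models for each key (SD is 0 for a single model)."""
    grouped = per_model.groupby(list(key_cols))[list(value_cols)]
    mean = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=0).add_suffix("_sd")
    return mean.join(sd).reset_index()
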