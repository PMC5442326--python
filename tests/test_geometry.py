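"""Base frames, helical parameters, torsions, puckers and grooves."""
import math

import numpy as np
import pytest

from tetrahelix.geometry import (
    BaseFrame,
    chi_class,
    dihedral,
    ensemble_stats,
    fit_base_frame,
    groove_widths,
    model_torsions,
    pair_params,
    pseudorotation,
    pucker_class,
    quartet_params,
    rotation_about,
    step_params,
    template_coords,
    unit_frame,
)
from tetrahelix.pairing import model_frames
from tetrahelix.structio import AtomRecord, Residue
from tetrahelix.structio import RING_ATOMS

from conftest import analytic_b_duplex


def residue_from_template(resname="DG", R=np.eye(3), t=np.zeros(3)):
    from tetrahelix.geometry import base_templates

    tpl = base_templates()[resname]
    res = Residue(name=resname, number=1, chain_id="A")
    for name, elem, xyz in zip(tpl["atoms"], tpl["elements"], tpl["coords"]):
        res.add(AtomRecord(name, elem, R @ np.asarray(xyz) + t))
    return res


class TestBaseFrame:
    def test_identity_fit(self):
        f = fit_base_frame(residue_from_template())
        assert np.allclose(f.axes, np.eye(3), atol=1e-9)
        assert np.allclose(f.origin, 0, atol=1e-9)
        assert f.rmsd < 1e-9 and not f.distorted

    def test_translation_recovered(self):
        f = fit_base_frame(residue_from_template(t=np.array([1.0, 2.0, 3.0])))
        assert np.allclose(f.origin, [1, 2, 3], atol=1e-9)

    def test_rotation_about_normal_recovered(self):
        R = rotation_about([0, 0, 1], 25.0)
        f = fit_base_frame(residue_from_template(R=R))
        err = np.degrees(np.arccos(np.clip((np.trace(f.axes.T @ R) - 1) / 2, -1, 1)))
        assert err < 1e-6

    def test_axes_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            BaseFrame(np.zeros(3), np.eye(3) * 2.0)


def make_pair_frames(buckle=0.0, propeller=0.0, opening=0.0,
                     M=np.eye(3), o=np.zeros(3)):
    """Exact frame construction: symmetric half-rotations about the pair
    frame axes, partner anti-oriented (flipped about x)."""
    flip = np.diag([1.0, -1.0, -1.0])
    Rb = rotation_about([1, 0, 0], buckle / 2)
    Rp = rotation_about([0, 1, 0], propeller / 2)
    Ro = rotation_about([0, 0, 1], opening / 2)
    A1 = M @ np.linalg.multi_dot([Rb, Rp, Ro]).T
    A2 = M @ np.linalg.multi_dot([Rb, Rp, Ro]) @ flip
    return BaseFrame(o, A1), BaseFrame(o, A2)


class TestPairParams:
    def test_identical_coplanar_frames_zero(self):
        f1, f2 = make_pair_frames()
        p = pair_params(f1, f2)
        assert np.allclose(list(p.as_dict().values()), 0, atol=1e-9)

    def test_buckle_28_propeller_0(self):
        f1, f2 = make_pair_frames(buckle=28.0)
        p = pair_params(f1, f2)
        assert p.buckle == pytest.approx(28.0, abs=0.1)
        assert p.propeller == pytest.approx(0.0, abs=0.1)

    def test_propeller_14(self):
        f1, f2 = make_pair_frames(propeller=14.0)
        p = pair_params(f1, f2)
        assert p.propeller == pytest.approx(14.0, abs=0.1)
        assert p.buckle == pytest.approx(0.0, abs=0.1)

    def test_symmetry_of_arguments_flips_signs_only(self):
        f1, f2 = make_pair_frames(buckle=20.0, propeller=-8.0)
        a, b = pair_params(f1, f2), pair_params(f2, f1)
        assert abs(a.buckle) == pytest.approx(abs(b.buckle), abs=1e-6)
        assert abs(a.propeller) == pytest.approx(abs(b.propeller), abs=1e-6)


class TestStepParams:
    def test_pure_rise(self):
        f1 = BaseFrame(np.zeros(3), np.eye(3))
        f2 = BaseFrame(np.array([0, 0, 3.4]), np.eye(3))
        s = step_params(f1, f2)
        assert s.rise == pytest.approx(3.4, abs=1e-9)
        assert s.twist == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("rise", [2.5, 3.4, 4.5, 5.5])
    @pytest.mark.parametrize("twist", [-60.0, -25.0, 0.0, 30.0, 60.0])
    def test_injection_recovery_sweep(self, rise, twist):
        f1 = BaseFrame(np.zeros(3), np.eye(3))
        f2 = BaseFrame(np.array([0, 0, rise]),
                       rotation_about([0, 0, 1], twist))
        s = step_params(f1, f2)
        assert s.rise == pytest.approx(rise, abs=0.01)
        assert s.twist == pytest.approx(twist, abs=0.1)

    def test_swap_negates_twist(self):
        f1 = BaseFrame(np.zeros(3), np.eye(3))
        f2 = BaseFrame(np.array([0.3, -0.2, 3.4]),
                       rotation_about([0.2, 0.1, 1], 25.0))
        a, b = step_params(f1, f2), step_params(f2, f1)
        assert a.twist == pytest.approx(-b.twist, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        f1 = BaseFrame(np.zeros(3), rotation_about([1, 2, 0.5], 12.0))
        f2 = BaseFrame(np.array([0.5, 0.1, 3.3]),
                       rotation_about([0, 0.3, 1], 30.0))
        for _ in range(5):
            axis, ang = rng.normal(size=3), rng.uniform(0, 360)
            R = rotation_about(axis, ang)
            t = rng.normal(scale=10, size=3)
            g1 = BaseFrame(R @ f1.origin + t, R @ f1.axes)
            g2 = BaseFrame(R @ f2.origin + t, R @ f2.axes)
            a = np.array(list(step_params(f1, f2).as_dict().values()))
            b = np.array(list(step_params(g1, g2).as_dict().values()))
            assert np.allclose(a, b, atol=1e-6)


class TestGeneratorInjectionRecovery:
    """End-to-end: parameters injected by the stack generator are recovered
    from fitted base frames within 0.1 of the injected value."""

    @pytest.mark.parametrize("rise,twist", [(2.5, -60.0), (3.4, 25.0),
                                            (4.5, -30.0), (5.5, 60.0)])
    def test_step_recovery(self, rise, twist):
        from tetrahelix.geometry import pair_mid_frame
        from tetrahelix.synthetic import StackSpec, build_quartet_stack

        ens, truth = build_quartet_stack(
            StackSpec(layer_classes=["GG_PAIR", "GG_PAIR"], rise=rise,
                      twist=twist))
        frames = model_frames(ens.models[0])
        (p1, p2) = truth["pairs"]
        f1 = pair_mid_frame(frames[p1["residues"][0]], frames[p1["residues"][1]])
        f2 = pair_mid_frame(frames[p2["residues"][0]], frames[p2["residues"][1]])
        s = step_params(f1, f2)
        assert s.rise == pytest.approx(rise, abs=0.1)
        assert s.twist == pytest.approx(twist, abs=0.1)

    @pytest.mark.parametrize("buckle", [-40.0, -15.0, 20.0, 40.0])
    def test_pair_buckle_recovery(self, buckle):
        from tetrahelix.synthetic import StackSpec, build_quartet_stack

        ens, truth = build_quartet_stack(
            StackSpec(layer_classes=["GC_PAIR"], buckle=buckle))
        frames = model_frames(ens.models[0])
        (ra, rb) = truth["pairs"][0]["residues"]
        p = pair_params(frames[ra], frames[rb])
        assert p.buckle == pytest.approx(buckle, abs=0.1)


class TestQuartetParams:
    def test_planar_quartet_zero_buckle(self, gaga_stack):
        ens, truth = gaga_stack
        model = ens.models[0]
        idx = {r.key: r for r in model.residues()}
        layer = truth["layers"][0]
        pair_a = [idx[k] for k in layer["residues"][:2]]
        pair_b = [idx[k] for k in layer["residues"][2:]]
        qp = quartet_params(pair_a, pair_b)
        assert qp.quartet_buckle == pytest.approx(0.0, abs=0.1)
        assert qp.plane_rmsd < 0.5

    def test_buckle_15_recovered(self):
        from tetrahelix.synthetic import StackSpec, build_quartet_stack

        ens, truth = build_quartet_stack(
            StackSpec(layer_classes=["GAGA"], buckle=15.0))
        model = ens.models[0]
        idx = {r.key: r for r in model.residues()}
        keys = truth["layers"][0]["residues"]
        qp = quartet_params([idx[k] for k in keys[:2]],
                            [idx[k] for k in keys[2:]])
        assert qp.quartet_buckle == pytest.approx(15.0, abs=0.1)

    def test_buckle_range_invariant(self, tetramer_core_stack):
        ens, _ = tetramer_core_stack
        model = ens.models[0]
        idx = {r.key: r for r in model.residues()}
        from tetrahelix.pairing import (assemble_quartets, find_hbonds,
                                        find_pairs)

        hb = find_hbonds(model)
        qts = assemble_quartets(find_pairs(model, hb), hb, model)
        for q in qts:
            a = [idx[k] for k in q.residues[:2]]
            b = [idx[k] for k in q.residues[2:]]
            qp = quartet_params(a, b)
            assert 0.0 <= qp.quartet_buckle <= 90.0


class TestTorsions:
    def test_pseudorotation_closed_form(self):
        # C2'-endo: P = 162, tau_m = 35 by construction
        nu = [35.0 * math.cos(math.radians(162.0 + 144.0 * (j - 2)))
              for j in range(5)]
        P, tau = pseudorotation(nu)
        assert P == pytest.approx(162.0, abs=1e-9)
        assert tau == pytest.approx(35.0, abs=1e-9)
        assert pucker_class(P) == "South"

    def test_pseudorotation_north(self):
        nu = [38.0 * math.cos(math.radians(9.0 + 144.0 * (j - 2)))
              for j in range(5)]
        P, _ = pseudorotation(nu)
        assert P == pytest.approx(9.0, abs=1e-9)
        assert pucker_class(P) == "North"

    @pytest.mark.parametrize(
        "chi,expected",
        [(60.0, "syn"), (350.0, "syn"), (200.0, "anti"), (280.0, "anti"),
         (300.0, "high_anti"), (120.0, "other")],
    )
    def test_chi_windows(self, chi, expected):
        assert chi_class(chi) == expected

    def test_dihedral_right_angle_both_chiralities(self):
        p0, p1, p2 = np.array([1.0, 0, 0]), np.zeros(3), np.array([0.0, 0, 1])
        assert dihedral(p0, p1, p2, np.array([0.0, 1, 1])) == pytest.approx(270.0)
        assert dihedral(p0, p1, p2, np.array([0.0, -1, 1])) == pytest.approx(90.0)

    def test_model_torsions_complete(self, backbone_pair_stack):
        ens, _ = backbone_pair_stack
        df = model_torsions(ens.models[0])
        assert len(df) == 4
        assert df["chi"].notna().all()
        assert df["pucker_phase"].between(0, 360).all()
        assert set(df["chi_class"]) <= {"syn", "anti", "high_anti", "other"}

    def test_missing_sugar_raises(self, gaga_stack):
        # bases-only models carry no sugar ring
        ens, _ = gaga_stack
        res = next(ens.models[0].residues())
        from tetrahelix.geometry import torsion_profile

        with pytest.raises(ValueError, match="sugar"):
            torsion_profile(res)


class TestGrooves:
    def test_b_duplex_minor_narrower_than_major(self):
        model = analytic_b_duplex()
        df = groove_widths(model, [("A", "B")])
        mid = df.iloc[6:14]
        assert (mid["width_5p"] < mid["width_3p"]).all()
        # canonical B-form values: minor ~5-7 A, major ~10-12 A after the
        # 5.8 A phosphate correction
        assert mid["width_5p"].mean() == pytest.approx(5.9, abs=1.5)
        assert mid["width_3p"].mean() == pytest.approx(11.0, abs=1.5)

    def test_symmetric_stack_symmetric_profile(self):
        model = analytic_b_duplex(n=16)
        df = groove_widths(model, [("A", "B")])
        w = df["width"].to_numpy()[4:-4]
        assert np.allclose(w, w[::-1], atol=1e-6)


def test_ensemble_stats_sd_zero_for_identical_models():
    import pandas as pd

    df = pd.DataFrame({
        "model": [1, 2], "key": ["a", "a"], "twist": [25.0, 25.0],
    })
    out = ensemble_stats(df, ["twist"], ["key"])
    assert out.loc[0, "twist_mean"] == 25.0
    assert out.loc[0, "twist_sd"] == 0.0


def test_unit_frame_rigid_equivariance():
    rng = np.random.default_rng(3)
    frames = [
        BaseFrame(rng.normal(size=3), rotation_about(rng.normal(size=3),
                                                     rng.uniform(0, 180)))
        for _ in range(4)
    ]
    R = rotation_about([1, 1, 1], 40.0)
    t = np.array([1.0, -2.0, 0.5])
    moved = [BaseFrame(R @ f.origin + t, R @ f.axes) for f in frames]
    u, v = unit_frame(frames), unit_frame(moved)
    assert np.allclose(R @ u.axes, v.axes, atol=1e-9)
    assert np.allclose(R @ u.origin + t, v.origin, atol=1e-9)
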