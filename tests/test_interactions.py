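"""Geometric interaction detection: criteria, filtering and invariants."""

import math

import numpy as np
import pytest

from contactprof import synthgen
from contactprof.bruteforce import detect_frame_naive
from contactprof.config import DetectionConfig
from contactprof.interactions import (detect_frame, detect_hbonds,
                                      detect_hydrophobic, detect_pistacking,
                                      detect_saltbridges, detect_waterbridges,
                                      filter_redundant)
from contactprof.bonds import infer_bonds
from contactprof.perception import perceive
from contactprof.structure import Atom, Frame, classify_entities
from tests.conftest import make_frame


def _frame(entries):
    """entries: (name, element, res_name, res_seq, chain, xyz)"""
    atoms = [Atom(serial=i + 1, name=n, element=e, res_name=rn, res_seq=rs,
                  chain_id=ch, coords=np.asarray(x, float))
             for i, (n, e, rn, rs, ch, x) in enumerate(entries)]
    return Frame(atoms)


def _detect_all(frame, ligand="LIG", config=None):
    em = classify_entities(frame, {ligand})
    return detect_frame(frame, em, config)


def _hbond_frame(distance, angle_deg_val):
    """Ser hydroxyl donating to a ligand carbonyl O at a given D-A distance
    and D-H...A angle (H placed on the circle that realizes the angle)."""
    d = np.array([0.0, 0.0, 0.0])          # donor O (Ser OG)
    a = np.array([distance, 0.0, 0.0])     # acceptor O
    # place H at 0.97 A from D such that angle(D-H-A) = angle_deg_val
    # use law of sines on triangle D-H-A
    theta = math.radians(angle_deg_val)
    # angle at D between D->H and D->A follows from the triangle
    # |DH| = 0.97; solve for H position in the xy-plane
    dh = 0.97
    # angle at H is theta; side DA = distance; use law of sines:
    # sin(angle at A)/dh = sin(theta)/distance
    sin_a = dh * math.sin(theta) / distance
    ang_a = math.asin(min(1.0, sin_a))
    ang_d = math.pi - theta - ang_a
    h = d + dh * np.array([math.cos(ang_d), math.sin(ang_d), 0.0])
    return _frame([
        ("CB", "C", "SER", 10, "A", d + np.array([-1.43, 0.0, 0.0])),
        ("OG", "O", "SER", 10, "A", d),
        ("HG", "H", "SER", 10, "A", h),
        ("C1", "C", "LIG", 900, "L", a + np.array([1.23, 0.0, 0.0])),
        ("O1", "O", "LIG", 900, "L", a),
    ])


class TestHbonds:
    @pytest.mark.parametrize("dist,ang,expected", [
        (2.9, 165.0, True),    # canonical short hydrogen bond
        (3.4, 150.0, True),    # longer polar contact, still in range
        (2.9, 60.0, False),    # angle gate
        (5.0, 150.0, False),   # distance gate
    ])
    def test_distance_and_angle_gates(self, dist, ang, expected):
        recs = [r for r in _detect_all(_hbond_frame(dist, ang))
                if r.itype == "hbond"]
        assert bool(recs) is expected
        if expected:
            assert recs[0].geometry["distance"] == pytest.approx(dist, abs=1e-6)
            assert recs[0].geometry["angle"] == pytest.approx(ang, abs=1e-6)

    def test_no_hydrogen_fallback_waives_angle(self):
        fr = _hbond_frame(3.4, 150.0)
        keep = [i for i, a in enumerate(fr.atoms) if a.element != "H"]
        stripped = Frame([fr.atoms[i] for i in keep], fr.coords[keep])
        recs = [r for r in _detect_all(stripped) if r.itype == "hbond"]
        assert len(recs) == 1
        assert recs[0].geometry["angle"] is None
        assert recs[0].subtype == "no-h-fallback"
        # fallback cutoff is tighter: 3.6 A is out
        fr2 = _hbond_frame(3.6, 150.0)
        stripped2 = Frame([fr2.atoms[i] for i in keep], fr2.coords[keep])
        assert [r for r in _detect_all(stripped2) if r.itype == "hbond"] == []


class TestHydrophobic:
    def _leu_frame(self, *lig_dists):
        entries = [("CD1", "C", "LEU", 20, "A", (0.0, 0.0, 0.0)),
                   ("HD1", "H", "LEU", 20, "A", (0.0, -1.09, 0.0))]
        for k, dist in enumerate(lig_dists):
            entries.append((f"C{k+1}", "C", "LIG", 900, "L",
                            (dist, 0.0, 0.0)))
            entries.append((f"H{k+1}", "H", "LIG", 900, "L",
                            (dist, 1.09, 0.0)))
        return _frame(entries)

    def test_contact_within_cutoff(self):
        recs = _detect_all(self._leu_frame(3.6))
        assert [r.itype for r in recs] == ["hydrophobic"]
        assert recs[0].geometry["distance"] == pytest.approx(3.6)

    def test_contact_beyond_cutoff(self):
        assert _detect_all(self._leu_frame(4.5)) == []

    def test_min_distance_per_residue(self):
        # one ligand atom vs three Tyr-like ring carbons at 3.2/3.6/3.9
        entries = [("CG", "C", "PHE", 30, "A", (3.2, 0.0, 0.0)),
                   ("CD1", "C", "PHE", 30, "A", (3.6, 1.8, 0.0)),
                   ("CD2", "C", "PHE", 30, "A", (3.9, -1.8, 0.0)),
                   ("C1", "C", "LIG", 900, "L", (0.0, 0.0, 0.0)),
                   ("H1", "H", "LIG", 900, "L", (0.0, -1.09, 0.0))]
        recs = _detect_all(_frame(entries))
        hyd = [r for r in recs if r.itype == "hydrophobic"]
        assert len(hyd) == 1
        assert hyd[0].geometry["distance"] == pytest.approx(3.2)
        assert hyd[0].receptor_atom_names == ("CG",)


def _ring(center, normal_axis, resname, resseq, chain, names=None, z_rot=0.0):
    """Planar 6-ring of carbons with the given normal axis ('z' or 'x').

    For PHE the wwPDB ring atom names are used (in cycle order) so the
    template ring perception finds it; ligand rings use generic names.
    """
    if names is None:
        names = (["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
                 if resname == "PHE" else [f"CR{k+1}" for k in range(6)])
    out = []
    for k in range(6):
        a = math.radians(60 * k + z_rot)
        if normal_axis == "z":
            xyz = center + 1.39 * np.array([math.cos(a), math.sin(a), 0.0])
        else:
            xyz = center + 1.39 * np.array([0.0, math.cos(a), math.sin(a)])
        out.append((names[k], "C", resname, resseq, chain, xyz))
    return out


class TestPiStacking:
    def test_parallel_stack(self):
        entries = _ring(np.zeros(3), "z", "PHE", 30, "A") + \
            _ring(np.array([0.0, 0.0, 3.5]), "z", "LIG", 900, "L")
        recs = [r for r in _detect_all(_frame(entries)) if r.itype == "pistacking"]
        assert len(recs) == 1 and recs[0].subtype == "parallel"
        assert recs[0].geometry["distance"] == pytest.approx(3.5)
        assert recs[0].geometry["offset"] == pytest.approx(0.0, abs=1e-9)

    def test_tshaped_stack(self):
        entries = _ring(np.zeros(3), "z", "PHE", 30, "A") + \
            _ring(np.array([0.0, 1.0, 4.9]), "x", "LIG", 900, "L")
        recs = [r for r in _detect_all(_frame(entries)) if r.itype == "pistacking"]
        assert len(recs) == 1 and recs[0].subtype == "tshaped"
        assert recs[0].geometry["angle"] == pytest.approx(90.0)

    def test_parallel_but_too_far(self):
        entries = _ring(np.zeros(3), "z", "PHE", 30, "A") + \
            _ring(np.array([0.0, 0.0, 7.0]), "z", "LIG", 900, "L")
        assert [r for r in _detect_all(_frame(entries))
                if r.itype == "pistacking"] == []


class TestSaltBridges:
    def _frame_with_lys(self, dy, ligand_charged=True):
        o_h = [] if ligand_charged else [("HO1", "H", "LIG", 900, "L",
                                          (0.866 * 1.25, 0.625 + 0.97, 0.0))]
        entries = [
            ("CE", "C", "LYS", 40, "A", (0.0, dy + 1.47, 0.0)),
            ("NZ", "N", "LYS", 40, "A", (0.0, dy, 0.0)),
            ("HZ1", "H", "LYS", 40, "A", (0.95, dy + 0.35, 0.0)),
            ("HZ2", "H", "LYS", 40, "A", (-0.95, dy + 0.35, 0.0)),
            ("HZ3", "H", "LYS", 40, "A", (0.0, dy - 0.3, 0.95)),
            ("C9", "C", "LIG", 900, "L", (0.0, -0.417, 0.0)),
            ("O91", "O", "LIG", 900, "L", (1.0825, 0.208, 0.0)),
            ("O92", "O", "LIG", 900, "L", (-1.0825, 0.208, 0.0)),
        ] + o_h
        return _frame(entries)

    def test_carboxylate_to_ammonium(self):
        recs = [r for r in _detect_all(self._frame_with_lys(4.0))
                if r.itype == "saltbridge"]
        assert len(recs) == 1
        assert recs[0].geometry["distance"] == pytest.approx(4.0, abs=1e-3)

    def test_out_of_range(self):
        assert [r for r in _detect_all(self._frame_with_lys(6.0))
                if r.itype == "saltbridge"] == []

    def test_same_sign_centers_never_bridge(self, toy_frame, toy_entities):
        # the toy ligand carboxylate vs the DA phosphate and Asp: all negative
        recs = [r for r in detect_frame(toy_frame, toy_entities)
                if r.itype == "saltbridge"]
        assert [(r.receptor_residue[1]) for r in recs] == ["LYS"]


class TestWaterBridges:
    def _bridge_frame(self, lig_leg=2.85, rec_leg=3.0, water_angle=110.0):
        w = np.array([0.0, 0.0, 0.0])
        o2 = w + np.array([0.0, lig_leg, 0.0])
        th = math.radians(water_angle)
        od1 = w + rec_leg * np.array([math.sin(th), math.cos(th), 0.0])
        leg = (od1 - w) / np.linalg.norm(od1 - w)
        return _frame([
            ("C2", "C", "LIG", 900, "L", o2 + np.array([0.0, 1.43, 0.0])),
            ("O2", "O", "LIG", 900, "L", o2),
            ("HO2", "H", "LIG", 900, "L", o2 - np.array([0.0, 1.01, 0.0])),
            ("O", "O", "HOH", 401, "W", w),
            ("H1", "H", "HOH", 401, "W", w + 0.96 * leg),
            ("H2", "H", "HOH", 401, "W", w + 0.96 * np.array([-0.94, 0.34, 0.0])),
            ("CG", "C", "ASP", 50, "A", od1 + 1.25 * leg),
            ("OD1", "O", "ASP", 50, "A", od1),
            ("OD2", "O", "ASP", 50, "A", od1 + 1.25 * leg
             + 1.25 * np.array([0.0, -0.97, 0.242])),
        ])

    def test_canonical_bridge(self):
        recs = [r for r in _detect_all(self._bridge_frame())
                if r.itype == "waterbridge"]
        assert len(recs) == 1
        r = recs[0]
        assert r.ligand_atom_names == ("O2",)
        assert r.receptor_atom_names == ("OD1",)
        assert r.geometry["water_angle"] == pytest.approx(110.0, abs=1e-6)

    def test_collinearity_gate(self):
        assert [r for r in _detect_all(self._bridge_frame(water_angle=30.0))
                if r.itype == "waterbridge"] == []

    def test_long_leg_gate(self):
        assert [r for r in _detect_all(self._bridge_frame(rec_leg=4.8))
                if r.itype == "waterbridge"] == []


class TestFilterRedundant:
    def test_saltbridge_absorbs_member_hbond(self, toy_frame, toy_entities):
        """The Lys ammonium donates to the ligand carboxylate oxygens; the
        raw hydrogen bond must be subsumed by the salt bridge."""
        bonds = infer_bonds(toy_frame)
        ps = perceive(toy_frame, bonds, toy_entities)
        raw = detect_hbonds(toy_frame, ps, toy_entities)
        raw_lys = [r for r in raw if r.receptor_residue[1] == "LYS"]
        assert raw_lys  # the overlap genuinely exists pre-filter
        final = detect_frame(toy_frame, toy_entities)
        assert [r for r in final
                if r.itype == "hbond" and r.receptor_residue[1] == "LYS"] == []
        assert [r for r in final if r.itype == "saltbridge"]

    def test_pistack_absorbs_intra_ring_hydrophobics(self):
        # stacked all-carbon rings produce ring-ring hydrophobic contacts
        entries = _ring(np.zeros(3), "z", "PHE", 30, "A") + \
            _ring(np.array([0.0, 0.0, 3.5]), "z", "LIG", 900, "L")
        fr = _frame(entries)
        em = classify_entities(fr, {"LIG"})
        bonds = infer_bonds(fr)
        ps = perceive(fr, bonds, em)
        assert detect_hydrophobic(fr, ps, em)   # present pre-filter
        final = detect_frame(fr, em)
        assert [r.itype for r in final] == ["pistacking"]

    def test_disjoint_records_survive(self):
        recs = _detect_all(self._two_site_frame())
        assert sorted(r.itype for r in recs) == ["hbond", "hydrophobic"]

    def _two_site_frame(self):
        hb = _hbond_frame(2.9, 165.0)
        entries = [(a.name, a.element, a.res_name, a.res_seq, a.chain_id,
                    hb.coords[i]) for i, a in enumerate(hb.atoms)]
        entries += [("CD1", "C", "LEU", 20, "A", (20.0, 0.0, 0.0)),
                    ("HDL", "H", "LEU", 20, "A", (20.0, 1.09, 0.0)),
                    ("C13", "C", "LIG", 900, "L", (23.6, 0.0, 0.0)),
                    ("HTL", "H", "LIG", 900, "L", (23.6, 1.09, 0.0))]
        return _frame(entries)


class TestDetectFrameProperties:
    def test_bound_fixture_equals_planted_set(self, toy_frame, toy_entities):
        from contactprof.ledger import record_key
        keys = {record_key(r) for r in detect_frame(toy_frame, toy_entities)}
        assert keys == {s.ledger_key for s in synthgen.PLANTED_KEYS.values()}

    def test_apo_frame_is_empty(self, toy_frame, toy_entities):
        shifted = toy_frame.coords.copy()
        for i in toy_entities.ligand:
            shifted[i] += np.array([0.0, -40.0, 0.0])
        assert detect_frame(toy_frame.with_coords(shifted), toy_entities) == []

    def test_detection_is_deterministic(self, toy_frame, toy_entities):
        a = [r.signature() for r in detect_frame(toy_frame, toy_entities)]
        b = [r.signature() for r in detect_frame(toy_frame, toy_entities)]
        assert a == b

    def test_ligand_receptor_only(self, toy_entities):
        lig = set(toy_entities.ligand)
        for s in range(5):
            fr = synthgen.make_random_frame(s)
            for r in detect_frame(fr, toy_entities):
                assert set(r.ligand_atoms) <= lig
                assert not set(r.receptor_atoms) & lig

    def test_rigid_transform_invariance(self, toy_frame, toy_entities):
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("xyz", [31, -57, 113], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 11.0])
        moved = toy_frame.with_coords(toy_frame.coords @ R.T + t)
        a = [r.signature() for r in detect_frame(toy_frame, toy_entities)]
        b = [r.signature() for r in detect_frame(moved, toy_entities)]
        assert a == b

    @pytest.mark.parametrize("param,loose,tight", [
        ("hbond_dist_max", 5.0, 2.0),
        ("hydrophobic_dist_max", 5.0, 3.0),
        ("pistack_dist_max", 7.0, 3.0),
        ("saltbridge_dist_max", 7.0, 3.0),
    ])
    def test_threshold_monotonicity(self, toy_entities, param, loose, tight):
        for s in range(3):
            fr = synthgen.make_random_frame(s)
            base = {r.signature()[:5] for r in detect_frame(fr, toy_entities)}
            cl = DetectionConfig().replace(**{param: loose})
            ct = DetectionConfig().replace(**{param: tight})
            got_l = {r.signature()[:5] for r in detect_frame(fr, toy_entities, cl)}
            got_t = {r.signature()[:5] for r in detect_frame(fr, toy_entities, ct)}
            itype = {"hbond_dist_max": "hbond",
                     "hydrophobic_dist_max": "hydrophobic",
                     "pistack_dist_max": "pistacking",
                     "saltbridge_dist_max": "saltbridge"}[param]
            assert {g for g in base if g[0] == itype} <= \
                {g for g in got_l if g[0] == itype}
            assert {g for g in got_t if g[0] == itype} <= \
                {g for g in base if g[0] == itype}


@pytest.mark.parametrize("seed", range(8))
def test_oracle_equivalence_on_random_frames(seed, toy_entities):
    fr = synthgen.make_random_frame(seed)
    fast = [r.signature() for r in detect_frame(fr, toy_entities)]
    naive = [r.signature() for r in detect_frame_naive(fr, toy_entities)]
    assert fast == naive
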