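"""Deterministic synthetic complexes and trajectories with planted interactions.

The toy complex is a miniature receptor (Arg, Lys, Tyr and Asp side-chain
groups, one adenine and one thymine nucleotide with a phosphate, waters, one
sodium ion) plus a multi-fragment ligand carrying hydroxyls, an ester
carbonyl, a carboxylate, a phenyl ring and an aliphatic tail.  Six planted
interactions — two hydrogen bonds, a water bridge, a pi-stack, a hydrophobic
contact and a salt bridge — sit at spatially separated "stations" roughly
16 A apart, so each one can be toggled per frame without disturbing the
others.  Bound geometry satisfies every detection criterion with at least a
0.3 A / 15 deg margin; broken geometry violates the tested criterion by at
least the same margin.  Detection on a generated trajectory must therefore
recover the planted occupancy exactly, frame for frame.

The ligand fragments share one residue but are not covalently linked to each
other; bond lengths inside every fragment are standard.  Physical realism
(force fields, dynamics) is explicitly out of scope: the generator's job is
planted ground truth, not chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from contactprof.structure import Atom, Frame, Trajectory

__all__ = [
    "PlantSchedule", "GroundTruth", "make_toy_complex", "make_trajectory",
    "make_jitter_trajectory", "make_random_frame", "make_crystal_site_synthetic",
    "DEFAULT_FRACTIONS", "PLANTED_KEYS", "LIGAND_RESNAME",
]

LIGAND_RESNAME = "LIG"

# occupancy fractions of the six planted interactions in the default schedule
DEFAULT_FRACTIONS = {
    "hbond:O6-Arg364": 1.00,
    "hbond:O1-Tyr426": 0.98,
    "waterbridge:O2-Asp533": 0.93,
    "pistacking:ring-DA113": 0.778,
    "hydrophobic:C13-DT9": 0.56,
    "saltbridge:COO-Lys425": 0.10,
}


def _u(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _rot2(v, deg: float) -> np.ndarray:
    """Rotate a 2-vector (xy) by deg; z passes through unchanged."""
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    v = np.asarray(v, dtype=float)
    return np.array([v[0] * c - v[1] * s, v[0] * s + v[1] * c] + list(v[2:]))


class _Builder:
    def __init__(self):
        self.atoms: list = []
        self.coords: list = []
        self.fragments: dict = {}

    def add(self, name, element, res_name, res_seq, chain, xyz,
            het=False, frag=None):
        i = len(self.atoms)
        self.atoms.append(Atom(serial=i + 1, name=name, element=element,
                               res_name=res_name, res_seq=res_seq,
                               chain_id=chain, coords=np.asarray(xyz, float),
                               het=het))
        self.coords.append(np.asarray(xyz, dtype=float))
        if frag:
            self.fragments.setdefault(frag, []).append(i)
        return i

    def frame(self) -> Frame:
        return Frame(self.atoms, np.array(self.coords))


def _hexagon(center, radius, angles_deg, z):
    cx, cy = center
    return [np.array([cx + radius * math.cos(math.radians(a)),
                      cy + radius * math.sin(math.radians(a)), z])
            for a in angles_deg]


def _build_toy(b: _Builder) -> None:
    """Emit the full toy complex into the builder (base = all-bound geometry)."""
    # ---- station 0 (x=0): Arg364 guanidinium donating to ligand ester O6
    nh1 = np.array([0.0, 4.13, 0.0])
    cz = nh1 + 1.33 * np.array([0, 1, 0])
    ne = cz + 1.33 * _rot2([0, -1, 0], 120)
    nh2 = cz + 1.33 * _rot2([0, -1, 0], -120)
    hh11 = nh1 + 1.01 * np.array([0.866, -0.5, 0.0])
    hh12 = nh1 + 1.01 * np.array([-0.866, -0.5, 0.0])
    he = ne + 1.01 * np.array([0.0, 1.0, 0.0])
    cd = ne + 1.46 * np.array([0.866, -0.5, 0.0])
    A = "A"
    b.add("NE", "N", "ARG", 364, A, ne)
    b.add("HE", "H", "ARG", 364, A, he)
    b.add("CZ", "C", "ARG", 364, A, cz)
    b.add("NH1", "N", "ARG", 364, A, nh1)
    b.add("HH11", "H", "ARG", 364, A, hh11)
    b.add("HH12", "H", "ARG", 364, A, hh12)
    b.add("NH2", "N", "ARG", 364, A, nh2)
    b.add("HH21", "H", "ARG", 364, A, nh2 + 1.01 * np.array([0, 1, 0.0]))
    b.add("HH22", "H", "ARG", 364, A, nh2 + 1.01 * np.array([-0.866, -0.5, 0.0]))
    b.add("CD", "C", "ARG", 364, A, cd)
    b.add("HD1", "H", "ARG", 364, A, cd + 1.09 * np.array([0, 0, 1.0]))
    b.add("HD2", "H", "ARG", 364, A, cd + 1.09 * np.array([0, 0, -1.0]))

    # ligand ester fragment: O6 accepts from NH1 along the N-H direction
    o6 = nh1 + 2.9 * np.array([0.866, -0.5, 0.0])
    c6a = o6 + 1.23 * np.array([0.866, -0.5, 0.0])
    # ester: O=C-O and O=C-C both at 120 deg from the C->O6 direction
    o7 = c6a + 1.34 * _rot2([-0.866, 0.5, 0], 120)
    c5a = c6a + 1.50 * _rot2([-0.866, 0.5, 0], -120)
    c7a = o7 + 1.43 * np.array([0.866, -0.5, 0.0])
    L = "L"
    b.add("C5A", "C", LIGAND_RESNAME, 900, L, c5a, het=True, frag="F1")
    b.add("H5A1", "H", LIGAND_RESNAME, 900, L, c5a + 1.09 * np.array([0, 0, 1.0]),
          het=True, frag="F1")
    b.add("H5A2", "H", LIGAND_RESNAME, 900, L, c5a + 1.09 * np.array([0, 0, -1.0]),
          het=True, frag="F1")
    b.add("C6A", "C", LIGAND_RESNAME, 900, L, c6a, het=True, frag="F1")
    b.add("O6", "O", LIGAND_RESNAME, 900, L, o6, het=True, frag="F1")
    b.add("O7", "O", LIGAND_RESNAME, 900, L, o7, het=True, frag="F1")
    b.add("C7A", "C", LIGAND_RESNAME, 900, L, c7a, het=True, frag="F1")
    b.add("H7A1", "H", LIGAND_RESNAME, 900, L, c7a + 1.09 * np.array([0, 0, 1.0]),
          het=True, frag="F1")
    b.add("H7A2", "H", LIGAND_RESNAME, 900, L, c7a + 1.09 * np.array([0, 0, -1.0]),
          het=True, frag="F1")

    # ---- station 1 (x=16): ligand hydroxyl O1 donating to Tyr426 OH
    oh = np.array([16.0, 0.0, 0.0])
    czt = np.array([16.0, -1.37, 0.0])
    rc = np.array([16.0, -2.76])
    ring = _hexagon(rc, 1.39, [90, 30, 150, -30, 210, 270], 0.0)
    czr, ce1, ce2, cd1, cd2, cg = ring
    ringH = _hexagon(rc, 1.39 + 1.08, [30, 150, -30, 210], 0.0)
    cb = cg + np.array([0, -1.51, 0.0])
    b.add("CB", "C", "TYR", 426, A, cb)
    b.add("HB1", "H", "TYR", 426, A, cb + 1.09 * np.array([0, 0, 1.0]))
    b.add("HB2", "H", "TYR", 426, A, cb + 1.09 * np.array([0, 0, -1.0]))
    b.add("CG", "C", "TYR", 426, A, cg)
    b.add("CD1", "C", "TYR", 426, A, cd1)
    b.add("HD1", "H", "TYR", 426, A, ringH[2])
    b.add("CD2", "C", "TYR", 426, A, cd2)
    b.add("HD2", "H", "TYR", 426, A, ringH[3])
    b.add("CE1", "C", "TYR", 426, A, ce1)
    b.add("HE1", "H", "TYR", 426, A, ringH[0])
    b.add("CE2", "C", "TYR", 426, A, ce2)
    b.add("HE2", "H", "TYR", 426, A, ringH[1])
    b.add("CZ", "C", "TYR", 426, A, czt)
    b.add("OH", "O", "TYR", 426, A, oh)
    b.add("HH", "H", "TYR", 426, A, oh + 0.97 * np.array([1.0, 0, 0]))

    o1 = oh + np.array([0, 2.85, 0.0])
    c1 = o1 + 1.43 * np.array([0, 1, 0.0])
    b.add("C1", "C", LIGAND_RESNAME, 900, L, c1, het=True, frag="F2")
    b.add("H11", "H", LIGAND_RESNAME, 900, L, c1 + 1.09 * np.array([0, 0, 1.0]),
          het=True, frag="F2")
    b.add("H12", "H", LIGAND_RESNAME, 900, L, c1 + 1.09 * np.array([0, 0, -1.0]),
          het=True, frag="F2")
    b.add("O1", "O", LIGAND_RESNAME, 900, L, o1, het=True, frag="F2")
    b.add("HO1", "H", LIGAND_RESNAME, 900, L, o1 + 1.01 * np.array([0, -1, 0.0]),
          het=True, frag="F2")

    # ---- station 2 (x=32): ligand hydroxyl O2 - water - Asp533 OD1 bridge
    ow = np.array([32.0, 0.0, 0.0])
    leg = _u([0.940, -0.342, 0.0])            # 110 deg from the O2 leg (+y)
    od1 = ow + 3.0 * leg
    cgd = od1 + 1.25 * leg
    od2 = cgd + 1.25 * _rot2(-leg, 124)
    cbd = cgd + 1.52 * _rot2(-leg, -118)
    b.add("CB", "C", "ASP", 533, A, cbd)
    b.add("HB1", "H", "ASP", 533, A, cbd + 1.09 * np.array([0, 0, 1.0]))
    b.add("HB2", "H", "ASP", 533, A, cbd + 1.09 * np.array([0, 0, -1.0]))
    b.add("CG", "C", "ASP", 533, A, cgd)
    b.add("OD1", "O", "ASP", 533, A, od1)
    b.add("OD2", "O", "ASP", 533, A, od2)

    o2 = ow + np.array([0, 2.85, 0.0])
    c2 = o2 + 1.43 * np.array([0, 1, 0.0])
    b.add("C2", "C", LIGAND_RESNAME, 900, L, c2, het=True, frag="F3")
    b.add("H21", "H", LIGAND_RESNAME, 900, L, c2 + 1.09 * np.array([0, 0, 1.0]),
          het=True, frag="F3")
    b.add("H22", "H", LIGAND_RESNAME, 900, L, c2 + 1.09 * np.array([0, 0, -1.0]),
          het=True, frag="F3")
    b.add("O2", "O", LIGAND_RESNAME, 900, L, o2, het=True, frag="F3")
    b.add("HO2", "H", LIGAND_RESNAME, 900, L, o2 + 1.01 * np.array([0, -1, 0.0]),
          het=True, frag="F3")

    # the bridging water (mobile fragment W401)
    b.add("O", "O", "HOH", 401, "W", ow, het=True, frag="W401")
    b.add("H1", "H", "HOH", 401, "W", ow + 0.96 * leg, het=True, frag="W401")
    b.add("H2", "H", "HOH", 401, "W", ow + 0.96 * _u([-0.940, 0.342, 0.0]),
          het=True, frag="W401")

    # ---- station 3 (x=48): ligand carboxylate - Lys425 ammonium salt bridge
    c9 = np.array([48.0, 0.0, 0.0])
    o91 = c9 + 1.25 * np.array([0.866, 0.5, 0.0])
    o92 = c9 + 1.25 * np.array([-0.866, 0.5, 0.0])
    cx = c9 + 1.52 * np.array([0, -1, 0.0])
    centroid = (c9 + o91 + o92) / 3.0
    nz = centroid + np.array([0, 4.0, 0.0])
    ce = nz + 1.47 * np.array([0, 1, 0.0])
    cdl = ce + 1.52 * np.array([0, 1, 0.0])
    b.add("CD", "C", "LYS", 425, A, cdl)
    b.add("HD1", "H", "LYS", 425, A, cdl + 1.09 * np.array([0, 0, 1.0]))
    b.add("HD2", "H", "LYS", 425, A, cdl + 1.09 * np.array([0, 0, -1.0]))
    b.add("CE", "C", "LYS", 425, A, ce)
    b.add("HE1", "H", "LYS", 425, A, ce + 1.09 * np.array([0, 0, 1.0]))
    b.add("HE2", "H", "LYS", 425, A, ce + 1.09 * np.array([0, 0, -1.0]))
    b.add("NZ", "N", "LYS", 425, A, nz)
    b.add("HZ1", "H", "LYS", 425, A, nz + 1.01 * np.array([0.943, -0.333, 0.0]))
    b.add("HZ2", "H", "LYS", 425, A, nz + 1.01 * np.array([-0.4715, -0.333, 0.8165]))
    b.add("HZ3", "H", "LYS", 425, A, nz + 1.01 * np.array([-0.4715, -0.333, -0.8165]))

    b.add("CX", "C", LIGAND_RESNAME, 900, L, cx, het=True, frag="F4")
    b.add("HX1", "H", LIGAND_RESNAME, 900, L, cx + 1.09 * np.array([0, 0, 1.0]),
          het=True, frag="F4")
    b.add("HX2", "H", LIGAND_RESNAME, 900, L, cx + 1.09 * np.array([0, 0, -1.0]),
          het=True, frag="F4")
    b.add("HX3", "H", LIGAND_RESNAME, 900, L, cx + 1.09 * np.array([0, -1, 0.0]),
          het=True, frag="F4")
    b.add("C9", "C", LIGAND_RESNAME, 900, L, c9, het=True, frag="F4")
    b.add("O91", "O", LIGAND_RESNAME, 900, L, o91, het=True, frag="F4")
    b.add("O92", "O", LIGAND_RESNAME, 900, L, o92, het=True, frag="F4")

    # ---- station 4 (x=64): ligand phenyl ring stacked on the DA113 six-ring
    c6c = np.array([64.0, 0.0])                # purine six-ring center, z=3.4
    z6 = 3.4
    hexpos = _hexagon(c6c, 1.39, [90, 150, 210, 270, 330, 30], z6)
    n1, c2b, n3, c4, c5, c6b = hexpos
    m = (c4 + c5) / 2.0
    uo = _u(m - np.array([64.0, 0.0, z6]))
    c5ring_center = m + 0.956 * uo
    v = c4 - c5ring_center
    n9 = c5ring_center + _rot2(v, 72)
    c8 = c5ring_center + _rot2(v, 144)
    n7 = c5ring_center + _rot2(v, 216)
    n6 = np.array([64.0, 0.0, z6]) + 2.73 * _u(c6b - np.array([64.0, 0.0, z6]))
    c1p = c5ring_center + _u(n9 - c5ring_center) * (1.182 + 1.47)
    B = "B"
    # phosphate (formal -1 charge center of the nucleotide)
    p = np.array([64.0, 6.0, z6])
    b.add("P", "P", "DA", 113, B, p)
    b.add("OP1", "O", "DA", 113, B, p + 1.48 * np.array([0.831, 0.554, 0.0]))
    b.add("OP2", "O", "DA", 113, B, p + 1.48 * np.array([-0.831, 0.554, 0.0]))
    b.add("O5'", "O", "DA", 113, B, p + 1.60 * np.array([0, -1, 0.0]))
    b.add("N1", "N", "DA", 113, B, n1)
    b.add("C2", "C", "DA", 113, B, c2b)
    b.add("H2", "H", "DA", 113, B,
          np.array([64.0, 0.0, z6]) + 2.47 * _u(c2b - np.array([64.0, 0.0, z6])))
    b.add("N3", "N", "DA", 113, B, n3)
    b.add("C4", "C", "DA", 113, B, c4)
    b.add("C5", "C", "DA", 113, B, c5)
    b.add("C6", "C", "DA", 113, B, c6b)
    b.add("N6", "N", "DA", 113, B, n6)
    b.add("H61", "H", "DA", 113, B, n6 + 1.01 * _u(_rot2(n6 - c6b, 120)))
    b.add("H62", "H", "DA", 113, B, n6 + 1.01 * _u(_rot2(n6 - c6b, -120)))
    b.add("N7", "N", "DA", 113, B, n7)
    b.add("C8", "C", "DA", 113, B, c8)
    b.add("H8", "H", "DA", 113, B, c8 + 1.08 * _u(c8 - c5ring_center))
    b.add("N9", "N", "DA", 113, B, n9)
    b.add("C1'", "C", "DA", 113, B, c1p)

    bc = np.array([64.0, 0.0]) - 0.8 * uo[:2]  # phenyl center, offset toward
    phen = _hexagon(bc, 1.39, [0, 60, 120, 180, 240, 300], 0.0)
    phenH = _hexagon(bc, 1.39 + 1.08, [0, 60, 120, 180, 240, 300], 0.0)
    for k in range(6):
        b.add(f"C{k + 1}R", "C", LIGAND_RESNAME, 900, L, phen[k], het=True, frag="F5")
        b.add(f"H{k + 1}R", "H", LIGAND_RESNAME, 900, L, phenH[k], het=True, frag="F5")

    # ---- station 5 (x=80): ligand aliphatic tail against the DT9 methyl
    tc = np.array([80.0, 0.0])
    thex = _hexagon(tc, 1.39, [90, 150, 210, 270, 330, 30], 0.0)
    tn1, tc2, tn3, tc4, tc5, tc6 = thex
    d330 = np.array([math.cos(math.radians(330)), math.sin(math.radians(330)), 0.0])
    c7 = np.array([80.0, 0.0, 0.0]) + (1.39 + 1.50) * d330
    b.add("C1'", "C", "DT", 9, B, np.array([80.0, 2.86, 0.0]))
    b.add("N1", "N", "DT", 9, B, tn1)
    b.add("C2", "C", "DT", 9, B, tc2)
    b.add("O2", "O", "DT", 9, B,
          np.array([80.0, 0.0, 0.0]) + 2.61 * _u(tc2 - np.array([80.0, 0.0, 0.0])))
    b.add("N3", "N", "DT", 9, B, tn3)
    b.add("H3", "H", "DT", 9, B,
          tn3 + 1.01 * _u(tn3 - np.array([80.0, 0.0, 0.0])))
    b.add("C4", "C", "DT", 9, B, tc4)
    b.add("O4", "O", "DT", 9, B, np.array([80.0, -2.61, 0.0]))
    b.add("C5", "C", "DT", 9, B, tc5)
    b.add("C7", "C", "DT", 9, B, c7)
    b.add("H71", "H", "DT", 9, B, c7 + 1.09 * np.array([0, 0, 1.0]))
    b.add("H72", "H", "DT", 9, B, c7 + 1.09 * np.array([0, 0, -1.0]))
    b.add("H73", "H", "DT", 9, B, c7 + 1.09 * _u(np.array([-0.5, -0.866, 0.0])))
    b.add("C6", "C", "DT", 9, B, tc6)
    b.add("H6", "H", "DT", 9, B,
          np.array([80.0, 0.0, 0.0]) + 2.47 * _u(tc6 - np.array([80.0, 0.0, 0.0])))

    c13 = c7 + 3.6 * d330
    c14 = c13 + 1.53 * d330
    b.add("C13", "C", LIGAND_RESNAME, 900, L, c13, het=True, frag="F6")
    b.add("HT1", "H", LIGAND_RESNAME, 900, L, c13 + 1.09 * np.array([0, 0, 1.0]),
          het=True, frag="F6")
    b.add("HT2", "H", LIGAND_RESNAME, 900, L, c13 + 1.09 * np.array([0, 0, -1.0]),
          het=True, frag="F6")
    b.add("C14", "C", LIGAND_RESNAME, 900, L, c14, het=True, frag="F6")
    b.add("HT3", "H", LIGAND_RESNAME, 900, L, c14 + 1.09 * np.array([0, 0, 1.0]),
          het=True, frag="F6")
    b.add("HT4", "H", LIGAND_RESNAME, 900, L, c14 + 1.09 * np.array([0, 0, -1.0]),
          het=True, frag="F6")
    b.add("HT5", "H", LIGAND_RESNAME, 900, L, c14 + 1.09 * d330, het=True, frag="F6")

    # ---- spectator waters, well away from every station (>10 A)
    for k in range(7):
        wx = 2.0 + 10.0 * k
        o = np.array([wx, 20.0, 0.0])
        b.add("O", "O", "HOH", 402 + k, "W", o, het=True)
        b.add("H1", "H", "HOH", 402 + k, "W", o + 0.96 * np.array([0.79, 0.61, 0.0]),
              het=True)
        b.add("H2", "H", "HOH", 402 + k, "W", o + 0.96 * np.array([-0.79, 0.61, 0.0]),
              het=True)
    b.add("NA", "NA", "NA", 501, "I", np.array([72.0, 20.0, 0.0]), het=True)


@dataclass(frozen=True)
class _Planted:
    name: str
    itype: str
    ledger_key: str
    mobile_frag: str
    break_shift: tuple
    pair_rows: tuple          # ((ligand atom, residue label), ...)


_D330 = (math.cos(math.radians(330)), math.sin(math.radians(330)), 0.0)

PLANTED_KEYS = {
    "hbond:O6-Arg364": _Planted(
        "hbond:O6-Arg364", "hbond", "hbond|O6|Arg364|NH1", "F1",
        (0.0, -4.0, 0.0), (("O6", "Arg364"),)),
    "hbond:O1-Tyr426": _Planted(
        "hbond:O1-Tyr426", "hbond", "hbond|O1|Tyr426|OH", "F2",
        (0.0, 3.0, 0.0), (("O1", "Tyr426"),)),
    "waterbridge:O2-Asp533": _Planted(
        "waterbridge:O2-Asp533", "waterbridge", "waterbridge|O2|Asp533|OD1",
        "W401", (0.0, 0.0, 5.0), (("O2", "Asp533"),)),
    "pistacking:ring-DA113": _Planted(
        "pistacking:ring-DA113", "pistacking",
        "pistacking|C1R+C2R+C3R+C4R+C5R+C6R|DA113|*", "F5",
        (0.0, 0.0, -4.5),
        tuple((f"C{k}R", "DA113") for k in range(1, 7))),
    "hydrophobic:C13-DT9": _Planted(
        "hydrophobic:C13-DT9", "hydrophobic", "hydrophobic|C13|DT9|*", "F6",
        (3.6 * _D330[0], 3.6 * _D330[1], 0.0), (("C13", "DT9"),)),
    "saltbridge:COO-Lys425": _Planted(
        "saltbridge:COO-Lys425", "saltbridge", "saltbridge|C9+O91+O92|Lys425|*",
        "F4", (0.0, -5.0, 0.0),
        (("C9", "Lys425"), ("O91", "Lys425"), ("O92", "Lys425"))),
}


@dataclass
class PlantSchedule:
    """Target occupancy fraction per planted interaction, frame count, seed."""

    fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, f in self.fractions.items():
            if name not in PLANTED_KEYS:
                raise ValueError(
                    f"unknown planted interaction {name!r}; known: "
                    + ", ".join(sorted(PLANTED_KEYS)))
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for {name} out of [0,1]: {f}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class GroundTruth:
    """The realized per-interaction frame sets of a generated trajectory."""

    n_frames: int
    frames: dict                # planted name -> sorted list of frame indices

    def ledger_occupancy(self) -> dict:
        """Expected ledger occupancy (canonical key -> frame list)."""
        return {PLANTED_KEYS[name].ledger_key: list(fr)
                for name, fr in self.frames.items() if fr}

    def expected_per_type(self) -> dict:
        """Exact per-type persistence percent (union over keys of a type)."""
        by_type: dict = {}
        for name, fr in self.frames.items():
            by_type.setdefault(PLANTED_KEYS[name].itype, set()).update(fr)
        return {t: 100.0 * len(s) / self.n_frames for t, s in by_type.items()}

    def expected_per_pair(self, min_percent: float = 10.0) -> dict:
        """(ligand atom, residue) -> exact percent, thresholded like the table."""
        pair: dict = {}
        for name, fr in self.frames.items():
            for row in PLANTED_KEYS[name].pair_rows:
                pair.setdefault(row, set()).update(fr)
        return {k: 100.0 * len(s) / self.n_frames
                for k, s in sorted(pair.items())
                if 100.0 * len(s) / self.n_frames >= min_percent}


def make_toy_complex(seed: int = 0, jitter_sigma: float = 0.0) -> Frame:
    """The toy complex in all-bound geometry (<= 150 atoms, explicit H).

    ``jitter_sigma`` adds seeded isotropic Gaussian noise (A) per atom; the
    default 0 yields a byte-identical frame for every call.
    """
    b = _Builder()
    _build_toy(b)
    frame = b.frame()
    if jitter_sigma > 0:
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 17])
        frame = frame.with_coords(
            frame.coords + rng.normal(0.0, jitter_sigma, frame.coords.shape))
    frame._fragments = b.fragments  # used by the trajectory generator
    return frame


def _fragments_of(frame: Frame) -> dict:
    frags = getattr(frame, "_fragments", None)
    if frags is None:
        raise ValueError("frame was not produced by make_toy_complex")
    return frags


def make_trajectory(schedule: PlantSchedule, stride_ps: float = 10.0):
    """(Trajectory, GroundTruth) realizing the schedule.

    Each planted interaction is present (bound geometry) in exactly
    ``round(fraction * n_frames)`` frames, chosen without replacement by a
    seeded generator; in every other frame its mobile fragment is displaced
    so the tested criterion fails with margin.
    """
    base = make_toy_complex()
    frags = _fragments_of(base)
    n = schedule.n_frames
    active: dict = {}
    for k, name in enumerate(sorted(schedule.fractions)):
        frac = schedule.fractions[name]
        count = int(round(frac * n))
        rng = np.random.default_rng([int(schedule.seed) & 0x7FFFFFFF, 101 + k])
        chosen = sorted(rng.choice(n, size=count, replace=False)) if count else []
        active[name] = [int(c) for c in chosen]
    active_sets = {name: set(v) for name, v in active.items()}
    frames = []
    for t in range(n):
        coords = base.coords.copy()
        for name in active_sets:
            if t not in active_sets[name]:
                spec = PLANTED_KEYS[name]
                idx = frags[spec.mobile_frag]
                coords[idx] += np.asarray(spec.break_shift)
        frames.append(base.with_coords(coords, index=t, time_ps=t * stride_ps))
    gt = GroundTruth(n_frames=n, frames={name: sorted(v)
                                         for name, v in active.items()})
    return Trajectory(frames, stride_ps=stride_ps), gt


def make_random_frame(seed: int) -> Frame:
    """A randomized toy frame for oracle-equivalence stress tests.

    Fragments get independent rigid shifts of up to +-2 A per axis and every
    atom 0.12 A Gaussian jitter, which pushes many contacts across their
    thresholds in both directions.
    """
    base = make_toy_complex()
    frags = _fragments_of(base)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 23])
    coords = base.coords.copy()
    for name in sorted(frags):
        coords[frags[name]] += rng.uniform(-2.0, 2.0, 3)
    coords += rng.normal(0.0, 0.12, coords.shape)
    out = base.with_coords(coords)
    out._fragments = frags
    return out


def make_jitter_trajectory(base: Frame, sigma: float, rigid_transform_series,
                           n_frames: int, seed: int,
                           stride_ps: float = 10.0) -> Trajectory:
    """Rigid motion of a base frame plus i.i.d. Gaussian atomic displacement.

    ``rigid_transform_series`` is None (identity), or a callable
    ``t -> (R, shift)``, or a sequence of ``(R, shift)`` pairs.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 31])
    frames = []
    for t in range(n_frames):
        if rigid_transform_series is None:
            R, shift = np.eye(3), np.zeros(3)
        elif callable(rigid_transform_series):
            R, shift = rigid_transform_series(t)
        else:
            R, shift = rigid_transform_series[t]
        coords = base.coords @ np.asarray(R).T + np.asarray(shift)
        if sigma > 0:
            coords = coords + rng.normal(0.0, sigma, coords.shape)
        frames.append(base.with_coords(coords, index=t, time_ps=t * stride_ps))
    return Trajectory(frames, stride_ps=stride_ps)


def make_crystal_site_synthetic() -> Frame:
    """Synthetic stand-in for a camptothecin ternary-complex binding site.

    A minimal CPT-like lactone/hydroxyl fragment placed between an arginine
    guanidinium and an aspartate carboxylate, with the two published contact
    distances built in: ligand carbonyl to Arg364 NH1 at 2.90 A and ligand
    hydroxyl to Asp533 OD1 at 3.40 A.  No hydrogens are present, so profiling
    must use the no-hydrogen fallback rule.  This is constructed data, not
    the crystal structure.
    """
    b = _Builder()
    A, L = "A", "L"
    o21 = np.array([0.0, 0.0, 0.0])
    c20 = np.array([1.43, 0.0, 0.0])
    c19 = np.array([2.95, 0.0, 0.0])
    o19 = c19 + np.array([0.0, 1.23, 0.0])
    o20 = c19 + 1.34 * np.array([0.866, -0.5, 0.0])
    c18 = o20 + 1.43 * np.array([0.866, -0.5, 0.0])
    b.add("O21", "O", "CPT", 600, L, o21, het=True)
    b.add("C20", "C", "CPT", 600, L, c20, het=True)
    b.add("C19", "C", "CPT", 600, L, c19, het=True)
    b.add("O19", "O", "CPT", 600, L, o19, het=True)
    b.add("O20", "O", "CPT", 600, L, o20, het=True)
    b.add("C18", "C", "CPT", 600, L, c18, het=True)

    nh1 = o19 + np.array([0.0, 2.9, 0.0])
    cz = nh1 + 1.33 * np.array([0, 1, 0.0])
    nh2 = cz + 1.33 * np.array([-0.866, 0.5, 0.0])
    ne = cz + 1.33 * np.array([0.866, 0.5, 0.0])
    cd = ne + 1.46 * np.array([0.866, -0.5, 0.0])
    b.add("CD", "C", "ARG", 364, A, cd)
    b.add("NE", "N", "ARG", 364, A, ne)
    b.add("CZ", "C", "ARG", 364, A, cz)
    b.add("NH1", "N", "ARG", 364, A, nh1)
    b.add("NH2", "N", "ARG", 364, A, nh2)

    leg = _u([-0.940, -0.342, 0.0])
    od1 = o21 + 3.4 * leg
    cg = od1 + 1.25 * leg
    od2 = cg + 1.25 * _rot2(-leg, 124)
    cb = cg + 1.52 * _rot2(-leg, -118)
    b.add("CB", "C", "ASP", 533, A, cb)
    b.add("CG", "C", "ASP", 533, A, cg)
    b.add("OD1", "O", "ASP", 533, A, od1)
    b.add("OD2", "O", "ASP", 533, A, od2)
    return b.frame()


def validate_independence(config=None) -> None:
    """Check that each planted interaction toggles alone.

    For every planted key, a frame with only that key broken must lose
    exactly that ledger key relative to the all-bound frame, and a frame
    with only that key bound must show exactly that key.  Raises
    ``AssertionError`` on any cross-talk.
    """
    from contactprof.interactions import detect_frame
    from contactprof.ledger import record_key
    from contactprof.structure import classify_entities

    base = make_toy_complex()
    frags = _fragments_of(base)
    entities = classify_entities(base, {LIGAND_RESNAME})

    def keys_of(coords):
        fr = base.with_coords(coords)
        return {record_key(r) for r in detect_frame(fr, entities, config)}

    all_keys = {PLANTED_KEYS[n].ledger_key for n in PLANTED_KEYS}
    bound = keys_of(base.coords)
    if bound != all_keys:
        raise AssertionError(
            f"all-bound frame: expected {sorted(all_keys)}, got {sorted(bound)}")
    for name, spec in PLANTED_KEYS.items():
        coords = base.coords.copy()
        coords[frags[spec.mobile_frag]] += np.asarray(spec.break_shift)
        got = keys_of(coords)
        if got != all_keys - {spec.ledger_key}:
            raise AssertionError(f"breaking {name} changed other keys: "
                                 f"{sorted(got.symmetric_difference(all_keys - {spec.ledger_key}))}")
        coords = base.coords.copy()
        for other, ospec in PLANTED_KEYS.items():
            if other != name:
                coords[frags[ospec.mobile_frag]] += np.asarray(ospec.break_shift)
        got = keys_of(coords)
        if got != {spec.ledger_key}:
            raise AssertionError(f"{name} alone: expected only its key, got {sorted(got)}")
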