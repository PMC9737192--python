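"""Geometric detection of ligand-receptor noncovalent interactions in one frame.

Five detectors (hydrogen bonds, hydrophobic contacts, pi-stacking, salt
bridges, water bridges) match the functional groups produced by
:mod:`contactprof.perception` under distance/angle criteria, followed by a
redundancy filter that removes hydrogen bonds subsumed by a salt bridge and
hydrophobic contacts subsumed by a pi-stack.  Only pairs with one side on the
ligand and the other on the receptor (protein + DNA) are considered; waters
appear solely as bridge mediators and ions are ignored as partners.

Candidate pairs are generated with k-d trees; :mod:`contactprof.bruteforce`
holds an independent all-pairs implementation of the same criteria used as a
correctness oracle.

Distances take no periodic-boundary imaging into account: frames are assumed
whole and imaged upstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from contactprof.bonds import BondGraph, infer_bonds
from contactprof.config import DetectionConfig
from contactprof.perception import PerceptionSet, perceive
from contactprof.structure import EntityMap, Frame, ROLE_LIGAND

ITYPES = ("hbond", "hydrophobic", "pistacking", "saltbridge", "waterbridge")


@dataclass
class InteractionRecord:
    """One detected interaction between the ligand and a receptor residue."""

    itype: str
    frame_index: int
    ligand_atoms: tuple          # atom indices
    ligand_atom_names: tuple
    receptor_residue: tuple      # (chain_id, res_name, res_seq)
    receptor_atoms: tuple        # atom indices
    receptor_atom_names: tuple
    geometry: dict = field(default_factory=dict)  # distances (A) / angles (deg)
    water_residue: Optional[tuple] = None         # (chain_id, res_seq)
    subtype: Optional[str] = None                 # e.g. parallel / tshaped

    def sort_key(self) -> tuple:
        ch, rn, rs = self.receptor_residue
        return (self.itype, ch, rs, rn, self.ligand_atom_names,
                self.receptor_atom_names, self.subtype or "")

    def signature(self, ndigits: int = 6) -> tuple:
        """Canonical comparison tuple (used by the oracle-equivalence check)."""
        geo = tuple(sorted((k, None if v is None else round(v, ndigits))
                           for k, v in self.geometry.items()))
        return (self.itype, self.ligand_atom_names, self.receptor_residue,
                self.receptor_atom_names, self.water_residue, self.subtype, geo)

    def to_dict(self) -> dict:
        return {
            "itype": self.itype,
            "frame_index": self.frame_index,
            "ligand_atoms": list(self.ligand_atom_names),
            "receptor_residue": list(self.receptor_residue),
            "receptor_atoms": list(self.receptor_atom_names),
            "water_residue": list(self.water_residue) if self.water_residue else None,
            "subtype": self.subtype,
            "geometry": {k: (None if v is None else round(float(v), 4))
                         for k, v in self.geometry.items()},
        }


def _residue_tuple(frame: Frame, i: int) -> tuple:
    a = frame.atoms[i]
    return (a.chain_id, a.res_name, a.res_seq)


def angle_deg(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> float:
    """Angle at ``vertex`` between directions to ``a`` and ``c``, degrees."""
    v1 = a - vertex
    v2 = c - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _mkrecord(frame: Frame, itype: str, lig: tuple, rec: tuple,
              geometry: dict, water: Optional[tuple] = None,
              subtype: Optional[str] = None) -> InteractionRecord:
    return InteractionRecord(
        itype=itype, frame_index=frame.index,
        ligand_atoms=tuple(lig),
        ligand_atom_names=tuple(frame.atoms[i].name for i in lig),
        receptor_residue=_residue_tuple(frame, rec[0]),
        receptor_atoms=tuple(rec),
        receptor_atom_names=tuple(frame.atoms[i].name for i in rec),
        geometry=geometry, water_residue=water, subtype=subtype)


# ---------------------------------------------------------------------------
# hydrogen bonds

def _hbond_pair(frame: Frame, perception: PerceptionSet, d: int, a: int,
                config: DetectionConfig):
    """Geometry of a donor->acceptor candidate, or None if it fails the gates."""
    dist = float(np.linalg.norm(frame.coords[d] - frame.coords[a]))
    hs = perception.donors.get(d, ())
    if hs:
        if dist > config.hbond_dist_max:
            return None
        best = max(angle_deg(frame.coords[d], frame.coords[h], frame.coords[a])
                   for h in hs)
        if best < config.hbond_angle_min:
            return None
        return {"distance": dist, "angle": best}
    # no explicit hydrogen on the donor: waive the angle gate, tighten distance
    if dist > config.hbond_noh_dist_max:
        return None
    return {"distance": dist, "angle": None}


def detect_hbonds(frame: Frame, perception: PerceptionSet, entities: EntityMap,
                  config: Optional[DetectionConfig] = None) -> list:
    """Donor-acceptor pairs, one side ligand and one side receptor."""
    config = config or DetectionConfig()
    records: list = []
    lig = set(entities.ligand)
    rec = set(entities.receptor)

    donors = dict(perception.donors)
    if not perception.has_polar_hydrogens:
        # H-stripped structure: every protonatable polar atom is a candidate
        for i in perception.potential_donors:
            donors.setdefault(i, ())
    acceptors = perception.acceptors

    d_idx = sorted(donors)
    a_idx = sorted(acceptors)
    if not d_idx or not a_idx:
        return records
    tree = cKDTree(frame.coords[a_idx])
    seen_pairs: set = set()
    for d in d_idx:
        near = tree.query_ball_point(frame.coords[d], r=config.hbond_dist_max)
        for k in near:
            a = a_idx[k]
            if a == d:
                continue
            if not ((d in lig and a in rec) or (d in rec and a in lig)):
                continue
            pair = (min(d, a), max(d, a))
            if not donors.get(d) and pair in seen_pairs:
                continue  # in fallback mode direction is unknowable: one record
            geo = _hbond_pair(frame, perception, d, a, config)
            if geo is None:
                continue
            if not donors.get(d):
                seen_pairs.add(pair)
            l, r = (d, a) if d in lig else (a, d)
            rec_out = _mkrecord(frame, "hbond", (l,), (r,), geo)
            rec_out.subtype = "ligand-donor" if d in lig else "receptor-donor"
            if geo["angle"] is None:
                rec_out.subtype = "no-h-fallback"
            records.append(rec_out)
    return records


# ---------------------------------------------------------------------------
# hydrophobic contacts

def detect_hydrophobic(frame: Frame, perception: PerceptionSet, entities: EntityMap,
                       config: Optional[DetectionConfig] = None) -> list:
    """One record per (ligand hydrophobic atom, receptor residue), at the
    shortest in-range pair distance."""
    config = config or DetectionConfig()
    lig = sorted(i for i in perception.hydrophobic if entities.roles[i] == ROLE_LIGAND)
    rec = sorted(i for i in perception.hydrophobic if entities.is_receptor(i))
    if not lig or not rec:
        return []
    tree = cKDTree(frame.coords[rec])
    best: dict = {}
    for l in lig:
        for k in tree.query_ball_point(frame.coords[l], r=config.hydrophobic_dist_max):
            r = rec[k]
            d = float(np.linalg.norm(frame.coords[l] - frame.coords[r]))
            if d > config.hydrophobic_dist_max:
                continue
            key = (l, _residue_tuple(frame, r))
            cand = (d, frame.atoms[r].name, r)
            if key not in best or cand < best[key]:
                best[key] = cand
    records = []
    for (l, _res), (d, _nm, r) in sorted(best.items(),
                                         key=lambda kv: (kv[0][0], kv[0][1])):
        records.append(_mkrecord(frame, "hydrophobic", (l,), (r,), {"distance": d}))
    return records


# ---------------------------------------------------------------------------
# pi-stacking

def _stack_geometry(r1, r2, config: DetectionConfig):
    """(distance, angle, offset, subtype) for a ring pair, or None."""
    dvec = r2.center - r1.center
    dist = float(np.linalg.norm(dvec))
    if dist > config.pistack_dist_max:
        return None
    cosang = abs(float(np.dot(r1.normal, r2.normal)))
    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if ang <= config.pistack_parallel_angle_max:
        subtype = "parallel"
    elif config.pistack_tshape_angle_min <= ang <= 90.0:
        subtype = "tshaped"
    else:
        return None
    # in-plane offset of the projected centers, taken on each ring's plane
    offs = []
    for base, other in ((r1, r2), (r2, r1)):
        v = other.center - base.center
        in_plane = v - np.dot(v, base.normal) * base.normal
        offs.append(float(np.linalg.norm(in_plane)))
    offset = min(offs)
    if offset > config.pistack_offset_max:
        return None
    return dist, ang, offset, subtype


def detect_pistacking(frame: Frame, perception: PerceptionSet, entities: EntityMap,
                      config: Optional[DetectionConfig] = None) -> list:
    config = config or DetectionConfig()
    lig_rings = [r for r in perception.rings if r.role == ROLE_LIGAND]
    rec_rings = [r for r in perception.rings if r.role != ROLE_LIGAND]
    records = []
    for lr in lig_rings:
        for rr in rec_rings:
            geo = _stack_geometry(lr, rr, config)
            if geo is None:
                continue
            dist, ang, offset, subtype = geo
            records.append(_mkrecord(
                frame, "pistacking",
                tuple(sorted(lr.members)), tuple(sorted(rr.members)),
                {"distance": dist, "angle": ang, "offset": offset},
                subtype=subtype))
    return records


# ---------------------------------------------------------------------------
# salt bridges

def detect_saltbridges(frame: Frame, perception: PerceptionSet, entities: EntityMap,
                       config: Optional[DetectionConfig] = None) -> list:
    config = config or DetectionConfig()
    lig_c = [c for c in perception.charge_centers if c.role == ROLE_LIGAND]
    rec_c = [c for c in perception.charge_centers if c.role != ROLE_LIGAND]
    records = []
    for lc in lig_c:
        for rc in rec_c:
            if lc.sign * rc.sign >= 0:
                continue
            d = float(np.linalg.norm(lc.centroid - rc.centroid))
            if d > config.saltbridge_dist_max:
                continue
            records.append(_mkrecord(
                frame, "saltbridge",
                tuple(sorted(lc.members)), tuple(sorted(rc.members)),
                {"distance": d}, subtype=f"{lc.label}-{rc.label}"))
    return records


# ---------------------------------------------------------------------------
# water bridges

def _water_oxygens(frame: Frame, entities: EntityMap) -> list:
    return [i for i in entities.water if frame.atoms[i].element == "O"]


def _leg_valid(frame: Frame, perception: PerceptionSet, partner: int, w: int,
               w_hs: tuple, dist: float, config: DetectionConfig) -> bool:
    """A water-bridge leg: the partner-water contact must be H-bond-compatible."""
    if not (config.waterbridge_dist_min <= dist <= config.waterbridge_dist_max):
        return False
    hs = perception.donors.get(partner, ())
    if hs:  # partner donates to the water
        best = max(angle_deg(frame.coords[partner], frame.coords[h], frame.coords[w])
                   for h in hs)
        if best >= config.waterbridge_donor_angle_min:
            return True
    if partner in perception.acceptors and w_hs:  # water donates to the partner
        best = max(angle_deg(frame.coords[w], frame.coords[h], frame.coords[partner])
                   for h in w_hs)
        if best >= config.waterbridge_donor_angle_min:
            return True
    if not perception.has_polar_hydrogens and not w_hs:
        # H-less structure: same fallback as the hydrogen-bond detector
        return dist <= config.hbond_noh_dist_max and (
            partner in perception.acceptors or partner in perception.potential_donors)
    return False


def detect_waterbridges(frame: Frame, perception: PerceptionSet, entities: EntityMap,
                        bonds: Optional[BondGraph] = None,
                        config: Optional[DetectionConfig] = None) -> list:
    """Ligand-water-receptor double hydrogen bonds through one water oxygen."""
    config = config or DetectionConfig()
    waters = _water_oxygens(frame, entities)
    if not waters:
        return []
    elements = [a.element for a in frame.atoms]
    if bonds is None:
        bonds = infer_bonds(frame)
    lig_polar = sorted((set(perception.donors) | perception.acceptors
                        | perception.potential_donors)
                       & set(entities.ligand))
    rec_polar = sorted((set(perception.donors) | perception.acceptors
                        | perception.potential_donors)
                       & set(entities.receptor))
    if not lig_polar or not rec_polar:
        return []
    lt = cKDTree(frame.coords[lig_polar])
    rt = cKDTree(frame.coords[rec_polar])
    records = []
    for w in waters:
        w_hs = tuple(j for j in bonds.neighbors(w) if elements[j] == "H")
        near_l = [lig_polar[k] for k in
                  lt.query_ball_point(frame.coords[w], r=config.waterbridge_dist_max)]
        if not near_l:
            continue
        near_r = [rec_polar[k] for k in
                  rt.query_ball_point(frame.coords[w], r=config.waterbridge_dist_max)]
        for l in sorted(near_l):
            dl = float(np.linalg.norm(frame.coords[l] - frame.coords[w]))
            if not _leg_valid(frame, perception, l, w, w_hs, dl, config):
                continue
            for r in sorted(near_r):
                dr = float(np.linalg.norm(frame.coords[r] - frame.coords[w]))
                if not _leg_valid(frame, perception, r, w, w_hs, dr, config):
                    continue
                wang = angle_deg(frame.coords[l], frame.coords[w], frame.coords[r])
                if not (config.waterbridge_angle_min <= wang
                        <= config.waterbridge_angle_max):
                    continue
                wa = frame.atoms[w]
                records.append(_mkrecord(
                    frame, "waterbridge", (l,), (r,),
                    {"distance_ligand": dl, "distance_receptor": dr,
                     "water_angle": wang},
                    water=(wa.chain_id, wa.res_seq)))
    return records


# ---------------------------------------------------------------------------
# redundancy filter and the per-frame driver

def filter_redundant(records: list) -> list:
    """Remove interaction overlaps and order the survivors deterministically.

    (i) hydrogen bonds whose donor and acceptor belong to a salt bridge
    between the same residue pair are dropped; (ii) hydrophobic contacts whose
    two atoms both lie in the rings of a detected pi-stack are dropped;
    (iii) at most one hydrogen bond survives per (donor, acceptor) atom pair
    (best angle; smallest distance for angle-waived records).
    """
    salt = [r for r in records if r.itype == "saltbridge"]
    stacks = [r for r in records if r.itype == "pistacking"]

    def in_saltbridge(hb: InteractionRecord) -> bool:
        for sb in salt:
            if (hb.receptor_residue == sb.receptor_residue
                    and set(hb.ligand_atoms) <= set(sb.ligand_atoms)
                    and set(hb.receptor_atoms) <= set(sb.receptor_atoms)):
                return True
        return False

    def in_stack(hp: InteractionRecord) -> bool:
        for st in stacks:
            if (set(hp.ligand_atoms) <= set(st.ligand_atoms)
                    and set(hp.receptor_atoms) <= set(st.receptor_atoms)):
                return True
        return False

    out: list = []
    best_hb: dict = {}
    for r in records:
        if r.itype == "hbond":
            if in_saltbridge(r):
                continue
            # the (donor, acceptor) pair: direction is part of the identity
            key = (r.ligand_atoms, r.receptor_atoms, r.subtype)
            prev = best_hb.get(key)
            if prev is not None:
                pa, ca = prev.geometry.get("angle"), r.geometry.get("angle")
                if pa is None and ca is None:
                    if r.geometry["distance"] < prev.geometry["distance"]:
                        best_hb[key] = r
                elif (pa or -1) < (ca or -1):
                    best_hb[key] = r
            else:
                best_hb[key] = r
        elif r.itype == "hydrophobic":
            if not in_stack(r):
                out.append(r)
        else:
            out.append(r)
    out.extend(best_hb.values())
    out.sort(key=InteractionRecord.sort_key)
    return out


def detect_frame(frame: Frame, entities: EntityMap,
                 config: Optional[DetectionConfig] = None,
                 bonds: Optional[BondGraph] = None,
                 perception: Optional[PerceptionSet] = None) -> list:
    """All five detectors plus the redundancy filter, for one frame."""
    config = config or DetectionConfig()
    if bonds is None:
        bonds = infer_bonds(frame)
    if perception is None:
        perception = perceive(frame, bonds, entities, config)
    records: list = []
    records += detect_hbonds(frame, perception, entities, config)
    records += detect_hydrophobic(frame, perception, entities, config)
    records += detect_pistacking(frame, perception, entities, config)
    records += detect_saltbridges(frame, perception, entities, config)
    records += detect_waterbridges(frame, perception, entities, bonds, config)
    return filter_redundant(records)


def write_frame_report(path: str | Path, records: list) -> None:
    """Per-frame JSON report: one entry per record."""
    Path(path).write_text(json.dumps([r.to_dict() for r in records], indent=1,
                                     sort_keys=True) + "\n")
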