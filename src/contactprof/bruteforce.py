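"""Naive all-pairs reference detection, used as a correctness oracle.

Every detector here enumerates all candidate pairs with plain nested loops
and restates the geometric criteria directly, independently of the
k-d-tree-accelerated implementations in :mod:`contactprof.interactions`.
On any frame the two paths must produce identical record sets; the test
suite and the acceptance run enforce this on frames of up to a few hundred
atoms.  Do not "optimise" this module: being obvious is its purpose.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from contactprof.bonds import BondGraph, infer_bonds
from contactprof.config import DetectionConfig
from contactprof.interactions import InteractionRecord, _mkrecord, filter_redundant
from contactprof.perception import PerceptionSet, perceive
from contactprof.structure import EntityMap, Frame, ROLE_LIGAND


def _dist(frame: Frame, i: int, j: int) -> float:
    d = frame.coords[i] - frame.coords[j]
    return math.sqrt(float(d @ d))


def _ang(frame: Frame, i: int, vertex: int, j: int) -> float:
    v1 = frame.coords[i] - frame.coords[vertex]
    v2 = frame.coords[j] - frame.coords[vertex]
    c = float(v1 @ v2) / (math.sqrt(float(v1 @ v1)) * math.sqrt(float(v2 @ v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _hbonds_naive(frame, perception, entities, cfg):
    lig, rec = set(entities.ligand), set(entities.receptor)
    donors = dict(perception.donors)
    if not perception.has_polar_hydrogens:
        for i in perception.potential_donors:
            donors.setdefault(i, ())
    out, seen = [], set()
    for d in sorted(donors):
        for a in sorted(perception.acceptors):
            if a == d:
                continue
            if not ((d in lig and a in rec) or (d in rec and a in lig)):
                continue
            dist = _dist(frame, d, a)
            hs = donors[d]
            if hs:
                if dist > cfg.hbond_dist_max:
                    continue
                best = max(_ang(frame, d, h, a) for h in hs)
                if best < cfg.hbond_angle_min:
                    continue
                geo = {"distance": dist, "angle": best}
                subtype = "ligand-donor" if d in lig else "receptor-donor"
            else:
                if dist > cfg.hbond_noh_dist_max:
                    continue
                pair = (min(d, a), max(d, a))
                if pair in seen:
                    continue
                seen.add(pair)
                geo = {"distance": dist, "angle": None}
                subtype = "no-h-fallback"
            l, r = (d, a) if d in lig else (a, d)
            rec_out = _mkrecord(frame, "hbond", (l,), (r,), geo)
            rec_out.subtype = subtype
            out.append(rec_out)
    return out


def _hydrophobic_naive(frame, perception, entities, cfg):
    ligs = sorted(i for i in perception.hydrophobic
                  if entities.roles[i] == ROLE_LIGAND)
    recs = sorted(i for i in perception.hydrophobic if entities.is_receptor(i))
    best = {}
    for l in ligs:
        for r in recs:
            d = _dist(frame, l, r)
            if d > cfg.hydrophobic_dist_max:
                continue
            a = frame.atoms[r]
            key = (l, (a.chain_id, a.res_name, a.res_seq))
            cand = (d, a.name, r)
            if key not in best or cand < best[key]:
                best[key] = cand
    return [_mkrecord(frame, "hydrophobic", (l,), (r,), {"distance": d})
            for (l, _k), (d, _n, r) in sorted(best.items())]


def _pistacking_naive(frame, perception, entities, cfg):
    out = []
    for lr in perception.rings:
        if lr.role != ROLE_LIGAND:
            continue
        for rr in perception.rings:
            if rr.role == ROLE_LIGAND:
                continue
            dist = float(np.linalg.norm(lr.center - rr.center))
            if dist > cfg.pistack_dist_max:
                continue
            cosang = abs(float(lr.normal @ rr.normal))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if ang <= cfg.pistack_parallel_angle_max:
                subtype = "parallel"
            elif cfg.pistack_tshape_angle_min <= ang <= 90.0:
                subtype = "tshaped"
            else:
                continue
            offs = []
            for base, other in ((lr, rr), (rr, lr)):
                v = other.center - base.center
                inpl = v - (v @ base.normal) * base.normal
                offs.append(float(np.linalg.norm(inpl)))
            if min(offs) > cfg.pistack_offset_max:
                continue
            out.append(_mkrecord(frame, "pistacking",
                                 tuple(sorted(lr.members)),
                                 tuple(sorted(rr.members)),
                                 {"distance": dist, "angle": ang,
                                  "offset": min(offs)}, subtype=subtype))
    return out


def _saltbridges_naive(frame, perception, entities, cfg):
    out = []
    for lc in perception.charge_centers:
        if lc.role != ROLE_LIGAND:
            continue
        for rc in perception.charge_centers:
            if rc.role == ROLE_LIGAND or lc.sign * rc.sign >= 0:
                continue
            d = float(np.linalg.norm(lc.centroid - rc.centroid))
            if d > cfg.saltbridge_dist_max:
                continue
            out.append(_mkrecord(frame, "saltbridge",
                                 tuple(sorted(lc.members)),
                                 tuple(sorted(rc.members)),
                                 {"distance": d},
                                 subtype=f"{lc.label}-{rc.label}"))
    return out


def _waterbridges_naive(frame, perception, entities, bonds, cfg):
    elements = [a.element for a in frame.atoms]
    polar = set(perception.donors) | perception.acceptors | perception.potential_donors
    ligs = sorted(polar & set(entities.ligand))
    recs = sorted(polar & set(entities.receptor))

    def leg_ok(p, w, w_hs, dist):
        if not (cfg.waterbridge_dist_min <= dist <= cfg.waterbridge_dist_max):
            return False
        hs = perception.donors.get(p, ())
        if hs and max(_ang(frame, p, h, w) for h in hs) >= cfg.waterbridge_donor_angle_min:
            return True
        if p in perception.acceptors and w_hs:
            if max(_ang(frame, w, h, p) for h in w_hs) >= cfg.waterbridge_donor_angle_min:
                return True
        if not perception.has_polar_hydrogens and not w_hs:
            return dist <= cfg.hbond_noh_dist_max and (
                p in perception.acceptors or p in perception.potential_donors)
        return False

    out = []
    for w in entities.water:
        if frame.atoms[w].element != "O":
            continue
        w_hs = tuple(j for j in bonds.neighbors(w) if elements[j] == "H")
        for l in ligs:
            dl = _dist(frame, l, w)
            if not leg_ok(l, w, w_hs, dl):
                continue
            for r in recs:
                dr = _dist(frame, r, w)
                if not leg_ok(r, w, w_hs, dr):
                    continue
                wang = _ang(frame, l, w, r)
                if not (cfg.waterbridge_angle_min <= wang <= cfg.waterbridge_angle_max):
                    continue
                wa = frame.atoms[w]
                out.append(_mkrecord(frame, "waterbridge", (l,), (r,),
                                     {"distance_ligand": dl,
                                      "distance_receptor": dr,
                                      "water_angle": wang},
                                     water=(wa.chain_id, wa.res_seq)))
    return out


def detect_frame_naive(frame: Frame, entities: EntityMap,
                       config: Optional[DetectionConfig] = None,
                       bonds: Optional[BondGraph] = None,
                       perception: Optional[PerceptionSet] = None) -> list:
    """All-pairs detection of the five interaction classes, then filtering."""
    cfg = config or DetectionConfig()
    if bonds is None:
        bonds = infer_bonds(frame)
    if perception is None:
        perception = perceive(frame, bonds, entities, cfg)
    records = []
    records += _hbonds_naive(frame, perception, entities, cfg)
    records += _hydrophobic_naive(frame, perception, entities, cfg)
    records += _pistacking_naive(frame, perception, entities, cfg)
    records += _saltbridges_naive(frame, perception, entities, cfg)
    records += _waterbridges_naive(frame, perception, entities, bonds, cfg)
    return filter_redundant(records)
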