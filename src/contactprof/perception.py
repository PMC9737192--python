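"""Functional characterization of interacting groups in one frame.

For the ligand and the receptor (protein + DNA) this module finds:

* hydrophobic atoms — carbons bonded only to carbon or hydrogen;
* hydrogen-bond donors (N/O/S bearing at least one hydrogen) and
  acceptors (N/O with an available lone pair: amide-like or quaternary
  nitrogens and bridging ether/ester oxygens are excluded);
* aromatic rings — template rings for the standard residues
  (Phe/Tyr/Trp/His, purine and pyrimidine rings of the nucleotides) and,
  for the ligand, 5/6-membered C/N/O/S cycles passing a planarity test;
* charge centers — guanidinium (Arg), ammonium (Lys), doubly protonated
  imidazolium (His), carboxylates (Asp/Glu, C-terminus), DNA phosphates,
  and pattern-matched ligand groups (carboxylate by default).

Water atoms are handled separately by the water-bridge detector and never
appear in these sets.  Perception is a pure function of
``(frame, bonds, entities)`` plus the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from contactprof.bonds import BondGraph
from contactprof.config import DetectionConfig
from contactprof.structure import (
    EntityMap, Frame, ROLE_DNA, ROLE_LIGAND, ROLE_PROTEIN,
)


@dataclass
class AromaticRing:
    members: tuple            # atom indices, ring order
    center: np.ndarray        # A
    normal: np.ndarray        # unit vector
    planarity_rms: float      # A
    residue_key: tuple
    role: str

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.members)


@dataclass
class ChargeCenter:
    sign: int                 # +1 or -1
    members: tuple            # atom indices
    centroid: np.ndarray
    label: str                # e.g. guanidinium, carboxylate, phosphate
    residue_key: tuple
    role: str


@dataclass
class PerceptionSet:
    """Per-frame functional annotation of ligand and receptor atoms."""

    hydrophobic: set = field(default_factory=set)
    donors: dict = field(default_factory=dict)        # donor idx -> tuple of H idx
    acceptors: set = field(default_factory=set)
    rings: list = field(default_factory=list)
    charge_centers: list = field(default_factory=list)
    potential_donors: set = field(default_factory=set)  # for H-less structures
    has_polar_hydrogens: bool = True


def _ring_geometry(coords: np.ndarray):
    """Best-fit plane of a ring: (center, unit normal, planarity rms)."""
    center = coords.mean(axis=0)
    x = coords - center
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    rms = float(np.sqrt(np.mean((x @ normal) ** 2)))
    return center, normal, rms


# template rings of the standard residues, by atom name
_TEMPLATE_RINGS = {
    "PHE": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "TYR": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
    "HIS": [("CG", "ND1", "CE1", "NE2", "CD2")],
    "DA": [("N1", "C2", "N3", "C4", "C5", "C6"), ("C4", "C5", "N7", "C8", "N9")],
    "DG": [("N1", "C2", "N3", "C4", "C5", "C6"), ("C4", "C5", "N7", "C8", "N9")],
    "DC": [("N1", "C2", "N3", "C4", "C5", "C6")],
    "DT": [("N1", "C2", "N3", "C4", "C5", "C6")],
    "DU": [("N1", "C2", "N3", "C4", "C5", "C6")],
}
for _his in ("HID", "HIE", "HIP", "HSD", "HSE", "HSP"):
    _TEMPLATE_RINGS[_his] = _TEMPLATE_RINGS["HIS"]


def _base_resname(name: str) -> str:
    n = name.upper()
    if n.endswith(("3", "5")) and n[:-1] in _TEMPLATE_RINGS:
        return n[:-1]
    return n


def find_hydrophobic_atoms(frame: Frame, bonds: BondGraph, entities: EntityMap) -> set:
    """Carbon atoms (ligand or receptor) bonded only to carbon or hydrogen."""
    out = set()
    for i, a in enumerate(frame.atoms):
        if entities.roles[i] not in (ROLE_LIGAND, ROLE_PROTEIN, ROLE_DNA):
            continue
        if a.element != "C":
            continue
        nbrs = bonds.neighbors(i)
        if nbrs and all(frame.atoms[j].element in ("C", "H") for j in nbrs):
            out.add(i)
    return out


def find_donors_acceptors(frame: Frame, bonds: BondGraph, entities: EntityMap,
                          config: Optional[DetectionConfig] = None):
    """(donors, acceptors, potential_donors) over ligand + receptor atoms.

    ``potential_donors`` lists N/O/S atoms that could carry a hydrogen in a
    structure stripped of hydrogens; it backs the no-H fallback rule of the
    hydrogen-bond detector.
    """
    config = config or DetectionConfig()
    donors: dict = {}
    acceptors: set = set()
    potential: set = set()
    elements = [a.element for a in frame.atoms]
    for i, a in enumerate(frame.atoms):
        if entities.roles[i] not in (ROLE_LIGAND, ROLE_PROTEIN, ROLE_DNA):
            continue
        el = a.element
        donor_ok = el in ("N", "O") or (el == "S" and config.sulfur_donor)
        if el not in ("N", "O", "S"):
            continue
        hs = tuple(j for j in bonds.neighbors(i) if elements[j] == "H")
        heavy = bonds.heavy_neighbors(i, elements)
        if donor_ok and hs:
            donors[i] = hs
        if el == "O":
            if len(heavy) <= 1:          # hydroxyl / carbonyl / carboxylate / terminal
                acceptors.add(i)
                potential.add(i)
            # bridging ether/ester O: neither acceptor nor potential donor
        elif el == "N":
            if len(heavy) <= 2:
                acceptors.add(i)
                potential.add(i)
            # >= 3 heavy neighbors: amide-like / quaternary, no lone pair exposed
        elif el == "S":
            if config.sulfur_acceptor:
                acceptors.add(i)
            if config.sulfur_donor and len(heavy) <= 1:
                potential.add(i)
    return donors, acceptors, potential


def find_aromatic_rings(frame: Frame, bonds: BondGraph, entities: EntityMap,
                        config: Optional[DetectionConfig] = None) -> list:
    """Aromatic rings: residue templates plus planar ligand cycles."""
    config = config or DetectionConfig()
    rings: list = []
    residues = frame.residues()
    name_index = {}
    for key, idxs in residues.items():
        name_index[key] = {frame.atoms[i].name: i for i in idxs}

    for key, idxs in residues.items():
        role = entities.roles[idxs[0]]
        if role not in (ROLE_PROTEIN, ROLE_DNA):
            continue
        templ = _TEMPLATE_RINGS.get(_base_resname(frame.atoms[idxs[0]].res_name))
        if not templ:
            continue
        for names in templ:
            try:
                members = tuple(name_index[key][nm] for nm in names)
            except KeyError:
                continue  # incomplete residue
            center, normal, rms = _ring_geometry(frame.coords[list(members)])
            rings.append(AromaticRing(members, center, normal, rms, key, role))

    # ligand: exhaustive 5/6-cycles of sp2-capable atoms, planarity-gated
    lig = [i for i in entities.ligand
           if frame.atoms[i].element in ("C", "N", "O", "S")]
    if lig:
        g = nx.Graph()
        g.add_nodes_from(lig)
        ligset = set(lig)
        for i in lig:
            for j in bonds.neighbors(i):
                if j in ligset:
                    g.add_edge(i, j)
        seen = set()
        for cyc in nx.cycle_basis(g):
            if len(cyc) not in (5, 6):
                continue
            ms = frozenset(cyc)
            if ms in seen:
                continue
            seen.add(ms)
            center, normal, rms = _ring_geometry(frame.coords[list(cyc)])
            if rms <= config.ring_planarity_max:
                key = frame.atoms[cyc[0]].residue_key
                rings.append(AromaticRing(tuple(cyc), center, normal, rms,
                                          key, ROLE_LIGAND))
    return rings


def _residue_atom(frame: Frame, idxs: list, name: str):
    for i in idxs:
        if frame.atoms[i].name == name:
            return i
    return None


def find_charge_centers(frame: Frame, bonds: BondGraph, entities: EntityMap,
                        config: Optional[DetectionConfig] = None) -> list:
    """Formal charge centers of receptor residues and the ligand."""
    config = config or DetectionConfig()
    centers: list = []
    elements = [a.element for a in frame.atoms]

    def add(sign, members, label, key, role):
        members = tuple(m for m in members if m is not None)
        if not members:
            return
        centroid = frame.coords[list(members)].mean(axis=0)
        centers.append(ChargeCenter(sign, members, centroid, label, key, role))

    for key, idxs in frame.residues().items():
        role = entities.roles[idxs[0]]
        rn = _base_resname(frame.atoms[idxs[0]].res_name)
        at = lambda nm: _residue_atom(frame, idxs, nm)
        if role == ROLE_PROTEIN:
            if rn == "ARG":
                mem = [at(n) for n in ("CZ", "NH1", "NH2", "NE")]
                if all(m is not None for m in mem):
                    add(+1, mem, "guanidinium", key, role)
            elif rn in ("LYS", "LYN"):
                nz = at("NZ")
                if nz is not None:
                    add(+1, [nz], "ammonium", key, role)
            elif rn in ("HIS", "HIP", "HSP", "HID", "HIE", "HSD", "HSE"):
                nd1, ne2 = at("ND1"), at("NE2")
                if nd1 is not None and ne2 is not None:
                    both_h = all(
                        any(elements[j] == "H" for j in bonds.neighbors(i))
                        for i in (nd1, ne2))
                    if both_h:
                        ring = [at(n) for n in ("CG", "ND1", "CE1", "NE2", "CD2")]
                        add(+1, ring, "imidazolium", key, role)
            if rn in ("ASP", "ASH"):
                mem = [at(n) for n in ("CG", "OD1", "OD2")]
                if all(m is not None for m in mem):
                    add(-1, mem, "carboxylate", key, role)
            elif rn in ("GLU", "GLH"):
                mem = [at(n) for n in ("CD", "OE1", "OE2")]
                if all(m is not None for m in mem):
                    add(-1, mem, "carboxylate", key, role)
            oxt = at("OXT")
            if oxt is not None:
                add(-1, [at("C"), at("O"), oxt], "carboxylate-cterm", key, role)
        elif role == ROLE_DNA:
            p = at("P")
            if p is not None:
                add(-1, [p, at("OP1"), at("OP2")], "phosphate", key, role)
        elif role == ROLE_LIGAND:
            centers.extend(_ligand_charge_centers(frame, bonds, idxs, key, config))
    return centers


def _ligand_charge_centers(frame: Frame, bonds: BondGraph, idxs: list,
                           key: tuple, config: DetectionConfig) -> list:
    """Conservative pattern matching of formally charged ligand groups."""
    out: list = []
    elements = [a.element for a in frame.atoms]
    idxset = set(idxs)
    if "carboxylate" in config.ligand_charge_patterns:
        for c in idxs:
            if elements[c] != "C":
                continue
            os = [j for j in bonds.neighbors(c)
                  if j in idxset and elements[j] == "O"
                  and len(bonds.heavy_neighbors(j, elements)) == 1
                  and not any(elements[k] == "H" for k in bonds.neighbors(j))]
            if len(os) == 2:
                members = (c, *sorted(os))
                centroid = frame.coords[list(members)].mean(axis=0)
                out.append(ChargeCenter(-1, members, centroid, "carboxylate",
                                        key, ROLE_LIGAND))
    if "ammonium" in config.ligand_charge_patterns:
        for n in idxs:
            if elements[n] != "N":
                continue
            hs = [j for j in bonds.neighbors(n) if elements[j] == "H"]
            if len(hs) >= 3:
                out.append(ChargeCenter(+1, (n,), frame.coords[n].copy(),
                                        "ammonium", key, ROLE_LIGAND))
    return out


def perceive(frame: Frame, bonds: BondGraph, entities: EntityMap,
             config: Optional[DetectionConfig] = None) -> PerceptionSet:
    """Full functional annotation of one frame."""
    config = config or DetectionConfig()
    donors, acceptors, potential = find_donors_acceptors(frame, bonds, entities, config)
    ps = PerceptionSet(
        hydrophobic=find_hydrophobic_atoms(frame, bonds, entities),
        donors=donors,
        acceptors=acceptors,
        rings=find_aromatic_rings(frame, bonds, entities, config),
        charge_centers=find_charge_centers(frame, bonds, entities, config),
        potential_donors=potential,
    )
    # a structure counts as H-less when no polar atom carries any hydrogen
    ps.has_polar_hydrogens = bool(donors)
    return ps
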