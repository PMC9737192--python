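"""Covalent bond inference for PDB frames that carry no connectivity.

Two heavy atoms of the same residue are bonded when their distance does not
exceed the sum of their covalent radii plus a 0.45 A tolerance.  Between
residues only the standard polymer links are considered (peptide C-N and
nucleic O3'-P), with the same distance rule, so a ligand can never become
covalently attached to the receptor by accident.  Each hydrogen is bonded to
its nearest in-range heavy atom only.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from contactprof.structure import Frame, ROLE_ION

# Cordero covalent radii (A); 0.77 fallback for anything exotic.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "NA": 1.66, "K": 2.03,
    "MG": 1.41, "CA": 1.76, "ZN": 1.22, "FE": 1.32, "MN": 1.39, "SE": 1.20,
    "B": 0.84, "SI": 1.11,
}
BOND_TOLERANCE = 0.45

_PEPTIDE_LINK = {("C", "N"), ("N", "C")}
_NUCLEIC_LINK = {("O3'", "P"), ("P", "O3'")}


def covalent_radius(element: str) -> float:
    return COVALENT_RADII.get(element.upper(), 0.77)


class BondGraph:
    """Symmetric adjacency over the atom indices of one frame."""

    def __init__(self, n: int):
        self.n = n
        self._adj: list = [set() for _ in range(n)]
        self.warnings: list = []

    def add_edge(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("self-edges are not allowed")
        self._adj[i].add(j)
        self._adj[j].add(i)

    def has_edge(self, i: int, j: int) -> bool:
        return j in self._adj[i]

    def neighbors(self, i: int) -> list:
        return sorted(self._adj[i])

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def edges(self) -> set:
        return {(min(i, j), max(i, j)) for i in range(self.n) for j in self._adj[i]}

    def heavy_neighbors(self, i: int, elements) -> list:
        return [j for j in self.neighbors(i) if elements[j] != "H"]


def _cutoff(e1: str, e2: str) -> float:
    return covalent_radius(e1) + covalent_radius(e2) + BOND_TOLERANCE


def infer_bonds(frame: Frame) -> BondGraph:
    """Bond graph of one frame (see module docstring for the rule set).

    Hydrogens with no in-range heavy partner and isolated non-ion heavy atoms
    produce entries in ``graph.warnings`` (and a ``UserWarning``), not errors.
    """
    n = frame.n_atoms
    g = BondGraph(n)
    if n == 0:
        return g
    elements = [a.element for a in frame.atoms]
    reskeys = [a.residue_key for a in frame.atoms]
    coords = frame.coords
    is_h = np.array([e == "H" for e in elements])

    max_r = max(covalent_radius(e) for e in set(elements))
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=2 * max_r + BOND_TOLERANCE, output_type="ndarray")

    # candidate heavy-heavy edges + hydrogen candidate lists
    h_candidates: dict = {i: [] for i in range(n) if is_h[i]}
    for i, j in pairs:
        i, j = int(i), int(j)
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d > _cutoff(elements[i], elements[j]):
            continue
        if is_h[i] and is_h[j]:
            continue
        if is_h[i] or is_h[j]:
            h, x = (i, j) if is_h[i] else (j, i)
            if reskeys[h] == reskeys[x]:
                h_candidates[h].append((d, x))
            continue
        if reskeys[i] == reskeys[j]:
            g.add_edge(i, j)
        else:
            names = (frame.atoms[i].name, frame.atoms[j].name)
            if names in _PEPTIDE_LINK or names in _NUCLEIC_LINK:
                g.add_edge(i, j)

    for h, cands in h_candidates.items():
        if cands:
            _, x = min(cands, key=lambda t: (t[0], t[1]))
            g.add_edge(h, x)
        else:
            msg = f"hydrogen atom {frame.atoms[h].serial} ({frame.atoms[h].name}) has no bonded heavy atom"
            g.warnings.append(msg)
            warnings.warn(msg)

    for i in range(n):
        if g.degree(i) == 0 and not is_h[i]:
            a = frame.atoms[i]
            if a.res_name.upper() in ("NA", "CL", "K", "MG") or a.element in ("NA", "CL", "K", "MG", "ZN"):
                continue  # ions are legitimately unbonded
            msg = f"atom {a.serial} ({a.name} {a.res_name}{a.res_seq}) has no covalent neighbors"
            g.warnings.append(msg)
            warnings.warn(msg)
    return g
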