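"""Trajectory I/O over PDB files, entity classification and atom selection.

A trajectory is either one multi-model PDB file or a directory of per-frame
PDB files (lexicographic filename order defines frame order).  Parsing is
backed by gemmi; frames are exposed through lightweight :class:`Atom`,
:class:`Frame` and :class:`Trajectory` containers whose coordinate arrays are
plain numpy ``(N, 3)`` arrays in angstroms.

Entity classification assigns every atom exactly one of the roles
``protein``, ``dna``, ``water``, ``ion`` or ``ligand``; the receptor is the
union of protein and DNA (the duplex is treated as part of the receptor
throughout the package).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import gemmi
import numpy as np

ROLE_PROTEIN = "protein"
ROLE_DNA = "dna"
ROLE_WATER = "water"
ROLE_ION = "ion"
ROLE_LIGAND = "ligand"

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common MD protonation-state / cap variants
    "HID", "HIE", "HIP", "HSD", "HSE", "HSP", "ASH", "GLH", "LYN", "CYX",
    "CYM", "ACE", "NME", "NMA", "MSE",
}

_DNA_BASES = {"DA", "DT", "DG", "DC", "DU", "A", "T", "G", "C", "U"}
WATER_RES = {"HOH", "WAT", "SOL", "TIP3", "TIP", "T3P", "TIP4", "SPC"}
ION_RES = {"NA", "CL", "K", "MG", "ZN", "MN", "FE", "CA2", "NA+", "CL-", "K+", "MG2"}


def _is_dna_resname(name: str) -> bool:
    """DA/DT/DG/DC plus 5'/3'-terminal variants (DA5, DT3, ...)."""
    n = name.upper()
    if n in _DNA_BASES and n.startswith("D"):
        return True
    if n.endswith(("3", "5")) and n[:-1] in _DNA_BASES and n.startswith("D"):
        return True
    return False


@dataclass(eq=False)
class Atom:
    """One atom with its PDB identity fields; coordinates in angstroms."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    insertion_code: str = ""
    coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    het: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.element:
            self.element = infer_element(self.name)
        self.element = self.element.strip().upper()
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} {self.name}: non-finite coordinates")

    @property
    def identity(self) -> tuple:
        return (self.name, self.res_name, self.res_seq, self.chain_id, self.insertion_code)

    @property
    def residue_key(self) -> tuple:
        return (self.chain_id, self.res_seq, self.insertion_code)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"Atom({self.serial} {self.name} {self.res_name}{self.res_seq}"
                f" chain {self.chain_id!r})")


_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "FE", "ZN", "MN", "SE", "SI", "AL", "CU", "NI", "CO"}


def infer_element(atom_name: str) -> str:
    """Element from an atom name when the PDB element column is blank.

    First alphabetic character of the name, except that two-letter ion /
    heavy-element names are matched case-insensitively.
    """
    stripped = atom_name.strip()
    if stripped[:2].upper() in _TWO_LETTER_ELEMENTS and not stripped[2:3].isalpha():
        return stripped[:2].upper()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


class Frame:
    """One snapshot: an ordered atom list plus an ``(N, 3)`` coordinate array.

    Frames of one trajectory share the ``atoms`` list (identity is constant
    over time); per-frame geometry lives in :attr:`coords`.
    """

    __slots__ = ("index", "time_ps", "atoms", "coords", "_fragments")

    def __init__(self, atoms: Sequence[Atom], coords: Optional[np.ndarray] = None,
                 index: int = 0, time_ps: float = 0.0):
        self.atoms = list(atoms)
        if coords is None:
            coords = np.array([a.coords for a in self.atoms], dtype=float) \
                if self.atoms else np.zeros((0, 3))
        self.coords = np.asarray(coords, dtype=float).reshape(len(self.atoms), 3)
        self.index = int(index)
        self.time_ps = float(time_ps)
        self._fragments = None  # optional generator metadata
        if self.index < 0:
            raise ValueError("frame index must be >= 0")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residues(self) -> dict:
        """Ordered map residue_key -> list of atom indices."""
        out: dict = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_key, []).append(i)
        return out

    def with_coords(self, coords: np.ndarray, index: int = 0, time_ps: float = 0.0) -> "Frame":
        """A new frame sharing this frame's atom list."""
        f = Frame.__new__(Frame)
        f.atoms = self.atoms
        f.coords = np.asarray(coords, dtype=float).reshape(len(self.atoms), 3)
        f.index = int(index)
        f.time_ps = float(time_ps)
        f._fragments = None
        return f

    def identity_sequence(self) -> list:
        return [a.identity for a in self.atoms]


@dataclass
class Trajectory:
    """Ordered frames with a constant sampling stride (ps)."""

    frames: list
    stride_ps: float = 10.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    def validate(self) -> None:
        """Check the cross-frame invariants (identity sequence, times)."""
        ref = self.frames[0].identity_sequence()
        for fi, fr in enumerate(self.frames):
            ids = fr.identity_sequence()
            if len(ids) != len(ref):
                raise ValueError(f"frame {fi}: atom count {len(ids)} != {len(ref)}")
            for ai, (a, b) in enumerate(zip(ids, ref)):
                if a != b:
                    raise ValueError(
                        f"frame {fi}, atom {ai}: identity {a} differs from frame 0 ({b})")
        times = [fr.time_ps for fr in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")


# ---------------------------------------------------------------------------
# parsing

def _frame_from_model(model: gemmi.Model, index: int, time_ps: float) -> Frame:
    atoms: list[Atom] = []
    serial = 0
    seen_serials: set[int] = set()
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                # keep blank or 'A' altLocs, drop the rest (deterministic choice)
                if at.altloc not in ("\0", "", "A"):
                    continue
                serial += 1
                el = "H" if at.element.is_hydrogen else at.element.name.upper()
                if el in ("X", ""):
                    el = infer_element(at.name)
                sn = at.serial if at.serial > 0 else serial
                if sn in seen_serials:
                    raise ValueError(
                        f"frame {index}: duplicate atom serial {sn}")
                seen_serials.add(sn)
                atoms.append(Atom(
                    serial=sn, name=at.name, element=el,
                    res_name=res.name, res_seq=res.seqid.num,
                    chain_id=chain.name,
                    insertion_code=(res.seqid.icode or " ").strip(),
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    het=het,
                ))
    return Frame(atoms, index=index, time_ps=time_ps)


def parse_frames(source: str | Path, stride_ps: float = 10.0) -> Trajectory:
    """Read a trajectory from a multi-model PDB file or a directory of PDBs.

    Filenames in a directory are taken in lexicographic order; MODEL records
    in a single file define the order otherwise (a file with no MODEL records
    is one frame).  Times are assigned as ``index * stride_ps``.

    Raises ``ValueError`` if zero frames are found or if any frame's
    (name, res_name, res_seq, chain_id) sequence differs from frame 0.
    """
    source = Path(source)
    frames: list[Frame] = []
    if source.is_dir():
        files = sorted(p for p in source.iterdir()
                       if p.suffix.lower() in (".pdb", ".ent"))
        for i, f in enumerate(files):
            st = gemmi.read_pdb(str(f))
            if len(st) == 0:
                raise ValueError(f"{f}: no atoms parsed")
            frames.append(_frame_from_model(st[0], i, i * stride_ps))
    else:
        st = gemmi.read_pdb(str(source))
        for i, model in enumerate(st):
            frames.append(_frame_from_model(model, i, i * stride_ps))
    if not frames:
        raise ValueError(f"{source}: zero frames found")
    traj = Trajectory(frames, stride_ps=stride_ps)
    traj.validate()
    return traj


# ---------------------------------------------------------------------------
# writing (fixed-column wwPDB v3.3 ATOM/HETATM records, 3-decimal coordinates)

def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def _atom_line(a: Atom, xyz: np.ndarray, serial: int) -> str:
    rec = "HETATM" if a.het else "ATOM  "
    icode = a.insertion_code if a.insertion_code else " "
    el = a.element.capitalize() if len(a.element) == 2 else a.element
    return (f"{rec}{serial:>5d} {_format_atom_name(a.name, a.element)} "
            f"{a.res_name:<4s}{a.chain_id[:1] or 'A'}{a.res_seq:>4d}{icode}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {el:>2s}")


def write_pdb(path: str | Path, obj: Frame | Trajectory) -> None:
    """Write a frame or trajectory as a (multi-model) PDB file."""
    frames = obj.frames if isinstance(obj, Trajectory) else [obj]
    lines: list[str] = []
    multi = len(frames) > 1
    for fr in frames:
        if multi:
            lines.append(f"MODEL     {fr.index + 1:>4d}")
        for i, a in enumerate(fr.atoms):
            lines.append(_atom_line(a, fr.coords[i], a.serial))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# entity classification

@dataclass
class EntityMap:
    """Role per atom; receptor = protein + DNA."""

    roles: list

    def indices(self, *roles: str) -> list:
        want = set(roles)
        return [i for i, r in enumerate(self.roles) if r in want]

    @property
    def receptor(self) -> list:
        return self.indices(ROLE_PROTEIN, ROLE_DNA)

    @property
    def ligand(self) -> list:
        return self.indices(ROLE_LIGAND)

    @property
    def water(self) -> list:
        return self.indices(ROLE_WATER)

    def role(self, i: int) -> str:
        return self.roles[i]

    def is_receptor(self, i: int) -> bool:
        return self.roles[i] in (ROLE_PROTEIN, ROLE_DNA)


def classify_entities(frame: Frame, ligand_resnames: Iterable[str] = ()) -> EntityMap:
    """Assign each atom one role: protein / dna / water / ion / ligand.

    Residue names that match none of the standard sets and are not configured
    as ligand raise ``ValueError`` listing the unknown names.
    """
    lig = {r.upper() for r in ligand_resnames}
    roles: list = [None] * frame.n_atoms
    residues = frame.residues()
    unknown: set = set()
    for key, idxs in residues.items():
        rn = frame.atoms[idxs[0]].res_name.upper()
        if rn in lig:
            role = ROLE_LIGAND
        elif rn in STANDARD_AA:
            role = ROLE_PROTEIN
        elif _is_dna_resname(rn):
            role = ROLE_DNA
        elif rn in WATER_RES:
            role = ROLE_WATER
        elif rn in ION_RES and len(idxs) == 1:
            role = ROLE_ION
        else:
            unknown.add(rn)
            role = None
        for i in idxs:
            roles[i] = role
    if unknown:
        raise ValueError(
            "unclassifiable residue names (configure as ligand if intended): "
            + ", ".join(sorted(unknown)))
    em = EntityMap(roles)
    if lig and not em.ligand:
        raise ValueError(f"no atoms matched ligand residue names {sorted(lig)}")
    return em


def select_atoms(frame: Frame, selection: Callable[[Atom], bool]) -> list:
    """Indices (in frame order) of atoms satisfying the predicate."""
    return [i for i, a in enumerate(frame.atoms) if selection(a)]
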