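"""Time-indexed interaction ledger and persistence statistics.

Per-frame record lists are accumulated into a map from a canonical
interaction key to the sorted set of frame indices where that interaction is
present.  From the ledger the module derives:

* per-type persistence — for each interaction class, the percentage of frames
  containing at least one interaction of that class (one decimal);
* per-pair persistence — percentage per (ligand atom, receptor residue)
  pair, aggregated across interaction types and receptor atoms (nearest
  integer, rows below a relevance threshold omitted);
* a per-atom interaction-type profile (ligand atom x type matrix);
* bond durations (maximal consecutive-frame runs per key).

Keys deliberately ignore water identity for water bridges: waters exchange,
and an identity-free key is what makes bridge persistence well-defined.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from contactprof.interactions import ITYPES, InteractionRecord
from contactprof.structure import STANDARD_AA


def residue_label(residue: tuple) -> str:
    """Human-readable residue label, e.g. ('A','ARG',364) -> 'Arg364'."""
    _chain, res_name, res_seq = residue
    rn = res_name.upper()
    if rn in STANDARD_AA:
        rn = rn.capitalize()
    return f"{rn}{res_seq}"


def record_key(rec: InteractionRecord) -> str:
    """Canonical ledger key of a record.

    Hydrogen bonds and water bridges keep the receptor atom name (atom-tuple
    identification); hydrophobic contacts, pi-stacks and salt bridges are
    residue-level (their closest receptor atom varies frame to frame).
    Water identity is never part of the key.
    """
    lig = "+".join(rec.ligand_atom_names)
    res = residue_label(rec.receptor_residue)
    if rec.itype in ("hbond", "waterbridge"):
        rec_atom = "+".join(rec.receptor_atom_names)
    else:
        rec_atom = "*"
    return f"{rec.itype}|{lig}|{res}|{rec_atom}"


def split_key(key: str) -> tuple:
    itype, lig, res, rec_atom = key.split("|")
    return itype, tuple(lig.split("+")), res, rec_atom


@dataclass
class InteractionLedger:
    """Occupancy map: canonical key -> sorted list of frame indices."""

    total_frames: int
    occupancy: dict = field(default_factory=dict)

    def frames_present(self, key: str) -> int:
        return len(self.occupancy.get(key, ()))

    def percent(self, key: str) -> float:
        return 100.0 * self.frames_present(key) / self.total_frames

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"total_frames": self.total_frames,
             "occupancy": {k: list(v) for k, v in sorted(self.occupancy.items())}},
            indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "InteractionLedger":
        raw = json.loads(Path(path).read_text())
        return cls(total_frames=raw["total_frames"],
                   occupancy={k: sorted(v) for k, v in raw["occupancy"].items()})


def accumulate(per_frame_records, total_frames: int | None = None) -> InteractionLedger:
    """Build a ledger from per-frame record lists (list position = frame index).

    Duplicate records mapping to one key within a frame collapse to a single
    occurrence.  Raises if more frames are supplied than ``total_frames``.
    """
    per_frame_records = list(per_frame_records)
    if total_frames is None:
        total_frames = len(per_frame_records)
    if len(per_frame_records) > total_frames:
        raise ValueError(
            f"{len(per_frame_records)} record lists but total_frames={total_frames}")
    occ: dict = {}
    for fi, records in enumerate(per_frame_records):
        for rec in records:
            occ.setdefault(record_key(rec), set()).add(fi)
    return InteractionLedger(
        total_frames=total_frames,
        occupancy={k: sorted(v) for k, v in occ.items()})


def _runs(frames: list) -> list:
    """Maximal consecutive runs in a sorted frame-index list."""
    runs: list = []
    prev = None
    for f in frames:
        if prev is not None and f == prev + 1:
            runs[-1] += 1
        else:
            runs.append(1)
        prev = f
    return runs


def _round1(x: float) -> float:
    return math.floor(x * 10 + 0.5) / 10 if x >= 0 else -math.floor(-x * 10 + 0.5) / 10


def _round_int(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def per_type_persistence(ledger: InteractionLedger) -> pd.DataFrame:
    """Percentage of frames with >= 1 interaction of each type (one decimal)."""
    if ledger.total_frames == 0:
        raise ValueError("ledger has zero frames")
    rows = []
    for itype in ITYPES:
        frames: set = set()
        for key, occ in ledger.occupancy.items():
            if key.startswith(itype + "|"):
                frames.update(occ)
        runs = _runs(sorted(frames))
        rows.append({
            "itype": itype,
            "percent": _round1(100.0 * len(frames) / ledger.total_frames),
            "frames_present": len(frames),
            "longest_run_frames": max(runs) if runs else 0,
        })
    return pd.DataFrame(rows)


def per_pair_persistence(ledger: InteractionLedger,
                         min_percent: float = 10.0) -> pd.DataFrame:
    """(ligand atom, receptor residue) persistence, unioned across types.

    Multi-atom ligand groups (rings, carboxylates) attribute their occupancy
    to each member atom.  Rows whose exact percentage is below ``min_percent``
    are omitted; surviving percentages are rounded to the nearest integer
    (ties away from zero) to match the usual table format.
    """
    pair_frames: dict = {}
    for key, occ in ledger.occupancy.items():
        _itype, lig_atoms, res, _ra = split_key(key)
        for atom in lig_atoms:
            pair_frames.setdefault((atom, res), set()).update(occ)
    rows = []
    for (atom, res), frames in sorted(pair_frames.items()):
        pct = 100.0 * len(frames) / ledger.total_frames
        if pct < min_percent:
            continue
        runs = _runs(sorted(frames))
        rows.append({
            "ligand_atom": atom, "residue": res,
            "percent": _round_int(pct),
            "frames_present": len(frames),
            "longest_run_frames": max(runs) if runs else 0,
        })
    return pd.DataFrame(rows, columns=["ligand_atom", "residue", "percent",
                                       "frames_present", "longest_run_frames"])


def per_atom_type_profile(ledger: InteractionLedger) -> pd.DataFrame:
    """Ligand atom x interaction type occupancy matrix (percent, one decimal).

    Atoms participating in no interaction are omitted.
    """
    cell_frames: dict = {}
    atoms: set = set()
    for key, occ in ledger.occupancy.items():
        itype, lig_atoms, _res, _ra = split_key(key)
        for atom in lig_atoms:
            atoms.add(atom)
            cell_frames.setdefault((atom, itype), set()).update(occ)
    rows = []
    for atom in sorted(atoms):
        row = {"ligand_atom": atom}
        for itype in ITYPES:
            frames = cell_frames.get((atom, itype), set())
            row[itype] = _round1(100.0 * len(frames) / ledger.total_frames)
        if any(row[t] > 0 for t in ITYPES):
            rows.append(row)
    return pd.DataFrame(rows, columns=["ligand_atom", *ITYPES])


@dataclass
class DurationStats:
    frames_present: int
    longest_run: int
    runs: list


def bond_durations(ledger: InteractionLedger) -> dict:
    """Per-key run-length statistics; sum(runs) == frames_present."""
    out = {}
    for key, occ in sorted(ledger.occupancy.items()):
        runs = _runs(occ)
        out[key] = DurationStats(frames_present=len(occ),
                                 longest_run=max(runs) if runs else 0,
                                 runs=runs)
    return out
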