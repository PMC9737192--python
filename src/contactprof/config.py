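"""Configuration objects: geometric detection thresholds and pipeline run settings.

All distance cutoffs are in angstroms, all angles in degrees.  The detection
defaults follow the published defaults of the widely used protein-ligand
interaction profiler family of tools; every threshold can be overridden from a
YAML config file or the command line.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml


@dataclass
class DetectionConfig:
    """Geometric criteria for the five noncovalent interaction classes.

    Hydrogen bonds use a donor-acceptor heavy-atom distance gate plus a
    D-H...A angle gate; when a donor carries no explicit hydrogen (e.g. a
    crystal structure) the angle gate is waived and a tighter distance cutoff
    applies (``hbond_noh_dist_max``).
    """

    # hydrogen bonds
    hbond_dist_max: float = 4.1
    hbond_angle_min: float = 100.0
    hbond_noh_dist_max: float = 3.5  # fallback when donors carry no explicit H

    # hydrophobic contacts
    hydrophobic_dist_max: float = 4.0

    # pi-stacking
    pistack_dist_max: float = 5.5
    pistack_parallel_angle_max: float = 30.0
    pistack_tshape_angle_min: float = 60.0
    pistack_offset_max: float = 2.0

    # salt bridges (charge-center centroid distance)
    saltbridge_dist_max: float = 5.5

    # water bridges
    waterbridge_dist_min: float = 2.5
    waterbridge_dist_max: float = 4.1
    waterbridge_angle_min: float = 75.0   # water-centred angle, lower bound
    waterbridge_angle_max: float = 140.0  # water-centred angle, upper bound
    waterbridge_donor_angle_min: float = 100.0

    # perception toggles
    his_positive_rule: str = "doubly-protonated"
    sulfur_donor: bool = True
    sulfur_acceptor: bool = False
    ligand_charge_patterns: Sequence[str] = ("carboxylate",)

    # ring perception
    ring_planarity_max: float = 0.25

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                if f.name.endswith(("_max", "_min")) and v < 0:
                    raise ValueError(f"threshold {f.name} must be positive, got {v}")

    def replace(self, **kw) -> "DetectionConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class RunConfig:
    """Settings for a full pipeline run (frames -> detection -> ledger -> tables)."""

    input_path: Optional[str] = None
    output_dir: str = "contactprof_out"
    ligand_resnames: tuple[str, ...] = ()
    stride: int = 1                      # analyse every stride-th frame
    stride_ps: float = 10.0              # time between saved frames
    min_percent: float = 10.0            # per-pair table relevance filter
    reference_index: int = 0             # RMSD reference frame
    fit_selection: str = "auto"          # "auto" | "calpha" | "receptor-heavy"
    moieties: dict = field(default_factory=dict)  # label -> list of ligand atom names
    seed: int = 0
    detection: DetectionConfig = field(default_factory=DetectionConfig)

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        self.ligand_resnames = tuple(self.ligand_resnames)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides win over file values."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        det_raw = raw.pop("detection", {})
        raw.update({k: v for k, v in overrides.items() if v is not None})
        det = DetectionConfig(**det_raw)
        return cls(detection=det, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d
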