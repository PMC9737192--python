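"""Binding-stability metrics: Kabsch superposition, RMSD series and RMSF.

All deviations are reported in nanometres (coordinates are handled in
angstroms internally and converted at the boundary).  The standard protocol
is applied: every frame is least-squares fitted onto the reference over a fit
mask (receptor C-alpha atoms by default) before the deviation is measured
over a possibly different mask, so a ligand RMSD measures motion of the
ligand within the binding pocket rather than global tumbling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from contactprof.structure import Frame, Trajectory

A_PER_NM = 10.0


@dataclass
class RMSDSeries:
    times_ps: np.ndarray
    values_nm: np.ndarray
    selection: str = ""
    reference: str = "frame 0"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times_ps,
                             "rmsd_nm": self.values_nm})


@dataclass
class RMSFProfile:
    labels: list                 # residue (or atom) labels
    values_nm: np.ndarray
    selection: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.labels,
                             "rmsf_nm": self.values_nm})


def superpose(mobile: Frame, reference: Frame, fit_mask) -> tuple:
    """Least-squares (Kabsch) fit of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, fitted_frame)`` with a proper rotation
    matrix (det = +1); the transform maps mobile coordinates as
    ``x @ R.T + t``.  Raises for fewer than 3 fit atoms.
    """
    fit_mask = list(fit_mask)
    if len(fit_mask) < 3:
        raise ValueError(f"need >= 3 fit atoms, got {len(fit_mask)}")
    mob = mobile.coords[fit_mask]
    ref = reference.coords[fit_mask]
    if np.array_equal(mob, ref):
        # already superposed (e.g. the reference frame itself): exact identity
        return np.eye(3), np.zeros(3), mobile.with_coords(
            mobile.coords, index=mobile.index, time_ps=mobile.time_ps)
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    rot, _rssd = Rotation.align_vectors(ref - rc, mob - mc)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    fitted = mobile.with_coords(mobile.coords @ R.T + t,
                                index=mobile.index, time_ps=mobile.time_ps)
    return R, t, fitted


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(traj: Trajectory, fit_mask, measure_mask,
                reference_index: int = 0, selection: str = "") -> RMSDSeries:
    """Per-frame RMSD over ``measure_mask`` after fitting on ``fit_mask``."""
    measure_mask = list(measure_mask)
    if not measure_mask:
        raise ValueError("measure_mask is empty")
    if not (0 <= reference_index < len(traj)):
        raise ValueError(f"reference_index {reference_index} out of range")
    ref = traj[reference_index]
    times = np.array([f.time_ps for f in traj])
    vals = np.empty(len(traj))
    for i, fr in enumerate(traj):
        _R, _t, fitted = superpose(fr, ref, fit_mask)
        vals[i] = _rmsd(fitted.coords[measure_mask], ref.coords[measure_mask]) / A_PER_NM
    return RMSDSeries(times, vals, selection=selection,
                      reference=f"frame {reference_index}")


def rmsf(traj: Trajectory, fit_mask, measure_mask, labels=None,
         selection: str = "") -> RMSFProfile:
    """Root-mean-square fluctuation about the time-average structure.

    Frames are first fitted to frame 0 on ``fit_mask``, the mean structure is
    formed, and every frame is re-fitted to that mean (one iteration) before
    the per-atom fluctuation over ``measure_mask`` is computed.
    """
    measure_mask = list(measure_mask)
    if len(traj) < 2:
        raise ValueError("RMSF needs at least two frames")
    fitted = [superpose(fr, traj[0], fit_mask)[2] for fr in traj]
    mean_coords = np.mean([f.coords for f in fitted], axis=0)
    mean_frame = traj[0].with_coords(mean_coords)
    refit = np.empty((len(traj), len(measure_mask), 3))
    for i, fr in enumerate(fitted):
        refit[i] = superpose(fr, mean_frame, fit_mask)[2].coords[measure_mask]
    mean2 = refit.mean(axis=0)
    vals = np.sqrt(np.mean(np.sum((refit - mean2) ** 2, axis=2), axis=0))
    if labels is None:
        labels = [f"{traj[0].atoms[i].res_name}{traj[0].atoms[i].res_seq}"
                  for i in measure_mask]
    return RMSFProfile(list(labels), vals / A_PER_NM, selection=selection)
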