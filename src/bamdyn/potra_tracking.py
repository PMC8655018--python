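"""In-plane tracking of a sub-domain (POTRA5) relative to the barrel.

Positions are reported in the membrane frame, relative to the per-frame
barrel center, so a rigid translation of the whole complex leaves the
track unchanged.  The area explored is summarized by a convex hull
(default) or an occupancy grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import ParameterError
from .geometry import (ComplexSelection, SelectionEntry, kabsch_superpose,
                       membrane_frame, select_atoms, select_indices)
from .structio import StructureModel, Trajectory

__all__ = [
    "TrackSeries",
    "AreaResult",
    "track_center",
    "displacement_between_states",
    "explored_area",
]


@dataclass
class TrackSeries:
    """In-plane 2D positions (Å) of a tracked selection, barrel-relative."""

    times: np.ndarray
    points: np.ndarray   # (n_frames, 2)
    label: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times,
                             "x_A": self.points[:, 0],
                             "y_A": self.points[:, 1]})


def track_center(traj: Trajectory, entry: SelectionEntry,
                 selection: ComplexSelection | None = None,
                 frame_mode: str = "z_axis") -> TrackSeries:
    """Per-frame in-plane center of ``entry`` relative to the barrel center.

    The membrane frame orientation comes from frame 0 (mode as given);
    the in-plane origin is the per-frame barrel center, so global
    translations drop out frame by frame.
    """
    selection = selection or ComplexSelection()
    top = traj.topology
    frame = membrane_frame(top.with_coords(traj.frames[0]), selection, mode=frame_mode)
    sel_idx = select_indices(top, entry)
    barrel_idx = select_indices(top, selection.barrel)
    pts = np.empty((traj.n_frames, 2))
    for f in range(traj.n_frames):
        coords = traj.frames[f]
        d = coords[sel_idx].mean(axis=0) - coords[barrel_idx].mean(axis=0)
        pts[f] = frame.project_in_plane(d)
    return TrackSeries(times=np.array(traj.times), points=pts,
                       label=entry.name or entry.describe())


def displacement_between_states(a: StructureModel, b: StructureModel,
                                selection: ComplexSelection | None = None,
                                entry: SelectionEntry | None = None) -> float:
    """Distance (Å) between the tracked centers of two structures.

    b's barrel Cα atoms are first superposed onto a's (paired by residue),
    then the Cα geometric centers of the tracked selection (POTRA5 by
    default) are compared.
    """
    selection = selection or ComplexSelection()
    entry = entry or selection.potra5
    barrel_ca = replace(selection.barrel, atom_class="CA")
    ref = {at.key: at.position for at in select_atoms(a, barrel_ca)}
    mob_pairs = [(ref[at.key], at.position)
                 for at in select_atoms(b, barrel_ca) if at.key in ref]
    tr = kabsch_superpose(np.array([p[0] for p in mob_pairs]),
                          np.array([p[1] for p in mob_pairs]))
    entry_ca = replace(entry, atom_class="CA")
    center_a = np.mean([at.position for at in select_atoms(a, entry_ca)], axis=0)
    center_b = np.mean([tr.apply(at.position[None, :])[0]
                        for at in select_atoms(b, entry_ca)], axis=0)
    return float(np.linalg.norm(center_a - center_b))


@dataclass(frozen=True)
class AreaResult:
    area: float           # Å²
    method: str
    degenerate: bool = False


def explored_area(track: TrackSeries, method: str = "convex_hull",
                  cell: float = 1.0) -> AreaResult:
    """Area explored by a 2D track, Å².

    ``convex_hull`` returns the hull area (0 with a degenerate flag for
    < 3 non-collinear points); ``occupancy_grid`` counts occupied cells
    of side ``cell``.
    """
    pts = np.asarray(track.points, dtype=float)
    if method == "convex_hull":
        unique = np.unique(pts, axis=0)
        if len(unique) < 3:
            return AreaResult(0.0, method, degenerate=True)
        try:
            hull = ConvexHull(unique)
        except QhullError:
            return AreaResult(0.0, method, degenerate=True)  # collinear
        return AreaResult(float(hull.volume), method)  # 2D: volume == area
    if method == "occupancy_grid":
        if cell <= 0:
            raise ParameterError(f"cell must be positive, got {cell}")
        cells = np.unique(np.floor(pts / cell).astype(int), axis=0)
        return AreaResult(float(len(cells)) * cell * cell, method)
    raise ParameterError(f"unknown area method {method!r}")
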