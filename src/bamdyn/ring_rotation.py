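"""Periplasmic-ring rotation angle in the membrane plane.

The order parameter distinguishing the inward-open and outward-open
states of BAM: the in-plane angle of the accessory-lipoprotein ring
(BamB–E) about the BamA barrel, measured counterclockwise as seen from
the extracellular side.  The 0° reference is the geometric center of the
accessory carbonyl carbons in a chosen reference structure, relative to
the barrel carbonyl-carbon center (residues 425–810 by default).
Systems missing an accessory component exclude it from both the
reference and the measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FrameError, SelectionError
from .geometry import (ComplexSelection, MembraneFrame, geometric_center,
                       kabsch_superpose, membrane_frame, select_indices)
from .structio import StructureModel, Trajectory

__all__ = [
    "RotationReference",
    "AngleSeries",
    "build_reference",
    "rotation_angle",
    "rotation_series",
]


@dataclass(frozen=True)
class RotationReference:
    """Frozen 0° definition: membrane frame + in-plane unit reference vector."""

    frame: MembraneFrame
    reference_vector: np.ndarray           # unit 2-vector in (in_plane_x, in_plane_y)
    accessory_set: tuple[str, ...]
    source: str = ""
    # Cα barrel anchors for static structure-pair comparisons, keyed by
    # (chain, residue number, insertion code, atom name).
    barrel_anchor: dict = field(default_factory=dict, compare=False)


@dataclass
class AngleSeries:
    """Signed rotation angles (degrees) per frame; wrapped to (-180, 180]."""

    times: np.ndarray
    angles: np.ndarray
    reference: RotationReference
    unwrapped: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "angle_deg": self.angles})


def wrap_angle(deg):
    """Wrap degrees to the half-open interval (-180, 180]."""
    wrapped = np.remainder(np.asarray(deg, dtype=float), 360.0)
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # map -180 (from exactly 180 mod 360 edge cases) onto +180
    wrapped = np.where(np.isclose(wrapped, -180.0), 180.0, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def _present_accessories(model: StructureModel, selection: ComplexSelection,
                         subset=None) -> list[str]:
    names = []
    for name, entry in selection.accessory.items():
        if subset is not None and name not in subset:
            continue
        try:
            select_indices(model, entry)
        except SelectionError:
            continue
        names.append(name)
    return names


def _accessory_center(model: StructureModel, coords: np.ndarray,
                      selection: ComplexSelection, names) -> np.ndarray:
    idx = np.concatenate([select_indices(model, selection.accessory[n]) for n in names])
    return coords[idx].mean(axis=0)


def build_reference(reference_model: StructureModel, selection: ComplexSelection,
                    frame_mode: str = "z_axis", accessory_set=None,
                    source: str = "") -> RotationReference:
    """Build the 0° reference from a structure (typically frame 0 or 5D0O).

    The reference vector is the in-plane projection of (accessory
    carbonyl-C center − barrel carbonyl-C center), normalized.  Only
    accessory components present in the model (and in ``accessory_set``,
    when given) enter; the same set must be used for all measurements
    against this reference.
    """
    names = _present_accessories(reference_model, selection, accessory_set)
    if not names:
        raise SelectionError("no accessory component present to define the reference")
    frame = membrane_frame(reference_model, selection, mode=frame_mode)
    coords = reference_model.coords()
    acc = _accessory_center(reference_model, coords, selection, names)
    vec2 = frame.project_in_plane(acc - frame.origin)
    norm = np.linalg.norm(vec2)
    if norm < 1e-9:
        raise FrameError("accessory center projects onto the barrel axis; "
                         "degenerate 0-degree reference")
    anchors = {}
    barrel_ca = replace(selection.barrel, atom_class="CA")
    for i in select_indices(reference_model, barrel_ca, required=False):
        a = reference_model.atoms[i]
        anchors[a.key] = np.array(a.position)
    return RotationReference(
        frame=frame, reference_vector=vec2 / norm, accessory_set=tuple(names),
        source=source or reference_model.identifier, barrel_anchor=anchors)


def _angle_from_vectors(ref2: np.ndarray, cur2: np.ndarray) -> float:
    # signed angle from ref to cur, CCW positive about +normal
    cross = ref2[0] * cur2[1] - ref2[1] * cur2[0]
    dot = float(np.dot(ref2, cur2))
    return wrap_angle(np.degrees(np.arctan2(cross, dot)))


def rotation_angle(model: StructureModel, selection: ComplexSelection,
                   reference: RotationReference, superpose: bool = False,
                   coords: np.ndarray | None = None) -> float:
    """Rotation angle (degrees) of one structure/frame against a reference.

    ``superpose=True`` first fits the structure's barrel Cα atoms onto the
    reference barrel (by residue pairing) — required when comparing two
    independently deposited structures that do not share a coordinate
    frame.  ``coords`` may override the model's coordinates (trajectory
    fast path).
    """
    if coords is None:
        coords = model.coords()
    if superpose:
        if not reference.barrel_anchor:
            raise FrameError("reference carries no barrel Cα anchor for superposition")
        barrel_ca = replace(selection.barrel, atom_class="CA")
        idx = select_indices(model, barrel_ca)
        pairs = [(reference.barrel_anchor[model.atoms[i].key], coords[i])
                 for i in idx if model.atoms[i].key in reference.barrel_anchor]
        if len(pairs) < 3:
            raise FrameError(f"only {len(pairs)} barrel Cα atoms pair with the reference")
        tr = kabsch_superpose(np.array([p[0] for p in pairs]),
                              np.array([p[1] for p in pairs]))
        coords = tr.apply(coords)

    names = [n for n in reference.accessory_set]
    missing = [n for n in names if n not in _present_accessories(model, selection, names)]
    if missing:
        raise SelectionError(f"accessory components {missing} of the reference set "
                             "are absent from the measured structure")
    acc = _accessory_center(model, coords, selection, names)
    barrel_idx = select_indices(model, selection.barrel)
    barrel_center = coords[barrel_idx].mean(axis=0)
    cur2 = reference.frame.project_in_plane(acc - barrel_center)
    if np.linalg.norm(cur2) < 1e-9:
        raise FrameError("accessory center lies on the barrel axis; angle undefined")
    return _angle_from_vectors(reference.reference_vector, cur2)


def rotation_series(traj: Trajectory, selection: ComplexSelection,
                    reference: RotationReference | None = None,
                    unwrap: bool = False) -> AngleSeries:
    """Per-frame rotation angle of a trajectory.

    Without an explicit reference, frame 0 defines 0°.  With
    ``unwrap=True`` the wrapped series is unwrapped for continuity across
    ±180°.
    """
    if reference is None:
        reference = build_reference(traj.topology.with_coords(traj.frames[0]),
                                    selection, source="frame 0")
    top = traj.topology
    names = list(reference.accessory_set)
    acc_idx = np.concatenate([select_indices(top, selection.accessory[n]) for n in names])
    barrel_idx = select_indices(top, selection.barrel)
    frame = reference.frame
    ref2 = reference.reference_vector
    angles = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        coords = traj.frames[f]
        d = coords[acc_idx].mean(axis=0) - coords[barrel_idx].mean(axis=0)
        cur2 = frame.project_in_plane(d)
        if np.linalg.norm(cur2) < 1e-9:
            raise FrameError(f"frame {f}: accessory center on the barrel axis")
        angles[f] = _angle_from_vectors(ref2, cur2)
    if unwrap:
        angles = np.degrees(np.unwrap(np.radians(angles)))
    return AngleSeries(times=np.array(traj.times), angles=angles,
                       reference=reference, unwrapped=unwrap)
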