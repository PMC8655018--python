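"""Backbone hydrogen bonds across the BamA lateral seam (β1/β16).

Counts inter-strand backbone N–H···O=C hydrogen bonds per frame, applies
a centered moving average, and classifies each frame as open, tenuous or
closed.  The geometric criterion is the conventional one — donor–acceptor
N···O distance with an angular gate — since integer per-frame counts are
what the analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ParameterError, SelectionError
from .geometry import ComplexSelection, SelectionEntry
from .structio import StructureModel, Trajectory

__all__ = [
    "HBondCriteria",
    "HBond",
    "HBondSeries",
    "detect_backbone_hbonds",
    "hbond_series",
    "classify_seam_state",
    "moving_average",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion.

    With explicit amide hydrogens the gate is the D–H···A angle at H
    (default >= 150°); without them the fallback gate is the N···O=C
    angle at the acceptor oxygen (default >= 120°).
    """

    donor_acceptor_max: float = 3.5   # Å, N···O
    angle_min: float | None = None    # degrees; resolved per H availability
    use_explicit_H: bool = False

    def __post_init__(self) -> None:
        if self.donor_acceptor_max <= 0:
            raise ParameterError("donor_acceptor_max must be positive")
        if self.angle_min is not None and not (0 < self.angle_min <= 180):
            raise ParameterError("angle_min must lie in (0, 180]")

    @property
    def resolved_angle_min(self) -> float:
        if self.angle_min is not None:
            return self.angle_min
        return 150.0 if self.use_explicit_H else 120.0


class HBond(NamedTuple):
    donor_chain: str
    donor_residue: int
    acceptor_chain: str
    acceptor_residue: int
    distance: float   # N···O, Å
    angle: float      # gate angle, degrees


@dataclass
class HBondSeries:
    """Per-frame bond counts with a centered moving average."""

    times: np.ndarray
    counts: np.ndarray
    window: int
    smoothed: np.ndarray
    bonds_per_frame: list[list[HBond]]
    min_contact: np.ndarray = field(default=None)  # min cross-strand N···O per frame, Å

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "count": self.counts,
                             "smoothed": self.smoothed})


def _residue_table(model: StructureModel, entry: SelectionEntry, coords: np.ndarray):
    """Per-residue backbone atom indices within a strand selection."""
    table: dict[tuple[str, int, str], dict[str, int]] = {}
    for i, atom in enumerate(model.atoms):
        in_chain = entry.chain_id is None or atom.chain_id == entry.chain_id
        in_range = entry.residue_ranges is None or any(
            lo <= atom.residue_number <= hi for lo, hi in entry.residue_ranges)
        amide_h = in_chain and in_range and atom.name in ("H", "HN")
        if not (entry.matches(atom) or amide_h):
            continue
        rkey = (atom.chain_id, atom.residue_number, atom.insertion_code)
        table.setdefault(rkey, {})[atom.name] = i
    if not table:
        raise SelectionError(f"{entry.describe()} matches no residue")
    return table


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    if denom < 1e-12:
        return 0.0
    cosang = np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _directed_bonds(donors, acceptors, coords, criteria: HBondCriteria) -> list[HBond]:
    """Each donor N matched to its nearest satisfying acceptor O."""
    bonds = []
    angle_min = criteria.resolved_angle_min
    for (dchain, dres, _dic), datoms in donors.items():
        if "N" not in datoms:
            continue
        if criteria.use_explicit_H and not ({"H", "HN"} & datoms.keys()):
            raise SelectionError(
                f"residue {dchain}/{dres}: explicit amide H required but absent")
        n_pos = coords[datoms["N"]]
        h_pos = None
        if criteria.use_explicit_H:
            h_pos = coords[datoms.get("H", datoms.get("HN"))]
        best = None
        for (achain, ares, _aic), aatoms in acceptors.items():
            if "O" not in aatoms or "C" not in aatoms:
                continue
            o_pos = coords[aatoms["O"]]
            dist = float(np.linalg.norm(n_pos - o_pos))
            if dist > criteria.donor_acceptor_max:
                continue
            if criteria.use_explicit_H:
                ang = _angle_deg(n_pos, h_pos, o_pos)   # D–H···A at H
            else:
                ang = _angle_deg(n_pos, o_pos, coords[aatoms["C"]])  # N···O=C at O
            if ang < angle_min:
                continue
            if best is None or dist < best[0]:
                best = (dist, ang, achain, ares)
        if best is not None:
            dist, ang, achain, ares = best
            bonds.append(HBond(dchain, dres, achain, ares, dist, ang))
    return bonds


def detect_backbone_hbonds(model: StructureModel, seam1: SelectionEntry,
                           seam16: SelectionEntry,
                           criteria: HBondCriteria = HBondCriteria(),
                           coords: np.ndarray | None = None) -> list[HBond]:
    """Inter-strand backbone hydrogen bonds, both donor directions.

    Bonds are counted strand1-donor→strand16-acceptor and vice versa;
    each donor is matched to at most one (nearest satisfying) acceptor.
    """
    if coords is None:
        coords = model.coords()
    table1 = _residue_table(model, seam1, coords)
    table16 = _residue_table(model, seam16, coords)
    return (_directed_bonds(table1, table16, coords, criteria)
            + _directed_bonds(table16, table1, coords, criteria))


def min_seam_contact(model: StructureModel, seam1: SelectionEntry,
                     seam16: SelectionEntry,
                     coords: np.ndarray | None = None) -> float:
    """Minimum cross-strand N···O distance (either direction), Å."""
    if coords is None:
        coords = model.coords()
    t1 = _residue_table(model, seam1, coords)
    t16 = _residue_table(model, seam16, coords)

    def _pts(table, name):
        idx = [atoms[name] for atoms in table.values() if name in atoms]
        return coords[idx] if idx else np.empty((0, 3))

    best = np.inf
    for donors, acceptors in ((t1, t16), (t16, t1)):
        n = _pts(donors, "N")
        o = _pts(acceptors, "O")
        if len(n) and len(o):
            d = np.linalg.norm(n[:, None, :] - o[None, :, :], axis=2)
            best = min(best, float(d.min()))
    return best


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def hbond_series(traj: Trajectory, selection: ComplexSelection,
                 criteria: HBondCriteria = HBondCriteria(),
                 window: int = 51) -> HBondSeries:
    """Per-frame seam H-bond counts plus centered moving average."""
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    counts = np.empty(traj.n_frames, dtype=int)
    contacts = np.empty(traj.n_frames)
    bonds_all: list[list[HBond]] = []
    top = traj.topology
    for f in range(traj.n_frames):
        bonds = detect_backbone_hbonds(top, selection.seam_strand_1,
                                       selection.seam_strand_16, criteria,
                                       coords=traj.frames[f])
        bonds_all.append(bonds)
        counts[f] = len(bonds)
        contacts[f] = min_seam_contact(top, selection.seam_strand_1,
                                       selection.seam_strand_16,
                                       coords=traj.frames[f])
    smoothed = moving_average(counts, window)
    return HBondSeries(times=np.array(traj.times), counts=counts, window=window,
                       smoothed=smoothed, bonds_per_frame=bonds_all,
                       min_contact=contacts)


def classify_seam_state(series: HBondSeries, closed_min: float = 2.0,
                        open_max: float = 1.0,
                        contact_max: float | None = None) -> np.ndarray:
    """Label each frame open / tenuous / closed.

    A frame is *closed* when the smoothed count is >= ``closed_min``;
    *open* when the smoothed count is below ``open_max`` **and** no
    cross-strand N···O pair lies within ``contact_max`` (default: the
    detection distance cutoff); anything else — few bonds but persisting
    contact — is *tenuous*.
    """
    if open_max > closed_min:
        raise ParameterError("open_max must be <= closed_min")
    if contact_max is None:
        contact_max = HBondCriteria().donor_acceptor_max
    if series.min_contact is None:
        raise ParameterError("series carries no contact distances")
    labels = np.empty(len(series.smoothed), dtype=object)
    for i, (s, c) in enumerate(zip(series.smoothed, series.min_contact)):
        if s >= closed_min:
            labels[i] = "closed"
        elif s < open_max and c > contact_max:
            labels[i] = "open"
        else:
            labels[i] = "tenuous"
    return labels
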