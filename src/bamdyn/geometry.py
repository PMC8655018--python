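"""Geometric primitives: selections, centers, membrane frames, superposition.

The BAM-specific defaults follow the author numbering shared by the
deposited structures: the BamA barrel spans residues 425–810, POTRA5
344–421, and the lateral seam strands β1/β16 default to 424–435 and
800–810.  All selections are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FrameError, PairingError, ParameterError, SelectionError
from .structio import Atom, StructureModel

__all__ = [
    "SelectionEntry",
    "ComplexSelection",
    "MembraneFrame",
    "RigidTransform",
    "select_atoms",
    "select_indices",
    "geometric_center",
    "membrane_frame",
    "barrel_in_plane_diameter",
    "kabsch_superpose",
    "rmsd_between_models",
]

ATOM_CLASSES = {
    "carbonyl_C": ("C",),
    "CA": ("CA",),
    "CB": ("CB",),
    "backbone": ("N", "CA", "C", "O"),
    "all": None,
}


@dataclass(frozen=True)
class SelectionEntry:
    """One named selection: a chain, residue ranges, and an atom class.

    ``chain_id`` of None matches any chain; ``residue_ranges`` of None
    matches all residues.  Ranges are inclusive on both ends and match by
    plain author residue number (any insertion code).
    """

    chain_id: str | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_class: str = "CA"
    name: str = ""

    def __post_init__(self) -> None:
        if self.atom_class not in ATOM_CLASSES:
            raise ParameterError(
                f"unknown atom class {self.atom_class!r}; choose from {sorted(ATOM_CLASSES)}"
            )

    def matches(self, atom: Atom) -> bool:
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.residue_ranges is not None:
            if not any(lo <= atom.residue_number <= hi for lo, hi in self.residue_ranges):
                return False
        names = ATOM_CLASSES[self.atom_class]
        return names is None or atom.name in names

    def describe(self) -> str:
        chain = self.chain_id or "*"
        if self.residue_ranges is None:
            ranges = "*"
        else:
            ranges = ",".join(f"{lo}-{hi}" for lo, hi in self.residue_ranges)
        return f"{self.name or 'selection'}(chain {chain}, residues {ranges}, {self.atom_class})"


def _entry(chain, lo, hi, atom_class, name) -> SelectionEntry:
    return SelectionEntry(chain, ((lo, hi),), atom_class, name)


@dataclass
class ComplexSelection:
    """Named selections for a BAM-like complex.

    ``accessory`` maps component names (BamB…BamE) to chain selections and
    may be empty for single-protein systems.
    """

    barrel: SelectionEntry = field(
        default_factory=lambda: _entry("A", 425, 810, "carbonyl_C", "barrel"))
    accessory: dict[str, SelectionEntry] = field(default_factory=lambda: {
        "BamB": SelectionEntry("B", None, "carbonyl_C", "BamB"),
        "BamC": SelectionEntry("C", None, "carbonyl_C", "BamC"),
        "BamD": SelectionEntry("D", None, "carbonyl_C", "BamD"),
        "BamE": SelectionEntry("E", None, "carbonyl_C", "BamE"),
    })
    potra5: SelectionEntry = field(
        default_factory=lambda: _entry("A", 344, 421, "CA", "POTRA5"))
    seam_strand_1: SelectionEntry = field(
        default_factory=lambda: _entry("A", 424, 435, "backbone", "beta1"))
    seam_strand_16: SelectionEntry = field(
        default_factory=lambda: _entry("A", 800, 810, "backbone", "beta16"))

    def barrel_as(self, atom_class: str) -> SelectionEntry:
        return replace(self.barrel, atom_class=atom_class)


def select_indices(model: StructureModel, entry: SelectionEntry,
                   required: bool = True) -> np.ndarray:
    """Indices (in model order) of atoms matched by ``entry``."""
    idx = np.array([i for i, a in enumerate(model.atoms) if entry.matches(a)], dtype=int)
    if required and len(idx) == 0:
        raise SelectionError(f"{entry.describe()} matches no atom in "
                             f"{model.identifier or 'model'}")
    return idx


def select_atoms(model: StructureModel, entry: SelectionEntry) -> list[Atom]:
    """Atoms matched by ``entry``, in model order; errors when empty."""
    return [model.atoms[i] for i in select_indices(model, entry)]


def geometric_center(atoms_or_coords) -> np.ndarray:
    """Unweighted mean position of a set of atoms or an (N, 3) array."""
    if isinstance(atoms_or_coords, np.ndarray):
        coords = atoms_or_coords
    else:
        coords = np.array([a.position for a in atoms_or_coords], dtype=float)
    if coords.size == 0:
        raise SelectionError("geometric center of an empty atom set")
    return coords.reshape(-1, 3).mean(axis=0)


@dataclass(frozen=True)
class MembraneFrame:
    """Right-handed orthonormal triad with ``normal`` pointing extracellular."""

    origin: np.ndarray
    normal: np.ndarray
    in_plane_x: np.ndarray
    in_plane_y: np.ndarray

    @classmethod
    def from_normal(cls, origin: np.ndarray, normal: np.ndarray) -> "MembraneFrame":
        normal = np.asarray(normal, dtype=float)
        n = np.linalg.norm(normal)
        if n < 1e-12:
            raise FrameError("zero-length membrane normal")
        normal = normal / n
        # deterministic in-plane axis: project the lab axis least aligned with normal
        seed = np.eye(3)[np.argmin(np.abs(normal))]
        x = seed - np.dot(seed, normal) * normal
        x /= np.linalg.norm(x)
        y = np.cross(normal, x)
        return cls(np.asarray(origin, dtype=float), normal, x, y)

    def project_in_plane(self, vec: np.ndarray) -> np.ndarray:
        """2-vector of components along (in_plane_x, in_plane_y)."""
        return np.array([np.dot(vec, self.in_plane_x), np.dot(vec, self.in_plane_y)])


def _principal_axes(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)  # ascending variance
    return evals, evecs


def membrane_frame(model: StructureModel, selection: ComplexSelection,
                   mode: str = "z_axis") -> MembraneFrame:
    """Membrane frame centered on the barrel.

    ``z_axis`` takes the input +z as extracellular (the MD convention of
    membrane-aligned systems).  ``barrel_principal`` derives the normal
    from the barrel's principal axes: the axis best aligned with the
    direction from the periplasmic anchor (POTRA5 center, else accessory
    centers) to the barrel center, sign-fixed to point away from the
    periplasm.  Without a periplasmic anchor the smallest-variance axis
    is used with its raw sign.
    """
    barrel_coords = np.array(
        [model.atoms[i].position for i in select_indices(model, selection.barrel)])
    origin = barrel_coords.mean(axis=0)
    if mode == "z_axis":
        return MembraneFrame.from_normal(origin, np.array([0.0, 0.0, 1.0]))
    if mode != "barrel_principal":
        raise ParameterError(f"unknown frame mode {mode!r}")

    evals, evecs = _principal_axes(barrel_coords)
    if evals[1] < 1e-9 * max(evals[2], 1.0):
        raise FrameError("barrel atoms are (near-)collinear; no plane defined")

    peri = _periplasmic_center(model, selection)
    if peri is None:
        normal = evecs[:, 0]  # smallest variance
    else:
        up = origin - peri
        align = np.abs(evecs.T @ up)
        normal = evecs[:, int(np.argmax(align))]
        if np.dot(normal, up) < 0:
            normal = -normal
    return MembraneFrame.from_normal(origin, normal)


def _periplasmic_center(model: StructureModel, selection: ComplexSelection):
    coords = []
    try:
        idx = select_indices(model, selection.potra5)
        coords.append(np.array([model.atoms[i].position for i in idx]).mean(axis=0))
    except SelectionError:
        pass
    if not coords:
        for entry in selection.accessory.values():
            try:
                idx = select_indices(model, entry)
            except SelectionError:
                continue
            coords.append(np.array([model.atoms[i].position for i in idx]).mean(axis=0))
    if not coords:
        return None
    return np.mean(coords, axis=0)


def barrel_in_plane_diameter(model: StructureModel, selection: ComplexSelection,
                             mode: str = "barrel_principal",
                             atom_class: str = "CA") -> float:
    """Longest in-plane extent of the barrel (Å).

    Barrel atoms are projected onto the membrane plane and the maximum
    pairwise distance of the projections is returned — the "~5 nm along
    the longest axis" style of measurement for an elliptical barrel.
    """
    frame = membrane_frame(model, selection, mode=mode)
    entry = replace(selection.barrel, atom_class=atom_class)
    coords = np.array([model.atoms[i].position
                       for i in select_indices(model, entry)])
    rel = coords - frame.origin
    proj = np.column_stack([rel @ frame.in_plane_x, rel @ frame.in_plane_y])
    d = np.linalg.norm(proj[:, None, :] - proj[None, :, :], axis=2)
    return float(d.max())


# ---------------------------------------------------------------------------
# superposition

@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation mapping mobile onto reference."""

    rotation: np.ndarray      # (3, 3)
    translation: np.ndarray   # (3,)
    rmsd: float               # post-fit, Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _as_coords(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return np.asarray(x, dtype=float)
    return np.array([a.position for a in x], dtype=float)


def kabsch_superpose(reference, mobile) -> RigidTransform:
    """Least-squares rigid superposition (Kabsch), paired by order.

    Returns the proper rotation + translation minimizing the RMSD of the
    mobile set onto the reference, and that post-fit RMSD.
    """
    ref = _as_coords(reference)
    mob = _as_coords(mobile)
    if ref.shape != mob.shape:
        raise PairingError(f"atom count mismatch: reference {len(ref)}, mobile {len(mob)}")
    if len(ref) < 3:
        raise PairingError(f"need >= 3 paired atoms, got {len(ref)}")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    h = (mob - mob_c).T @ (ref - ref_c)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref_c - rot @ mob_c
    fitted = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return RigidTransform(rot, trans, rmsd)


@dataclass(frozen=True)
class RMSDResult:
    rmsd: float
    n_paired: int
    transform: RigidTransform


def rmsd_between_models(a: StructureModel, b: StructureModel,
                        entry: SelectionEntry,
                        pairing: str = "by_residue_and_name") -> RMSDResult:
    """Kabsch RMSD over atoms common to both models under ``entry``.

    Atoms are paired by (chain, residue number, insertion code, atom
    name); residues absent from either model simply drop out of the
    intersection.
    """
    if pairing != "by_residue_and_name":
        raise ParameterError(f"unknown pairing {pairing!r}")
    atoms_a = select_atoms(a, entry)
    lookup_b = {at.key: at for at in select_atoms(b, entry)}
    pairs = [(at.position, lookup_b[at.key].position) for at in atoms_a if at.key in lookup_b]
    if len(pairs) < 3:
        raise PairingError(
            f"only {len(pairs)} common atoms under {entry.describe()}; need >= 3")
    ref = np.array([p[0] for p in pairs])
    mob = np.array([p[1] for p in pairs])
    tr = kabsch_superpose(ref, mob)
    return RMSDResult(tr.rmsd, len(pairs), tr)
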