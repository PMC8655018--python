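"""Structure, trajectory, time-series and 2D-map I/O.

Structures are read from PDB or mmCIF with gemmi and exposed as plain
:class:`Atom`/:class:`StructureModel` records; trajectories use the
multi-model PDB convention (one MODEL/ENDMDL block per frame).  All
coordinates are in Å and all times in ns.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .errors import CongruenceError, EmptyInputError, FormatError, ParameterError

__all__ = [
    "Atom",
    "StructureModel",
    "Trajectory",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_timeseries",
    "read_timeseries",
    "write_map2d",
    "read_map2d",
]


@dataclass
class Atom:
    """One atom record.

    ``residue_number`` keeps the author numbering exactly as read; an
    insertion code, when present, is carried separately so selections by
    plain integer match any insertion code.
    """

    serial: int
    name: str
    residue_name: str
    residue_number: int
    chain_id: str
    element: str
    position: np.ndarray
    insertion_code: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ParameterError(
                f"atom {self.chain_id}/{self.residue_number}/{self.name}: "
                "position must be a finite 3-vector"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_number, self.insertion_code, self.name)


@dataclass
class StructureModel:
    """An ordered list of atoms with an identifier and model index."""

    atoms: list[Atom]
    identifier: str = ""
    model_index: int = 1

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in atom order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, model_index: int | None = None) -> "StructureModel":
        """Copy of this model with new coordinates, same atom identities."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise CongruenceError(
                f"coordinate array of shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [
            Atom(a.serial, a.name, a.residue_name, a.residue_number, a.chain_id,
                 a.element, c, a.insertion_code, a.occupancy, a.is_hetero)
            for a, c in zip(self.atoms, coords)
        ]
        return StructureModel(atoms, self.identifier,
                              self.model_index if model_index is None else model_index)


@dataclass
class Trajectory:
    """Frames sharing one topology.

    ``frames`` has shape (n_frames, n_atoms, 3); ``times`` is in ns and
    strictly increasing.  ``metadata`` carries generator provenance such
    as ground-truth schedules.
    """

    topology: StructureModel
    frames: np.ndarray
    times: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise CongruenceError(f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[1] != len(self.topology):
            raise CongruenceError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{len(self.topology)}"
            )
        if len(self.times) != len(self.frames):
            raise CongruenceError(
                f"{len(self.times)} time stamps for {len(self.frames)} frames"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_model(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.frames[i], model_index=i + 1)


# ---------------------------------------------------------------------------
# structure reading

def _convert_gemmi_model(model: gemmi.Model, identifier: str, index: int) -> StructureModel:
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            # resolve alternate locations: highest occupancy, ties to first listed
            groups: dict[str, list[gemmi.Atom]] = {}
            order: list[str] = []
            for at in res:
                if at.name not in groups:
                    groups[at.name] = []
                    order.append(at.name)
                groups[at.name].append(at)
            for name in order:
                cands = groups[name]
                best = max(cands, key=lambda a: a.occ)  # max() keeps first on ties
                icode = res.seqid.icode.strip()
                atoms.append(Atom(
                    serial=best.serial,
                    name=name,
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    chain_id=chain.name,
                    element=best.element.name,
                    position=np.array([best.pos.x, best.pos.y, best.pos.z]),
                    insertion_code=icode,
                    occupancy=best.occ,
                    is_hetero=(res.het_flag == "H"),
                ))
    return StructureModel(atoms, identifier=identifier, model_index=index)


def _read_gemmi(path: str | Path, format: str) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif format == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ParameterError(f"unknown structure format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    return st


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read the first model of a PDB/mmCIF file.

    Alternate locations are resolved to the highest-occupancy conformer
    (first listed on ties).  Raises :class:`FormatError` on parse failure
    and :class:`EmptyInputError` when no atoms with coordinates are found.
    """
    st = _read_gemmi(path, format)
    if len(st) == 0:
        raise EmptyInputError(f"{path}: no models")
    model = _convert_gemmi_model(st[0], identifier=st.name or Path(path).stem, index=1)
    if len(model) == 0:
        raise EmptyInputError(f"{path}: model contains no atoms")
    return model


def read_trajectory(path: str | Path, topology: StructureModel | None = None,
                    dt_ns: float = 1.0, t0_ns: float = 0.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory (one frame per MODEL).

    When ``topology`` is given each frame's atom count must match it;
    otherwise the first model becomes the topology.  Frame times are
    ``t0_ns + i * dt_ns`` (the PDB format carries no time stamps).
    """
    st = _read_gemmi(path, "auto")
    if len(st) == 0:
        raise EmptyInputError(f"{path}: no models")
    models = [_convert_gemmi_model(m, identifier=st.name or Path(path).stem, index=i + 1)
              for i, m in enumerate(st)]
    top = topology if topology is not None else models[0]
    frames = []
    for m in models:
        if len(m) != len(top):
            raise CongruenceError(
                f"frame {m.model_index} has {len(m)} atoms, topology has {len(top)}"
            )
        frames.append(m.coords())
    times = t0_ns + dt_ns * np.arange(len(frames))
    return Trajectory(top, np.array(frames), times)


# ---------------------------------------------------------------------------
# structure writing

def _to_gemmi(models: list[StructureModel], identifier: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = identifier
    for i, model in enumerate(models):
        gm = gemmi.Model(str(i + 1))
        cur_chain = None
        cur_res = None
        cur_res_key = None
        for a in model.atoms:
            if cur_chain is None or cur_chain.name != a.chain_id:
                cur_chain = gemmi.Chain(a.chain_id)
                gm.add_chain(cur_chain)
                cur_chain = gm[-1]
                cur_res_key = None
            key = (a.residue_number, a.insertion_code, a.residue_name)
            if key != cur_res_key:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
                res.het_flag = "H" if a.is_hetero else "A"
                cur_chain.add_residue(res)
                cur_res = cur_chain[-1]
                cur_res_key = key
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element or a.name[:1])
            ga.pos = gemmi.Position(*a.position)
            ga.occ = a.occupancy
            ga.serial = a.serial
            cur_res.add_atom(ga)
        st.add_model(gm)
    return st


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a single-model PDB file."""
    _to_gemmi([model], model.identifier).write_pdb(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL per frame)."""
    models = [traj.frame_model(i) for i in range(traj.n_frames)]
    _to_gemmi(models, traj.topology.identifier).write_pdb(str(path))


# ---------------------------------------------------------------------------
# time-series tables

def write_timeseries(series, path: str | Path) -> None:
    """Write any per-frame series (object exposing ``to_dataframe``) as CSV.

    The table has a header row starting with ``time_ns`` and one row per
    frame; decimal points are locale-independent.
    """
    if hasattr(series, "to_dataframe"):
        df = series.to_dataframe()
    elif isinstance(series, pd.DataFrame):
        df = series
    else:
        raise ParameterError(f"cannot serialize {type(series).__name__} as a time series")
    if len(df) == 0:
        raise EmptyInputError("refusing to write an empty time series")
    if df.columns[0] != "time_ns":
        raise ParameterError("first column of a time series must be time_ns")
    df.to_csv(path, index=False, float_format="%.8g")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# 2D density maps (MRC2014 mode-2, npz, or text grid)

_MRC_HEADER_BYTES = 1024


def _write_mrc2d(values: np.ndarray, pixel_size: float, path: Path) -> None:
    ny, nx = values.shape
    data = values.astype("<f4")
    header = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<3i", header, 0, nx, ny, 1)            # nx ny nz
    struct.pack_into("<i", header, 12, 2)                     # mode 2: float32
    struct.pack_into("<3i", header, 28, nx, ny, 1)            # mx my mz
    struct.pack_into("<3f", header, 40, nx * pixel_size, ny * pixel_size, pixel_size)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)     # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)              # mapc mapr maps
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<i", header, 88, 1)                     # ispg
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0, 0])               # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def _read_mrc2d(path: Path) -> tuple[np.ndarray, float]:
    with open(path, "rb") as fh:
        header = fh.read(_MRC_HEADER_BYTES)
        if header[208:212] != b"MAP ":
            raise FormatError(f"{path}: missing MRC 'MAP ' stamp")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        mode, = struct.unpack_from("<i", header, 12)
        if mode != 2 or nz != 1:
            raise FormatError(f"{path}: only 2D mode-2 (float32) maps supported")
        cella_x, = struct.unpack_from("<f", header, 40)
        pixel = cella_x / nx if nx else 1.0
        values = np.frombuffer(fh.read(4 * nx * ny), dtype="<f4").reshape(ny, nx)
    return values.astype(float), float(pixel)


def write_map2d(map2d, path: str | Path, format: str = "mrc") -> None:
    """Write a 2D density map as ``mrc``, ``npz`` or ``text``.

    The map object must expose ``values`` (square 2D array) and
    ``pixel_size`` (Å/px).  Pixel size is recorded in the header (mrc),
    as an array entry (npz) or as a comment line (text); values survive
    the round trip at 32-bit float precision.
    """
    values = np.asarray(map2d.values, dtype=float)
    pixel = float(map2d.pixel_size)
    if values.ndim != 2 or 0 in values.shape:
        raise ParameterError(f"map grid must be 2D and non-empty, got shape {values.shape}")
    if pixel <= 0:
        raise ParameterError(f"pixel size must be positive, got {pixel}")
    path = Path(path)
    if format == "mrc":
        _write_mrc2d(values, pixel, path)
    elif format == "npz":
        np.savez(path, values=values.astype(np.float32), pixel_size=pixel)
    elif format == "text":
        np.savetxt(path, values, fmt="%.8e", header=f"pixel_size_A {pixel:.8g}")
    else:
        raise ParameterError(f"unknown map format {format!r}")


def read_map2d(path: str | Path, format: str = "auto"):
    """Read a 2D map written by :func:`write_map2d`; returns a DensityMap2D."""
    from .nanodisc_density import DensityMap2D

    path = Path(path)
    if format == "auto":
        suffix = path.suffix.lower()
        format = {".mrc": "mrc", ".map": "mrc", ".npz": "npz"}.get(suffix, "text")
    if format == "mrc":
        values, pixel = _read_mrc2d(path)
    elif format == "npz":
        with np.load(path) as data:
            values = data["values"].astype(float)
            pixel = float(data["pixel_size"])
    elif format == "text":
        pixel = 1.0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#") and "pixel_size_A" in first:
                pixel = float(first.split()[-1])
        values = np.loadtxt(path)
    else:
        raise ParameterError(f"unknown map format {format!r}")
    return DensityMap2D(values=values, pixel_size=pixel)
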