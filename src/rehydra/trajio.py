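"""Data model and I/O for structures, trajectories and replica sets.

Internal conventions: lengths in Å (PDB native), times in ps, 0-based
residue indexing.  Multi-model PDB is the reference on-disk trajectory
format; parsing and writing are delegated to :mod:`biotite`, with
pre-validation supplying line- and model-numbered error messages.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "Condition",
    "ReplicaSet",
    "RadiiTable",
    "Window",
    "ParseError",
    "SelectionError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select_atoms",
    "frames_in_window",
]

#: residue names recognised as water/solvent (extendable per call)
SOLVENT_RESNAMES = frozenset({"HOH", "SOL", "WAT", "TIP4"})

_SELECTION_NAMES = ("protein", "calpha", "heavy", "solvent", "all")


class ParseError(ValueError):
    """A structure or trajectory file violated the expected format."""


class SelectionError(ValueError):
    """An atom selection could not be resolved on a topology."""


@dataclass(frozen=True)
class Atom:
    """One atom of a topology.

    ``residue_index`` is the 0-based internal index; author numbering is a
    display concern handled at the report layer.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain: str = "A"
    is_solvent: bool = False


class Topology:
    """Ordered atom list partitioned into residues.

    Residues follow file/sequence order; their atom ranges partition the
    atom list contiguously.
    """

    def __init__(self, atoms: Sequence[Atom]):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("topology needs at least one atom")
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a topology")
        self.atoms: list[Atom] = atoms
        # residue ranges: consecutive runs of residue_index
        residues: list[tuple[str, int, int]] = []
        start = 0
        for i in range(1, len(atoms) + 1):
            if i == len(atoms) or atoms[i].residue_index != atoms[start].residue_index:
                residues.append((atoms[start].residue_name, start, i))
                start = i
        self.residues: list[tuple[str, int, int]] = residues

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def protein_residue_indices(self) -> list[int]:
        """Indices (into ``self.residues``) of non-solvent residues."""
        return [
            i
            for i, (_, start, _) in enumerate(self.residues)
            if not self.atoms[start].is_solvent
        ]

    def residue_atom_indices(self, residue: int) -> np.ndarray:
        _, start, stop = self.residues[residue]
        return np.arange(start, stop)

    def residue_labels(self, protein_only: bool = True) -> list[str]:
        idx = self.protein_residue_indices if protein_only else range(self.n_residues)
        return [f"{self.residues[i][0]}{i}" for i in idx]

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    def __len__(self) -> int:
        return self.n_atoms

    def __eq__(self, other) -> bool:
        return isinstance(other, Topology) and self.atoms == other.atoms


@dataclass
class Frame:
    """Coordinates (n_atoms × 3, Å) at one time point (ps)."""

    coordinates: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n_atoms, 3) array")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")


class Trajectory:
    """An ordered sequence of frames sharing one topology."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        for k, f in enumerate(frames):
            if f.coordinates.shape[0] != topology.n_atoms:
                raise ValueError(
                    f"frame {k} has {f.coordinates.shape[0]} atoms, "
                    f"topology has {topology.n_atoms}"
                )
        times = np.array([f.time for f in frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.topology = topology
        self.frames: list[Frame] = frames

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinate_stack(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) array of all coordinates."""
        return np.stack([f.coordinates for f in self.frames])

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, k: int) -> Frame:
        return self.frames[k]


@dataclass(frozen=True)
class Condition:
    """Simulation condition: phase plus electric-field strength (V/nm).

    ``field`` is None for solution (no gas-phase field applies).
    """

    phase: str  # solution | vacuum | rehydration
    field: float | None = None

    _PHASES = ("solution", "vacuum", "rehydration")

    def __post_init__(self):
        if self.phase not in self._PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {self._PHASES}")
        if self.phase != "solution" and self.field is None:
            raise ValueError(f"{self.phase} condition requires a field strength")

    @classmethod
    def parse(cls, label: str) -> "Condition":
        """Parse labels like ``solution``, ``vacuum@0.2``, ``rehydration@0.0``."""
        if "@" in label:
            phase, f = label.split("@", 1)
            return cls(phase.strip(), float(f))
        return cls(label.strip(), None)

    def __str__(self) -> str:
        if self.field is None:
            return self.phase
        return f"{self.phase}@{self.field:g}"


class ReplicaSet:
    """N replica trajectories of one system under one condition.

    The study design this mirrors uses five replicas per protein and
    condition; the count is free here but all replicas must share a
    topology.
    """

    def __init__(self, condition: Condition, replicas: Sequence[Trajectory]):
        replicas = list(replicas)
        if not replicas:
            raise ValueError("replica set needs at least one replica")
        topo = replicas[0].topology
        for r, t in enumerate(replicas):
            if t.topology.n_atoms != topo.n_atoms:
                raise ValueError(f"replica {r} topology differs in atom count")
        self.condition = condition
        self.replicas: list[Trajectory] = replicas

    @property
    def topology(self) -> Topology:
        return self.replicas[0].topology

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def __iter__(self):
        return iter(self.replicas)

    def __len__(self) -> int:
        return self.n_replicas


# ---------------------------------------------------------------------------
# van der Waals radii


class RadiiTable:
    """Element → van der Waals radius (Å) mapping.

    The default is a Bondi-style set covering the elements that occur in
    proteins and water; it is shared by the CCS, SASA and volume
    calculations (the projection approximation uses plain vdW spheres).
    """

    DEFAULT = {
        "H": 1.20,
        "C": 1.70,
        "N": 1.55,
        "O": 1.52,
        "S": 1.80,
        "P": 1.80,
        "F": 1.47,
        "CL": 1.75,
        "BR": 1.85,
        "I": 1.98,
    }

    def __init__(self, radii: dict[str, float] | None = None):
        table = dict(self.DEFAULT)
        if radii:
            table.update({k.upper(): float(v) for k, v in radii.items()})
        for el, r in table.items():
            if r <= 0:
                raise ValueError(f"radius for {el} must be positive, got {r}")
        self._table = table

    @classmethod
    def from_json(cls, path: str | Path) -> "RadiiTable":
        with open(path) as fh:
            return cls(json.load(fh))

    def __getitem__(self, element: str) -> float:
        try:
            return self._table[element.upper()]
        except KeyError:
            raise KeyError(f"no van der Waals radius for element {element!r}") from None

    def __contains__(self, element: str) -> bool:
        return element.upper() in self._table

    def assign(self, topology: Topology, selection=None) -> np.ndarray:
        """Radii for the selected atoms (all atoms by default)."""
        idx = (
            np.arange(topology.n_atoms)
            if selection is None
            else select_atoms(topology, selection)
        )
        radii = np.empty(len(idx))
        for k, i in enumerate(idx):
            el = topology.atoms[i].element
            if not el:
                raise ValueError(f"atom serial {topology.atoms[i].serial} has no element")
            radii[k] = self[el]
        return radii


# ---------------------------------------------------------------------------
# PDB reading / writing

_COORD_SLICES = (slice(30, 38), slice(38, 46), slice(46, 54))


def _infer_element(atom_name: str, resname: str) -> str:
    """Element from a PDB atom name when columns 77–78 are absent.

    Handles leading digits (``1HB``) and two-letter guesses only for
    elements that actually occur in protein/water systems; anything
    unrecognised is a hard error rather than a silent carbon.
    """
    name = atom_name.strip()
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {atom_name!r}")
    head = stripped[:2].upper()
    if head in ("CL", "BR", "FE", "ZN", "MG", "NA") and len(name) == 4:
        return head
    first = stripped[0].upper()
    if first in "HCNOSPF":
        return first
    raise ParseError(f"cannot infer element from atom name {atom_name!r}")


def _prescan_pdb(text: str, path: str) -> list[int]:
    """Validate ATOM/HETATM records; return atom counts per MODEL block.

    Raises ParseError with a 1-based line number for malformed records.
    For single-model files the returned list has one entry.
    """
    counts: list[int] = []
    in_model = False
    current = 0
    seen_any_atom = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if in_model:
                raise ParseError(f"{path}: line {lineno}: nested MODEL record")
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            if not in_model:
                raise ParseError(f"{path}: line {lineno}: ENDMDL without MODEL")
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise ParseError(
                    f"{path}: line {lineno}: truncated {rec} record "
                    f"({len(line)} < 54 columns)"
                )
            for sl in _COORD_SLICES:
                try:
                    float(line[sl])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: unparseable coordinate field "
                        f"{line[sl]!r}"
                    ) from None
            current += 1
            seen_any_atom = True
    if in_model:
        counts.append(current)  # tolerate missing final ENDMDL
    if not counts:
        if not seen_any_atom:
            raise ParseError(f"{path}: no ATOM/HETATM records found")
        counts = [current]
    return counts


def _topology_from_atom_array(arr: AtomArray, solvent_names: frozenset[str]) -> Topology:
    atoms = []
    res_index = -1
    prev_key = None
    for i in range(arr.array_length()):
        key = (arr.chain_id[i], arr.res_id[i], arr.res_name[i])
        if key != prev_key:
            res_index += 1
            prev_key = key
        resname = str(arr.res_name[i]).strip()
        element = str(arr.element[i]).strip()
        name = str(arr.atom_name[i]).strip()
        if not element:
            element = _infer_element(name, resname)
        atoms.append(
            Atom(
                serial=i + 1,
                name=name,
                element=element.upper(),
                residue_index=res_index,
                residue_name=resname,
                chain=str(arr.chain_id[i]).strip() or "A",
                is_solvent=resname in solvent_names,
            )
        )
    return Topology(atoms)


def read_structure(
    path: str | Path,
    solvent_names: Iterable[str] = SOLVENT_RESNAMES,
) -> tuple[Topology, Frame]:
    """Read a single-model PDB file into a topology and one frame.

    Waters are flagged as solvent by residue name (HOH/SOL/WAT/TIP4 by
    default).  Elements come from PDB columns 77–78 when present, else
    from atom-name heuristics.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    _prescan_pdb(text, str(path))
    pdb = PDBFile.read(io.StringIO(text))
    arr = pdb.get_structure(model=1)
    topo = _topology_from_atom_array(arr, frozenset(n.upper() for n in solvent_names))
    return topo, Frame(np.asarray(arr.coord, dtype=float), time=0.0)


def read_trajectory(
    path: str | Path,
    topology: Topology | None = None,
    dt_ps: float = 1.0,
    times: Sequence[float] | None = None,
    solvent_names: Iterable[str] = SOLVENT_RESNAMES,
) -> Trajectory:
    """Read a multi-model PDB file as a trajectory.

    One frame per MODEL block.  PDB carries no time axis, so frame times
    are ``dt_ps * frame_index`` unless ``times`` is given explicitly.
    If ``topology`` is given, every model must match its atom count.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    counts = _prescan_pdb(text, str(path))
    expected = topology.n_atoms if topology is not None else counts[0]
    for m, c in enumerate(counts, start=1):
        if c != expected:
            raise ParseError(
                f"{path}: MODEL {m} has {c} atoms, expected {expected}"
            )
    pdb = PDBFile.read(io.StringIO(text))
    n_models = pdb.get_model_count()
    solvent = frozenset(n.upper() for n in solvent_names)
    frames = []
    topo = topology
    if times is not None and len(times) != n_models:
        raise ValueError(f"{len(times)} times given for {n_models} models")
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m)
        if topo is None:
            topo = _topology_from_atom_array(arr, solvent)
        t = times[m - 1] if times is not None else dt_ps * (m - 1)
        frames.append(Frame(np.asarray(arr.coord, dtype=float), time=t))
    return Trajectory(topo, frames)


def _atom_array_from(topology: Topology, coordinates: np.ndarray) -> AtomArray:
    n = topology.n_atoms
    arr = AtomArray(n)
    arr.coord = np.asarray(coordinates, dtype=np.float32)
    arr.chain_id = np.array([a.chain for a in topology.atoms])
    arr.res_id = np.array([a.residue_index + 1 for a in topology.atoms])
    arr.res_name = np.array([a.residue_name for a in topology.atoms])
    arr.atom_name = np.array([a.name for a in topology.atoms])
    arr.element = np.array([a.element for a in topology.atoms])
    arr.hetero = np.array([a.is_solvent for a in topology.atoms])
    return arr


def write_structure(path: str | Path, topology: Topology, frame: Frame) -> None:
    """Write one frame as a single-model PDB file."""
    pdb = PDBFile()
    pdb.set_structure(_atom_array_from(topology, frame.coordinates))
    pdb.write(str(path))


def write_trajectory(path: str | Path, trajectory: Trajectory) -> None:
    """Write a trajectory as a multi-model PDB file (one MODEL per frame)."""
    from biotite.structure import stack

    arrays = [
        _atom_array_from(trajectory.topology, f.coordinates) for f in trajectory.frames
    ]
    pdb = PDBFile()
    pdb.set_structure(stack(arrays))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# selections


def select_atoms(topology: Topology, selection) -> np.ndarray:
    """Resolve a selection to a sorted array of unique atom indices.

    ``selection`` is one of the predicate names ``protein``, ``calpha``,
    ``heavy``, ``solvent``, ``all`` or an explicit index collection.
    ``calpha`` requires exactly one CA atom per protein residue.
    """
    if selection is None:
        selection = "all"
    if not isinstance(selection, str):
        idx = np.unique(np.asarray(list(selection), dtype=int))
        if len(idx) and (idx[0] < 0 or idx[-1] >= topology.n_atoms):
            raise SelectionError(
                f"index selection out of bounds for {topology.n_atoms} atoms"
            )
        return idx
    if selection not in _SELECTION_NAMES:
        raise SelectionError(
            f"unknown selection {selection!r}; expected one of {_SELECTION_NAMES}"
        )
    atoms = topology.atoms
    if selection == "all":
        return np.arange(topology.n_atoms)
    if selection == "protein":
        return np.array([i for i, a in enumerate(atoms) if not a.is_solvent], dtype=int)
    if selection == "solvent":
        return np.array([i for i, a in enumerate(atoms) if a.is_solvent], dtype=int)
    if selection == "heavy":
        return np.array(
            [i for i, a in enumerate(atoms) if not a.is_solvent and a.element != "H"],
            dtype=int,
        )
    # calpha
    out = []
    missing = []
    for ri in topology.protein_residue_indices:
        ca = [
            i for i in topology.residue_atom_indices(ri) if atoms[i].name == "CA"
        ]
        if len(ca) != 1:
            missing.append(f"{topology.residues[ri][0]}{ri}")
        else:
            out.append(ca[0])
    if missing:
        raise SelectionError(
            f"calpha selection failed: residues without a unique CA atom: "
            f"{', '.join(missing)}"
        )
    return np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# time windows


@dataclass(frozen=True)
class Window:
    """Trailing analysis window: either the last ``last_ps`` picoseconds
    or the last ``last_fraction`` of the frames.

    The study convention is the final 50 ns of each 200 ns trajectory,
    i.e. ``Window(last_fraction=0.25)``.
    """

    last_ps: float | None = None
    last_fraction: float | None = None

    def __post_init__(self):
        if (self.last_ps is None) == (self.last_fraction is None):
            raise ValueError("specify exactly one of last_ps / last_fraction")
        if self.last_ps is not None and self.last_ps <= 0:
            raise ValueError("last_ps must be positive")
        if self.last_fraction is not None and not 0 < self.last_fraction <= 1:
            raise ValueError("last_fraction must be in (0, 1]")

    def frame_mask(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        n = len(times)
        if self.last_fraction is not None:
            keep = max(1, int(round(self.last_fraction * n)))
            mask = np.zeros(n, dtype=bool)
            mask[n - keep :] = True
            return mask
        span = times[-1] - times[0]
        dt = span / (n - 1) if n > 1 else self.last_ps
        if self.last_ps > span + dt + 1e-9:
            raise ValueError(
                f"window of {self.last_ps} ps exceeds trajectory span "
                f"({span + dt:g} ps)"
            )
        return times > times[-1] - self.last_ps


def frames_in_window(trajectory: Trajectory, window: Window) -> Trajectory:
    """View of the trailing frames selected by ``window``.

    A duration window keeps frames with time > t_end − duration; it is an
    error (not a clamp) for the window to exceed the trajectory span.
    """
    mask = window.frame_mask(trajectory.times)
    frames = [f for f, m in zip(trajectory.frames, mask) if m]
    return Trajectory(trajectory.topology, frames)
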