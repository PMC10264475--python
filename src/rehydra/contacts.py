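"""Residue-contact occupancy maps, difference maps, composite triangle
packing, and protein–solvent hydrogen-bond counting.

A residue–residue contact exists in a frame when any atom of one residue
(hydrogens included) is within 3.5 Å of any atom of the other, boundary
inclusive.  Occupancy is the fraction of pooled frames — all windowed
frames of all replicas — in which the contact exists.  Difference maps
subtract one condition's occupancy from another's: +1 marks contacts
present only in the first condition, −1 only in the second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from rehydra.trajio import (
    Frame,
    ReplicaSet,
    Topology,
    Window,
    frames_in_window,
    select_atoms,
)

__all__ = [
    "ContactMap",
    "DifferenceMap",
    "HBondCriterion",
    "contact_matrix_frame",
    "occupancy_map",
    "difference_map",
    "composite_triangle_map",
    "hbond_count_frame",
    "hbond_series_mean",
]

DEFAULT_CONTACT_CUTOFF = 3.5  # Å, boundary inclusive


@dataclass
class ContactMap:
    """Symmetric residue×residue occupancy matrix in [0, 1], diagonal 1."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")


@dataclass
class DifferenceMap:
    """Signed occupancy difference in [−1, 1], zero diagonal."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition: donor–acceptor distance and
    hydrogen–donor–acceptor angle cutoffs (gmx-hbond-style convention)."""

    distance_cutoff: float = 3.5  # Å, D–A
    angle_cutoff: float = 30.0  # degrees, H–D–A
    attachment_cutoff: float = 1.2  # Å, H considered bonded to its donor

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("H-bond cutoffs must be positive")


# ---------------------------------------------------------------------------
# per-frame contact matrix


def _contact_pairs_brute(
    coords: np.ndarray, res_of: np.ndarray, n_res: int, cutoff: float
) -> np.ndarray:
    contact = np.zeros((n_res, n_res), dtype=bool)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    hit = d2 <= cutoff * cutoff
    ii, jj = np.nonzero(hit)
    contact[res_of[ii], res_of[jj]] = True
    return contact


def _contact_pairs_cell(
    coords: np.ndarray, res_of: np.ndarray, n_res: int, cutoff: float
) -> np.ndarray:
    """Cell-list contact detection: atoms binned at cutoff resolution,
    only the 27 neighbouring cells inspected per atom."""
    contact = np.zeros((n_res, n_res), dtype=bool)
    np.fill_diagonal(contact, True)
    cells: dict[tuple[int, int, int], list[int]] = {}
    keys = np.floor(coords / cutoff).astype(int)
    for i, k in enumerate(map(tuple, keys)):
        cells.setdefault(k, []).append(i)
    c2 = cutoff * cutoff
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    for key, members in cells.items():
        neigh: list[int] = []
        for off in offsets:
            neigh.extend(cells.get((key[0] + off[0], key[1] + off[1], key[2] + off[2]), ()))
        nb = np.asarray(neigh)
        for i in members:
            d2 = np.sum((coords[nb] - coords[i]) ** 2, axis=1)
            close = nb[d2 <= c2]
            contact[res_of[i], res_of[close]] = True
    return contact


def contact_matrix_frame(
    frame: Frame,
    topology: Topology,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    method: str = "cell",
) -> np.ndarray:
    """Binary residue-contact matrix for one frame.

    Entry (i, j) is 1 iff the minimum atom–atom distance between protein
    residues i and j (all atoms, hydrogens included) is ≤ ``cutoff``.
    The boundary is inclusive: a closest pair at exactly 3.5 Å counts.
    ``method`` selects the O(n) cell-list grid or the brute-force
    all-pairs path (retained for cross-checking).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    prot_res = topology.protein_residue_indices
    if len(prot_res) < 2:
        raise ValueError("contact map needs at least 2 protein residues")
    idx = select_atoms(topology, "protein")
    if len(idx) == 0:
        raise ValueError("no protein atoms in topology")
    coords = frame.coordinates[idx]
    # map residue index -> row in the protein-residue matrix
    row_of = {r: k for k, r in enumerate(prot_res)}
    res_of = np.array([row_of[topology.atoms[i].residue_index] for i in idx])
    for r in prot_res:
        if len(topology.residue_atom_indices(r)) == 0:
            raise ValueError(f"residue {r} has no atoms")
    if method == "brute":
        contact = _contact_pairs_brute(coords, res_of, len(prot_res), cutoff)
    elif method == "cell":
        contact = _contact_pairs_cell(coords, res_of, len(prot_res), cutoff)
    else:
        raise ValueError(f"unknown contact method {method!r}")
    contact |= contact.T
    np.fill_diagonal(contact, True)
    return contact.astype(float)


def occupancy_map(
    replica_set: ReplicaSet,
    window: Window | None = None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    method: str = "cell",
) -> ContactMap:
    """Mean contact matrix over all windowed frames pooled across
    replicas — the per-contact occupancy in [0, 1]."""
    topo = replica_set.topology
    total = None
    n = 0
    for traj in replica_set:
        view = frames_in_window(traj, window) if window is not None else traj
        for f in view.frames:
            m = contact_matrix_frame(f, topo, cutoff=cutoff, method=method)
            total = m if total is None else total + m
            n += 1
    if n == 0:
        raise ValueError("empty frame pool for occupancy map")
    return ContactMap(matrix=total / n, labels=topo.residue_labels())


def difference_map(map_a: ContactMap, map_b: ContactMap) -> DifferenceMap:
    """Elementwise occupancy difference map_a − map_b.

    +1 marks contacts present only in condition a, −1 only in b; the
    result is antisymmetric under operand swap."""
    if map_a.labels != map_b.labels or map_a.matrix.shape != map_b.matrix.shape:
        raise ValueError("difference map requires matching residue labels")
    return DifferenceMap(matrix=map_a.matrix - map_b.matrix, labels=list(map_a.labels))


def composite_triangle_map(
    lower_source: DifferenceMap, upper_source: DifferenceMap
) -> np.ndarray:
    """Pack two difference maps into one matrix: strictly-lower triangle
    from the first, strictly-upper from the second, zero diagonal."""
    if lower_source.labels != upper_source.labels:
        raise ValueError("composite map requires matching residue labels")
    if lower_source.matrix.shape != upper_source.matrix.shape:
        raise ValueError("composite map requires matching shapes")
    return np.tril(lower_source.matrix, k=-1) + np.triu(upper_source.matrix, k=1)


# ---------------------------------------------------------------------------
# hydrogen bonds


def _donors_and_acceptors(topology: Topology, frame: Frame, attachment_cutoff: float):
    """Identify N/O donors (with an attached H) and N/O acceptors.

    Attachment is purely geometric: an H within ``attachment_cutoff`` of
    an N/O belongs to it (no bond table needed)."""
    elements = topology.elements
    coords = frame.coordinates
    heavy_idx = np.flatnonzero((elements == "N") | (elements == "O"))
    h_idx = np.flatnonzero(elements == "H")
    donors: list[tuple[int, int]] = []
    if len(h_idx) and len(heavy_idx):
        tree = cKDTree(coords[heavy_idx])
        for h in h_idx:
            for j in tree.query_ball_point(coords[h], attachment_cutoff):
                donors.append((int(heavy_idx[j]), int(h)))
    return donors, heavy_idx


def hbond_count_frame(
    frame: Frame,
    topology: Topology,
    criterion: HBondCriterion = HBondCriterion(),
) -> int:
    """Number of protein–solvent hydrogen bonds in one frame.

    A bond is a donor–acceptor pair (donor: N/O with attached H;
    acceptor: N/O) with one side protein and the other solvent, D–A
    distance ≤ the distance cutoff and H–D–A angle ≤ the angle cutoff.
    Distinct donor–acceptor pairs are counted once each.
    """
    is_solvent = np.array([a.is_solvent for a in topology.atoms])
    if not is_solvent.any():
        warnings.warn("no solvent atoms present; hydrogen-bond count is 0")
        return 0
    coords = frame.coordinates
    donors, acceptors = _donors_and_acceptors(topology, frame, criterion.attachment_cutoff)
    if not donors or not len(acceptors):
        return 0
    acc_tree = cKDTree(coords[acceptors])
    cos_cut = np.cos(np.radians(criterion.angle_cutoff))
    counted: set[tuple[int, int]] = set()
    for d, h in donors:
        for j in acc_tree.query_ball_point(coords[d], criterion.distance_cutoff):
            a = int(acceptors[j])
            if a == d or is_solvent[a] == is_solvent[d]:
                continue  # need one protein side and one solvent side
            if (d, a) in counted:
                continue
            dh = coords[h] - coords[d]
            da = coords[a] - coords[d]
            norm = np.linalg.norm(dh) * np.linalg.norm(da)
            if norm == 0:
                continue
            if np.dot(dh, da) / norm >= cos_cut:
                counted.add((d, a))
    return len(counted)


def hbond_series_mean(
    replica_set: ReplicaSet,
    window: Window | None = None,
    criterion: HBondCriterion = HBondCriterion(),
):
    """Pooled mean ± sd of per-frame protein–solvent H-bond counts over
    the trailing window of every replica."""
    from rehydra.shape import ShapeResult

    counts: list[float] = []
    for traj in replica_set:
        view = frames_in_window(traj, window) if window is not None else traj
        counts.extend(
            float(hbond_count_frame(f, replica_set.topology, criterion))
            for f in view.frames
        )
    if not counts:
        raise ValueError("empty frame pool for hydrogen-bond statistics")
    arr = np.asarray(counts)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return ShapeResult(
        metric="hbonds", value=float(arr.mean()), uncertainty=sd, n=len(arr), units="count"
    )
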