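"""Superposition, RMSD reference schemes, average structures and RMSF.

The RMSD machinery mirrors the three-reference design used to follow
rehydration dynamics: each trajectory against its own first frame
(RMSD_f), against a shared solution-control final structure (RMSD_s),
and against the per-replica "parent" structure from the zero-field
rehydration run (RMSD_zf).  RMSF follows the concatenate → average
structure → re-fit recipe: all replicas of a condition are concatenated,
the ensemble-average structure computed, and per-residue fluctuations
taken about it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from rehydra.trajio import Frame, ReplicaSet, Topology, Trajectory, select_atoms

__all__ = [
    "SuperpositionResult",
    "RMSDScheme",
    "MetricSeries",
    "ResidueProfile",
    "kabsch_superpose",
    "apply_superposition",
    "rmsd_series",
    "replica_mean_series",
    "average_structure",
    "rmsf_profile",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body fit: x ↦ R x + t, with the residual RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclass
class MetricSeries:
    """Per-frame scalar series with times (ps) and declared units."""

    times: np.ndarray
    values: np.ndarray
    units: str = "A"
    sd: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ResidueProfile:
    """Per-residue scalar profile (e.g. RMSF in Å)."""

    residue_indices: np.ndarray
    values: np.ndarray
    units: str = "A"

    def __post_init__(self):
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.residue_indices.shape != self.values.shape:
            raise ValueError("residue_indices and values must have equal length")


@dataclass(frozen=True)
class RMSDScheme:
    """Which reference each frame's RMSD is measured against.

    * ``first_frame`` — the trajectory's own frame 0 (RMSD_f);
    * ``external_reference`` — one shared reference frame, e.g. the final
      solution-control structure (RMSD_s);
    * ``parent_mapped`` — one reference per replica index, e.g. the final
      frame of the matching zero-field rehydration replica (RMSD_zf).
    """

    variant: str
    reference: Frame | None = None
    references: tuple[Frame, ...] | None = None

    _VARIANTS = ("first_frame", "external_reference", "parent_mapped")

    def __post_init__(self):
        if self.variant not in self._VARIANTS:
            raise ValueError(f"unknown RMSD scheme variant {self.variant!r}")
        if self.variant == "external_reference" and self.reference is None:
            raise ValueError("external_reference scheme needs a reference frame")
        if self.variant == "parent_mapped" and not self.references:
            raise ValueError("parent_mapped scheme needs per-replica references")

    def reference_for(self, trajectory: Trajectory, replica_index: int | None) -> Frame:
        if self.variant == "first_frame":
            return trajectory.frames[0]
        if self.variant == "external_reference":
            return self.reference
        if replica_index is None:
            raise ValueError("parent_mapped scheme requires a replica index")
        if replica_index >= len(self.references):
            raise ValueError(
                f"no parent reference for replica {replica_index} "
                f"({len(self.references)} references given)"
            )
        return self.references[replica_index]


# ---------------------------------------------------------------------------
# Kabsch superposition


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid-body superposition (Kabsch, via SVD).

    Finds the proper rotation R and translation t minimising the
    (weighted) RMSD of ``R @ mobile + t`` to ``reference``.  Reflections
    are excluded by construction, so a chiral point set fitted to its
    mirror image retains a non-zero residual.

    Parameters
    ----------
    mobile, reference : (n, 3) arrays, n ≥ 3, not all collinear.
    weights : optional non-negative per-point weights (default uniform).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have the same shape")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points in 3-D")
    n = mobile.shape[0]
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    mob_c = mobile - w @ mobile
    ref_c = reference - w @ reference
    cov = (w[:, None] * mob_c).T @ ref_c
    # degenerate (collinear / coincident) configurations have rank < 2
    if np.linalg.matrix_rank(ref_c, tol=1e-10) < 2 or np.linalg.matrix_rank(
        mob_c, tol=1e-10
    ) < 2:
        raise ValueError("degenerate point set: all points (near-)collinear")
    U, _, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt)) or 1.0
    D = np.diag([1.0, 1.0, d])
    rotation = (U @ D @ Vt).T  # maps mobile-centered onto reference-centered
    translation = (w @ reference) - rotation @ (w @ mobile)
    fitted = mob_c @ rotation.T
    rmsd = float(np.sqrt(np.sum(w * np.sum((fitted - ref_c) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def apply_superposition(result: SuperpositionResult, coordinates: np.ndarray) -> np.ndarray:
    """Apply a fitted rigid motion to an (n, 3) coordinate array."""
    return np.asarray(coordinates, dtype=float) @ result.rotation.T + result.translation


# ---------------------------------------------------------------------------
# RMSD series and replica averaging


def rmsd_series(
    trajectory: Trajectory,
    scheme: RMSDScheme,
    selection="calpha",
    replica_index: int | None = None,
    weights: np.ndarray | None = None,
) -> MetricSeries:
    """Per-frame Kabsch RMSD of the selected atoms against the scheme's
    reference.  The ``first_frame`` scheme yields 0 at frame 0 by
    construction."""
    idx = select_atoms(trajectory.topology, selection)
    reference = scheme.reference_for(trajectory, replica_index)
    ref = reference.coordinates[idx]
    values = np.array(
        [
            kabsch_superpose(f.coordinates[idx], ref, weights=weights).rmsd
            for f in trajectory.frames
        ]
    )
    return MetricSeries(times=trajectory.times, values=values, units="A")


def replica_mean_series(series: Sequence[MetricSeries]) -> MetricSeries:
    """Pointwise mean (and sd) over replica series sharing one time grid.

    Time grids are compared with 1e-6 ps tolerance; length mismatches are
    hard errors rather than truncations.
    """
    series = list(series)
    if not series:
        raise ValueError("no series to average")
    n = len(series[0])
    times = series[0].times
    for k, s in enumerate(series[1:], start=1):
        if len(s) != n:
            raise ValueError(f"series 0 has {n} points but series {k} has {len(s)}")
        if not np.allclose(s.times, times, atol=1e-6, rtol=0):
            raise ValueError(f"series {k} time grid differs from series 0")
    stack = np.stack([s.values for s in series])
    return MetricSeries(
        times=times,
        values=stack.mean(axis=0),
        units=series[0].units,
        sd=stack.std(axis=0, ddof=0),
    )


# ---------------------------------------------------------------------------
# average structure and RMSF


def _superpose_stack(
    stack: np.ndarray, reference_sel: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """Fit every frame's selection onto ``reference_sel``; transform all atoms."""
    out = np.empty_like(stack)
    for k in range(stack.shape[0]):
        res = kabsch_superpose(stack[k, idx], reference_sel)
        out[k] = apply_superposition(res, stack[k])
    return out


def average_structure(trajectory: Trajectory, selection="calpha") -> Frame:
    """Coordinate-wise mean frame after superposing every frame's
    selection onto the first frame's selection."""
    idx = select_atoms(trajectory.topology, selection)
    stack = trajectory.coordinate_stack()
    fitted = _superpose_stack(stack, stack[0, idx], idx)
    return Frame(fitted.mean(axis=0), time=float(np.mean(trajectory.times)))


def concatenate_replicas(replica_set: ReplicaSet) -> Trajectory:
    """All replica frames joined into one trajectory (times renumbered
    consecutively to keep them strictly increasing)."""
    frames = []
    t = 0.0
    dt = 1.0
    for traj in replica_set:
        times = traj.times
        if len(times) > 1:
            dt = float(times[1] - times[0])
        for f in traj.frames:
            frames.append(Frame(f.coordinates, time=t))
            t += dt
    return Trajectory(replica_set.topology, frames)


def rmsf_profile(
    replica_set: ReplicaSet,
    selection="calpha",
    per_residue: str = "calpha",
) -> ResidueProfile:
    """Per-residue RMSF about the ensemble-average structure.

    All replicas are concatenated; frames are superposed onto the first
    frame, the average structure computed, frames re-fitted onto that
    average (one refinement pass), and RMSF_i = √⟨|x_i − x̄_i|²⟩ taken per
    selected atom.  With the default Cα selection this is one value per
    protein residue; ``per_residue="mean"`` averages atom RMSF within
    each residue for broader selections.
    """
    concat = concatenate_replicas(replica_set)
    topo = concat.topology
    idx = select_atoms(topo, selection)
    if len(idx) == 0:
        raise ValueError("empty selection for RMSF")
    stack = concat.coordinate_stack()
    fitted = _superpose_stack(stack, stack[0, idx], idx)
    avg = fitted.mean(axis=0)
    refitted = _superpose_stack(fitted, avg[idx], idx)
    disp2 = np.sum((refitted[:, idx] - refitted[:, idx].mean(axis=0)) ** 2, axis=2)
    atom_rmsf = np.sqrt(disp2.mean(axis=0))
    # map selected atoms to residues
    res_of = np.array([topo.atoms[i].residue_index for i in idx])
    residues = np.unique(res_of)
    values = np.array(
        [atom_rmsf[res_of == r].mean() for r in residues]
    )
    return ResidueProfile(residue_indices=residues, values=values, units="A")
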