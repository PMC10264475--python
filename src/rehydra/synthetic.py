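"""Synthetic replica-trajectory generator with closed-form ground truth.

Emulates the statistical structure of a rehydration study — a compacted
starting conformation relaxing exponentially toward an expanded
reference, per-residue thermal fluctuation, controllable protein–water
hydrogen-bond geometry — without any molecular dynamics.  Every
generated quantity has an analytic expectation (final RMSD, per-residue
RMSF = σ√3, shape-metric scaling factors, planted hydrogen-bond count),
so the analysis pipeline can be validated end to end.

Idealised convex fixtures (single spheres, dumbbells) serve the shape
module's analytic oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from rehydra.align import kabsch_superpose
from rehydra.trajio import (
    Atom,
    Condition,
    Frame,
    ReplicaSet,
    Topology,
    Trajectory,
    select_atoms,
    write_trajectory,
)

__all__ = [
    "ToyProteinSpec",
    "RehydrationSimSpec",
    "GroundTruth",
    "ShapeFixture",
    "make_toy_protein",
    "make_sphere_fixture",
    "make_dumbbell_fixture",
    "simulate_replicas",
    "add_waters_with_hbonds",
    "write_replica_set",
]

#: per-replica seed offset (recorded in ground-truth metadata)
REPLICA_SEED_OFFSET = 1000


@dataclass(frozen=True)
class ToyProteinSpec:
    """Geometry of a synthetic helical toy protein.

    Each residue carries a Cα on a helical arc with consecutive Cα–Cα
    spacing ``spacing`` (3.8 Å, the trans-peptide value), plus — for
    ``atoms_per_residue`` ≥ 2 — an amide-like N, H and carbonyl-like O so
    hydrogen-bond donors and acceptors exist, and beyond five atoms,
    seeded dummy side-chain carbons.
    """

    n_residues: int
    atoms_per_residue: int = 5
    spacing: float = 3.8
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("toy protein needs at least 2 residues")
        if self.atoms_per_residue < 1:
            raise ValueError("atoms_per_residue must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


@dataclass(frozen=True)
class RehydrationSimSpec:
    """Parameters of the synthetic rehydration process.

    The conformation starts compacted by factor ``compaction_scale``
    (s < 1) and relaxes exponentially (time constant ``tau_relax_ps``)
    toward the expanded reference, with independent isotropic Gaussian
    jitter of per-residue amplitude σ_i added every frame.  Defaults
    mirror the study design: five replicas per set and a trajectory long
    enough that the trailing quarter is equilibrated.
    """

    compaction_scale: float = 0.8
    tau_relax_ps: float = 10.0
    sigma: float | tuple[float, ...] = 0.3
    n_frames: int = 200
    dt_ps: float = 1.0
    n_replicas: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.compaction_scale <= 1:
            raise ValueError("compaction_scale must be in (0, 1]")
        if self.tau_relax_ps <= 0:
            raise ValueError("tau_relax_ps must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.n_replicas < 1:
            raise ValueError("need at least one replica")
        sig = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(sig < 0):
            raise ValueError("fluctuation amplitudes must be non-negative")


@dataclass
class GroundTruth:
    """Closed-form expectations implied by a generator spec."""

    expected_final_rmsd: float | None = None
    expected_rmsf: np.ndarray | None = None
    expected_ccs_ratio: float | None = None
    expected_sasa_ratio: float | None = None
    expected_volume_ratio: float | None = None
    planted_hbond_count: int | None = None
    replica_seeds: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {}
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                v = v.tolist()
            payload[k] = v
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class ShapeFixture:
    """An idealised body (topology + frame + explicit radii) for the
    shape module's analytic oracles."""

    topology: Topology
    frame: Frame
    radii: np.ndarray


# ---------------------------------------------------------------------------
# toy protein


def _spherical_spiral_trace(n: int, spacing: float) -> np.ndarray:
    """Cα trace: a helical arc wound on a sphere of protein-like radius,
    walked in exact constant chord steps.

    The shell geometry keeps the rigid-body leverage of every residue
    comparable (as in a globular protein), unlike a straight helix whose
    ends dominate any superposition fit.  The sphere radius follows the
    surface area needed for ``n`` residues at the given spacing and is
    enlarged deterministically if the winding runs off the pole.
    """
    for attempt in range(30):
        radius = spacing * np.sqrt(n / (4.0 * np.pi)) * 1.12 * 1.1**attempt
        turns = max(2, int(np.ceil(np.pi * radius / spacing)))

        def point(phi: float) -> np.ndarray:
            theta = turns * phi
            return radius * np.array(
                [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
            )

        pts = [point(1e-3)]
        phi = 1e-3
        ok = True
        for _ in range(n - 1):
            hi = phi
            step = spacing / (radius * max(turns * np.sin(max(phi, 0.05)), 1.0))
            while np.linalg.norm(point(hi) - pts[-1]) < spacing:
                hi += step
                if hi > np.pi:
                    ok = False
                    break
            if not ok:
                break
            lo = hi - step
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if np.linalg.norm(point(mid) - pts[-1]) < spacing:
                    lo = mid
                else:
                    hi = mid
            phi = 0.5 * (lo + hi)
            pts.append(point(phi))
        if ok:
            return np.array(pts)
    raise RuntimeError(f"could not wind a {n}-residue trace at spacing {spacing}")


def make_toy_protein(spec: ToyProteinSpec) -> tuple[Topology, Frame]:
    """Deterministic globular toy protein.

    Consecutive Cα atoms are exactly ``spec.spacing`` apart on a
    sphere-wound helical arc; side-chain dummy placements depend on the
    seed, the backbone does not.
    """
    rng = np.random.default_rng(spec.seed)
    trace = _spherical_spiral_trace(spec.n_residues, spec.spacing)
    names_3 = ["ALA", "GLY", "SER", "VAL", "LEU"]
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 1
    for k in range(spec.n_residues):
        ca = trace[k]
        radial = ca / np.linalg.norm(ca)  # outward from the fold center
        resname = names_3[k % len(names_3)]

        def add(name: str, element: str, xyz: np.ndarray):
            nonlocal serial
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_index=k,
                    residue_name=resname,
                )
            )
            coords.append(xyz)
            serial += 1

        add("CA", "C", ca)
        if spec.atoms_per_residue >= 2:
            # amide-like N sits outward of the Cα; its H points further out
            n_pos = ca + 1.45 * radial
            add("N", "N", n_pos)
        if spec.atoms_per_residue >= 3:
            add("H", "H", n_pos + 1.0 * radial)
        if spec.atoms_per_residue >= 4:
            # carbonyl-like O displaced along the helix axis
            add("O", "O", ca + np.array([0.0, 0.0, 1.24]) - 0.4 * radial)
        for extra in range(max(0, spec.atoms_per_residue - 4)):
            offset = rng.normal(scale=0.6, size=3)
            add(f"CB{extra + 1}" if extra else "CB", "C", ca - 1.2 * radial + offset)
    return Topology(atoms), Frame(np.array(coords), time=0.0)


# ---------------------------------------------------------------------------
# idealised shape fixtures


def _single_atom_topology(n: int, name: str = "X", element: str = "C") -> Topology:
    return Topology(
        [
            Atom(
                serial=i + 1,
                name=name,
                element=element,
                residue_index=i,
                residue_name="SPH",
            )
            for i in range(n)
        ]
    )


def make_sphere_fixture(radius: float, center=(0.0, 0.0, 0.0)) -> ShapeFixture:
    """Single sphere: CCS = πr², SASA(probe 0) = 4πr², V = 4πr³/3."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return ShapeFixture(
        topology=_single_atom_topology(1),
        frame=Frame(np.array([center], dtype=float)),
        radii=np.array([radius]),
    )


def make_dumbbell_fixture(radius: float, separation: float) -> ShapeFixture:
    """Two equal spheres with centers ``separation`` apart along x."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    coords = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    return ShapeFixture(
        topology=_single_atom_topology(2),
        frame=Frame(coords),
        radii=np.array([radius, radius]),
    )


# ---------------------------------------------------------------------------
# replica simulation


def _per_atom_sigma(topology: Topology, sigma) -> np.ndarray:
    sig = np.atleast_1d(np.asarray(sigma, dtype=float))
    n_res = topology.n_residues
    if len(sig) == 1:
        per_res = np.full(n_res, sig[0])
    elif len(sig) == n_res:
        per_res = sig
    else:
        # cycle a short amplitude pattern over the residues
        per_res = np.resize(sig, n_res)
    return np.array([per_res[a.residue_index] for a in topology.atoms]), per_res


def simulate_replicas(
    topology: Topology,
    start_frame: Frame,
    spec: RehydrationSimSpec,
    condition: Condition | None = None,
) -> tuple[ReplicaSet, GroundTruth]:
    """Generate a replica set of synthetic rehydration trajectories.

    ``start_frame`` is the *expanded* reference conformation X.  Frame k
    (time t = k·dt) of every replica is

        x(t) = x̄ + (X − x̄)·[s + (1 − s)·(1 − e^(−t/τ))] + ε,

    i.e. compacted by s about the centroid x̄ at t = 0, relaxing
    exponentially to X, with ε ~ N(0, σ_i²·I₃) drawn independently per
    atom and frame.  Replica r uses seed ``spec.seed + r·1000``.

    Ground truth: the final RMSD against the first frame equals the
    Kabsch RMSD between the compacted and relaxed Cα conformations (for
    τ ≪ total time and σ = 0); RMSF_i = σ_i√3; compact/expanded shape
    ratios are s² (CCS, SASA) and s³ (volume).
    """
    if start_frame.coordinates.shape[0] != topology.n_atoms:
        raise ValueError("start_frame does not match topology")
    s = spec.compaction_scale
    center = start_frame.coordinates.mean(axis=0)
    centered = start_frame.coordinates - center
    per_atom_sigma, per_res_sigma = _per_atom_sigma(topology, spec.sigma)
    times = spec.dt_ps * np.arange(spec.n_frames)
    scale_t = s + (1.0 - s) * (1.0 - np.exp(-times / spec.tau_relax_ps))
    replicas = []
    seeds = []
    for r in range(spec.n_replicas):
        seed = spec.seed + r * REPLICA_SEED_OFFSET
        seeds.append(seed)
        rng = np.random.default_rng(seed)
        frames = []
        for k, t in enumerate(times):
            noise = rng.normal(size=(topology.n_atoms, 3)) * per_atom_sigma[:, None]
            frames.append(Frame(center + scale_t[k] * centered + noise, time=float(t)))
        replicas.append(Trajectory(topology, frames))
    cond = condition or Condition("rehydration", 0.0)
    replica_set = ReplicaSet(cond, replicas)

    # closed-form expectations
    try:
        ca = select_atoms(topology, "calpha")
    except Exception:
        ca = np.arange(topology.n_atoms)
    expected_final_rmsd = None
    if s < 1:
        compact = center + s * centered
        expected_final_rmsd = kabsch_superpose(
            start_frame.coordinates[ca], compact[ca]
        ).rmsd
    truth = GroundTruth(
        expected_final_rmsd=expected_final_rmsd,
        expected_rmsf=per_res_sigma * np.sqrt(3.0),
        expected_ccs_ratio=s**2,
        expected_sasa_ratio=s**2,
        expected_volume_ratio=s**3,
        replica_seeds=seeds,
    )
    return replica_set, truth


def compacted_structures(
    topology: Topology,
    start_frame: Frame,
    spec: RehydrationSimSpec,
) -> ReplicaSet:
    """Per-replica compacted 'vacuum' structures (single-frame
    trajectories): the expanded reference scaled by s about its centroid
    plus one draw of the per-residue jitter."""
    s = spec.compaction_scale
    center = start_frame.coordinates.mean(axis=0)
    centered = start_frame.coordinates - center
    per_atom_sigma, _ = _per_atom_sigma(topology, spec.sigma)
    replicas = []
    for r in range(spec.n_replicas):
        rng = np.random.default_rng(spec.seed + r * REPLICA_SEED_OFFSET + 17)
        noise = rng.normal(size=(topology.n_atoms, 3)) * per_atom_sigma[:, None]
        replicas.append(
            Trajectory(topology, [Frame(center + s * centered + noise, time=0.0)])
        )
    return ReplicaSet(Condition("vacuum", 0.0), replicas)


# ---------------------------------------------------------------------------
# solvent placement


def add_waters_with_hbonds(
    topology: Topology,
    frame: Frame,
    k_bonded: int,
    k_far: int = 0,
    seed: int = 0,
) -> tuple[Topology, Frame, GroundTruth]:
    """Add waters at ideal hydrogen-bond geometry plus distant spectators.

    ``k_bonded`` waters are placed with their oxygen 2.9 Å from a protein
    N–H donor along the N→H direction (H–D–A angle ≈ 0°); donor sites are
    chosen so each planted water is the only solvent within hydrogen-bond
    range of any protein N/O, making the planted count exact ground
    truth.  ``k_far`` waters are placed beyond 8 Å of every protein atom.
    Water geometry is a rigid 3-site model (O–H 0.96 Å) with hydrogens
    pointing away from the protein.
    """
    rng = np.random.default_rng(seed)
    coords = frame.coordinates
    elements = topology.elements
    heavy_no = np.flatnonzero((elements == "N") | (elements == "O"))
    h_idx = np.flatnonzero(elements == "H")
    # candidate donors: protein N/O with an H within 1.2 Å
    donors = []
    for d in heavy_no:
        if topology.atoms[d].is_solvent:
            continue
        for h in h_idx:
            if np.linalg.norm(coords[h] - coords[d]) < 1.2:
                donors.append((int(d), int(h)))
                break
    placed: list[np.ndarray] = []
    chosen: list[tuple[int, int]] = []
    exclusion = 4.5  # Å clearance of a planted O from every other protein N/O
    for d, h in donors:
        if len(chosen) == k_bonded:
            break
        direction = coords[h] - coords[d]
        direction = direction / np.linalg.norm(direction)
        o_pos = coords[d] + 2.9 * direction
        others = heavy_no[heavy_no != d]
        if len(others) and np.min(
            np.linalg.norm(coords[others] - o_pos, axis=1)
        ) < exclusion:
            continue
        if placed and np.min(np.linalg.norm(np.array(placed) - o_pos, axis=1)) < exclusion:
            continue
        placed.append(o_pos)
        chosen.append((d, h))
    if len(chosen) < k_bonded:
        raise ValueError(
            f"insufficient isolated donor sites: placed {len(chosen)} of "
            f"{k_bonded} requested waters"
        )
    new_atoms = list(topology.atoms)
    new_coords = [coords]
    serial = max(a.serial for a in topology.atoms)
    res_index = topology.n_residues

    def add_water(o_pos: np.ndarray, away: np.ndarray):
        nonlocal serial, res_index
        # hydrogens on the far side of the oxygen, HOH angle 104.5°
        perp = np.cross(away, rng.normal(size=3))
        perp /= np.linalg.norm(perp)
        half = np.radians(104.5 / 2.0)
        h1 = o_pos + 0.96 * (np.cos(half) * away + np.sin(half) * perp)
        h2 = o_pos + 0.96 * (np.cos(half) * away - np.sin(half) * perp)
        for name, element, xyz in (("O", "O", o_pos), ("H1", "H", h1), ("H2", "H", h2)):
            serial += 1
            new_atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_index=res_index,
                    residue_name="HOH",
                    is_solvent=True,
                )
            )
            new_coords.append(xyz[None, :])
        res_index += 1

    for (d, h), o_pos in zip(chosen, placed):
        away = o_pos - coords[d]
        away /= np.linalg.norm(away)
        add_water(o_pos, away)
    # distant spectators
    protein_center = coords.mean(axis=0)
    max_extent = np.max(np.linalg.norm(coords - protein_center, axis=1))
    for _ in range(k_far):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        o_pos = protein_center + (max_extent + 10.0 + rng.uniform(0, 5)) * direction
        add_water(o_pos, direction)
    new_topology = Topology(new_atoms)
    new_frame = Frame(np.vstack(new_coords), time=frame.time)
    truth = GroundTruth(planted_hbond_count=len(chosen))
    return new_topology, new_frame, truth


# ---------------------------------------------------------------------------
# file emission


def write_replica_set(
    replica_set: ReplicaSet,
    directory: str | Path,
    prefix: str = "replica",
    ground_truth: GroundTruth | None = None,
) -> list[Path]:
    """Write each replica as a multi-model PDB file (plus an optional
    JSON ground-truth sidecar); returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for r, traj in enumerate(replica_set):
        path = directory / f"{prefix}_{r}.pdb"
        write_trajectory(path, traj)
        paths.append(path)
    if ground_truth is not None:
        ground_truth.to_json(directory / f"{prefix}_ground_truth.json")
    return paths
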