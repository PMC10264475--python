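"""Molecular size and shape metrics: projection-approximation CCS,
Shrake–Rupley SASA, van-der-Waals envelope volume, window statistics and
the compaction-delta report arithmetic.

The collision cross section Ω is computed in the projection
approximation: the molecule is a union of van der Waals spheres, and Ω
is the mean shadow (projected) area over uniformly random orientations.
For a convex body the Cauchy surface formula gives Ω = A_s/4 with A_s
the surface area, which is the diagnostic exposed by
:func:`convexity_ratio` (equality for a sphere, ratio > 4 for concave
bodies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from rehydra.align import MetricSeries
from rehydra.trajio import Window

__all__ = [
    "ShapeResult",
    "CompactionDelta",
    "ccs_projection_approximation",
    "apply_ccs_calibration",
    "sasa_shrake_rupley",
    "envelope_volume",
    "convexity_ratio",
    "window_stats",
    "compaction_deltas",
    "round_half_away",
]

#: default number of random orientations for the projection approximation
DEFAULT_N_ROTATIONS = 300
#: default scanline spacing (Å) for projected-area integration
DEFAULT_GRID_RESOLUTION = 0.2
#: default empirical multiplicative CCS calibration
DEFAULT_CALIBRATION_FACTOR = 1.14


@dataclass
class ShapeResult:
    """A shape metric with its spread.

    ``uncertainty`` is the Monte-Carlo standard error for single-structure
    CCS, or the pooled standard deviation for windowed ensemble metrics;
    ``n`` the sample count behind it.  ``per_atom`` carries the atomic
    breakdown where the metric has one (SASA).
    """

    metric: str
    value: float
    uncertainty: float
    n: int
    units: str = "A^2"
    per_atom: np.ndarray | None = None


@dataclass(frozen=True)
class CompactionDelta:
    """Rounded percent changes of a rehydrated ensemble versus the vacuum
    structures and versus the solution control."""

    delta_vs_vacuum_pct: int
    delta_vs_solution_pct: int


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (report convention)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _check_geometry(coordinates, radii):
    coords = np.asarray(coordinates, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise ValueError("coordinates must be a non-empty (n, 3) array")
    if radii.shape != (coords.shape[0],):
        raise ValueError(
            f"need one radius per atom: {radii.shape} vs {coords.shape[0]} atoms"
        )
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("all radii must be positive and finite")
    return coords, radii


# ---------------------------------------------------------------------------
# projection-approximation CCS


def _union_interval_length(starts: np.ndarray, ends: np.ndarray) -> float:
    """Total length of the union of 1-D intervals."""
    order = np.argsort(starts)
    s = starts[order]
    e = ends[order]
    cummax = np.maximum.accumulate(e)
    # segment boundaries: where a new interval starts past all previous ends
    new_seg = np.empty(len(s), dtype=bool)
    new_seg[0] = True
    new_seg[1:] = s[1:] > cummax[:-1]
    seg_idx = np.flatnonzero(new_seg)
    seg_end = np.append(seg_idx[1:], len(s)) - 1
    return float(np.sum(cummax[seg_end] - s[seg_idx]))


def _projected_area(
    xy: np.ndarray, radii: np.ndarray, resolution: float, rng: np.random.Generator
) -> float:
    """Area of the union of discs by scanline integration.

    Each scanline contributes the exact union length of the chord
    intervals; the y-grid origin is jittered uniformly so that averaging
    over orientations is free of rasterisation bias.
    """
    y = xy[:, 1]
    ymin = float(np.min(y - radii)) - resolution
    ymax = float(np.max(y + radii)) + resolution
    offset = rng.uniform(0.0, resolution)
    rows = np.arange(ymin + offset, ymax, resolution)
    area = 0.0
    x = xy[:, 0]
    for yr in rows:
        dy = yr - y
        active = np.abs(dy) < radii
        if not np.any(active):
            continue
        half = np.sqrt(radii[active] ** 2 - dy[active] ** 2)
        area += _union_interval_length(x[active] - half, x[active] + half)
    return area * resolution


def ccs_projection_approximation(
    coordinates,
    radii,
    n_rotations: int = DEFAULT_N_ROTATIONS,
    seed: int | np.random.Generator | None = None,
    grid_resolution: float = DEFAULT_GRID_RESOLUTION,
) -> ShapeResult:
    """Projection-approximation collision cross section (Å²).

    Averages, over ``n_rotations`` uniformly random orientations, the
    shadow area of the union of atomic van der Waals spheres projected
    onto a plane.  The reported ``uncertainty`` is the Monte-Carlo
    standard error over orientations; identical seeds give identical
    values.
    """
    coords, radii = _check_geometry(coordinates, radii)
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rotations = Rotation.random(n_rotations, random_state=rng)
    centered = coords - coords.mean(axis=0)
    areas = np.empty(n_rotations)
    for k in range(n_rotations):
        rotated = rotations[k].apply(centered)
        areas[k] = _projected_area(rotated[:, :2], radii, grid_resolution, rng)
    se = float(areas.std(ddof=1) / np.sqrt(n_rotations)) if n_rotations > 1 else 0.0
    return ShapeResult(
        metric="ccs", value=float(areas.mean()), uncertainty=se, n=n_rotations
    )


def apply_ccs_calibration(
    ccs_value: float, factor: float = DEFAULT_CALIBRATION_FACTOR
) -> float:
    """Scale a projection-approximation CCS by an empirical factor.

    The projection approximation systematically underestimates measured
    collision cross sections; a multiplicative correction (1.14 by
    default) brings it in line with ion-mobility experiments.  Report
    tables round the calibrated value to integer Å².
    """
    if ccs_value <= 0:
        raise ValueError("ccs_value must be positive")
    if factor <= 0:
        raise ValueError("calibration factor must be positive")
    return ccs_value * factor


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA


def _golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa_shrake_rupley(
    coordinates,
    radii,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> ShapeResult:
    """Shrake–Rupley solvent-accessible surface area (Å²).

    Each atom's accessible sphere (radius r_i + probe) is sampled on a
    deterministic golden-section spiral of ``n_sphere_points``; a point
    is exposed when outside every other atom's accessible sphere.  The
    total is Σ_i exposed_fraction_i · 4π(r_i + probe)², with the per-atom
    breakdown on ``per_atom``.
    """
    coords, radii = _check_geometry(coordinates, radii)
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    if n_sphere_points < 16:
        raise ValueError("n_sphere_points must be at least 16")
    extended = radii + probe_radius
    sphere = _golden_spiral_points(n_sphere_points)
    tree = cKDTree(coords)
    n = len(coords)
    per_atom = np.empty(n)
    rmax = extended.max()
    for i in range(n):
        pts = coords[i] + extended[i] * sphere
        neighbors = [
            j for j in tree.query_ball_point(coords[i], extended[i] + rmax) if j != i
        ]
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = np.sum(
                (pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2
            )
            buried = np.any(d2 < extended[nb][None, :] ** 2, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * extended[i] ** 2
    return ShapeResult(
        metric="sasa",
        value=float(per_atom.sum()),
        uncertainty=0.0,
        n=n_sphere_points,
        per_atom=per_atom,
    )


def residue_sasa(topology, per_atom: np.ndarray) -> np.ndarray:
    """Sum a per-atom SASA breakdown into per-residue totals."""
    out = np.zeros(topology.n_residues)
    for i, a in enumerate(topology.atoms):
        out[a.residue_index] += per_atom[i]
    return out


# ---------------------------------------------------------------------------
# envelope volume


def envelope_volume(
    coordinates,
    radii,
    voxel_size: float = 0.3,
) -> ShapeResult:
    """Van-der-Waals envelope volume (Å³) by voxel counting.

    Counts voxels whose centers lie inside the union of atomic spheres on
    a grid padded by the largest radius; converges to the exact union
    volume as ``voxel_size`` → 0.
    """
    coords, radii = _check_geometry(coordinates, radii)
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if voxel_size > radii.min():
        raise ValueError(
            f"voxel_size {voxel_size} exceeds smallest atomic radius {radii.min():g}"
        )
    rmax = radii.max()
    lo = coords.min(axis=0) - rmax - voxel_size
    hi = coords.max(axis=0) + rmax + voxel_size
    shape = np.ceil((hi - lo) / voxel_size).astype(int)
    occupied = np.zeros(shape, dtype=bool)
    for c, r in zip(coords, radii):
        i0 = np.floor((c - r - lo) / voxel_size).astype(int)
        i1 = np.ceil((c + r - lo) / voxel_size).astype(int) + 1
        i0 = np.maximum(i0, 0)
        i1 = np.minimum(i1, shape)
        ax = [lo[d] + (np.arange(i0[d], i1[d]) + 0.5) * voxel_size - c[d] for d in range(3)]
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        occupied[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]] |= d2 <= r * r
    return ShapeResult(
        metric="volume",
        value=float(occupied.sum()) * voxel_size**3,
        uncertainty=0.0,
        n=int(occupied.size),
        units="A^3",
    )


# ---------------------------------------------------------------------------
# convexity diagnostic


def convexity_ratio(
    coordinates,
    radii,
    seed: int | None = None,
    n_rotations: int = DEFAULT_N_ROTATIONS,
    n_sphere_points: int = 960,
) -> float:
    """A_s/Ω with SASA at probe 0 on the same radii as the projection.

    Cauchy's surface formula makes this exactly 4 for a convex body; a
    shadow argument (the hull's shadow contains the body's, the hull's
    surface is no larger) makes it ≥ 4 in general, so values above 4
    flag concavity.
    """
    sasa = sasa_shrake_rupley(
        coordinates, radii, probe_radius=0.0, n_sphere_points=n_sphere_points
    )
    ccs = ccs_projection_approximation(
        coordinates, radii, n_rotations=n_rotations, seed=seed
    )
    return sasa.value / ccs.value


# ---------------------------------------------------------------------------
# windowed ensemble statistics and the compaction report arithmetic


def window_stats(
    series: Sequence[MetricSeries],
    window: Window | None,
    metric: str = "value",
    units: str = "A^2",
) -> ShapeResult:
    """Pooled mean ± sd of per-frame metric values over the trailing
    window of every replica series.

    All windowed frames of all replicas enter one pool, matching the
    convention of averaging the final 50 ns over all replicas and quoting
    a single standard deviation.
    """
    pool: list[np.ndarray] = []
    for s in series:
        mask = (
            window.frame_mask(s.times)
            if window is not None
            else np.ones(len(s), dtype=bool)
        )
        pool.append(s.values[mask])
    if not pool or sum(len(p) for p in pool) == 0:
        raise ValueError("empty frame pool for window statistics")
    values = np.concatenate(pool)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return ShapeResult(
        metric=metric,
        value=float(values.mean()),
        uncertainty=sd,
        n=len(values),
        units=units,
    )


def compaction_deltas(
    solution_mean: float,
    vacuum_means: Mapping[float, float],
    rehydration_means: Mapping[float, float],
) -> CompactionDelta:
    """Percent change of the rehydrated ensembles versus vacuum and
    versus the solution control.

    Per field strength f, the rehydrated mean R_f is compared with the
    matching vacuum mean V_f and with the single solution mean S; the
    per-field percent changes are averaged over fields and rounded half
    away from zero:

        Δ_vs_vacuum   = round( mean_f 100·(R_f − V_f)/V_f )
        Δ_vs_solution = round( mean_f 100·(R_f − S)/S )
    """
    if solution_mean <= 0:
        raise ValueError("solution mean must be positive")
    fields = sorted(rehydration_means)
    if not fields:
        raise ValueError("no rehydration conditions given")
    missing = [f for f in fields if f not in vacuum_means]
    if missing:
        raise ValueError(f"missing vacuum means for fields: {missing}")
    for f in fields:
        if vacuum_means[f] <= 0 or rehydration_means[f] <= 0:
            raise ValueError("condition means must be positive")
    dv = np.mean(
        [100.0 * (rehydration_means[f] - vacuum_means[f]) / vacuum_means[f] for f in fields]
    )
    ds = np.mean(
        [100.0 * (rehydration_means[f] - solution_mean) / solution_mean for f in fields]
    )
    return CompactionDelta(
        delta_vs_vacuum_pct=round_half_away(float(dv)),
        delta_vs_solution_pct=round_half_away(float(ds)),
    )
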