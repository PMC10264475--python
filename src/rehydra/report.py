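"""Configuration-driven analysis pipeline and report emission.

Runs the full analysis battery on replica sets organised per condition
(solution, vacuum at each field strength, rehydration at each field
strength): RMSD under the three reference schemes, concatenated-replica
RMSF, windowed CCS/SASA/volume statistics with the compaction-delta
table, contact occupancy/difference/composite maps, and protein–solvent
hydrogen-bond means.  Outputs are tidy CSV tables, dense text matrices
and a JSON report; reruns with the same config and seeds reproduce the
numeric tables byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rehydra import align, contacts, shape, trajio
from rehydra.align import MetricSeries, RMSDScheme
from rehydra.contacts import ContactMap, DifferenceMap, HBondCriterion
from rehydra.shape import CompactionDelta, ShapeResult
from rehydra.trajio import Condition, RadiiTable, ReplicaSet, Window

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "ConfigError",
    "validate_config",
    "run_pipeline",
    "export_table1",
    "table_from_means",
]


class ConfigError(ValueError):
    """The pipeline configuration is invalid; the message lists every
    problem found, not just the first."""


@dataclass
class PipelineConfig:
    """Fully-resolved pipeline settings.

    ``conditions`` maps labels like ``solution``, ``vacuum@0.0`` or
    ``rehydration@0.2`` to lists of multi-model PDB replica paths.
    Defaults gather the study's stated parameters: trailing-quarter
    analysis window (the last 50 ns of 200 ns), 3.5 Å boundary-inclusive
    contact cutoff, 3.5 Å/30° hydrogen-bond criterion, 1.14 CCS
    calibration, 1.4 Å SASA probe.
    """

    conditions: dict[str, list[Path]]
    selection: str = "calpha"
    window_last_fraction: float = 0.25
    contact_cutoff: float = 3.5
    hbond_distance_cutoff: float = 3.5
    hbond_angle_cutoff: float = 30.0
    ccs_n_rotations: int = shape.DEFAULT_N_ROTATIONS
    ccs_grid_resolution: float = shape.DEFAULT_GRID_RESOLUTION
    ccs_calibration_factor: float = shape.DEFAULT_CALIBRATION_FACTOR
    sasa_probe_radius: float = 1.4
    sasa_n_points: int = 960
    voxel_size: float = 0.3
    dt_ps: float = 1.0
    seed: int = 0
    output_dir: Path = Path("rehydra_out")
    radii_json: Path | None = None

    def window(self) -> Window:
        return Window(last_fraction=self.window_last_fraction)

    def hbond_criterion(self) -> HBondCriterion:
        return HBondCriterion(
            distance_cutoff=self.hbond_distance_cutoff,
            angle_cutoff=self.hbond_angle_cutoff,
        )

    def radii_table(self) -> RadiiTable:
        if self.radii_json is not None:
            return RadiiTable.from_json(self.radii_json)
        return RadiiTable()

    def canonical_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Path):
                v = str(v)
            elif isinstance(v, dict):
                v = {kk: [str(p) for p in vv] for kk, vv in v.items()}
            d[k] = v
        return d

    def hash(self) -> str:
        # output_dir is presentation, not analysis: excluded so reruns into
        # a different directory hash identically
        payload = {k: v for k, v in self.canonical_dict().items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Everything the pipeline produced, keyed by condition label."""

    config: PipelineConfig
    rmsd_tables: dict[str, pd.DataFrame] = dc_field(default_factory=dict)
    rmsf_table: pd.DataFrame | None = None
    shape_stats: dict[str, dict[str, ShapeResult]] = dc_field(default_factory=dict)
    shape_table: pd.DataFrame | None = None
    deltas: dict[str, CompactionDelta] = dc_field(default_factory=dict)
    occupancy_maps: dict[str, ContactMap] = dc_field(default_factory=dict)
    difference_maps: dict[str, DifferenceMap] = dc_field(default_factory=dict)
    composite_maps: dict[str, np.ndarray] = dc_field(default_factory=dict)
    hbond_stats: dict[str, ShapeResult] = dc_field(default_factory=dict)
    metadata: dict = dc_field(default_factory=dict)


_POSITIVE_FIELDS = (
    "window_last_fraction",
    "contact_cutoff",
    "hbond_distance_cutoff",
    "hbond_angle_cutoff",
    "ccs_n_rotations",
    "ccs_grid_resolution",
    "ccs_calibration_factor",
    "sasa_probe_radius",
    "sasa_n_points",
    "voxel_size",
    "dt_ps",
)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config.

    Applies defaults, resolves paths relative to the config file, and
    raises one ConfigError listing *all* detected problems.
    """
    path = Path(path)
    problems: list[str] = []
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    base = path.parent
    known = set(PipelineConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            problems.append(f"unknown config key: {key!r}")
    conditions: dict[str, list[Path]] = {}
    raw_conditions = raw.get("conditions") or {}
    if not raw_conditions:
        problems.append("no conditions given")
    for label, paths in raw_conditions.items():
        try:
            Condition.parse(label)
        except ValueError as exc:
            problems.append(str(exc))
        resolved = []
        for p in paths if isinstance(paths, list) else [paths]:
            p = (base / p).resolve() if not Path(p).is_absolute() else Path(p)
            if not p.exists():
                problems.append(f"condition {label!r}: file not found: {p}")
            resolved.append(p)
        conditions[label] = resolved
    kwargs = {
        k: raw[k]
        for k in known
        if k in raw and k not in ("conditions", "output_dir", "radii_json")
    }
    for key in _POSITIVE_FIELDS:
        if key in kwargs and not (
            isinstance(kwargs[key], (int, float)) and kwargs[key] > 0
        ):
            problems.append(f"{key} must be a positive number, got {kwargs[key]!r}")
            del kwargs[key]
    if "window_last_fraction" in kwargs and kwargs["window_last_fraction"] > 1:
        problems.append("window_last_fraction must be in (0, 1]")
        del kwargs["window_last_fraction"]
    if problems:
        raise ConfigError(
            f"{path}: invalid configuration:\n  - " + "\n  - ".join(problems)
        )
    out_dir = Path(raw.get("output_dir", "rehydra_out"))
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    radii_json = raw.get("radii_json")
    if radii_json is not None:
        radii_json = (base / radii_json).resolve()
    return PipelineConfig(
        conditions=conditions, output_dir=out_dir, radii_json=radii_json, **kwargs
    )


# ---------------------------------------------------------------------------
# pipeline stages


def _load_replica_sets(config: PipelineConfig) -> dict[str, ReplicaSet]:
    sets = {}
    for label, paths in config.conditions.items():
        cond = Condition.parse(label)
        replicas = [
            trajio.read_trajectory(p, dt_ps=config.dt_ps) for p in paths
        ]
        sets[label] = ReplicaSet(cond, replicas)
    return sets


def _shape_series(
    replica_set: ReplicaSet,
    config: PipelineConfig,
    radii: np.ndarray,
    protein_idx: np.ndarray,
    window: Window | None,
) -> dict[str, list[MetricSeries]]:
    """Per-replica per-frame CCS/SASA/volume series, windowed upstream to
    avoid paying for frames the statistics never see."""
    out: dict[str, list[MetricSeries]] = {"ccs": [], "sasa": [], "volume": []}
    rng_seed = config.seed
    for traj in replica_set:
        view = trajio.frames_in_window(traj, window) if window is not None else traj
        values = {"ccs": [], "sasa": [], "volume": []}
        for f in view.frames:
            coords = f.coordinates[protein_idx]
            ccs = shape.ccs_projection_approximation(
                coords,
                radii,
                n_rotations=config.ccs_n_rotations,
                seed=rng_seed,
                grid_resolution=config.ccs_grid_resolution,
            )
            sasa = shape.sasa_shrake_rupley(
                coords,
                radii,
                probe_radius=config.sasa_probe_radius,
                n_sphere_points=config.sasa_n_points,
            )
            vol = shape.envelope_volume(coords, radii, voxel_size=config.voxel_size)
            values["ccs"].append(ccs.value)
            values["sasa"].append(sasa.value)
            values["volume"].append(vol.value)
        for metric in out:
            out[metric].append(
                MetricSeries(times=view.times, values=np.array(values[metric]))
            )
    return out


def run_pipeline(config: PipelineConfig, stages: set[str] | None = None) -> ReportBundle:
    """Execute the analysis battery described by ``config``.

    ``stages`` restricts the run to a subset of
    {rmsd, rmsf, shape, contacts, hbonds}; the default runs everything
    available given the configured conditions.  All outputs are written
    under ``config.output_dir`` and returned in a :class:`ReportBundle`.
    """
    stages = stages or {"rmsd", "rmsf", "shape", "contacts", "hbonds"}
    bundle = ReportBundle(config=config)
    sets = _load_replica_sets(config)
    window = config.window()
    radii_table = config.radii_table()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    bundle.metadata = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "conditions": sorted(sets),
    }

    rehydration = {
        label: rs for label, rs in sets.items() if rs.condition.phase == "rehydration"
    }
    vacuum = {label: rs for label, rs in sets.items() if rs.condition.phase == "vacuum"}
    solution = {
        label: rs for label, rs in sets.items() if rs.condition.phase == "solution"
    }

    # --- RMSD (three reference schemes) --------------------------------
    if "rmsd" in stages:
        schemes: dict[str, RMSDScheme] = {"first_frame": RMSDScheme("first_frame")}
        if solution:
            sol = next(iter(solution.values()))
            schemes["solution_final"] = RMSDScheme(
                "external_reference", reference=sol.replicas[0].frames[-1]
            )
        zf = rehydration.get("rehydration@0")
        if zf is None:
            zf = rehydration.get("rehydration@0.0")
        if zf is None:
            for label, rs in rehydration.items():
                if rs.condition.field == 0.0:
                    zf = rs
                    break
        if zf is not None:
            schemes["zero_field_parent"] = RMSDScheme(
                "parent_mapped",
                references=tuple(t.frames[-1] for t in zf.replicas),
            )
        for scheme_name, scheme in schemes.items():
            rows = []
            for label, rs in {**rehydration, **solution}.items():
                if scheme_name == "zero_field_parent" and rs.condition.phase != "rehydration":
                    continue
                series = []
                for r, traj in enumerate(rs):
                    if (
                        scheme_name == "zero_field_parent"
                        and len(scheme.references) != rs.n_replicas
                    ):
                        raise ValueError(
                            f"parent-mapped scheme has {len(scheme.references)} "
                            f"references but {label} has {rs.n_replicas} replicas"
                        )
                    s = align.rmsd_series(
                        traj, scheme, selection=config.selection, replica_index=r
                    )
                    series.append(s)
                    rows.extend(
                        {
                            "time_ps": t,
                            "value": v,
                            "replicate": r,
                            "condition": label,
                            "scheme": scheme_name,
                        }
                        for t, v in zip(s.times, s.values)
                    )
                mean = align.replica_mean_series(series)
                rows.extend(
                    {
                        "time_ps": t,
                        "value": v,
                        "replicate": "mean",
                        "condition": label,
                        "scheme": scheme_name,
                    }
                    for t, v in zip(mean.times, mean.values)
                )
            df = pd.DataFrame(rows)
            bundle.rmsd_tables[scheme_name] = df
            _write_csv(df, out_dir / f"rmsd_{scheme_name}.csv", cfg_hash)

    # --- RMSF ----------------------------------------------------------
    if "rmsf" in stages:
        rows = []
        for label, rs in sets.items():
            profile = align.rmsf_profile(rs, selection=config.selection)
            rows.extend(
                {"residue": int(r), "rmsf_A": v, "condition": label}
                for r, v in zip(profile.residue_indices, profile.values)
            )
        if rows:
            bundle.rmsf_table = pd.DataFrame(rows)
            _write_csv(bundle.rmsf_table, out_dir / "rmsf.csv", cfg_hash)

    # --- shape metrics and compaction deltas ---------------------------
    if "shape" in stages:
        for label, rs in sets.items():
            topo = rs.topology
            protein_idx = trajio.select_atoms(topo, "protein")
            radii = radii_table.assign(topo, protein_idx)
            # vacuum structures are single conformations: no trailing window
            win = None if rs.condition.phase == "vacuum" else window
            series = _shape_series(rs, config, radii, protein_idx, win)
            units = {"ccs": "A^2", "sasa": "A^2", "volume": "A^3"}
            bundle.shape_stats[label] = {
                metric: shape.window_stats(
                    series[metric], None, metric=metric, units=units[metric]
                )
                for metric in series
            }
        bundle.shape_table = _shape_table(bundle, config)
        _write_csv(bundle.shape_table, out_dir / "shape.csv", cfg_hash)
        # Δ columns need the full condition triplet
        sol_label = next(iter(solution), None)
        fields = sorted(
            {
                rs.condition.field
                for rs in rehydration.values()
                if any(
                    v.condition.field == rs.condition.field for v in vacuum.values()
                )
            }
        )
        if sol_label and fields:
            for metric in ("ccs", "sasa", "volume"):
                S = bundle.shape_stats[sol_label][metric].value
                V = {
                    rs.condition.field: bundle.shape_stats[label][metric].value
                    for label, rs in vacuum.items()
                }
                R = {
                    rs.condition.field: bundle.shape_stats[label][metric].value
                    for label, rs in rehydration.items()
                }
                fields_common = {f: V[f] for f in R if f in V}
                if fields_common:
                    bundle.deltas[metric] = shape.compaction_deltas(
                        S, V, {f: R[f] for f in R if f in V}
                    )

    # --- contacts ------------------------------------------------------
    if "contacts" in stages:
        for label, rs in sets.items():
            win = None if rs.condition.phase == "vacuum" else window
            cmap = contacts.occupancy_map(rs, win, cutoff=config.contact_cutoff)
            bundle.occupancy_maps[label] = cmap
            _write_matrix(cmap.matrix, cmap.labels, out_dir / f"occupancy_{_safe(label)}")
        for rl, rs in rehydration.items():
            for other_group, tag in ((vacuum, "vacuum"), (solution, "solution")):
                for ol, os_ in other_group.items():
                    if tag == "vacuum" and os_.condition.field != rs.condition.field:
                        continue
                    dmap = contacts.difference_map(
                        bundle.occupancy_maps[rl], bundle.occupancy_maps[ol]
                    )
                    key = f"{rl}_minus_{ol}"
                    bundle.difference_maps[key] = dmap
                    _write_matrix(
                        dmap.matrix, dmap.labels, out_dir / f"diff_{_safe(key)}"
                    )
        # composite triangles: zero-field minus 0.2 (lower) / minus 0.4 (upper)
        zf_map = None
        by_field = {}
        for label, rs in rehydration.items():
            by_field[rs.condition.field] = bundle.occupancy_maps[label]
        if 0.0 in by_field:
            zf_map = by_field[0.0]
            lower = upper = None
            if 0.2 in by_field:
                lower = contacts.difference_map(zf_map, by_field[0.2])
            if 0.4 in by_field:
                upper = contacts.difference_map(zf_map, by_field[0.4])
            if lower is not None and upper is not None:
                comp = contacts.composite_triangle_map(lower, upper)
                bundle.composite_maps["rehydration_0.0_vs_0.2_and_0.4"] = comp
                _write_matrix(
                    comp, zf_map.labels, out_dir / "composite_rehydration"
                )

    # --- hydrogen bonds ------------------------------------------------
    if "hbonds" in stages:
        criterion = config.hbond_criterion()
        rows = []
        for label, rs in sets.items():
            has_solvent = any(a.is_solvent for a in rs.topology.atoms)
            if not has_solvent:
                continue
            win = None if rs.condition.phase == "vacuum" else window
            stat = contacts.hbond_series_mean(rs, win, criterion)
            bundle.hbond_stats[label] = stat
            rows.append(
                {
                    "condition": label,
                    "mean": stat.value,
                    "sd": stat.uncertainty,
                    "n_frames": stat.n,
                }
            )
        if rows:
            _write_csv(pd.DataFrame(rows), out_dir / "hbonds.csv", cfg_hash)

    (out_dir / "metadata.json").write_text(
        json.dumps(
            {**bundle.metadata, "config": config.canonical_dict()},
            indent=2,
            sort_keys=True,
            default=str,
        )
    )
    return bundle


# ---------------------------------------------------------------------------
# tables


def _fmt_mean_sd(mean: float, sd: float) -> str:
    return f"{mean:.1f} (± {sd:.1f})"


def _shape_table(bundle: ReportBundle, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for label, stats in bundle.shape_stats.items():
        for metric, res in stats.items():
            value = res.value
            if metric == "ccs":
                calibrated = shape.apply_ccs_calibration(
                    value, config.ccs_calibration_factor
                )
            else:
                calibrated = np.nan
            rows.append(
                {
                    "condition": label,
                    "metric": metric,
                    "mean": value,
                    "sd": res.uncertainty,
                    "n_frames": res.n,
                    "calibrated_ccs": calibrated,
                    "units": res.units,
                }
            )
    return pd.DataFrame(rows).sort_values(["metric", "condition"]).reset_index(drop=True)


def export_table1(bundle: ReportBundle, path: str | Path | None = None) -> pd.DataFrame:
    """Compaction table: per metric, condition means ± sd plus the
    rounded Δ%-vs-vacuum and Δ%-vs-solution columns.

    Requires solution, vacuum and rehydration conditions in the bundle;
    missing cells are a hard error listing what is absent.
    """
    if bundle.shape_table is None:
        raise ValueError("shape stage has not run")
    stats = bundle.shape_stats
    phases = {label.split("@")[0] for label in stats}
    missing = {"solution", "vacuum", "rehydration"} - phases
    if missing:
        raise ValueError(
            f"cannot build compaction table; missing conditions: {sorted(missing)}"
        )
    rows = []
    for metric in ("ccs", "sasa", "volume"):
        row: dict = {"metric": metric}
        for label in sorted(stats):
            res = stats[label][metric]
            row[label] = _fmt_mean_sd(res.value, res.uncertainty)
        delta = bundle.deltas.get(metric)
        if delta is None:
            raise ValueError(f"missing compaction deltas for metric {metric!r}")
        row["delta_vs_vacuum_pct"] = delta.delta_vs_vacuum_pct
        row["delta_vs_solution_pct"] = delta.delta_vs_solution_pct
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        _write_csv(df, Path(path), bundle.config.hash())
    return df


def table_from_means(
    means: dict[str, dict],
) -> pd.DataFrame:
    """Δ columns computed directly from externally supplied condition
    means (an override path for comparing against published tables).

    ``means`` maps metric → {"solution": S, "vacuum": {field: V_f},
    "rehydration": {field: R_f}}.
    """
    rows = []
    for metric, spec in means.items():
        delta = shape.compaction_deltas(
            spec["solution"],
            {float(k): v for k, v in spec["vacuum"].items()},
            {float(k): v for k, v in spec["rehydration"].items()},
        )
        rows.append(
            {
                "metric": metric,
                "delta_vs_vacuum_pct": delta.delta_vs_vacuum_pct,
                "delta_vs_solution_pct": delta.delta_vs_solution_pct,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers


def _safe(label: str) -> str:
    return label.replace("@", "_").replace("/", "_")


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def _write_matrix(matrix: np.ndarray, labels: list[str], stem: Path) -> None:
    np.savetxt(f"{stem}.txt", matrix, fmt="%.6f")
    Path(f"{stem}.labels.txt").write_text("\n".join(labels) + "\n")
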