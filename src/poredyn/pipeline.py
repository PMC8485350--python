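"""Configuration-driven analysis pipeline with replicate aggregation.

A run is described by one YAML config naming either real inputs (topology +
one trajectory per replica) or a synthetic-generator spec, the pore region
(given or derived from the peptide geometry), and per-stage toggles and
parameters.  Each stage runs per replica; replicate aggregation is the mean
of replicate means with the sd taken across replicates.  Outputs are CSV
tables with unit-bearing headers, density grids as plain matrix files, a
JSON manifest and a plain-text log.  A failing stage is recorded in the
manifest and does not stop the remaining stages.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import __version__
from .confinement import filling_curve, mean_occupancy
from .core import Topology, Trajectory, load_topology, load_trajectory, select_group
from .density import density_map_xy, density_profile_z, normalize_map
from .dynamics import displacement_histogram, survival_probability, windowed_displacements
from .geometry import PoreRegion, derive_pore_region
from .hbond import HBondCriteria, count_hbonds_between
from .ions import count_entrants, first_minimum, ion_z_traces, rdf, selectivity_summary
from .synthetic import PoreSystemSpec, simulate_pore_system

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every violation."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


class SyntheticConfig(BaseModel):
    D_water: float = 2.3e-9
    box: tuple[float, float, float] = (6.0, 6.0, 6.0)
    membrane_slab: Optional[tuple[float, float]] = (2.0, 4.0)
    pore_radius: float = 0.5
    n_waters: int = 400
    n_cations: int = 10
    n_anions: int = 10
    anion_pore_penalty: float = 0.0
    dt: float = 1.0
    n_steps: int = 200
    n_replicas: int = 2


class InputConfig(BaseModel):
    topology: str
    trajectories: list[str]
    residues_per_ring: Optional[int] = None


class RegionConfig(BaseModel):
    center_xy: Optional[tuple[float, float]] = None
    z_lo: Optional[float] = None
    z_hi: Optional[float] = None
    radial_bound: Optional[float] = None
    margin: float = 0.0


class AnalysesConfig(BaseModel):
    occupancy: bool = True
    survival: bool = True
    displacement: bool = True
    hbonds: bool = False
    density: bool = True
    ions: bool = True
    window_length: float = 100.0
    n_windows: int = 160
    survival_max_lag: Optional[float] = None
    bin_size: float = 0.05
    hbond_max_da: float = 0.35
    hbond_max_angle: float = 30.0
    rdf_r_max: float = 1.0
    rdf_bin: float = 0.002
    coordination_cutoff: Optional[float] = None


class RunConfig(BaseModel):
    input: Optional[InputConfig] = None
    synthetic: Optional[SyntheticConfig] = None
    region: Optional[RegionConfig] = None
    analyses: AnalysesConfig = Field(default_factory=AnalysesConfig)
    output_dir: str = "poredyn_out"
    seed: int = 0

    @model_validator(mode="after")
    def _exclusive_inputs(self) -> "RunConfig":
        if (self.input is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'input' and 'synthetic' must be set")
        return self


@dataclass
class RunReport:
    output_dir: Path
    outputs: dict[str, Path] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    manifest_path: Path | None = None

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_config(path: str | Path) -> RunConfig:
    """Parse and fully validate a YAML run config; list every violation."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except OSError as exc:
        raise ConfigError([f"cannot read config: {exc}"])
    except yaml.YAMLError as exc:
        raise ConfigError([f"config does not parse as YAML: {exc}"])
    errors: list[str] = []
    try:
        config = RunConfig.model_validate(raw or {})
    except ValidationError as exc:
        raise ConfigError([f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()])
    if config.input is not None:
        if not Path(config.input.topology).exists():
            errors.append(f"topology not found: {config.input.topology}")
        if not config.input.trajectories:
            errors.append("at least one trajectory required")
        for t in config.input.trajectories:
            if not Path(t).exists():
                errors.append(f"trajectory not found: {t}")
    if errors:
        raise ConfigError(errors)
    return config


def _region_from_config(cfg: RegionConfig | None, topology: Topology, frame: np.ndarray) -> PoreRegion:
    if cfg is not None and None not in (cfg.z_lo, cfg.z_hi, cfg.radial_bound):
        center = cfg.center_xy or (float(frame[:, 0].mean()), float(frame[:, 1].mean()))
        return PoreRegion(center, cfg.z_lo - cfg.margin, cfg.z_hi + cfg.margin, cfg.radial_bound)
    margin = cfg.margin if cfg is not None else 0.0
    bound = cfg.radial_bound if cfg is not None else None
    return derive_pore_region(topology, frame, margin=margin, radial_bound=bound)


def _load_replicas(config: RunConfig) -> list[tuple[Topology, Trajectory, PoreRegion]]:
    replicas = []
    if config.synthetic is not None:
        s = config.synthetic
        for r in range(s.n_replicas):
            spec = PoreSystemSpec(
                D_water=s.D_water, box=s.box, membrane_slab=s.membrane_slab,
                pore_radius=s.pore_radius, n_waters=s.n_waters, n_cations=s.n_cations,
                n_anions=s.n_anions, anion_pore_penalty=s.anion_pore_penalty,
                dt=s.dt, n_steps=s.n_steps, seed=config.seed + r,
            )
            system = simulate_pore_system(spec)
            region = system.truth.region or _region_from_config(config.region, system.topology, system.trajectory.coords[0])
            replicas.append((system.topology, system.trajectory, region))
    else:
        topology = load_topology(config.input.topology, residues_per_ring=config.input.residues_per_ring)
        for path in config.input.trajectories:
            traj = load_trajectory(path, topology)
            region = _region_from_config(config.region, topology, traj.coords[0])
            replicas.append((topology, traj, region))
    return replicas


def _aggregate(per_replica: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    stack = np.stack(per_replica)
    sd = stack.std(axis=0, ddof=1) if len(per_replica) > 1 else np.zeros(stack.shape[1])
    return stack.mean(axis=0), sd


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all requested stages for every replica and aggregate.

    Stage failures are caught, logged and recorded in the manifest; the
    remaining stages still run.  Rerunning with the same seed reproduces
    every table bit-for-bit.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(output_dir=out_dir)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}")

    log(f"poredyn {__version__} pipeline start (seed={config.seed})")
    replicas = _load_replicas(config)
    log(f"{len(replicas)} replica(s) loaded")
    a = config.analyses
    criteria = HBondCriteria(a.hbond_max_da, a.hbond_max_angle)

    def stage(name: str, fn) -> None:
        try:
            fn()
            log(f"stage {name}: ok")
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            report.failures[name] = str(exc)
            log(f"stage {name}: FAILED ({exc})")

    def save(name: str, df: pd.DataFrame) -> None:
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        report.outputs[name] = path

    def do_occupancy() -> None:
        series = [filling_curve(t, reg, select_group(top, role="water_oxygen")) for top, t, reg in replicas]
        df = pd.DataFrame({"time_ps": series[0].times})
        for r, s in enumerate(series):
            df[f"count_rep{r}"] = s.counts
            df[f"cumulative_entrants_rep{r}"] = s.cumulative_entrants
        mean, sd = _aggregate([s.counts for s in series])
        df["count_mean"], df["count_sd"] = mean, sd
        save("occupancy", df)
        m, s_ = mean_occupancy(series)
        save("occupancy_summary", pd.DataFrame({"mean_count": [m], "sd_across_replicas": [s_]}))

    def do_survival() -> None:
        curves = [
            survival_probability(t, reg, select_group(top, role="water_oxygen"), max_lag=a.survival_max_lag)
            for top, t, reg in replicas
        ]
        n = min(len(c.lags) for c in curves)
        df = pd.DataFrame({"lag_ps": curves[0].lags[:n]})
        for r, c in enumerate(curves):
            df[f"P_rep{r}"] = c.probability[:n]
        mean, sd = _aggregate([c.probability[:n] for c in curves])
        df["P_mean"], df["P_sd"] = mean, sd
        save("survival", df)

    def do_displacement() -> None:
        dds = [
            windowed_displacements(t, reg, select_group(top, role="water_oxygen"), a.window_length, a.n_windows)
            for top, t, reg in replicas
        ]
        pooled = np.concatenate([d.displacements for d in dds])
        edges = np.histogram_bin_edges(pooled, bins=50)
        df = pd.DataFrame({"bin_lo_nm2": edges[:-1], "bin_hi_nm2": edges[1:]})
        for r, d in enumerate(dds):
            counts, _ = np.histogram(d.displacements, bins=edges)
            df[f"P_rep{r}"] = counts / counts.sum()
        mean, sd = _aggregate([df[f"P_rep{r}"].to_numpy() for r in range(len(dds))])
        df["P_mean"], df["P_sd"] = mean, sd
        save("displacement_histogram", df)

    def do_hbonds() -> None:
        rows = []
        for r, (top, t, reg) in enumerate(replicas):
            bb = select_group(top, role="backbone")
            m, s_ = count_hbonds_between(t, bb, bb, criteria)
            rows.append({"replica": r, "backbone_backbone_mean": m, "backbone_backbone_sd": s_})
        df = pd.DataFrame(rows)
        agg = {"replica": "aggregate", "backbone_backbone_mean": df["backbone_backbone_mean"].mean(),
               "backbone_backbone_sd": df["backbone_backbone_mean"].std(ddof=1) if len(df) > 1 else 0.0}
        save("hbond_counts", pd.concat([df, pd.DataFrame([agg])], ignore_index=True))

    def do_density() -> None:
        maps_xy = [density_map_xy(t, reg, select_group(top, role="water_oxygen"), a.bin_size) for top, t, reg in replicas]
        maps_xy = normalize_map(maps_xy)  # joint cross-replica reference
        for r, m in enumerate(maps_xy):
            path = out_dir / f"density_xy_rep{r}.txt"
            np.savetxt(path, m.normalized, header=f"normalized xy density, bin {a.bin_size} nm")
            report.outputs[f"density_xy_rep{r}"] = path
        profs = [density_profile_z(t, reg, select_group(top, role="water_oxygen"), a.bin_size) for top, t, reg in replicas]
        df = pd.DataFrame({"z_nm": (profs[0].edges[0][:-1] + profs[0].edges[0][1:]) / 2})
        for r, p in enumerate(profs):
            df[f"count_rep{r}"] = p.counts
        save("density_z", df)

    def do_ions() -> None:
        rows = []
        for r, (top, t, reg) in enumerate(replicas):
            cations = select_group(top, role="cation")
            anions = select_group(top, role="anion")
            ct = ion_z_traces(t, cations, reg) if len(cations) else []
            at = ion_z_traces(t, anions, reg) if len(anions) else []
            rep = selectivity_summary(ct, at)
            cutoff = a.coordination_cutoff
            if cutoff is None and len(cations):
                try:
                    curve = rdf(t, cations, select_group(top, role="water_oxygen"), r_max=a.rdf_r_max, bin_size=a.rdf_bin)
                    cutoff = first_minimum(curve)
                except ValueError:
                    cutoff = np.nan
            rows.append({
                "replica": r,
                "cation_entrants": rep.cation_entrants,
                "anion_entrants": rep.anion_entrants,
                "mean_occupancy_cation": rep.mean_occupancy_cation,
                "mean_occupancy_anion": rep.mean_occupancy_anion,
                "selectivity_ratio": rep.ratio,
                "coordination_cutoff_nm": cutoff,
            })
        save("ion_summary", pd.DataFrame(rows))

    if a.occupancy:
        stage("occupancy", do_occupancy)
    if a.survival:
        stage("survival", do_survival)
    if a.displacement:
        stage("displacement", do_displacement)
    if a.hbonds:
        stage("hbonds", do_hbonds)
    if a.density:
        stage("density", do_density)
    if a.ions:
        stage("ions", do_ions)

    manifest = {
        "poredyn_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "outputs": {k: str(v) for k, v in report.outputs.items()},
        "failures": report.failures,
    }
    report.manifest_path = out_dir / "manifest.json"
    report.manifest_path.write_text(json.dumps(manifest, indent=2))
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
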