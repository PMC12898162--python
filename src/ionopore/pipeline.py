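"""Pipeline orchestration: simulate -> grid -> solve -> detect -> report.

One run produces a RunReport (electroporation time, inner potential, charge
concentration) plus, when an output directory is given, the trajectory
(GRO + XYZ), cube grids, TSV profiles/maps and a JSON report. Everything is
deterministic for a given config + seed. The charge-density averaging window
is the field-on portion of the trajectory strictly before pore formation,
after discarding an initial equilibration fraction.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .grids import (
    GridSpec,
    axial_charge_profile,
    time_averaged_charge_density,
)
from .io import (
    config_from_mapping,
    save_config,
    write_cube,
    write_gro,
    write_map_tsv,
    write_profile_tsv,
    write_xyz,
)
from .kinematics import charge_concentration
from .langevin import counts_from_concentration, run_simulation
from .model import SyntheticConfig, Trajectory
from .poisson import inner_potential, solve_poisson, y_average
from .pores import DEFAULT_CUTOFF, DEFAULT_PERSISTENCE, PoreEvent, electroporation_time

__all__ = [
    "AnalysisParams",
    "RunReport",
    "StageError",
    "load_pipeline_config",
    "analyze_trajectory",
    "run_pipeline",
    "concentration_sweep",
]

log = logging.getLogger("ionopore.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class AnalysisParams:
    grid_spacing: float = 0.1  # nm, target; actual spacing snaps to the box
    scheme: str = "CIC"
    epsilon_r_poisson: float = 1.0
    pore_cutoff: float = DEFAULT_CUTOFF
    persistence: int = DEFAULT_PERSISTENCE
    slab_width: float = 1.0
    slab_offset: float = 1.0
    equilibration_fraction: float = 0.25


@dataclass
class RunReport:
    config: dict
    analysis: dict
    seed: int
    version: str
    electroporation_time_ns: float | None  # None when censored
    censored: bool
    inner_potential: dict
    charge_concentration_mol_e_per_L: float
    outputs: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)


def load_pipeline_config(path: str | Path) -> tuple[SyntheticConfig, AnalysisParams]:
    """Read a YAML pipeline config.

    Either a flat generator config, or a mapping with ``simulation:`` and an
    optional ``analysis:`` section. Unknown keys are an error in both.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError("pipeline config must be a mapping")
    if "simulation" in data:
        unknown = set(data) - {"simulation", "analysis"}
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        sim = config_from_mapping(data["simulation"])
        ana_raw = dict(data.get("analysis") or {})
        valid = set(AnalysisParams.__dataclass_fields__)
        unknown = set(ana_raw) - valid
        if unknown:
            raise ValueError(f"unknown analysis keys: {sorted(unknown)}")
        return sim, AnalysisParams(**ana_raw)
    return config_from_mapping(data), AnalysisParams()


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as err:
                raise StageError(f"stage {name!r} failed: {err}") from err
            log.info("stage=%s ok", name)
            return out

        return run

    return wrap


def _density_window(traj: Trajectory, pore: PoreEvent, equil_frac: float) -> list[int]:
    """Frame indices averaged for rho: after equilibration, strictly pre-pore."""
    end = len(traj) if pore.censored else pore.frame_index
    start = int(equil_frac * len(traj))
    idx = list(range(min(start, max(end - 1, 0)), end))
    if not idx:  # pore at frame 0: fall back to the initial frame
        idx = [0]
    return idx


def analyze_trajectory(
    traj: Trajectory, params: AnalysisParams = AnalysisParams()
) -> dict:
    """All per-run analysis products from a trajectory with config attached."""
    config = traj.config
    if config is None:
        raise ValueError("trajectory must carry its generator config")
    membrane = config.membrane

    pore = _stage("pore_detection")(electroporation_time)(
        traj, membrane, cutoff=params.pore_cutoff, persistence=params.persistence
    )

    spec = GridSpec.from_box(config.box, params.grid_spacing)
    window = _density_window(traj, pore, params.equilibration_fraction)

    rho = _stage("charge_density")(time_averaged_charge_density)(
        traj, spec, params.scheme, window
    )
    phi = _stage("poisson")(solve_poisson)(rho, params.epsilon_r_poisson)
    pmap = _stage("y_average")(y_average)(phi)
    inner = _stage("inner_potential")(inner_potential)(
        phi, membrane, params.slab_width, params.slab_offset
    )
    return {
        "pore": pore,
        "rho": rho,
        "phi": phi,
        "map": pmap,
        "inner": inner,
        "charge_profile": axial_charge_profile(rho),
        "window": window,
    }


def run_pipeline(
    config: SyntheticConfig,
    params: AnalysisParams = AnalysisParams(),
    outdir: str | Path | None = None,
    write_trajectory: bool = True,
) -> RunReport:
    """Simulate and analyze one system; optionally write all artifacts."""
    log.info("stage=simulate seed=%d n_steps=%d", config.seed, config.n_steps)
    traj = _stage("simulate")(run_simulation)(config)
    products = analyze_trajectory(traj, params)
    pore: PoreEvent = products["pore"]

    outputs: dict[str, str] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if write_trajectory:
            write_gro(outdir / "trajectory.gro", traj)
            write_xyz(outdir / "trajectory.xyz", traj)
            outputs["trajectory_gro"] = str(outdir / "trajectory.gro")
            outputs["trajectory_xyz"] = str(outdir / "trajectory.xyz")
        write_cube(outdir / "charge_density.cube", products["rho"])
        write_cube(outdir / "potential.cube", products["phi"])
        write_map_tsv(outdir / "potential_map_xz.tsv", products["map"])
        write_profile_tsv(outdir / "charge_profile.tsv", products["charge_profile"])
        write_profile_tsv(outdir / "potential_profile.tsv", products["inner"].profile)
        save_config(outdir / "config.yaml", config)
        outputs.update(
            charge_density_cube=str(outdir / "charge_density.cube"),
            potential_cube=str(outdir / "potential.cube"),
            potential_map=str(outdir / "potential_map_xz.tsv"),
            charge_profile=str(outdir / "charge_profile.tsv"),
            potential_profile=str(outdir / "potential_profile.tsv"),
        )

    report = RunReport(
        config=json.loads(json.dumps(_config_dict(config))),
        analysis=asdict(params),
        seed=config.seed,
        version=__version__,
        electroporation_time_ns=None if pore.censored else pore.time,
        censored=pore.censored,
        inner_potential=products["inner"].to_dict(),
        charge_concentration_mol_e_per_L=charge_concentration(config),
        outputs=outputs,
    )
    if outdir is not None:
        (Path(outdir) / "report.json").write_text(report.to_json())
        report.outputs["report"] = str(Path(outdir) / "report.json")
    return report


def _config_dict(config: SyntheticConfig) -> dict:
    return {
        "box": list(config.box),
        "membrane": [config.membrane.z_lower, config.membrane.z_upper],
        "species_counts": dict(config.species_counts),
        "applied_field_Ez": config.applied_field_Ez,
        "temperature": config.temperature,
        "timestep": config.timestep,
        "n_steps": config.n_steps,
        "frame_stride": config.frame_stride,
        "coulomb_cutoff": config.coulomb_cutoff,
        "seed": config.seed,
        "interacting": config.interacting,
        "epsilon_r": config.epsilon_r,
        "wall_sigma": config.wall_sigma,
    }


def concentration_sweep(
    base_config: SyntheticConfig,
    concentrations: Sequence[float],
    n_seeds: int = 5,
    salt: str = "NaCl",
    params: AnalysisParams = AnalysisParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run (concentration x seed) replicates and aggregate.

    Returns ``(runs, summary)``: one row per run, and per-concentration means
    and spreads. Censored runs are counted, never averaged as finite times.
    Duplicate concentrations merge into one summary row with combined seeds.
    """
    if len(concentrations) == 0:
        raise ValueError("concentration list must not be empty")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    rows = []
    for conc in concentrations:
        counts = counts_from_concentration(
            conc, salt, base_config.box, base_config.membrane
        )
        counts = {**base_config.species_counts, **counts}
        for k in range(n_seeds):
            cfg = base_config.with_(
                species_counts=counts, seed=base_config.seed + k
            )
            report = run_pipeline(cfg, params, outdir=None)
            rows.append(
                {
                    "salt": salt,
                    "concentration_mol_per_L": conc,
                    "charge_concentration_mol_e_per_L": report.charge_concentration_mol_e_per_L,
                    "seed": cfg.seed,
                    "inner_potential_V": report.inner_potential["delta_phi_V"],
                    "pore_time_ns": report.electroporation_time_ns,
                    "censored": report.censored,
                }
            )
    runs = pd.DataFrame(rows)

    def agg(group: pd.DataFrame) -> pd.Series:
        finite = group.loc[~group["censored"], "pore_time_ns"]
        return pd.Series(
            {
                "n_runs": len(group),
                "n_censored": int(group["censored"].sum()),
                "charge_concentration_mol_e_per_L": group[
                    "charge_concentration_mol_e_per_L"
                ].iloc[0],
                "inner_potential_mean_V": group["inner_potential_V"].mean(),
                "inner_potential_std_V": group["inner_potential_V"].std(ddof=1),
                "pore_time_mean_ns": finite.mean() if len(finite) else np.nan,
                "pore_time_std_ns": finite.std(ddof=1) if len(finite) > 1 else np.nan,
            }
        )

    summary = (
        runs.groupby(["salt", "concentration_mol_per_L"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    return runs, summary
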