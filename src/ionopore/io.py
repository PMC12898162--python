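"""File formats: GRO / XYZ trajectories, Gaussian cube grids, TSV tables, YAML config.

Dialects
--------
GRO: one model per frame (title carries ``t= <ns>``), coordinates in nm, a box
line per frame — the standard GROMACS layout, concatenated for multi-frame.
XYZ: plain XYZ with coordinates in angstrom (the format's convention); the
comment line carries the time stamp and box.
Cube: charge densities are stored in e/bohr^3 (the format's atomic-unit
convention, converted on write/read); potential grids are stored in volts,
flagged in the comment line as a dialect note. One dummy atom is emitted for
reader compatibility.
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .constants import BOHR_NM
from .grids import AxialProfile, GridSpec, ScalarGrid3D
from .model import Frame, MembraneSlab, SyntheticConfig, Trajectory, get_species
from .poisson import PotentialMap2D

__all__ = [
    "write_gro",
    "read_gro",
    "write_xyz",
    "read_xyz",
    "write_cube",
    "read_cube",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_map_tsv",
    "load_config",
    "save_config",
]

_NM_TO_ANG = 10.0


# ---------------------------------------------------------------- GRO / XYZ

def write_gro(path: str | Path, trajectory: Trajectory) -> None:
    names = [sp.name for sp in trajectory.species]
    with open(path, "w") as fh:
        for frame in trajectory:
            fh.write(f"ionopore trajectory, t= {frame.time:.6f} ns\n")
            fh.write(f"{frame.n_particles:5d}\n")
            for i in range(frame.n_particles):
                name = names[frame.species_index[i]]
                x, y, z = frame.positions[i]
                resid = (i % 99999) + 1
                fh.write(
                    f"{resid:5d}{name:<5s}{name:>5s}{resid:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            lx, ly, lz = frame.box
            fh.write(f"{lx:10.5f}{ly:10.5f}{lz:10.5f}\n")


def read_gro(path: str | Path) -> Trajectory:
    frames: list[Frame] = []
    name_order: list[str] = []
    with open(path) as fh:
        while True:
            title = fh.readline()
            if not title:
                break
            time = _parse_time(title)
            n = int(fh.readline())
            pos = np.empty((n, 3))
            spidx = np.empty(n, dtype=np.intp)
            for i in range(n):
                line = fh.readline()
                name = line[5:10].strip()
                if name not in name_order:
                    name_order.append(name)
                spidx[i] = name_order.index(name)
                pos[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            box = tuple(float(v) for v in fh.readline().split()[:3])
            frames.append(Frame(time, pos, spidx, box))
    species = tuple(get_species(n) for n in name_order)
    return Trajectory(frames, species)


def write_xyz(path: str | Path, trajectory: Trajectory) -> None:
    names = [sp.name for sp in trajectory.species]
    with open(path, "w") as fh:
        for frame in trajectory:
            fh.write(f"{frame.n_particles}\n")
            lx, ly, lz = frame.box
            fh.write(f"t= {frame.time:.6f} ns box= {lx:.6f} {ly:.6f} {lz:.6f} nm\n")
            for i in range(frame.n_particles):
                x, y, z = frame.positions[i] * _NM_TO_ANG
                fh.write(
                    f"{names[frame.species_index[i]]:<5s}"
                    f"{x:14.6f}{y:14.6f}{z:14.6f}\n"
                )


def read_xyz(path: str | Path) -> Trajectory:
    frames: list[Frame] = []
    name_order: list[str] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            time = _parse_time(comment)
            box = _parse_box(comment)
            pos = np.empty((n, 3))
            spidx = np.empty(n, dtype=np.intp)
            for i in range(n):
                parts = fh.readline().split()
                name = parts[0]
                if name not in name_order:
                    name_order.append(name)
                spidx[i] = name_order.index(name)
                pos[i] = [float(v) / _NM_TO_ANG for v in parts[1:4]]
            frames.append(Frame(time, pos, spidx, box))
    species = tuple(get_species(n) for n in name_order)
    return Trajectory(frames, species)


def _parse_time(line: str) -> float:
    if "t=" not in line:
        raise ValueError(f"no time stamp in frame header: {line!r}")
    return float(line.split("t=")[1].split()[0])


def _parse_box(line: str) -> tuple[float, float, float]:
    if "box=" not in line:
        raise ValueError(f"no box in frame header: {line!r}")
    vals = line.split("box=")[1].split()[:3]
    return tuple(float(v) for v in vals)


# ---------------------------------------------------------------- cube

def write_cube(path: str | Path, grid: ScalarGrid3D) -> None:
    nx, ny, nz = grid.spec.dims
    dx, dy, dz = (s / BOHR_NM for s in grid.spec.spacing)
    if grid.quantity == "charge_density":
        values = grid.values * BOHR_NM**3  # e/nm^3 -> e/bohr^3
        note = "values in e/bohr^3"
    else:
        values = grid.values
        note = f"DIALECT: values in native units ({grid.quantity}; V for potential)"
    with open(path, "w") as fh:
        fh.write(f"ionopore scalar field: {grid.quantity}\n")
        fh.write(f"{note}; loop order x (outer), y, z (inner)\n")
        fh.write(f"{1:5d}{0.0:12.6f}{0.0:12.6f}{0.0:12.6f}\n")
        fh.write(f"{nx:5d}{dx:12.6f}{0.0:12.6f}{0.0:12.6f}\n")
        fh.write(f"{ny:5d}{0.0:12.6f}{dy:12.6f}{0.0:12.6f}\n")
        fh.write(f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{dz:12.6f}\n")
        fh.write(f"{1:5d}{0.0:12.6f}{0.0:12.6f}{0.0:12.6f}{0.0:12.6f}\n")  # dummy atom
        flat = values.reshape(-1)
        for start in range(0, flat.size, 6):
            fh.write(
                "".join(f"{v: 14.6e}" for v in flat[start : start + 6]) + "\n"
            )


def read_cube(path: str | Path) -> ScalarGrid3D:
    with open(path) as fh:
        title = fh.readline()
        fh.readline()
        quantity = title.split(":", 1)[1].strip() if ":" in title else "charge_density"
        natoms = int(fh.readline().split()[0])
        dims, spacing = [], []
        for axis in range(3):
            parts = fh.readline().split()
            dims.append(int(parts[0]))
            spacing.append(float(parts[1 + axis]) * BOHR_NM)
        for _ in range(abs(natoms)):
            fh.readline()
        flat = np.array(fh.read().split(), dtype=float)
    values = flat.reshape(dims)
    if quantity == "charge_density":
        values = values / BOHR_NM**3
    return ScalarGrid3D(GridSpec(tuple(spacing), tuple(dims)), values, quantity)


# ---------------------------------------------------------------- TSV tables

def write_profile_tsv(path: str | Path, profile: AxialProfile) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {profile.quantity} ({profile.units})\n")
        fh.write("z_nm\tvalue\n")
        for z, v in zip(profile.z_centers, profile.values):
            fh.write(f"{z:.6f}\t{v:.10e}\n")


def read_profile_tsv(path: str | Path) -> AxialProfile:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
        quantity, units = header.rsplit("(", 1)
        fh.readline()
        data = np.loadtxt(fh)
    return AxialProfile(data[:, 0], data[:, 1], quantity.strip(), units.rstrip(")"))


def write_map_tsv(path: str | Path, pmap: PotentialMap2D) -> None:
    """Potential map as a TSV matrix: first row z centers, first column x centers."""
    with open(path, "w") as fh:
        fh.write("# y-averaged potential map, V; rows: x (nm), columns: z (nm)\n")
        fh.write("x\\z\t" + "\t".join(f"{z:.6f}" for z in pmap.z_centers) + "\n")
        for x, row in zip(pmap.x_centers, pmap.values):
            fh.write(f"{x:.6f}\t" + "\t".join(f"{v:.8e}" for v in row) + "\n")


# ---------------------------------------------------------------- config

_CONFIG_KEYS = {
    "box",
    "membrane",
    "species_counts",
    "applied_field_Ez",
    "temperature",
    "timestep",
    "n_steps",
    "frame_stride",
    "coulomb_cutoff",
    "seed",
    "interacting",
    "epsilon_r",
    "wall_sigma",
}


def config_from_mapping(data: Mapping) -> SyntheticConfig:
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "box" in kwargs:
        kwargs["box"] = tuple(float(v) for v in kwargs["box"])
    if "membrane" in kwargs and kwargs["membrane"] is not None:
        lo, hi = kwargs["membrane"]
        kwargs["membrane"] = MembraneSlab(float(lo), float(hi))
    return SyntheticConfig(**kwargs)


def load_config(path: str | Path) -> SyntheticConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError("config file must contain a key-value mapping")
    return config_from_mapping(data)


def save_config(path: str | Path, config: SyntheticConfig) -> None:
    data = {
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
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
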