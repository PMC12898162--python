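"""Electrophoretic ion kinematics: unwrapping, drift, surface accumulation,
and the charge-concentration covariate.

Unwrapping accumulates per-step minimum-image displacements, so it is valid
only while no particle moves half a box edge between stored frames (checked).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import MOLAR_TO_PER_NM3
from .model import MembraneSlab, SyntheticConfig, Trajectory, get_species

__all__ = [
    "unwrap",
    "drift_displacement",
    "surface_accumulation",
    "charge_concentration",
]


def unwrap(trajectory: Trajectory) -> np.ndarray:
    """Continuous displacements, shape (n_frames, n_particles, 3), nm.

    Row 0 is zero; subsequent rows accumulate minimum-image frame-to-frame
    displacements. Raises if any single-frame jump reaches L/2 on an axis
    (ambiguous image), naming the particle and frame.
    """
    box = np.asarray(trajectory.frames[0].box)
    n_frames = len(trajectory)
    n = trajectory.frames[0].n_particles
    disp = np.zeros((n_frames, n, 3))
    for f in range(1, n_frames):
        d = trajectory.frames[f].positions - trajectory.frames[f - 1].positions
        d -= box * np.round(d / box)
        bad = np.abs(d) >= box / 2.0 - 1e-12
        if bad.any():
            p, ax = np.argwhere(bad)[0]
            raise ValueError(
                f"ambiguous periodic jump (|d| >= L/2) for particle {int(p)} "
                f"axis {int(ax)} between frames {f-1} and {f}; store frames "
                "more often"
            )
        disp[f] = disp[f - 1] + d
    return disp


def rewrap(trajectory: Trajectory, displacements: np.ndarray) -> np.ndarray:
    """Positions recovered from frame-0 coordinates plus displacements, wrapped."""
    box = np.asarray(trajectory.frames[0].box)
    return (trajectory.frames[0].positions[None] + displacements) % box


def drift_displacement(
    trajectory: Trajectory, displacements: np.ndarray, species: str
) -> pd.DataFrame:
    """Ensemble-mean z-displacement vs time for one species.

    Under a positive applied E_z the slope's sign matches the species valence.
    Returns columns ``time`` (ns) and ``mean_dz`` (nm).
    """
    mask = trajectory.species_mask(species)
    if not mask.any():
        raise ValueError(f"no particles of species {species!r}")
    mean_dz = displacements[:, mask, 2].mean(axis=1)
    return pd.DataFrame({"time": trajectory.times, "mean_dz": mean_dz})


def drift_velocity(
    trajectory: Trajectory, displacements: np.ndarray, species: str
) -> float:
    """Least-squares slope of mean z-displacement vs time, nm/ns."""
    df = drift_displacement(trajectory, displacements, species)
    t = df["time"].to_numpy()
    return float(np.polyfit(t, df["mean_dz"].to_numpy(), 1)[0])


def surface_accumulation(
    trajectory: Trajectory, membrane: MembraneSlab | None = None, shell: float = 1.0
) -> pd.DataFrame:
    """Per-frame counts of each species within ``shell`` of each membrane face.

    The upper shell is [z_upper, z_upper+shell], the lower [z_lower-shell,
    z_lower]. Returns tidy columns frame, time, species, face, count.
    """
    if shell <= 0:
        raise ValueError("shell must be > 0")
    if membrane is None:
        if trajectory.config is None:
            raise ValueError("membrane slab required when trajectory has no config")
        membrane = trajectory.config.membrane
    rows = []
    names = [sp.name for sp in trajectory.species]
    for i, frame in enumerate(trajectory):
        z = frame.positions[:, 2]
        upper = (z >= membrane.z_upper) & (z <= membrane.z_upper + shell)
        lower = (z >= membrane.z_lower - shell) & (z <= membrane.z_lower)
        for s, name in enumerate(names):
            sp_mask = frame.species_index == s
            rows.append((i, frame.time, name, "upper", int((sp_mask & upper).sum())))
            rows.append((i, frame.time, name, "lower", int((sp_mask & lower).sum())))
    return pd.DataFrame(rows, columns=["frame", "time", "species", "face", "count"])


def charge_concentration(
    source: SyntheticConfig | None = None,
    salt: str | None = None,
    molarity: float | None = None,
) -> float:
    """Cationic charge concentration, mol*e/L.

    Defined as the sum over cation species of molar concentration times
    valence (a stated convention: NaCl at c gives c, MgCl2 at c gives 2c).
    Accepts either a generator config (cation molarity inferred from counts
    and solvent volume) or an explicit salt + molarity.
    """
    if source is not None:
        total = 0.0
        for name, count in source.species_counts.items():
            sp = get_species(name)
            if sp.valence > 0:
                c = count / (MOLAR_TO_PER_NM3 * source.solvent_volume)
                total += c * sp.valence
        return total
    if salt is None or molarity is None:
        raise ValueError("provide either a config or salt + molarity")
    if molarity < 0:
        raise ValueError("molarity must be >= 0")
    valence = {"NaCl": 1, "MgCl2": 2}.get(salt)
    if valence is None:
        raise ValueError(f"unknown salt {salt!r}; supported: NaCl, MgCl2")
    return molarity * valence
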