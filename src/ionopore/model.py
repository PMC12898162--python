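"""Domain types: ion species, membrane slab, frames, trajectories, run config.

The membrane is represented as an impermeable slab [z_lower, z_upper]; ions and
free water markers reflect off its faces, while planted water-chain beads (the
pore-detection fixtures) are static and may sit inside it.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "IonSpecies",
    "MembraneSlab",
    "SyntheticConfig",
    "Frame",
    "Trajectory",
    "SPECIES_REGISTRY",
    "get_species",
]


@dataclass(frozen=True)
class IonSpecies:
    """A particle species of the electrolyte model.

    Parameters
    ----------
    name
        Short label (also used as GRO residue/atom name, <= 5 chars).
    valence
        Signed charge in units of e. 0 marks water/marker beads.
    diffusion_coefficient
        nm^2/ns. Zero freezes the species (used for planted chain beads).
    mass
        amu. Coarse-grained water beads represent 4 waters (72 amu).
    """

    name: str
    valence: int
    diffusion_coefficient: float
    mass: float

    def __post_init__(self) -> None:
        if self.valence not in (-2, -1, 0, 1, 2):
            raise ValueError(f"unsupported valence {self.valence} for {self.name}")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.mass <= 0:
            raise ValueError("mass must be > 0")


# Diffusion coefficients are infinite-dilution values at ~310 K (nm^2/ns);
# the water bead is a 4-water coarse-grained particle.
SPECIES_REGISTRY: dict[str, IonSpecies] = {
    "NA": IonSpecies("NA", +1, 1.33, 22.99),
    "CL": IonSpecies("CL", -1, 2.03, 35.45),
    "MG": IonSpecies("MG", +2, 0.706, 24.305),
    "W": IonSpecies("W", 0, 2.3, 72.0),
    "WCH": IonSpecies("WCH", 0, 0.0, 72.0),  # planted water-chain bead, frozen
}


def get_species(name: str) -> IonSpecies:
    try:
        return SPECIES_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown species {name!r}; known: {sorted(SPECIES_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class MembraneSlab:
    """The z-interval occupied by the bilayer; its faces are the leaflet planes."""

    z_lower: float
    z_upper: float

    def __post_init__(self) -> None:
        if not self.z_lower < self.z_upper:
            raise ValueError("membrane slab requires z_lower < z_upper")

    @property
    def thickness(self) -> float:
        return self.z_upper - self.z_lower

    @property
    def midplane(self) -> float:
        return 0.5 * (self.z_lower + self.z_upper)

    @classmethod
    def centered(cls, lz: float, thickness: float = 4.3) -> "MembraneSlab":
        mid = 0.5 * lz
        return cls(mid - 0.5 * thickness, mid + 0.5 * thickness)


#: Default box matching the study system, nm.
DEFAULT_BOX: tuple[float, float, float] = (18.1, 18.1, 12.6)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the Brownian-dynamics electrolyte generator.

    ``wall_sigma`` places an antisymmetric uniform surface charge on the slab
    faces (+wall_sigma e/nm^2 on the upper face, -wall_sigma on the lower), so
    the wall is globally neutral and the electrolyte stays neutral too; it
    exists for equilibrium double-layer validation fixtures and defaults to 0.
    """

    box: tuple[float, float, float] = DEFAULT_BOX
    membrane: MembraneSlab | None = None
    species_counts: Mapping[str, int] = field(default_factory=dict)
    applied_field_Ez: float = 0.2  # V/nm
    temperature: float = 310.0  # K
    timestep: float = 1e-3  # ns
    n_steps: int = 1000
    frame_stride: int = 10
    coulomb_cutoff: float = 1.4  # nm
    seed: int = 0
    interacting: bool = False
    epsilon_r: float = 78.0
    wall_sigma: float = 0.0  # e/nm^2 per slab face

    def __post_init__(self) -> None:
        if self.membrane is None:
            object.__setattr__(self, "membrane", MembraneSlab.centered(self.box[2]))
        object.__setattr__(self, "species_counts", dict(self.species_counts))
        if any(L <= 0 for L in self.box):
            raise ValueError("box edges must be positive")
        m = self.membrane
        if not (0.0 < m.z_lower and m.z_upper < self.box[2]):
            raise ValueError("membrane slab must lie strictly inside the box z-extent")
        if any(c < 0 for c in self.species_counts.values()):
            raise ValueError("species counts must be >= 0")
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.n_steps < 0 or self.frame_stride < 1:
            raise ValueError("n_steps >= 0 and frame_stride >= 1 required")
        if (
            self.interacting
            and np.isfinite(self.coulomb_cutoff)
            and min(self.box) <= 2 * self.coulomb_cutoff
        ):
            raise ValueError(
                "interacting mode requires box edges > 2*coulomb_cutoff "
                "(minimum-image convention)"
            )
        net = self.total_ion_charge
        if abs(net) > 1e-9:
            raise ValueError(f"system not electroneutral: ion charge {net} e")

    @property
    def species_table(self) -> tuple[IonSpecies, ...]:
        return tuple(get_species(name) for name in self.species_counts)

    @property
    def total_ion_charge(self) -> float:
        return float(
            sum(get_species(n).valence * c for n, c in self.species_counts.items())
        )

    @property
    def wall_face_charge(self) -> float:
        """Charge on the upper face, e (the lower face carries the negative)."""
        return self.wall_sigma * self.box[0] * self.box[1]

    @property
    def solvent_volume(self) -> float:
        """Box volume minus the membrane slab volume, nm^3."""
        lx, ly, lz = self.box
        return lx * ly * (lz - self.membrane.thickness)

    @property
    def n_frames(self) -> int:
        return self.n_steps // self.frame_stride + 1

    def with_(self, **changes) -> "SyntheticConfig":
        return replace(self, **changes)


@dataclass
class Frame:
    """One trajectory frame: wrapped positions, species indices, time, box."""

    time: float
    positions: np.ndarray  # (N, 3) nm, wrapped into [0, L)
    species_index: np.ndarray  # (N,) int, indices into the species table
    box: tuple[float, float, float]
    planted_chain: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.species_index = np.asarray(self.species_index, dtype=np.intp).ravel()
        if self.positions.shape[0] != self.species_index.shape[0]:
            raise ValueError("positions and species_index lengths differ")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "Frame":
        return Frame(
            self.time,
            self.positions.copy(),
            self.species_index.copy(),
            tuple(self.box),
            self.planted_chain,
        )


@dataclass
class Trajectory:
    """Ordered frames with a shared species table and optional run config."""

    frames: list[Frame]
    species: tuple[IonSpecies, ...]
    config: SyntheticConfig | None = None

    def __post_init__(self) -> None:
        self.frames = list(self.frames)
        self.species = tuple(self.species)
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        times = [f.time for f in self.frames]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        n0 = self.frames[0].n_particles
        if any(f.n_particles != n0 for f in self.frames):
            raise ValueError("particle count must be constant across frames")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def charges(self) -> np.ndarray:
        """Per-particle charge (e) for any frame (constant across frames)."""
        valences = np.array([sp.valence for sp in self.species], dtype=float)
        return valences[self.frames[0].species_index]

    def masses(self) -> np.ndarray:
        m = np.array([sp.mass for sp in self.species], dtype=float)
        return m[self.frames[0].species_index]

    def species_mask(self, names: Iterable[str] | str) -> np.ndarray:
        """Boolean particle mask selecting the named species."""
        if isinstance(names, str):
            names = [names]
        wanted = set(names)
        known = {sp.name for sp in self.species}
        missing = wanted - known
        if missing:
            raise KeyError(f"species not in trajectory: {sorted(missing)}")
        idx = {i for i, sp in enumerate(self.species) if sp.name in wanted}
        return np.isin(self.frames[0].species_index, list(idx))

    def ion_mask(self) -> np.ndarray:
        """Particles with nonzero valence (solution ions only)."""
        valences = np.array([sp.valence for sp in self.species])
        return valences[self.frames[0].species_index] != 0
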