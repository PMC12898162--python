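"""Brownian-dynamics electrolyte generator.

Produces trajectories with the statistical structure relevant to the inner
potential analysis: electrophoretic drift of cations/anions under a uniform
field along +z, accumulation against an impermeable membrane slab, charge
neutrality, and (in interacting mode) Debye-type screening. Dynamics are
overdamped Langevin:

    x' = x + (D / k_B T) * F * dt + sqrt(2 D dt) * xi,   xi ~ N(0, 1)

with F the sum of the applied-field force q*E_z, optional wall-sheet forces
and (interacting mode) minimum-image truncated Coulomb forces. A free ion's
mean drift velocity is therefore D*q*E_z/(k_B T), the Einstein relation the
tests check against.

This is a statistical stand-in for coarse-grained MD, not an MD engine: no
inertia, implicit solvent (uniform epsilon_r scaling the Coulomb forces), no
lipid degrees of freedom.
"""
from __future__ import annotations

import numpy as np

from .constants import EPS0, MOLAR_TO_PER_NM3, thermal_energy, COULOMB_K
from .model import (
    Frame,
    IonSpecies,
    MembraneSlab,
    SyntheticConfig,
    Trajectory,
    get_species,
)

__all__ = [
    "NumericalInstabilityError",
    "counts_from_concentration",
    "water_count_for_density",
    "initialize_system",
    "step_langevin",
    "run_simulation",
    "plant_transmembrane_chain",
]

#: Pair distances are clamped below this (nm) when evaluating Coulomb forces:
#: a soft-core regularization standing in for the finite ion/bead core.
SOFTCORE_RMIN = 0.3

#: Placement-capacity guard, particles per nm^3 of solvent.
MAX_NUMBER_DENSITY = 50.0


class NumericalInstabilityError(RuntimeError):
    """A Langevin step produced a non-finite coordinate."""


def counts_from_concentration(
    concentration: float,
    salt: str,
    box: tuple[float, float, float],
    membrane: MembraneSlab | None = None,
) -> dict[str, int]:
    """Ion counts for a salt molarity in the solvent-accessible volume.

    The cation count is rounded to the nearest integer; the Cl- count is then
    fixed by electroneutrality (|z_cation| anions per cation).
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    lx, ly, lz = box
    v_solvent = lx * ly * lz
    if membrane is not None:
        v_solvent -= lx * ly * membrane.thickness
    if v_solvent <= 0:
        raise ValueError("solvent-accessible volume must be positive")
    cation = {"NaCl": "NA", "MgCl2": "MG"}.get(salt)
    if cation is None:
        raise ValueError(f"unknown salt {salt!r}; supported: NaCl, MgCl2")
    n_cat = int(round(concentration * MOLAR_TO_PER_NM3 * v_solvent))
    z = get_species(cation).valence
    return {cation: n_cat, "CL": n_cat * z}


def water_count_for_density(
    number_density: float, box: tuple[float, float, float], membrane: MembraneSlab | None
) -> int:
    """Water-bead count giving ``number_density`` (nm^-3) in the solvent region."""
    lx, ly, lz = box
    v = lx * ly * lz - (lx * ly * membrane.thickness if membrane else 0.0)
    return int(round(number_density * v))


def _sample_solvent_z(rng: np.random.Generator, n: int, lz: float, m: MembraneSlab):
    """Uniform z in [0, z_lower] U [z_upper, Lz]."""
    u = rng.uniform(0.0, lz - m.thickness, size=n)
    return np.where(u < m.z_lower, u, u + m.thickness)


def initialize_system(config: SyntheticConfig, rng_seed: int | None = None) -> Frame:
    """Place all configured particles uniformly at random in the solvent region.

    Deterministic for a given seed. Planted-chain beads are never created here;
    see :func:`plant_transmembrane_chain`.
    """
    seed = config.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    lx, ly, lz = config.box
    total = sum(config.species_counts.values())
    if total > MAX_NUMBER_DENSITY * config.solvent_volume:
        raise ValueError(
            f"{total} particles exceed placement capacity of the solvent region "
            f"({config.solvent_volume:.1f} nm^3)"
        )
    positions = np.empty((total, 3))
    species_index = np.empty(total, dtype=np.intp)
    at = 0
    for i, (name, count) in enumerate(config.species_counts.items()):
        positions[at : at + count, 0] = rng.uniform(0, lx, size=count)
        positions[at : at + count, 1] = rng.uniform(0, ly, size=count)
        positions[at : at + count, 2] = _sample_solvent_z(
            rng, count, lz, config.membrane
        )
        species_index[at : at + count] = i
        at += count
    return Frame(0.0, positions, species_index, config.box)


def _species_arrays(config: SyntheticConfig):
    table = config.species_table
    counts = list(config.species_counts.values())
    idx = np.repeat(np.arange(len(table)), counts)
    D = np.array([sp.diffusion_coefficient for sp in table])[idx]
    q = np.array([float(sp.valence) for sp in table])[idx]
    return D, q


def _coulomb_forces(pos, q, box, cutoff, epsilon_r):
    """Minimum-image pairwise Coulomb forces with hard cutoff, eV/nm.

    O(N^2) with broadcasting; pair distances are clamped at SOFTCORE_RMIN so
    overlapping point charges cannot produce divergent forces.
    """
    L = np.asarray(box)
    d = pos[:, None, :] - pos[None, :, :]
    d -= L * np.round(d / L)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    np.fill_diagonal(r2, np.inf)
    r2 = np.maximum(r2, SOFTCORE_RMIN**2)
    within = r2 <= cutoff * cutoff
    inv_r3 = np.where(within, r2**-1.5, 0.0)
    qq = q[:, None] * q[None, :]
    # F_i = k/eps_r * sum_j q_i q_j (r_i - r_j) / r^3
    coef = (COULOMB_K / epsilon_r) * qq * inv_r3
    return np.einsum("ij,ijk->ik", coef, d)


def _wall_field(z, q, config: SyntheticConfig):
    """Force (eV/nm, z-component) from uniformly charged slab faces.

    The upper face carries +wall_sigma, the lower face -wall_sigma: a periodic
    capacitor whose exact 1D field in the solvent channel is the uniform
    return field

        E_z = wall_sigma * t_membrane / (Lz * eps_r * eps0),

    driving cations toward the negative (lower) face around the periodic
    channel and anions toward the positive (upper) face. For self-consistent
    equilibrium screening of this exact long-range field, pair interactions
    should be all-pairs minimum-image (coulomb_cutoff = inf).
    """
    if config.wall_sigma == 0.0:
        return 0.0
    m = config.membrane
    e_z = (
        config.wall_sigma
        * m.thickness
        / (config.box[2] * config.epsilon_r * EPS0)
    )
    return q * e_z


def _step(pos, spid, D, q, config: SyntheticConfig, rng, step_index=0):
    kT = thermal_energy(config.temperature)
    dt = config.timestep
    m = config.membrane
    lz = config.box[2]

    force = np.zeros_like(pos)
    force[:, 2] = q * config.applied_field_Ez
    force[:, 2] += _wall_field(pos[:, 2], q, config)
    if config.interacting:
        force += _coulomb_forces(
            pos, q, config.box, config.coulomb_cutoff, config.epsilon_r
        )

    mobility = (D / kT)[:, None]
    noise = np.sqrt(2.0 * D * dt)[:, None] * rng.standard_normal(pos.shape)
    mobile = D > 0  # frozen beads (planted chains) never move
    new = pos + np.where(mobile[:, None], mobility * force * dt + noise, 0.0)

    if not np.all(np.isfinite(new)):
        bad = int(np.argwhere(~np.isfinite(new))[0, 0])
        raise NumericalInstabilityError(
            f"non-finite coordinate for particle {bad} at step {step_index}"
        )

    # Specular reflection off the slab faces, based on the pre-step side.
    z_old, z_new = pos[:, 2], new[:, 2]
    inside = (z_new > m.z_lower) & (z_new < m.z_upper) & mobile
    from_below = inside & (z_old <= m.midplane)
    from_above = inside & (z_old > m.midplane)
    z_new = np.where(from_below, 2.0 * m.z_lower - z_new, z_new)
    z_new = np.where(from_above, 2.0 * m.z_upper - z_new, z_new)
    still = (z_new > m.z_lower) & (z_new < m.z_upper) & mobile
    if np.any(still):
        bad = int(np.argwhere(still)[0, 0])
        raise NumericalInstabilityError(
            f"particle {bad} crossed the membrane slab in one step "
            f"(step {step_index}); reduce the timestep"
        )
    new[:, 2] = z_new
    new %= np.asarray(config.box)
    return new


def step_langevin(
    frame: Frame, config: SyntheticConfig, rng: np.random.Generator
) -> Frame:
    """Advance one overdamped Langevin step; periodic wrap, slab reflection."""
    D, q = _species_arrays(config)
    if D.shape[0] != frame.n_particles:
        raise ValueError("frame particle count does not match config species_counts")
    new = _step(frame.positions, frame.species_index, D, q, config, rng)
    return Frame(
        frame.time + config.timestep,
        new,
        frame.species_index.copy(),
        frame.box,
        frame.planted_chain,
    )


def run_simulation(
    config: SyntheticConfig, initial: Frame | None = None
) -> Trajectory:
    """Run the generator, storing every ``frame_stride``-th step (plus frame 0).

    Bit-reproducible for a given config+seed.
    """
    rng = np.random.default_rng(config.seed + 1)  # decorrelated from placement
    frame0 = initialize_system(config) if initial is None else initial.copy()
    D, q = _species_arrays(config)
    if D.shape[0] != frame0.n_particles:
        raise ValueError("initial frame does not match config species_counts")
    pos = frame0.positions.copy()
    frames = [frame0]
    for step in range(1, config.n_steps + 1):
        try:
            pos = _step(pos, frame0.species_index, D, q, config, rng, step)
        except NumericalInstabilityError as err:
            raise NumericalInstabilityError(f"{err} (frame {len(frames)})") from err
        if step % config.frame_stride == 0:
            frames.append(
                Frame(
                    step * config.timestep,
                    pos.copy(),
                    frame0.species_index.copy(),
                    config.box,
                    frame0.planted_chain,
                )
            )
    return Trajectory(frames, config.species_table, config)


def plant_transmembrane_chain(
    frame: Frame,
    species: tuple[IonSpecies, ...],
    membrane: MembraneSlab,
    bead_spacing: float,
    xy: tuple[float, float] | None = None,
) -> tuple[Frame, tuple[IonSpecies, ...]]:
    """Insert a straight column of frozen water beads spanning the membrane.

    The column runs from ``z_lower - bead_spacing`` to at least
    ``z_upper + bead_spacing`` in steps of ``bead_spacing`` at the box x,y
    center (or ``xy``); planting again auto-offsets in x so columns stay
    disjoint. Returns the augmented frame plus the species table extended with
    the chain-bead species if absent.
    """
    if bead_spacing <= 0:
        raise ValueError("bead_spacing must be > 0")
    lx, ly, _ = frame.box
    wch = get_species("WCH")
    species = tuple(species)
    if wch not in species:
        species = species + (wch,)
    wch_index = species.index(wch)

    x, y = (lx / 2.0, ly / 2.0) if xy is None else xy
    existing = frame.positions[frame.species_index == wch_index]
    while existing.size and np.any(
        (np.abs(existing[:, 0] - x) < 0.25) & (np.abs(existing[:, 1] - y) < 0.25)
    ):
        x = (x + 0.5) % lx

    span = membrane.thickness + 2.0 * bead_spacing
    n_beads = int(np.ceil(span / bead_spacing - 1e-12)) + 1
    zs = membrane.z_lower - bead_spacing + bead_spacing * np.arange(n_beads)
    beads = np.column_stack([np.full(n_beads, x), np.full(n_beads, y), zs])
    beads %= np.asarray(frame.box)

    new = frame.copy()
    new.positions = np.vstack([new.positions, beads])
    new.species_index = np.concatenate(
        [new.species_index, np.full(n_beads, wch_index, dtype=np.intp)]
    )
    new.planted_chain = True
    return new, species
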