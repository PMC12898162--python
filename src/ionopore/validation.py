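"""Independent reference computations and validation fixtures.

Everything here deliberately avoids the production code paths it is used to
check: the capacitor oracle integrates the 1D periodic field directly, the
dense Poisson reference builds explicit DFT matrices (no FFT), and the Debye
length is the closed-form electrolyte screening length. Tests and the
acceptance script compare the package's solvers against these.
"""
from __future__ import annotations

import numpy as np

from .constants import EPS0, thermal_energy
from .grids import GridSpec, ScalarGrid3D
from .model import MembraneSlab, SyntheticConfig, Trajectory

__all__ = [
    "capacitor_delta_phi",
    "make_sheet_capacitor",
    "dense_poisson_reference",
    "debye_length",
    "debye_wall_config",
    "double_layer_excess_profile",
    "fit_decay_length",
    "einstein_drift_velocity",
]


def capacitor_delta_phi(
    sigma: float, z_plus: float, z_minus: float, lz: float, n: int = 100_000
) -> float:
    """Potential drop phi(z_plus) - phi(z_minus) of periodic +/- sheet pair, V.

    Direct 1D integration: E(z) is piecewise constant with jumps sigma/eps0 at
    the sheets, shifted to zero mean (periodicity); phi = -int E dz. For
    sheets at separation d this reproduces sigma*d*(1 - d/Lz)/eps0.
    """
    z = (np.arange(n) + 0.5) * (lz / n)
    rho = np.zeros(n)
    dz = lz / n
    rho[int(z_plus / dz) % n] = sigma / dz
    rho[int(z_minus / dz) % n] = -sigma / dz
    e_field = np.cumsum(rho) * dz / EPS0
    e_field -= e_field.mean()
    phi = -np.cumsum(e_field) * dz
    return float(phi[int(z_plus / dz) % n] - phi[int(z_minus / dz) % n])


def make_sheet_capacitor(
    sigma: float = 0.1,
    z_plus: float = 4.3,
    z_minus: float = 8.3,
    box: tuple[float, float, float] = (1.6, 1.6, 12.6),
    spacing: float = 0.1,
) -> tuple[ScalarGrid3D, int, int]:
    """Uniform +/- sigma sheets, each occupying one z voxel layer.

    Returns the charge-density grid plus the z-node indices of the two
    sheets (where the potential drop is evaluated).
    """
    spec = GridSpec.from_box(box, spacing)
    dz = spec.spacing[2]
    i_plus = int(round(z_plus / dz)) % spec.dims[2]
    i_minus = int(round(z_minus / dz)) % spec.dims[2]
    values = np.zeros(spec.dims)
    values[:, :, i_plus] = sigma / dz
    values[:, :, i_minus] = -sigma / dz
    return ScalarGrid3D(spec, values, "charge_density"), i_plus, i_minus


def dense_poisson_reference(rho: ScalarGrid3D, epsilon_r: float = 1.0) -> np.ndarray:
    """Dense direct solve of the periodic finite-spectrum Poisson problem, V.

    Builds explicit per-axis DFT matrices (outer-product exponentials, no FFT
    code path) and inverts the continuum -|k|^2 symbol mode by mode. Intended
    for grids up to ~16^3.
    """
    dims = rho.spec.dims
    if int(np.prod(dims)) > 32**3:
        raise ValueError("dense reference is meant for small grids")
    Ws = []
    ks = []
    for n, s in zip(dims, rho.spec.spacing):
        j = np.arange(n)
        Ws.append(np.exp(-2j * np.pi * np.outer(j, j) / n))
        ks.append(2.0 * np.pi * np.fft.fftfreq(n, d=s))
    rho_hat = np.einsum("ai,bj,ck,ijk->abc", Ws[0], Ws[1], Ws[2], rho.values)
    kx, ky, kz = np.meshgrid(*ks, indexing="ij", sparse=True)
    k2 = kx**2 + ky**2 + kz**2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_hat = rho_hat / (EPS0 * epsilon_r * k2)
    phi_hat[0, 0, 0] = 0.0
    inv = [np.conj(W) / n for W, n in zip(Ws, dims)]
    phi = np.einsum("ai,bj,ck,ijk->abc", inv[0], inv[1], inv[2], phi_hat)
    return phi.real


def debye_length(
    number_densities: dict[int, float], temperature: float, epsilon_r: float
) -> float:
    """Closed-form screening length sqrt(eps_r eps0 kT / sum n_i q_i^2), nm.

    ``number_densities`` maps valence -> bulk number density (nm^-3).
    """
    ionic = sum(n * z**2 for z, n in number_densities.items())
    if ionic <= 0:
        raise ValueError("need nonzero ionic strength")
    return float(np.sqrt(epsilon_r * EPS0 * thermal_energy(temperature) / ionic))


def debye_wall_config(
    concentration: float = 0.05,
    wall_charge: float = 8.0,
    seed: int = 11,
    n_steps: int = 126_000,
) -> SyntheticConfig:
    """Charged-wall double-layer fixture at a dilute NaCl-like condition.

    Antisymmetric face charges (+-wall_charge e per 7x7 nm face), no applied
    field, all-pairs minimum-image Coulomb (the wall's exact periodic
    capacitor field is long-ranged, so pair forces must not be truncated for
    consistent equilibrium screening), eps_r = 78.
    """
    from .constants import MOLAR_TO_PER_NM3

    lx = ly = 7.0
    lz = 14.0
    slab = MembraneSlab(5.0, 9.0)
    v = lx * ly * (lz - slab.thickness)
    n = int(round(concentration * MOLAR_TO_PER_NM3 * v))
    return SyntheticConfig(
        box=(lx, ly, lz),
        membrane=slab,
        species_counts={"NA": n, "CL": n},
        applied_field_Ez=0.0,
        temperature=310.0,
        timestep=5e-3,
        n_steps=n_steps,
        frame_stride=10,
        seed=seed,
        interacting=True,
        coulomb_cutoff=float("inf"),
        epsilon_r=78.0,
        wall_sigma=wall_charge / (lx * ly),
    )


def double_layer_excess_profile(
    trajectory: Trajectory,
    equilibration_fraction: float = 0.125,
    max_distance: float = 5.0,
    bin_width: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Face-antisymmetrized charge density vs distance from the wall, e/nm^3.

    Pools the counterion excess of the lower (negative) face with the sign-
    flipped excess of the upper face; for the antisymmetric wall fixture both
    layers carry the same exponential decay.
    """
    config = trajectory.config
    slab = config.membrane
    lx, ly, _ = config.box
    frames = trajectory.frames[int(equilibration_fraction * len(trajectory)) :]
    q = trajectory.charges()
    edges = np.arange(0.0, max_distance + bin_width / 2, bin_width)
    acc_low = np.zeros(len(edges) - 1)
    acc_up = np.zeros(len(edges) - 1)
    for f in frames:
        z = f.positions[:, 2]
        lo = z < slab.midplane
        acc_low += np.histogram(slab.z_lower - z[lo], bins=edges, weights=q[lo])[0]
        acc_up += np.histogram(z[~lo] - slab.z_upper, bins=edges, weights=q[~lo])[0]
    scale = len(frames) * lx * ly * bin_width
    excess = 0.5 * (acc_low - acc_up) / scale
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, excess


def fit_decay_length(
    distance: np.ndarray,
    excess: np.ndarray,
    fit_range: tuple[float, float] = (0.2, 2.4),
) -> float:
    """Exponential decay length from a log-linear least-squares fit, nm."""
    m = (distance >= fit_range[0]) & (distance <= fit_range[1]) & (excess > 0)
    if m.sum() < 3:
        raise ValueError("too few positive bins in the fit range")
    slope = np.polyfit(distance[m], np.log(excess[m]), 1)[0]
    if slope >= 0:
        raise ValueError("profile does not decay in the fit range")
    return float(-1.0 / slope)


def einstein_drift_velocity(
    diffusion_coefficient: float, valence: int, field: float, temperature: float
) -> float:
    """Free-ion drift velocity D*q*E/(k_B T), nm/ns."""
    return diffusion_coefficient * valence * field / thermal_energy(temperature)
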