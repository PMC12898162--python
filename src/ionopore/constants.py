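"""Physical constants in the package's native unit system.

Lengths are nm, time ns, charge e, energy eV, electrostatic potential V.
In these units eV/e == V, so a Poisson solve over a charge density in e/nm^3
yields a potential directly in volts with no trailing conversion factor.
"""

#: Boltzmann constant, eV/K.
KB_EV: float = 8.617333262e-5

#: Coulomb constant 1/(4*pi*eps0), eV*nm/e^2.
COULOMB_K: float = 1.43996

#: Vacuum permittivity, e^2/(eV*nm) (equivalently e/(V*nm)).
EPS0: float = 1.0 / (4.0 * 3.141592653589793 * COULOMB_K)

#: Avogadro constant, 1/mol.
N_AVOGADRO: float = 6.02214076e23

#: mol/L -> particles/nm^3 (N_A * 1e-24).
MOLAR_TO_PER_NM3: float = N_AVOGADRO * 1e-24

#: Atomic mass unit, kg.
AMU_KG: float = 1.66053906660e-27

#: amu/nm^3 -> kg/m^3  (AMU_KG / 1e-27).
AMU_PER_NM3_TO_KG_PER_M3: float = AMU_KG * 1e27

#: Bohr radius, nm (Gaussian cube files use atomic units of length).
BOHR_NM: float = 0.0529177210903


def thermal_energy(temperature: float) -> float:
    """k_B*T in eV for a temperature in kelvin."""
    return KB_EV * temperature
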