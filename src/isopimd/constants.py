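"""Physical constants and isotope masses in the package unit system.

Units used throughout: length nm, time ps, mass amu (g/mol), energy
kJ/mol, charge e, temperature K.  These are internally consistent:
1 kJ/mol = 1 amu nm^2 ps^-2, so no unit conversion factors appear in the
equations of motion.
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 8.314462618e-3

#: Reduced Planck constant, kJ mol^-1 ps
HBAR = 6.350779923e-2

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2
COULOMB = 138.935458

#: Avogadro constant, mol^-1
N_AVOGADRO = 6.02214076e23

#: Speed of light, cm/ps (converts frequency in ps^-1 to wavenumber cm^-1)
C_CM_PER_PS = 2.99792458e-2

#: Atomic masses, amu
MASS_H = 1.00783
MASS_D = 2.01410
MASS_T = 3.01605
MASS_O = 15.9949

#: Per-composition covalent-site masses (site order O, X1, X2)
COMPOSITION_MASSES = {
    "H2O": (MASS_O, MASS_H, MASS_H),
    "HDO": (MASS_O, MASS_H, MASS_D),
    "D2O": (MASS_O, MASS_D, MASS_D),
    "T2O": (MASS_O, MASS_T, MASS_T),
}


def molar_mass(composition: str) -> float:
    """Molar mass of one molecule of the given composition, g/mol."""
    return float(sum(COMPOSITION_MASSES[composition]))


def wavenumber_from_angular_frequency(omega_ps: float) -> float:
    """Convert angular frequency (rad/ps) to wavenumber (cm^-1)."""
    import math

    return omega_ps / (2.0 * math.pi * C_CM_PER_PS)
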