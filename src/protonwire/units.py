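"""Internal unit system and physical constants.

Lengths are in angstrom, time in picoseconds, mass in atomic mass units and
energies in kJ/mol throughout the package.  These units are *not* mutually
consistent: 1 kJ/mol equals 100 amu A^2/ps^2, so kinetic energies and
accelerations carry the conversion factor below.
"""

#: Boltzmann constant, kJ/(mol K).
KB = 0.0083144621

#: amu A^2/ps^2 per kJ/mol (1 kJ/mol = 100 amu A^2/ps^2).
KJ_PER_MOL = 100.0

#: Atomic masses in amu, by element symbol (upper case).
ATOMIC_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "FE": 55.845,
    "MG": 24.305,
    "NA": 22.990,
    "CL": 35.45,
}

DEFAULT_MASS = 12.011


def mass_of(element: str) -> float:
    """Mass in amu for an element symbol; unknown elements get a carbon mass."""
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_MASS)
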