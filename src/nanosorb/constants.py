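"""Physical constants and unit conventions.

Internal units: lengths in Å for atomistic structures and force fields,
nm for collective-variable space (metadynamics, PMFs); energies in kJ/mol;
masses in amu (g/mol); times in ps; charges in elementary charges.

With these units 1 kJ/mol = 1 amu nm^2 ps^-2, so a force in kJ mol^-1 Å^-1
divided by a mass in amu gives an acceleration of 100 Å ps^-2.
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 8.314462618e-3

#: Coulomb constant k_C = 1/(4 pi eps0), kJ mol^-1 nm e^-2
COULOMB_K_NM = 138.935458

#: Coulomb constant in Å units, kJ mol^-1 Å e^-2
COULOMB_K = 1389.35458

#: Conversion factor: (kJ mol^-1 Å^-1) / amu  ->  Å ps^-2
ACC_UNIT = 100.0

#: Atomic masses, amu
MASSES = {
    "Zn": 65.38,
    "S": 32.06,
    "O": 15.999,
    "OW": 15.999,
    "OC": 15.999,
    "H": 1.008,
    "HW": 1.008,
    "C": 12.011,
    "N": 14.007,
    "Na": 22.990,
    "Cl": 35.45,
}

#: Formal charges used for the zinc-blende ZnS model, e
FORMAL_CHARGES = {"Zn": 2.0, "S": -2.0}


def mass_of(species: str, default: float = 40.0) -> float:
    """Atomic mass for a species label, with a generic fallback."""
    return MASSES.get(species, default)
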