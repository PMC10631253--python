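"""Physical constants and unit conversions used throughout the package.

Internal unit system: lengths in angstrom, energies in kcal/mol, masses in
amu, time in femtoseconds, frequencies (wavenumbers) in cm^-1.
"""

from __future__ import annotations

import scipy.constants as _c

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL_MOL_K = 1.98720425e-3

#: Hartree -> kcal/mol.
HARTREE_TO_KCAL = 627.5095

#: Default analysis temperature (K).
DEFAULT_TEMPERATURE_K = 298.15

# 1 kcal/mol expressed in joule per molecule.
_KCAL_PER_MOL_J = _c.calorie * 1e3 / _c.N_A

#: Acceleration conversion: (kcal/mol/angstrom) / amu  ->  angstrom/fs^2.
#: a[A/fs^2] = F[kcal/mol/A] * ACC_CONV / m[amu]
ACC_CONV = _KCAL_PER_MOL_J / 1e-10 / _c.atomic_mass * 1e10 / 1e30

# Fast path for the elements that dominate organic chemistry; anything else
# falls back to rdkit's periodic table (standard atomic weights).
_COMMON_MASSES = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998403162, "Si": 28.085, "P": 30.973761998, "S": 32.06,
    "Cl": 35.45, "Br": 79.904, "I": 126.90447,
}


def atomic_mass(symbol: str) -> float:
    """Standard atomic weight (amu) for an element symbol.

    Raises ``KeyError`` for symbols not in the periodic table.
    """
    try:
        return _COMMON_MASSES[symbol]
    except KeyError:
        pass
    from rdkit import Chem  # deferred: rdkit import is slow

    pt = Chem.GetPeriodicTable()
    z = pt.GetAtomicNumber(symbol)  # raises for unknown symbols
    if z == 0:
        raise KeyError(symbol)
    return float(pt.GetAtomicWeight(z))


def harmonic_sigma_zero_point(wavenumber_cm1: float, reduced_mass_amu: float) -> float:
    """Ground-state (zero-point) harmonic position spread sqrt(hbar/(2 mu omega)), in angstrom."""
    omega = 2.0 * _c.pi * _c.c * 1e2 * wavenumber_cm1  # rad/s
    mu = reduced_mass_amu * _c.atomic_mass
    return float((_c.hbar / (2.0 * mu * omega)) ** 0.5 * 1e10)


def harmonic_sigma_thermal(
    wavenumber_cm1: float, reduced_mass_amu: float, temperature_K: float
) -> float:
    """Classical thermal harmonic position spread sqrt(kB T/(mu omega^2)), in angstrom."""
    omega = 2.0 * _c.pi * _c.c * 1e2 * wavenumber_cm1
    mu = reduced_mass_amu * _c.atomic_mass
    return float((_c.k * temperature_K / (mu * omega**2)) ** 0.5 * 1e10)
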