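"""Unit conventions and physical constants.

All coordinates are stored in nm. Energies are handled in units of kT
internally wherever estimator math is unit-free (WHAM, BAR, toy potentials);
conversion to kJ/mol happens only at I/O boundaries.
"""

from __future__ import annotations

#: Gas constant, kJ mol^-1 K^-1.
R_KJ_PER_MOL_K: float = 0.0083144621

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE: float = 298.0

#: Coulomb prefactor f_elec = 1/(4 pi eps0), kJ nm mol^-1 e^-2.
F_ELEC: float = 138.935

#: Thermochemical calorie.
KCAL_TO_KJ: float = 4.184

#: Kabsch-Sander electrostatic H-bond prefactor, kcal/mol * Angstrom.
KS_PREFACTOR: float = 27.888

#: DSSP hydrogen-bond energy threshold, kcal/mol.
HB_ENERGY_THRESHOLD_KCAL: float = -0.5

NM_TO_ANGSTROM: float = 10.0


def kt_in_kj_per_mol(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """kT (per mole) in kJ/mol at the given temperature."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KJ_PER_MOL_K * temperature


def kj_to_kt(energy_kj: float, temperature: float = DEFAULT_TEMPERATURE):
    """Convert kJ/mol to kT units."""
    return energy_kj / kt_in_kj_per_mol(temperature)


def kt_to_kj(energy_kt: float, temperature: float = DEFAULT_TEMPERATURE):
    """Convert kT units to kJ/mol."""
    return energy_kt * kt_in_kj_per_mol(temperature)
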