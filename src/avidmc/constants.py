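"""Physical constants and unit conversions.

Internal unit system: lengths in nm, energies in k_BT at T = 298 K.
Mechanical stiffnesses quoted in SI (N/m, J/m^2) are converted with
:data:`NM_PER_M` style factors below; masses stay in kg because they only
enter logarithmically (quasiharmonic and Sackur-Tetrode entropies).
"""

import math

#: Boltzmann constant (J/K)
KB_J = 1.380649e-23
#: Planck constant (J s)
H_J = 6.62607015e-34
#: Reduced Planck constant (J s)
HBAR_J = H_J / (2.0 * math.pi)

#: Reference temperature (K). The source study states none; 298 K documented.
T_REF = 298.0
#: Thermal energy at the reference temperature (J)
KBT_J = KB_J * T_REF

#: 1 N/m expressed in k_BT/nm^2 at T_REF (~243.06)
NPM_TO_KBT_NM2 = 1e-18 / KBT_J
#: 1 pN*nm expressed in k_BT at T_REF (~0.2431)
PNNM_TO_KBT = 1e-21 / KBT_J


def stiffness_kbt(k_si: float) -> float:
    """Convert a spring stiffness from N/m (= J/m^2) to k_BT/nm^2."""
    return k_si * NPM_TO_KBT_NM2


def thermal_wavelength_nm(mass_kg: float, temperature: float = T_REF) -> float:
    """Thermal de Broglie wavelength (nm) of a particle of given mass."""
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    lam_m = H_J / math.sqrt(2.0 * math.pi * mass_kg * KB_J * temperature)
    return lam_m * 1e9
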