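"""Physical constants and unit conversions.

Internal units throughout the package: length in Å, time in ns, energy in
kcal/mol, concentration in mmol/L (reported) or molecules/Å³ (internal).
Permeability is reported in cm/s.
"""

from __future__ import annotations

#: Boltzmann constant, kcal/(mol·K).
KB_KCAL_PER_MOL_K: float = 1.987204e-3

#: Avogadro's number, 1/mol.
AVOGADRO: float = 6.02214076e23

#: Number density of 1 mmol/L expressed in molecules/Å³.
#: 1 mmol/L = 1e-3 mol / 1e27 Å³ = 6.02214076e-7 molecules/Å³.
MMOL_PER_L_TO_PER_A3: float = 1e-3 * AVOGADRO / 1e27

#: Inverse conversion: 1 molecule/Å³ in mmol/L (≈ 1.6605e6 mmol/L).
PER_A3_TO_MMOL_PER_L: float = 1.0 / MMOL_PER_L_TO_PER_A3

#: 1 Å/ns expressed in cm/s (1e-8 cm per 1e-9 s).
A_PER_NS_TO_CM_PER_S: float = 10.0

#: 1 ns/Å expressed in s/cm (inverse of the above).
NS_PER_A_TO_S_PER_CM: float = 1.0 / A_PER_NS_TO_CM_PER_S

#: Standard atmosphere in Pa.
ATM_TO_PA: float = 101325.0

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE_K: float = 310.0


def thermal_energy(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Return kB·T in kcal/mol for a temperature in kelvin."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return KB_KCAL_PER_MOL_K * temperature_k


def constant_table() -> dict[str, float]:
    """All unit constants as a dict, for logging in CLI runs."""
    return {
        "kB [kcal/mol/K]": KB_KCAL_PER_MOL_K,
        "N_A [1/mol]": AVOGADRO,
        "1 mmol/L [molecules/A^3]": MMOL_PER_L_TO_PER_A3,
        "1 molecule/A^3 [mmol/L]": PER_A3_TO_MMOL_PER_L,
        "1 A/ns [cm/s]": A_PER_NS_TO_CM_PER_S,
        "1 atm [Pa]": ATM_TO_PA,
    }
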