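"""Physical and physiological constants used across the DLW pipeline.

All isotope enrichments in this package are *atom-fraction excess* above the
subject's pre-dose baseline (dimensionless; 1 ppm excess = 1e-6).  Body-water
pools are in moles of water; times in days; energies in kcal/day.
"""

# Water and carbon
MOLAR_MASS_WATER_G = 18.0153
MOLAR_MASS_CARBON_G = 12.011

# Atomic masses (u), for molar masses of enriched dose waters
MASS_16O = 15.994915
MASS_18O = 17.999160
MASS_1H = 1.007825
MASS_2H = 2.014102

# Natural abundances (atom fraction) against which dose excess is computed
NATURAL_ABUNDANCE_18O = 0.002005
NATURAL_ABUNDANCE_2H = 0.000156

# Dose prescription: grams of labeled water per kg of estimated total body water
O18_DOSE_G_PER_KG_TBW = 2.0
D2_DOSE_G_PER_KG_TBW = 0.12
ATOM_FRACTION_18O_DOSE = 0.10     # 10 atom% 18O water
ATOM_FRACTION_2H_DOSE = 0.999    # 99.9 atom% 2H water

# Hydration of fat-free mass: TBW = 0.732 * FFM (classic Pace-Rathbun constant)
HYDRATION_OF_FFM = 0.732

# Two-pool steady-state CO2 production model with fractionation corrections:
#   rCO2 = 0.4554 * N * (1.007*kO - 1.041*kD)
RCO2_COEFFICIENT = 0.4554
KO_FRACTIONATION = 1.007
KD_FRACTIONATION = 1.041

# Modified Weir equation, fixed respiratory quotient:
#   TEE [kcal/d] = 22.4 * rCO2 [mol/d] * (3.941/RQ + 1.106)
LITERS_PER_MOL_GAS = 22.4
WEIR_O2_COEFF = 3.941
WEIR_CO2_COEFF = 1.106
DEFAULT_RQ = 0.86
RQ_BAND = (0.7, 1.0)

# Sanity band for the dilution-space ratio ND/NO, and the simulator default
SPACE_RATIO_BAND = (1.0, 1.07)
DEFAULT_SPACE_RATIO = 1.034


def kcal_per_mol_co2(rq: float = DEFAULT_RQ) -> float:
    """Energy equivalent of one mole of CO2 at a fixed RQ (~127.42 at RQ 0.86)."""
    return LITERS_PER_MOL_GAS * (WEIR_O2_COEFF / rq + WEIR_CO2_COEFF)
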