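"""Physical constants and unit conversions.

Internal units follow the Amber convention throughout the package:
lengths in Å, energies in kcal/mol, charges in elementary charges,
masses in amu, times in ps, entropies in cal/(mol·K).
"""

# Coulomb constant, kcal·Å/(mol·e²) (Amber convention)
COULOMB_K = 332.0637

# Gas constant
R_CAL = 1.98720425864083  # cal/(mol·K)
R_KCAL = R_CAL / 1000.0  # kcal/(mol·K)

# SI constants used by the statistical-mechanics formulas
KB_SI = 1.380649e-23  # J/K
H_SI = 6.62607015e-34  # J·s
C_SI = 2.99792458e8  # m/s
NA = 6.02214076e23  # 1/mol
AMU_KG = 1.66053906660e-27  # kg
ATM_PA = 101325.0  # Pa

# 1 (kcal/mol)/(Å²·amu) expressed in s⁻² ; ω[rad/s] = sqrt(λ · this)
# 4184 J/kcal / (NA · 1e-20 m²/Å² · AMU_KG)
KCAL_PER_MOL_A2_AMU_TO_S2 = 4184.0 / (NA * 1e-20 * AMU_KG)

# amu·Å² → kg·m²
AMU_A2_TO_KG_M2 = AMU_KG * 1e-20

DEFAULT_TEMPERATURE = 300.0  # K, the MD thermostat setting
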