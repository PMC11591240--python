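"""Physical constants and the fixed species ordering used throughout.

All energies in this package are molar (J/mol) and are used with the molar
gas constant ``R``; per-particle expressions (Boltzmann statistics) are
converted at the boundary via Avogadro's number.
"""

import scipy.constants as _sc

#: Molar gas constant as used by the instrument firmware, J mol^-1 K^-1.
#: Kept at the rounded value the jar model and TOF bookkeeping are defined
#: with, so printed worked-example numbers are reproduced exactly.
R_GAS = 8.314

#: CODATA values for the statistical-mechanics layer.
K_B = _sc.k            # Boltzmann constant, J/K
PLANCK = _sc.h         # Planck constant, J s
N_AV = _sc.N_A         # Avogadro number, 1/mol
AMU = _sc.atomic_mass  # atomic mass unit, kg
C_CM = 2.99792458e10   # speed of light, cm/s (for cm^-1 -> s^-1)

#: Fixed species order for all jar composition vectors.
SPECIES_ORDER = ("O2", "N2", "Ar", "H2", "CO2")

#: Molar masses (g/mol) in SPECIES_ORDER, as measured by GC/MS calibration.
MOLAR_MASSES = (31.998, 28.014, 39.948, 2.015, 44.01)
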