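"""Global unit system and physical constants.

Everything in the package uses: Å (length), kcal/mol (energy),
kcal/mol/Å (force), elementary charge e (charge), fs (time), K
(temperature), g/cm³ (density).
"""

# Coulomb constant, kcal·Å/(mol·e²)
KE_COULOMB = 332.0637

# Boltzmann constant, kcal/(mol·K)
KB = 0.0019872041

# atomic masses, g/mol
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "O": 15.999}

# covalent radii, Å (used for distance-based bond guessing)
COVALENT_RADII = {"H": 0.31, "C": 0.76, "O": 0.66}

# Avogadro's number
N_AVOGADRO = 6.02214076e23

# internal (kcal/mol, Å, g/mol) acceleration unit -> Å/fs² conversion:
# 1 kcal/mol/Å / (g/mol) = 4.184e26 erg/g/cm ... worked out:
# a [Å/fs²] = F [kcal/mol/Å] / m [g/mol] * KCAL_MOL_PER_GMOL_TO_A_FS2
KCAL_MOL_PER_GMOL_TO_A_FS2 = 4.184e-4

SUPPORTED_ELEMENTS = ("H", "C", "O")
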