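"""Physical constants and unit conventions.

Unit system used throughout the package:

========  ==============================
length    angstrom (A)
time      picosecond (ps)
mass      atomic mass unit (amu)
energy    kcal/mol
charge    elementary charge (e)
========  ==============================

Velocities are A/ps.  Kinetic energy in amu*A^2/ps^2 is converted to
kcal/mol by dividing by :data:`KCAL_MOL_IN_AMU_A2_PS2`; accelerations from
forces in kcal/mol/A are obtained by multiplying by the same constant and
dividing by the mass.
"""

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872041

#: 1 kcal/mol expressed in amu * A^2 / ps^2.
KCAL_MOL_IN_AMU_A2_PS2 = 418.4

#: Coulomb constant, kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0636

#: Default bead mass (amu), roughly one average amino-acid residue.
DEFAULT_BEAD_MASS = 110.0
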