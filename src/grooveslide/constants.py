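"""Shared physical constants and force-field defaults (kcal/mol, Angstrom, e)."""

# Harmonic/bonded force constants.  All harmonic terms are k * (X - X0)^2
# (no factor 1/2): a 0.1 A bond stretch costs 100 * 0.01 = 1 kcal/mol.
K_BOND = 100.0       # kcal/mol/A^2
K_ANGLE = 20.0       # kcal/mol/rad^2
K_DIHEDRAL = 1.0     # kcal/mol
K_CONTACT = 1.0      # kcal/mol, depth of the 12-10 native-contact well
K_EXCLUDED = 1.0     # kcal/mol, excluded-volume prefactor

# Per-class repulsion (excluded-volume) radii.
R_PROTEIN = 2.0      # A, Calpha beads
R_DNA = 3.7          # A, sugar/base/phosphate beads
R_DNA_TARGET = 3.0   # A, DNA beads engaged by a target-site potential

# Electrostatics.
K_COULOMB = 332.0            # kcal/mol * A / e^2, force-field prefactor
COULOMB_EXACT = 332.0637     # e^2/(4 pi eps0), used for the Bjerrum length
DIELECTRIC = 70.0
B_KAPPA = 1.0                # ion-dependency factor, ~1 for dilute solutions
KB_KCAL = 0.0019872          # kcal/mol/K
KBT_ROOM = 0.593             # kcal/mol at 298 K
AVOGADRO = 6.02214076e23

# B-DNA geometry.
BP_RISE = 3.32               # A per base-pair step
HELICAL_REPEAT_BP = 10.0     # bp per turn (36 deg/bp twist)
TWIST_DEG = 36.0

# Simulation clock and 1D-diffusion analysis defaults.
STEP_PS = 50.0               # physical time assigned to one MD step
R_C = 32.0                   # A, 1D/3D cutoff on the axis distance d
GROOVE_TOL_BP = 1.5          # max offset from the major-groove center
MIN_1D_NS = 5.0              # minimum usable 1D interval (approx 100 MD steps)
MIN_HOP_BP = 1.0             # hops shorter than this merge into groove tracking
MIN_GROOVE_NS = 0.5          # groove tracking shorter than this becomes a hop
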