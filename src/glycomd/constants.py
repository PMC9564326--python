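"""Physical constants in the unit system used throughout the package.

Lengths are Angstrom, energies kcal/mol, entropies cal/(mol K), masses amu,
charges in elementary-charge units, times ns.
"""

#: Coulomb constant, kcal*Angstrom/(mol*e^2).
COULOMB_KCAL = 332.0636

#: Gas constant, cal/(mol*K).
R_CAL = 1.98720425864083

#: Gas constant, kcal/(mol*K).
R_KCAL = R_CAL / 1000.0

# SI values used only inside the quasiharmonic frequency conversion.
KB_SI = 1.380649e-23          # J/K
HBAR_SI = 1.054571817e-34     # J*s
AMU_SI = 1.66053906660e-27    # kg
ANGSTROM_SI = 1.0e-10         # m

#: Default internal dielectric (mimics induced polarisation of the solute).
DEFAULT_EPS_INT = 3.0
#: Default solvent dielectric (water).
DEFAULT_EPS_SOLV = 78.5
#: Default analysis temperature, K.
DEFAULT_TEMPERATURE = 300.0
#: Solvent probe radius, Angstrom.
DEFAULT_PROBE_RADIUS = 1.4
#: Nonpolar surface tension, kcal/(mol*Angstrom^2).
DEFAULT_SURFACE_TENSION = 0.0072

# GB-OBC model I constants (tanh rescaling of intrinsic radii).
GB_OBC_ALPHA = 0.8
GB_OBC_BETA = 0.0
GB_OBC_GAMMA = 2.909125
GB_RADIUS_OFFSET = 0.09  # Angstrom
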