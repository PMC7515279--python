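"""Physical constants (exact SI) and unit conversions.

Internal units throughout the package: lengths in Å, forces in kJ mol⁻¹ Å⁻¹,
masses in g mol⁻¹, moments of inertia in g mol⁻¹ Å², torques in kJ mol⁻¹,
times in ps.  Entropies are reported per mole of molecules, J K⁻¹ mol⁻¹.
Conversion to SI happens only inside the eigenvalue → frequency step.
"""

KB = 1.380649e-23  # Boltzmann constant, J K^-1
H_PLANCK = 6.62607015e-34  # Planck constant, J s
AVOGADRO = 6.02214076e23  # mol^-1
R_GAS = KB * AVOGADRO  # molar gas constant, J K^-1 mol^-1

KCAL_TO_KJ = 4.184

# A mass-weighted force second moment in internal units,
# (kJ mol^-1 Å^-1)^2 / (g mol^-1), converted to per-molecule SI, N^2 kg^-1:
#   force:  1 kJ mol^-1 Å^-1 = 1e13 / N_A  N per molecule
#   mass:   1 g mol^-1       = 1e-3 / N_A  kg per molecule
# => lambda_SI = lambda_internal * 1e29 / N_A.
# The inertia-weighted torque second moment, (kJ mol^-1)^2 / (g mol^-1 Å^2),
# carries exactly the same factor.
LAMBDA_INTERNAL_TO_SI = 1.0e29 / AVOGADRO
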