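"""Unit conventions and physical constants.

Project-wide contract: pressure in MPa, volume changes in ml/mol, free
energies in kJ/mol. The product of 1 MPa and 1 ml/mol is exactly 1 J/mol,
so pressure-volume terms enter free-energy expressions with no numeric
conversion factor beyond the kJ -> J factor of 1000.
"""

R_GAS = 8.314  # gas constant, J mol^-1 K^-1

DEFAULT_T = 298.15  # K (25 degrees C, the temperature of all experiments)

# 1 MPa * 1 ml/mol = 1e6 Pa * 1e-6 m^3/mol = 1 J/mol
MPA_ML_PER_MOL_TO_J_PER_MOL = 1.0

KJ_TO_J = 1000.0


def rt(T: float = DEFAULT_T) -> float:
    """R*T in J/mol."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    return R_GAS * T
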