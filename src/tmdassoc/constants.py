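"""Physical constants, in the kcal/mol unit system used throughout."""

#: Molar gas constant R in kcal mol^-1 K^-1.
R_KCAL = 1.9872041e-3

#: Boltzmann constant expressed per mole (identical to R in these units);
#: kept as a separate name so thermodynamic formulas read like their sources.
KB_KCAL = R_KCAL


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol (0.59616 kcal/mol at 300 K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL * temperature
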