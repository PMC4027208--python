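"""Unit conventions shared across the package.

All energies are in kcal/mol, lengths in angstrom (Å), times in ps,
temperatures in K and angles in rad.  Nothing in the package converts
units; configuration files use the same conventions.
"""

#: Boltzmann constant in kcal/(mol K).
KB = 0.0019872041


def kT(temperature: float) -> float:
    """Thermal energy k_B * T in kcal/mol for a temperature in K."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
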