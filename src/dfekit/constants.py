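"""Physical constants and global unit conventions.

All quantities in the package use a single unit system: distances in
angstrom (Å), chemical time in picoseconds (ps, durations reported in ns),
energies in kcal/mol and temperatures in kelvin.
"""

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL_PER_MOL_K: float = 1.987204259e-3

#: Default simulation / analysis temperature (K); also used for the
#: dissociation-constant -> free-energy conversion.
DEFAULT_TEMPERATURE_K: float = 310.0


def kT(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy kT in kcal/mol at the given temperature."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_PER_MOL_K * temperature
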