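"""Physical constants in the kcal/mol, Å, e unit system."""

#: Boltzmann constant, kcal/(mol K)
KB = 0.0019872041

#: Coulomb constant, kcal Å / (mol e^2)
COULOMB = 332.0637128


def thermal_energy(temperature: float) -> float:
    """kB*T in kcal/mol."""
    return KB * temperature
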