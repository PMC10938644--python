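"""Physical constants and unit conventions.

The package works in piconewtons (force), nanometres (length), radians
(angles, once past I/O) and Kelvin.  Twist is stored in degrees on disk and
inside :class:`~dnaelastic.trajio.HelicalTrajectory`; the conversion to
radians happens exactly once, in :mod:`dnaelastic.observables`.
"""

#: Boltzmann constant in pN·nm/K (exact SI value rescaled).
KB = 0.01380649


def kbt(temperature: float) -> float:
    """Thermal energy k_B·T in pN·nm for a temperature in Kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
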