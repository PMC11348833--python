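"""Physical constants (CODATA 2018) pinned in one place.

Every unit conversion in the package goes through these values so that
irradiance → photon-flux and rate-constant computations stay mutually
consistent.
"""

PLANCK_J_S = 6.62607015e-34
"""Planck constant h [J s]."""

SPEED_OF_LIGHT_M_S = 2.99792458e8
"""Speed of light in vacuum c [m s^-1]."""

AVOGADRO_PER_MOL = 6.02214076e23
"""Avogadro constant N_A [mol^-1]."""

LN10 = 2.302585092994046
"""Natural log of 10; converts decadic extinction to natural-log absorption."""

MOLAR_PHOTON_ENERGY_FACTOR = AVOGADRO_PER_MOL * PLANCK_J_S * SPEED_OF_LIGHT_M_S
"""N_A·h·c [J m mol^-1]: energy of one einstein at wavelength λ is this / λ."""
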