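"""Unit conversions.

The solver works internally in CGS (cm, s, g, dyn/cm^2); every user-facing
pressure is in mmHg.  Flow is ml/s in both worlds (1 ml = 1 cm^3).
"""

MMHG = 1333.22387415  # dyn/cm^2 per mmHg


def mmhg_to_cgs(p_mmhg):
    """Pressure mmHg -> dyn/cm^2."""
    return p_mmhg * MMHG


def cgs_to_mmhg(p_cgs):
    """Pressure dyn/cm^2 -> mmHg."""
    return p_cgs / MMHG


UM = 1e-4  # cm per micrometre
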