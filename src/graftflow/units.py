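"""Unit conversions between clinical and CGS quantities.

All internal computation is in CGS (cm, g, s, dyn). Interfaces report
pressures in mmHg and flows in ml/min.
"""

MMHG_TO_DYN: float = 1333.22  # dyn/cm^2 per mmHg
DYN_TO_MMHG: float = 1.0 / MMHG_TO_DYN

CM3S_TO_MLMIN: float = 60.0  # cm^3/s -> ml/min
MLMIN_TO_CM3S: float = 1.0 / 60.0


def mmhg(p_dyn: float) -> float:
    """Pressure in mmHg from dyn/cm^2."""
    return p_dyn * DYN_TO_MMHG


def dyn(p_mmhg: float) -> float:
    """Pressure in dyn/cm^2 from mmHg."""
    return p_mmhg * MMHG_TO_DYN


def ml_min(q_cgs: float) -> float:
    """Flow in ml/min from cm^3/s."""
    return q_cgs * CM3S_TO_MLMIN


def cm3_s(q_mlmin: float) -> float:
    """Flow in cm^3/s from ml/min."""
    return q_mlmin * MLMIN_TO_CM3S
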