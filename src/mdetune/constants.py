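"""Physical constants and unit conversions.

All internal quantities are SI: gradients in T/m, times in s, diffusivities
in m^2/s, b-values in s/m^2.  Scanner-facing interfaces use mT/m and s/mm^2;
the helpers below make every conversion explicit.
"""

#: Proton gyromagnetic ratio (rad s^-1 T^-1).
GAMMA_PROTON = 2.6752218744e8

#: Default hardware gradient cap, 500 mT/m in T/m.
DEFAULT_GRADIENT_CAP = 0.5


def b_from_scanner(b_smm2: float) -> float:
    """s/mm^2 -> s/m^2."""
    return b_smm2 * 1e6


def b_to_scanner(b_sm2: float) -> float:
    """s/m^2 -> s/mm^2."""
    return b_sm2 * 1e-6


def gradient_from_scanner(g_mtm: float) -> float:
    """mT/m -> T/m."""
    return g_mtm * 1e-3


def gradient_to_scanner(g_tm: float) -> float:
    """T/m -> mT/m."""
    return g_tm * 1e3
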