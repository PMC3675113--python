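"""Explicit unit conversion helpers.

Internal conventions: concentrations in mol/L, times in ms, rates in
s^-1, lengths in Å (1 nm = 10 Å).
"""

__all__ = ["umolar", "to_umolar", "nm_to_angstrom", "angstrom_to_nm"]


def umolar(value_um: float) -> float:
    """µM -> mol/L."""
    return value_um * 1e-6


def to_umolar(value_m: float) -> float:
    """mol/L -> µM."""
    return value_m * 1e6


def nm_to_angstrom(value_nm: float) -> float:
    return value_nm * 10.0


def angstrom_to_nm(value_a: float) -> float:
    return value_a / 10.0
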