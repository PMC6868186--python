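"""Isotopic spacing along m/z.

Successive isotopic variants of a peptide ion differ by one neutron-bound
C13-for-C12 substitution, i.e. by 1.00335 Da of neutral mass; at charge ``z``
the peaks are therefore ``1.00335 / z`` m/z apart. Rounded to two decimals
this gives the familiar per-charge spacings 1.00, 0.50, 0.33, 0.25, ... .
"""
from __future__ import annotations

C13_C12_MASS_DIFF = 1.00335  # Da
PROTON_MASS = 1.00728  # Da

MIN_CHARGE = 1
MAX_CHARGE = 9


def isotope_spacing(charge: int) -> float:
    """m/z distance between adjacent isotopes of an ion with this charge."""
    if not MIN_CHARGE <= charge <= MAX_CHARGE:
        raise ValueError(f"charge must be in [{MIN_CHARGE}, {MAX_CHARGE}], got {charge}")
    return C13_C12_MASS_DIFF / charge
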