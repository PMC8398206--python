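"""Physical constants and unit conversions used throughout the package.

Every conversion factor is declared exactly once here.  All enthalpies enter
the package in Hartree (atomic units); bond-cleavage and charge-transfer
enthalpies are reported in kcal/mol, frontier-orbital energies in eV.
"""

from __future__ import annotations

import decimal

#: kcal/mol per Hartree.
HARTREE_TO_KCAL: float = 627.5095

#: eV per Hartree.
HARTREE_TO_EV: float = 27.2114

#: kcal/mol per eV (approx. 23.06; the field's back-of-envelope value is 23.0).
EV_TO_KCAL: float = HARTREE_TO_KCAL / HARTREE_TO_EV

#: Gas constant in kcal/(mol K).
R_KCAL: float = 1.9872042586e-3

#: Standard temperature (K) for thermal corrections.
T_STANDARD: float = 298.15

#: Ideal-gas proton enthalpy at 298.15 K, 5/2 RT in kcal/mol (~1.48).
#: Used as the default H+ enthalpy in proton-affinity evaluation; the
#: electron is assigned zero enthalpy by the electron convention.
PROTON_ENTHALPY_KCAL: float = 2.5 * R_KCAL * T_STANDARD


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, matching printed-table conventions.

    Python's built-in ``round`` is banker's rounding; displayed percentages
    and one-decimal error tables use conventional half-up instead.
    """
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)
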