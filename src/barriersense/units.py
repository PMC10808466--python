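"""Unit conversions and numeric helpers.

The transport model mixes two unit regimes: the shear-stress and hydrostatic
formulas are cgs (poise, dynes, barye), while Darcy flux and the osmotic term
are SI/mixed (Pa·s, Pa, atm). The constants and parsers here make every
conversion explicit so each operation can state a dimensional contract.
"""

from __future__ import annotations

import math
import re
from decimal import ROUND_HALF_UP, Decimal

from .errors import SchemaError

POISE_TO_PA_S = 0.1          # 1 poise = 0.1 Pa·s
BARYE_TO_PA = 0.1            # 1 dyn/cm^2 (barye) = 0.1 Pa
ATM_TO_PA = 101325.0
CM2_TO_UM2 = 1e8
UM3_TO_ML = 1e-12            # 1 um^3 = 1e-12 cm^3 = 1e-12 mL
GRAVITY_CM_S2 = 981.0
GAS_CONSTANT_ATM_L = 0.08206  # atm·L/(mol·K)

# volumetric flowrate unit -> factor to mL/s
_FLOWRATE_FACTORS = {
    ("ml", "s"): 1.0,
    ("ml", "min"): 1.0 / 60.0,
    ("ml", "h"): 1.0 / 3600.0,
    ("ul", "s"): 1e-3,
    ("ul", "min"): 1e-3 / 60.0,
    ("ul", "h"): 1e-3 / 3600.0,
}

_FLOWRATE_RE = re.compile(
    r"^\s*([-+0-9.eE]+)\s*(µl|ul|ml)\s*/\s*(s|sec|min|h|hr)\s*$", re.IGNORECASE
)


def parse_flowrate_ml_per_s(value: float | str, field: str = "flowrate") -> float:
    """Normalize a flowrate to mL/s.

    Bare numbers are taken to already be in mL/s; strings must carry a unit,
    e.g. ``"8 uL/min"`` -> 1.3333e-4.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        m = _FLOWRATE_RE.match(value)
        if m:
            num, vol, per = m.groups()
            vol = vol.lower().replace("µ", "u")
            per = {"sec": "s", "hr": "h"}.get(per.lower(), per.lower())
            return float(num) * _FLOWRATE_FACTORS[(vol, per)]
    raise SchemaError(field, "a number in mL/s or a string like '8 uL/min'")


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures, half away from zero.

    Binary representation noise is shed first via ``repr`` (shortest
    round-tripping decimal), so 30.7/2 rounds to 15.4 rather than 15.3.
    """
    if x == 0 or not math.isfinite(x):
        return float(x)
    d = Decimal(repr(float(x)))
    shift = sig - 1 - d.adjusted()
    q = d.scaleb(shift).quantize(Decimal(1), rounding=ROUND_HALF_UP).scaleb(-shift)
    return float(q)


def molarity_mol_per_l(concentration_mg_per_ml: float, molecular_weight: float) -> float:
    """Molarity of a solution given mass concentration.

    mg/mL is numerically identical to g/L, so M = C / MW with MW in g/mol.
    """
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    return concentration_mg_per_ml / molecular_weight
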