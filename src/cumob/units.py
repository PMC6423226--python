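"""Unit bookkeeping for depth profiles.

Concentrations are stored in the unit they were reported in; conversions go
through a volumetric base (umol m^-3 for molar units, items m^-3 for counts).
Depth integration of a profile in unit ``u`` yields the areal unit listed in
:data:`AREAL_UNIT` (e.g. nM integrates to nmol m^-2, since 1 nM = 1 umol m^-3).
"""

from __future__ import annotations

from .errors import UnitError

#: Canonical spelling for accepted unit aliases.
_ALIASES = {
    "nM": "nM",
    "nmol/L": "nM",
    "nmol L-1": "nM",
    "uM": "uM",
    "µM": "uM",
    "umol/L": "uM",
    "umol L-1": "uM",
    "mM": "mM",
    "cells L-1": "cells L-1",
    "cells/L": "cells L-1",
    "copies L-1": "copies L-1",
    "copies/L": "copies L-1",
    "umol m-2 s-1": "umol m-2 s-1",
    "µmol m-2 s-1": "umol m-2 s-1",
}

#: Molar concentration units -> umol m^-3 per unit.
_MOLAR_TO_UMOL_M3 = {"nM": 1.0, "uM": 1e3, "mM": 1e6}

#: Count concentration units -> items m^-3 per unit.
_COUNT_TO_PER_M3 = {"cells L-1": 1e3, "copies L-1": 1e3}

#: unit -> (areal unit after depth integration, factor applied to the raw
#: trapezoid integral computed in native-unit x metres).
AREAL_UNIT = {
    "nM": ("nmol m-2", 1e3),       # nM*m = umol m^-2 -> nmol m^-2
    "uM": ("mmol m-2", 1.0),       # uM*m = mmol m^-2
    "mM": ("mol m-2", 1.0),        # mM*m = mol m^-2
    "cells L-1": ("cells m-2", 1e3),
    "copies L-1": ("copies m-2", 1e3),
}


def canonical(unit: str) -> str:
    """Return the canonical spelling of *unit*, raising on unknown strings."""
    try:
        return _ALIASES[unit.strip()]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}") from None


def convert(value, from_unit: str, to_unit: str):
    """Convert a concentration between compatible units (e.g. nM <-> uM)."""
    fu, tu = canonical(from_unit), canonical(to_unit)
    if fu == tu:
        return value
    for table in (_MOLAR_TO_UMOL_M3, _COUNT_TO_PER_M3):
        if fu in table and tu in table:
            return value * (table[fu] / table[tu])
    raise UnitError(f"cannot convert {from_unit!r} to {to_unit!r}")


def areal_unit(unit: str) -> tuple[str, float]:
    """Areal unit and scale factor produced by depth-integrating *unit*."""
    cu = canonical(unit)
    try:
        return AREAL_UNIT[cu]
    except KeyError:
        raise UnitError(
            f"unit {unit!r} has no areal-density equivalent; "
            "cannot integrate this profile over depth"
        ) from None
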