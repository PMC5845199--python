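"""Unit conversions for laboratory analytes.

The package stores every laboratory value in one canonical unit per
analyte so that score thresholds and cohort data can never meet in
mixed units:

================  ==================
analyte           canonical unit
================  ==================
CRP               mg/L
total bilirubin   µmol/L
platelet count    10^9/L
albumin           g/L
sodium            mmol/L
================  ==================

Published score thresholds are frequently quoted in the older units
(CRP in mg/dL, bilirubin in mg/dL, platelets in 10^4/mm³); the
conversions below bring them onto the canonical scale.  The bilirubin
factor 17.104 µmol/L per mg/dL derives from the molar mass of
bilirubin (584.66 g/mol).
"""

from __future__ import annotations

from .errors import UnitError

#: µmol of bilirubin per mg/dL (584.66 g/mol molar mass).
TB_UMOL_PER_MG_DL = 17.104

# Normalised spellings for unit names users are likely to write.
_UNIT_ALIASES = {
    "mg/dl": "mg/dL",
    "mg/dL": "mg/dL",
    "mg/l": "mg/L",
    "mg/L": "mg/L",
    "umol/l": "umol/L",
    "umol/L": "umol/L",
    "µmol/l": "umol/L",
    "µmol/L": "umol/L",
    "umol": "umol/L",
    "10^9/l": "10^9/L",
    "10^9/L": "10^9/L",
    "10^4/mm^3": "10^4/mm^3",
    "10^4/mm3": "10^4/mm^3",
    "10^4/uL": "10^4/mm^3",
    "10^4/ul": "10^4/mm^3",
}

# (analyte, from, to) -> multiplicative factor, canonical direction only;
# the inverse direction is derived.
_FORWARD = {
    ("crp", "mg/dL", "mg/L"): 10.0,
    ("tb", "mg/dL", "umol/L"): TB_UMOL_PER_MG_DL,
    ("plt", "10^4/mm^3", "10^9/L"): 10.0,
}

#: Canonical unit per convertible analyte.
CANONICAL_UNITS = {"crp": "mg/L", "tb": "umol/L", "plt": "10^9/L"}


def _normalise(unit: str) -> str:
    try:
        return _UNIT_ALIASES[unit]
    except KeyError:
        return unit


def convert_unit(value: float, analyte: str, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` of ``analyte`` between two supported units.

    Parameters
    ----------
    value : float
        The measurement to convert.
    analyte : str
        One of ``"crp"``, ``"tb"``, ``"plt"``.
    from_unit, to_unit : str
        Unit names; common alias spellings (``mg/dl``, ``µmol/L``) are
        accepted.

    Returns
    -------
    float
        The converted value.  Converting a unit to itself is the
        identity, and round trips recover the input to within 1e-9
        relative error.

    Raises
    ------
    UnitError
        If the (analyte, from, to) triple is not supported.
    """
    src, dst = _normalise(from_unit), _normalise(to_unit)
    if src == dst:
        known = {u for (a, u, v) in _FORWARD if a == analyte}
        known |= {v for (a, u, v) in _FORWARD if a == analyte}
        if src not in known:
            raise UnitError(f"unsupported unit {from_unit!r} for analyte {analyte!r}")
        return value
    if (analyte, src, dst) in _FORWARD:
        return value * _FORWARD[(analyte, src, dst)]
    if (analyte, dst, src) in _FORWARD:
        return value / _FORWARD[(analyte, dst, src)]
    raise UnitError(
        f"unsupported conversion for analyte {analyte!r}: {from_unit!r} -> {to_unit!r}"
    )


def to_canonical(value: float, analyte: str, from_unit: str) -> float:
    """Convert ``value`` to the analyte's canonical unit.

    Analytes with no registered alternative unit (ALT, AST, Na, ALB,
    cell counts, percentages) are passed through unchanged — their
    declared unit must already be the canonical one.
    """
    if analyte not in CANONICAL_UNITS:
        return value
    return convert_unit(value, analyte, from_unit, CANONICAL_UNITS[analyte])
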