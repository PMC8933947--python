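"""Unit conversion for clinical covariates.

The six risk equations are published in two unit systems: the US models
(PCE, adjusted PCE, Framingham) take lipids in mg/dL, while the WHO models
are published in mmol/L.  The package's canonical internal units are mg/dL
for lipids, mmHg for blood pressure and kg/m^2 for BMI; model configs
declare their native lipid unit and the engine converts at evaluation time,
so a value is never converted twice.
"""

from __future__ import annotations

# mg/dL per mmol/L for cholesterol (molar mass 386.65 g/mol -> 38.67 mg/dL
# per mmol/L, the conversion factor used on clinical laboratory reports).
CHOLESTEROL_MGDL_PER_MMOLL = 38.67

_CONVERSIONS = {
    ("cholesterol", "mg/dL", "mmol/L"): lambda v: v / CHOLESTEROL_MGDL_PER_MMOLL,
    ("cholesterol", "mmol/L", "mg/dL"): lambda v: v * CHOLESTEROL_MGDL_PER_MMOLL,
}


def convert_units(value: float, quantity: str, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` of the given quantity between supported units.

    Parameters
    ----------
    value : float
        Measured value in ``from_unit``.
    quantity : str
        Physical quantity, currently only ``"cholesterol"``.
    from_unit, to_unit : str
        Unit labels, e.g. ``"mg/dL"`` and ``"mmol/L"``.

    Returns
    -------
    float
        The value expressed in ``to_unit``.  Round-trip conversion recovers
        the input to better than 1e-9 relative.
    """
    if from_unit == to_unit:
        return value
    key = (quantity, from_unit, to_unit)
    if key not in _CONVERSIONS:
        raise ValueError(
            f"unsupported unit conversion: {quantity} {from_unit} -> {to_unit}"
        )
    return _CONVERSIONS[key](value)
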