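"""Physical constants and unit conversions used throughout the model.

Internal unit contract: concentrations in mol/L, volumes in L, time in s,
energies in J/mol, membrane potential in V, per-cell fluxes in mol/s
(biomass pseudo-reaction: g/s).  Public reports convert to the field's
customary units (mM, kJ/mol, d^-1).
"""

FARADAY = 96485.0  # C/mol
GAS_CONST = 8.3145  # J/(mol K)

SECONDS_PER_DAY = 86400.0

#: multiplicative factors to mol/L (concentrations) or base SI (others)
_UNIT_FACTORS = {
    "M": 1.0,
    "mol/L": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "nM": 1e-9,
    "mol/m3": 1e-3,
    "1/s": 1.0,
    "mol/g/s": 1.0,
    "mol/gdw/s": 1.0,
    "mmol/gdw/hr": 1e-3 / 3600.0,
    "g/mol": 1.0,
    "dimensionless": 1.0,
    "": 1.0,
    "V": 1.0,
    "mV": 1e-3,
    "F": 1.0,
    "g": 1.0,
    "m": 1.0,
    "um": 1e-6,
    "m2/s": 1.0,
    "L": 1.0,
    "K": 1.0,
    "C/mol": 1.0,
    "J/mol": 1.0,
    "kJ/mol": 1e3,
}


def to_si(value: float, units: str) -> float:
    """Convert ``value`` with ``units`` to the internal unit system."""
    try:
        return float(value) * _UNIT_FACTORS[units.strip()]
    except KeyError:
        raise ValueError(f"unknown units {units!r}") from None
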