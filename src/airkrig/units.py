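"""Concentration unit conversion.

Mobile ozone sensors report parts per billion by volume; reference stations
report µg/m³. At 1 atm and 20 °C the two are related by

    µg/m³ = ppb · 12.187 · M / 293

where M is the molecular weight of the pollutant in g/mol (48 for ozone).
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

#: Molecular weight of ozone, g/mol.
MOLECULAR_WEIGHT_O3 = 48.0


def ppb_to_ugm3_factor(molecular_weight: float = MOLECULAR_WEIGHT_O3) -> float:
    """Multiplicative ppb → µg/m³ factor at 1 atm, 20 °C."""
    if not molecular_weight > 0:
        raise InvalidInputError(f"molecular weight must be > 0, got {molecular_weight}")
    return 12.187 * molecular_weight / 293.0


def convert_ppb_to_ugm3(
    ppb,
    molecular_weight: float = MOLECULAR_WEIGHT_O3,
    *,
    allow_negative: bool = False,
):
    """Convert a concentration (scalar or array) from ppb to µg/m³.

    Parameters
    ----------
    ppb:
        Concentration in parts per billion by volume. Must be >= 0 unless
        ``allow_negative`` is set (raw low-cost sensor signals can undershoot).
    molecular_weight:
        Pollutant molecular weight in g/mol; default is ozone (48).
    """
    arr = np.asarray(ppb, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("ppb values must be finite")
    if not allow_negative and np.any(arr < 0):
        raise InvalidInputError("negative ppb concentration")
    out = arr * ppb_to_ugm3_factor(molecular_weight)
    return float(out) if np.isscalar(ppb) or arr.ndim == 0 else out
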