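"""Pipette-resistance thermometry via Arrhenius calibration.

Ionic conductivity of the pipette electrolyte is thermally activated, so
ln(R) is linear in 1/T with slope E_a / R_gas. A calibration sweep
(resistance vs temperature while the bath cools) fixes E_a and the
reference pair (T_0, R_0); resistances then convert to temperatures via

    T_i = [ 1/T_0 - (R_gas / E_a) * ln(R_0 / R_i) ]^-1
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import ThermometryCalibration

R_GAS = 8.314  # J / (mol K)


def fit_arrhenius(
    pairs: np.ndarray, T_0: float | None = None
) -> ThermometryCalibration:
    """Least-squares Arrhenius fit of (resistance ohm, temperature K) pairs.

    The slope of ln(R) against 1/T gives E_a / R_gas; R_0 is the fitted
    resistance evaluated at the reference temperature T_0 (default: the
    lowest calibration temperature, i.e. room temperature).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need >= 3 (resistance, temperature) pairs")
    R, T = pairs[:, 0], pairs[:, 1]
    if np.any(R <= 0) or np.any(T <= 0):
        raise ValueError("resistances and temperatures must be positive")
    if np.ptp(T) < 5.0:
        raise ValueError("calibration must span >= 5 K")
    fit = stats.linregress(1.0 / T, np.log(R))
    E_a = fit.slope * R_GAS
    if E_a <= 0:
        raise ValueError("non-positive activation energy: calibration not Arrhenius")
    if T_0 is None:
        T_0 = float(T.min())
    R_0 = float(np.exp(fit.intercept + fit.slope / T_0))
    return ThermometryCalibration(E_a=E_a, T_0=float(T_0), R_0=R_0)


def resistance_to_temperature(R_i: float, cal: ThermometryCalibration) -> float:
    """Convert a pipette resistance (ohm) to temperature (K)."""
    R_i = np.asarray(R_i, dtype=float)
    if np.any(R_i <= 0):
        raise ValueError("R_i must be positive")
    inv = 1.0 / cal.T_0 - (cal.R_gas / cal.E_a) * np.log(cal.R_0 / R_i)
    if np.any(inv <= 0):
        raise ValueError("resistance outside the calibrated domain")
    out = 1.0 / inv
    return float(out) if out.ndim == 0 else out


def temperature_to_resistance(T_i: float, cal: ThermometryCalibration) -> float:
    """Algebraic inverse of the conversion (for round-trip checks)."""
    return float(
        cal.R_0 * np.exp((cal.E_a / cal.R_gas) * (1.0 / T_i - 1.0 / cal.T_0))
    )


def celsius(T_kelvin: float) -> float:
    return T_kelvin - 273.15


def kelvin(T_celsius: float) -> float:
    return T_celsius + 273.15
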