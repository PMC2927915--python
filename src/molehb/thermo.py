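"""Oxygenation thermodynamics: van't Hoff enthalpy and temperature coefficient.

The apparent oxygenation enthalpy follows from the integrated van't Hoff
equation as dH_app = R * d(ln P50)/d(1/T); because O2 must first dissolve,
the enthalpy of the Hb + O2 reaction proper is obtained by subtracting the
O2 solubilization heat (-12.5 kJ/mol): dH_corr = dH_app + 12.5. The
empirical temperature coefficient dlog10 P50/dT (per degC) summarises the
same data on the scale blood-gas tables use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synthetic import DH_SOLUTION, GAS_CONSTANT, ValidationError


@dataclass(frozen=True)
class ThermoResult:
    """Apparent and solubilization-corrected oxygenation enthalpies (kJ/mol O2)."""

    dh_apparent: float
    dh_corrected: float
    dh_solution: float
    temp_coefficient: float
    inputs: tuple
    gas_constant: float = GAS_CONSTANT

    def to_dict(self) -> dict:
        return {
            "dH_apparent_kJ_per_mol": self.dh_apparent,
            "dH_corrected_kJ_per_mol": self.dh_corrected,
            "dH_solution_kJ_per_mol": self.dh_solution,
            "dlog10P50_per_degC": self.temp_coefficient,
            "inputs": [list(p) for p in self.inputs],
        }


def _check_pairs(pairs: Sequence[tuple]) -> tuple:
    pairs = sorted(pairs)
    if len(pairs) < 2:
        raise ValidationError("need at least 2 (temperature, P50) pairs")
    t = np.array([p for p, _ in pairs], dtype=float)
    p50 = np.array([v for _, v in pairs], dtype=float)
    if np.any(p50 <= 0):
        raise ValidationError("P50 values must be > 0")
    if np.ptp(t) == 0:
        raise ValidationError("degenerate temperature range")
    return pairs, t, p50


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) == 2:
        return float((y[1] - y[0]) / (x[1] - x[0]))
    return float(np.polyfit(x, y, 1)[0])


def vant_hoff_enthalpy(
    pairs: Sequence[tuple], dh_solution: float = DH_SOLUTION
) -> ThermoResult:
    """Oxygenation enthalpy from (temperature degC, P50 mmHg) measurements.

    dH_apparent = R * slope of ln P50 vs 1/T (kelvin), reported in kJ per
    mol O2; dH_corrected removes the O2 solubilization contribution
    (``dh_solution``, default -12.5 kJ/mol). With two points the slope is
    the exact quotient; with more, OLS. The companion temperature
    coefficient is computed from the same pairs.
    """
    pairs, t_c, p50 = _check_pairs(pairs)
    inv_t = 1.0 / (t_c + 273.15)
    dh_app = GAS_CONSTANT * _slope(inv_t, np.log(p50)) / 1000.0
    return ThermoResult(
        dh_apparent=dh_app,
        dh_corrected=dh_app - dh_solution,
        dh_solution=dh_solution,
        temp_coefficient=temperature_coefficient(pairs),
        inputs=tuple(pairs),
    )


def temperature_coefficient(pairs: Sequence[tuple]) -> float:
    """Empirical dlog10 P50/dT (per degC) by OLS (two-point quotient at n=2)."""
    pairs, t_c, p50 = _check_pairs(pairs)
    return _slope(t_c, np.log10(p50))
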