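"""Heterotropic linkage coefficients: Bohr, CO2 Bohr, chloride and DPG effects.

Each coefficient is a slope of log10 P50 against the driving variable —
pH for the Bohr factor, log10[Cl-] for chloride sensitivity — or, for the
DPG effect, the paired log10 difference between a DPG-saturated and a
DPG-free measurement. With exactly two measurements the OLS slope reduces
to the two-point quotient, which is how such tables are conventionally
derived from paired equilibration runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .synthetic import ValidationError

KINDS = ("bohr", "co2_bohr", "chloride", "dpg", "temperature")


@dataclass(frozen=True)
class LinkageCoefficient:
    """A named linkage slope with the measurements it was derived from."""

    kind: str
    value: float
    inputs: tuple = field(default=())
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown coefficient kind {self.kind!r}")
        if not math.isfinite(self.value):
            raise ValidationError("coefficient must be finite")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "value": self.value,
            "n_points": self.n_points,
            "inputs": [list(p) for p in self.inputs],
        }


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    # two points: exact quotient; more: least squares
    if len(x) == 2:
        return float((y[1] - y[0]) / (x[1] - x[0]))
    return float(np.polyfit(x, y, 1)[0])


def bohr_coefficient(
    pairs: Sequence[tuple], kind: str = "bohr"
) -> LinkageCoefficient:
    """Bohr factor: OLS slope of log10 P50 against pH.

    ``kind="co2_bohr"`` tags a coefficient measured by varying PCO2 (the pH
    of deoxygenated sub-samples at each CO2 tension drives the slope); the
    arithmetic is identical.
    """
    pairs = sorted(pairs)
    if len(pairs) < 2:
        raise ValidationError("need at least 2 (pH, P50) pairs")
    ph = np.array([p for p, _ in pairs], dtype=float)
    p50 = np.array([v for _, v in pairs], dtype=float)
    if np.any(p50 <= 0):
        raise ValidationError("P50 values must be > 0")
    if np.ptp(ph) == 0:
        raise ValidationError("degenerate pH range")
    slope = _ols_slope(ph, np.log10(p50))
    return LinkageCoefficient(kind=kind, value=slope, inputs=tuple(pairs), n_points=len(pairs))


def co2_bohr_coefficient(pairs: Sequence[tuple]) -> LinkageCoefficient:
    """CO2 Bohr coefficient from paired PCO2 conditions (see bohr_coefficient)."""
    return bohr_coefficient(pairs, kind="co2_bohr")


def chloride_coefficient(
    pairs: Sequence[tuple],
    ph_values: Optional[Sequence[float]] = None,
    bohr: Union[LinkageCoefficient, float, None] = None,
) -> LinkageCoefficient:
    """Chloride sensitivity: OLS slope of log10 P50 against log10[Cl-].

    Stripped (zero-chloride) baselines cannot enter a log-log slope and are
    rejected. If per-pair pH values and a Bohr factor are supplied, each P50
    is first corrected to the mean pH with :func:`ph_correct_p50` so the
    chloride slope is not confounded by pH drift between runs.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValidationError("need at least 2 (chloride, P50) pairs")
    cl = np.array([c for c, _ in pairs], dtype=float)
    p50 = np.array([v for _, v in pairs], dtype=float)
    if np.any(cl <= 0):
        raise ValidationError("stripped (chloride <= 0) samples cannot enter a log-log slope")
    if np.any(p50 <= 0):
        raise ValidationError("P50 values must be > 0")
    if ph_values is not None:
        if bohr is None:
            raise ValidationError("pH adjustment requested without a Bohr factor")
        ph = np.asarray(ph_values, dtype=float)
        if ph.shape != cl.shape:
            raise ValidationError("ph_values must match pairs")
        target = float(np.mean(ph))
        p50 = np.array(
            [ph_correct_p50(v, po, target, bohr) for v, po in zip(p50, ph)]
        )
    order = np.argsort(cl)
    slope = _ols_slope(np.log10(cl[order]), np.log10(p50[order]))
    return LinkageCoefficient(
        kind="chloride", value=slope, inputs=tuple(zip(cl, p50)), n_points=len(pairs)
    )


def dpg_effect(p50_without: float, p50_with: float) -> LinkageCoefficient:
    """DPG effect: log10 P50(saturating DPG) - log10 P50(DPG-free).

    A paired difference at matched pH, temperature and chloride (the caller
    guarantees matching); positive values mean DPG lowers O2 affinity.
    """
    if p50_without <= 0 or p50_with <= 0:
        raise ValidationError("P50 values must be > 0")
    value = math.log10(p50_with) - math.log10(p50_without)
    return LinkageCoefficient(
        kind="dpg", value=value, inputs=((0.0, p50_without), (1.0, p50_with)), n_points=2
    )


def ph_correct_p50(
    p50: float,
    ph_obs: float,
    ph_target: float,
    bohr: Union[LinkageCoefficient, float],
) -> float:
    """Project a P50 measured at ``ph_obs`` onto ``ph_target`` via the Bohr slope.

    P50' = 10**(log10 P50 + phi * (ph_target - ph_obs)); correcting back to
    the observed pH recovers the input exactly.
    """
    if p50 <= 0:
        raise ValidationError("P50 must be > 0")
    phi = bohr.value if isinstance(bohr, LinkageCoefficient) else float(bohr)
    if not math.isfinite(phi):
        raise ValidationError("Bohr factor must be finite")
    return 10.0 ** (math.log10(p50) + phi * (ph_target - ph_obs))
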