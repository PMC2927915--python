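"""Hill-plot estimation of P50 and n50, and equilibration-curve construction.

The Hill plot linearizes a sigmoidal binding curve by regressing
log10(Y/(1-Y)) on log10(PO2); the slope is the cooperativity coefficient n50
and the PO2 at which the ordinate crosses zero is P50. Following standard
tonometry practice, the fit is restricted to steps with fractional saturation
between 30 and 70%, and requires at least four such steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats

from .synthetic import OECDataset, ValidationError, saturation_at


class InsufficientDataError(ValueError):
    """Too few usable equilibration steps for the requested fit."""


@dataclass(frozen=True)
class HillFit:
    """Result of a Hill-plot regression.

    ``slope`` equals ``n50`` and ``p50 = 10**(-intercept/slope)``; both
    identities are preserved exactly by construction.
    """

    p50: float
    n50: float
    intercept: float
    slope: float
    r2: float
    n_points_used: int
    window: tuple

    def to_dict(self) -> dict:
        return {
            "p50_mmHg": self.p50,
            "n50": self.n50,
            "r2": self.r2,
            "n_points_used": self.n_points_used,
            "window": list(self.window),
        }


def hill_transform(po2: float, saturation: float) -> tuple:
    """Map one equilibration step to Hill-plot coordinates.

    Returns ``(log10 PO2, log10(Y/(1-Y)))``. Saturations of exactly 0 or 1
    and non-positive PO2 have no finite image and raise.
    """
    if not 0.0 < saturation < 1.0 or po2 <= 0:
        raise ValidationError("untransformable step")
    return math.log10(po2), math.log10(saturation / (1.0 - saturation))


def fit_hill(
    dataset: OECDataset,
    window: tuple = (0.30, 0.70),
    min_points: int = 4,
) -> HillFit:
    """Estimate P50 and n50 by OLS on Hill-transformed in-window steps.

    Steps with saturation in ``[window[0], window[1]]`` (bounds inclusive)
    enter an ordinary least-squares line in (log10 PO2, logit10 Y) space.
    Deterministic and invariant to the ordering of input steps.

    Raises
    ------
    InsufficientDataError
        If fewer than ``min_points`` steps fall inside the window. Callers
        wanting a wider window must widen it explicitly.
    """
    lo, hi = window
    if not (0.0 < lo < hi < 1.0):
        raise ValidationError("window bounds must satisfy 0 < low < high < 1")
    po2 = np.asarray(dataset.po2)
    sat = np.asarray(dataset.saturation)
    mask = (sat >= lo) & (sat <= hi) & (po2 > 0)
    if int(mask.sum()) < min_points:
        raise InsufficientDataError(
            f"insufficient steps in saturation window: {int(mask.sum())} < {min_points}"
        )
    x = np.log10(po2[mask])
    y = np.log10(sat[mask] / (1.0 - sat[mask]))
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope <= 0:
        raise ValidationError("non-positive Hill slope; data not consistent with binding")
    return HillFit(
        p50=10.0 ** (-intercept / slope),
        n50=slope,
        intercept=intercept,
        slope=slope,
        r2=float(res.rvalue) ** 2,
        n_points_used=int(mask.sum()),
        window=(lo, hi),
    )


def construct_oec(
    fit_or_points: Union[HillFit, Sequence[tuple]],
    po2_grid: Sequence[float],
) -> list:
    """Construct a smooth oxygen equilibration curve on a PO2 grid.

    Given a :class:`HillFit`, evaluates the fitted Hill model. Given measured
    points, evaluates a monotone piecewise-linear interpolant in
    Hill-transformed coordinates, extrapolating the two terminal segments
    linearly — a transparent stand-in for classical nomogram-style curve
    construction. The output saturation is non-decreasing in PO2 and bounded
    in [0, 1].
    """
    grid = np.asarray(po2_grid, dtype=float)
    if isinstance(fit_or_points, HillFit):
        y = saturation_at(grid, fit_or_points.p50, fit_or_points.n50)
        return list(zip(grid.tolist(), np.atleast_1d(y).tolist()))

    pts = sorted(fit_or_points, key=lambda p: p[0])
    if len(pts) < 3:
        raise ValidationError("need a HillFit or at least 3 points")
    sats = [p[1] for p in pts]
    if any(b < a for a, b in zip(sats, sats[1:])):
        raise ValidationError("saturations must be non-decreasing in po2")
    xy = [hill_transform(po2, s) for po2, s in pts]
    xs = np.array([p[0] for p in xy])
    ys = np.array([p[1] for p in xy])
    out = np.empty_like(grid)
    for i, g in enumerate(grid):
        if g <= 0:
            out[i] = 0.0
            continue
        x = math.log10(g)
        if x <= xs[0]:
            slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
            yv = ys[0] + slope * (x - xs[0])
        elif x >= xs[-1]:
            slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            yv = ys[-1] + slope * (x - xs[-1])
        else:
            yv = float(np.interp(x, xs, ys))
        out[i] = 1.0 / (1.0 + 10.0 ** (-yv))
    return list(zip(grid.tolist(), out.tolist()))
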