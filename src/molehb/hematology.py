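"""Red-cell indices, Welch's t-test on summary statistics, and group contrasts."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .synthetic import ValidationError


@dataclass(frozen=True)
class PanelVariable:
    """One hematology variable for one group: mean +/- SE with sample size."""

    label: str
    mean: float
    se: float
    n: int
    units: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.se < 0:
            raise ValidationError("se must be >= 0")

    @property
    def sd(self) -> float:
        # SE is the primary published quantity; SD recovered as se*sqrt(n)
        return self.se * math.sqrt(self.n)


def red_cell_indices(hct: float, hb: float, rbc: float) -> tuple:
    """Derive (MCV fL, MCH pg, MCHC g/L) from Hct %, Hb g/dL and RBC 10^6/mm^3.

    MCV = Hct*10/RBC, MCH = Hb*10/RBC, MCHC = Hb*1000/Hct.
    """
    if rbc <= 0 or hct <= 0:
        raise ValidationError("rbc and hct must be > 0")
    if hb < 0:
        raise ValidationError("hb must be >= 0")
    mcv = hct * 10.0 / rbc
    mch = hb * 10.0 / rbc
    mchc = hb * 1000.0 / hct
    return mcv, mch, mchc


def welch_t(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> tuple:
    """Welch's unequal-variance t-test from group summary statistics.

    t = (mean1 - mean2)/sqrt(se1^2 + se2^2), with Welch-Satterthwaite
    degrees of freedom on the squared standard errors; returns
    (t, df, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if se1 < 0 or se2 < 0:
        raise ValidationError("standard errors must be >= 0")
    v1, v2 = se1 * se1, se2 * se2
    if v1 + v2 == 0:
        raise ValidationError("degenerate variance")
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p


def fold_ratio(a: float, b: float) -> float:
    """a/b (dimensionless); b must be positive."""
    if b <= 0:
        raise ValidationError("denominator must be > 0")
    return a / b


def percent_difference(a: float, b: float) -> float:
    """100*(a - b)/b, the percent excess of a over the baseline b."""
    if b <= 0:
        raise ValidationError("baseline must be > 0")
    return 100.0 * (a - b) / b


def compare_groups(
    g1: PanelVariable, g2: PanelVariable
) -> Optional[dict]:
    """Welch comparison of two groups of the same variable; None if untestable.

    Groups with n < 2 (single-animal measurements) cannot be tested and
    yield None rather than a fabricated p-value.
    """
    if g1.label != g2.label:
        raise ValidationError("variables differ between groups")
    if g1.n < 2 or g2.n < 2 or (g1.se == 0 and g2.se == 0):
        return None
    t, df, p = welch_t(g1.mean, g1.se, g1.n, g2.mean, g2.se, g2.n)
    return {"variable": g1.label, "t": t, "df": df, "p_two_sided": p}
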