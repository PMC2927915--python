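"""Forward allosteric model of hemoglobin O2 affinity and seeded data generators.

The forward model predicts the half-saturation pressure P50 of a hemoglobin
solution (or whole blood) from its experimental conditions — pH, chloride
concentration, 2,3-DPG:Hb4 ratio and temperature — by composing the standard
log-linear heterotropic linkage terms with the integrated van't Hoff relation.
On top of it sit generators for noisy oxygen-equilibration step series
(emulating diffusion-chamber tonometry) and for per-animal hematology draws,
so every downstream estimator in this package can be validated by parameter
recovery without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

GAS_CONSTANT = 8.314
"""Molar gas constant, J mol-1 K-1."""

DH_SOLUTION = -12.5
"""Heat of O2 solubilization in aqueous solution, kJ per mol O2."""

DPG_SATURATING_RATIO = 50.0
"""DPG:Hb4 molar ratio taken as fully saturating the effector site."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass(frozen=True)
class Conditions:
    """Experimental conditions of one equilibration trial.

    Parameters
    ----------
    temperature_c : float
        Temperature in degrees Celsius, must lie in (0, 45].
    ph : float
        Sample pH, must lie in [5.5, 9.5].
    chloride_m : float or None
        Added chloride in mol/L; ``None`` means a stripped (chloride-free)
        preparation.
    dpg_ratio : float
        DPG:Hb4 molar ratio; 0 means stripped.
    pco2_mmhg : float or None
        Optional CO2 tension annotation (mmHg); not used by the model.
    """

    temperature_c: float
    ph: float
    chloride_m: Optional[float] = None
    dpg_ratio: float = 0.0
    pco2_mmhg: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.temperature_c <= 45.0:
            raise ValidationError(f"temperature {self.temperature_c} outside (0, 45] degC")
        if not 5.5 <= self.ph <= 9.5:
            raise ValidationError(f"pH {self.ph} outside [5.5, 9.5]")
        if self.chloride_m is not None and self.chloride_m < 0:
            raise ValidationError("chloride must be >= 0 or None (stripped)")
        if self.dpg_ratio < 0:
            raise ValidationError("dpg_ratio must be >= 0")

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + 273.15


@dataclass(frozen=True)
class AllostericParams:
    """Ground-truth parameters of the forward P50 model.

    ``logp50_ref`` is log10 of P50 (mmHg) at ``ref_conditions``; the four
    sensitivity terms are the classical linkage coefficients: ``bohr_phi``
    (dlog10 P50/dpH, negative for a normal Bohr effect), ``k_cl``
    (dlog10 P50/dlog10[Cl-]), ``dpg_shift`` (log10 P50 shift at saturating
    DPG) and ``dh_corr`` (oxygenation enthalpy corrected for the O2
    solubilization heat, kJ per mol O2; negative = exothermic).
    """

    logp50_ref: float
    hill_n: float
    bohr_phi: float
    k_cl: float
    dpg_shift: float
    dh_corr: float
    ref_conditions: Conditions

    def __post_init__(self) -> None:
        if not 0.5 < self.hill_n <= 4.0:
            raise ValidationError(f"hill_n {self.hill_n} outside (0.5, 4]")
        if not math.isfinite(self.logp50_ref):
            raise ValidationError("logp50_ref must be finite")

    @property
    def p50_ref(self) -> float:
        return 10.0 ** self.logp50_ref


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on fractional saturation, with a fixed seed."""

    saturation_sd: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.saturation_sd <= 0.05:
            raise ValidationError("saturation_sd outside [0, 0.05]")


@dataclass(frozen=True)
class OECDataset:
    """One oxygen-equilibration experiment: ordered (PO2, saturation) steps."""

    po2: tuple
    saturation: tuple
    conditions: Conditions
    label: str = ""

    def __post_init__(self) -> None:
        po2 = np.asarray(self.po2, dtype=float)
        sat = np.asarray(self.saturation, dtype=float)
        if po2.size < 2:
            raise ValidationError("dataset needs at least 2 equilibration steps")
        if po2.size != sat.size:
            raise ValidationError("po2 and saturation must have equal length")
        if not np.all(np.diff(po2) > 0):
            raise ValidationError("po2 steps must be strictly increasing")
        if np.any((sat < 0) | (sat > 1)):
            raise ValidationError("saturations must lie in [0, 1]")
        object.__setattr__(self, "po2", tuple(po2))
        object.__setattr__(self, "saturation", tuple(sat))

    def __len__(self) -> int:
        return len(self.po2)

    @property
    def steps(self):
        return list(zip(self.po2, self.saturation))


def _dpg_occupancy(ratio: float) -> float:
    # linear dose-response up to the saturating ratio, flat above
    return min(1.0, ratio / DPG_SATURATING_RATIO)


def p50_at_conditions(
    params: AllostericParams,
    c: Conditions,
    dh_solution: float = DH_SOLUTION,
) -> float:
    """Predict P50 (mmHg) at conditions ``c`` under the log-linear linkage model.

    log10 P50 = log10 P50_ref
               + bohr_phi * (pH - pH_ref)
               + k_cl * (log10[Cl-] - log10[Cl-]_ref)
               + dpg_shift * (occ(ratio) - occ(ratio_ref))
               + (dH_app / (ln10 * R)) * (1/T - 1/T_ref)

    where occ(r) = min(1, r/50), T is in kelvin and dH_app = dh_corr +
    dh_solution is the apparent (uncorrected) oxygenation enthalpy actually
    governing the temperature dependence of measured P50.

    Raises
    ------
    ValidationError
        If chloride is present on exactly one side of the comparison while
        the chloride coefficient is nonzero ("chloride reference mismatch").
    """
    ref = params.ref_conditions
    log_p50 = params.logp50_ref
    log_p50 += params.bohr_phi * (c.ph - ref.ph)

    q_has_cl = c.chloride_m is not None and c.chloride_m > 0
    r_has_cl = ref.chloride_m is not None and ref.chloride_m > 0
    if params.k_cl != 0.0:
        if q_has_cl != r_has_cl:
            raise ValidationError("chloride reference mismatch")
        if q_has_cl and r_has_cl:
            log_p50 += params.k_cl * (math.log10(c.chloride_m) - math.log10(ref.chloride_m))

    log_p50 += params.dpg_shift * (_dpg_occupancy(c.dpg_ratio) - _dpg_occupancy(ref.dpg_ratio))

    dh_app_j = (params.dh_corr + dh_solution) * 1000.0
    log_p50 += (dh_app_j / (math.log(10.0) * GAS_CONSTANT)) * (
        1.0 / c.temperature_k - 1.0 / ref.temperature_k
    )
    return 10.0 ** log_p50


def saturation_at(po2: float, p50: float, n: float) -> float:
    """Hill-model fractional saturation Y = PO2^n / (PO2^n + P50^n).

    Vectorized over ``po2``. Y(P50) = 0.5 exactly; Y(0) = 0.
    """
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValidationError("po2 must be >= 0")
    if p50 <= 0 or n <= 0:
        raise ValidationError("p50 and n must be > 0")
    with np.errstate(divide="ignore", over="ignore"):
        y = np.where(po2 > 0, 1.0 / (1.0 + (p50 / np.maximum(po2, 1e-300)) ** n), 0.0)
    if y.ndim == 0:
        return float(y)
    return y


def generate_oec(
    params: AllostericParams,
    c: Conditions,
    po2_grid: Sequence[float],
    noise: NoiseModel,
    label: str = "",
) -> OECDataset:
    """Simulate one noisy equilibration step series at conditions ``c``.

    Saturations are the Hill-model values at the condition-specific P50 with
    additive N(0, saturation_sd) noise, clipped to [0, 1]. The same seed
    reproduces the dataset bit for bit.
    """
    grid = np.asarray(po2_grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("po2 grid must not be empty")
    if not np.all(np.diff(grid) > 0):
        raise ValidationError("po2 grid must be strictly increasing")
    p50 = p50_at_conditions(params, c)
    y = saturation_at(grid, p50, params.hill_n)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if noise.saturation_sd > 0:
        rng = np.random.default_rng(noise.seed)
        y = y + rng.normal(0.0, noise.saturation_sd, size=y.shape)
    y = np.clip(y, 0.0, 1.0)
    return OECDataset(po2=tuple(grid), saturation=tuple(y), conditions=c, label=label)


@dataclass
class GroupDraws:
    """Simulated per-animal measurements for one group of one variable."""

    label: str
    values: np.ndarray = field(repr=False)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def se(self) -> float:
        if len(self.values) < 2:
            return 0.0
        return float(np.std(self.values, ddof=1) / math.sqrt(len(self.values)))

    @property
    def n(self) -> int:
        return len(self.values)


def generate_blood_panel(
    group_specs: Sequence[tuple], seed: int
) -> list[GroupDraws]:
    """Draw per-animal values for each (label, mean, sd, n) group spec.

    Draws are normal with the given mean and SD; reported group mean and SE
    are computed from the draws, mirroring how a hematology table summarises
    individual animals. sd=0 yields identical draws equal to the mean.
    """
    rng = np.random.default_rng(seed)
    out = []
    for label, mean, sd, n in group_specs:
        if sd < 0:
            raise ValidationError("sd must be >= 0")
        if n < 1:
            raise ValidationError("n must be >= 1")
        out.append(GroupDraws(label=str(label), values=rng.normal(mean, sd, size=int(n))))
    return out
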