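"""Thermal-inactivation kinetics and activation thermodynamics.

Implements the classical chain used to characterize irreversible enzyme
inactivation: a first-order decay fit per temperature (ln A/A0 = -k t),
an Arrhenius fit across temperatures (ln k = -Ea/RT + c), the derived
half-life t1/2 = ln(2)/k and decimal-reduction time D = ln(10)/k, and the
transition-state (Eyring) activation parameters

    dG = -R T ln(k h / (kb T)),   dH = Ea - R T,   dS = (dH - dG)/T.

``thermodynamic_table`` runs the whole chain over a set of decay time
courses and returns one row per temperature plus the global Arrhenius fit.

A note on units for dG: the Eyring expression is dimensionally consistent
only with k in s^-1, but the per-hour convention is what reproduces the
published parameter sets this pipeline targets; the rate-constant time
unit is therefore an explicit argument (default ``"hour"``) and the choice
is echoed in the table metadata rather than applied silently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhysicalConstants",
    "DecayTimeCourse",
    "InactivationFit",
    "ArrheniusFit",
    "ThermoRow",
    "ThermoTable",
    "CELSIUS_OFFSET",
    "fit_inactivation_rate",
    "predict_residual_activity",
    "half_life",
    "decimal_reduction_time",
    "fit_arrhenius",
    "activation_enthalpy",
    "activation_free_energy",
    "activation_entropy",
    "thermodynamic_table",
]

CELSIUS_OFFSET = 273.15

RateTimeUnit = Literal["second", "minute", "hour"]

#: seconds per unit, used to convert a per-minute rate constant into the
#: reciprocal of the requested time unit.
_UNIT_MINUTES = {"second": 1.0 / 60.0, "minute": 1.0, "hour": 60.0}


class InsufficientDataError(ValueError):
    """Raised when a fit has too few usable points."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants, fixed at the conventional printed precision."""

    gas_constant: float = 8.314  # J mol-1 K-1
    planck: float = 6.626e-34  # J s
    boltzmann: float = 1.38e-23  # J K-1


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass
class DecayTimeCourse:
    """Residual-activity measurements over time at one temperature.

    Activities are percent of the initial activity A0 (the t=0 value, or
    ``a0`` if supplied explicitly).
    """

    temperature_c: float
    times_min: np.ndarray
    activities_pct: np.ndarray
    a0: float | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.activities_pct = np.asarray(self.activities_pct, dtype=float)
        if self.times_min.shape != self.activities_pct.shape:
            raise ValueError("times and activities must have equal length")
        if self.times_min.size and np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times_min.size and self.times_min[0] < 0:
            raise ValueError("times must be nonnegative")
        if self.a0 is None:
            if self.times_min.size == 0 or self.times_min[0] != 0:
                raise ValueError("first time point must be 0, or a0 supplied")
            self.a0 = float(self.activities_pct[0])
        if self.a0 <= 0:
            raise ValueError("initial activity must be positive")

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + CELSIUS_OFFSET


@dataclass
class InactivationFit:
    """First-order inactivation rate fit (k = -slope of ln A/A0 vs t)."""

    k_per_min: float
    intercept: float
    r_squared: float  # NaN when the response is constant
    points_used: int
    points_dropped: int = 0
    flags: list[str] = field(default_factory=list)


@dataclass
class ArrheniusFit:
    """ln(k) vs 1/T regression: Ea = -slope * R, c = intercept."""

    ea_j_mol: float
    c: float
    r_squared: float
    pairs_used: list[tuple[float, float]] = field(default_factory=list)

    @property
    def ea_kj_mol(self) -> float:
        return self.ea_j_mol / 1000.0


@dataclass
class ThermoRow:
    temperature_c: float
    temperature_k: float
    k_per_min: float
    half_life_min: float
    d_value_min: float
    delta_h_kj_mol: float
    delta_g_kj_mol: float
    delta_s_kj_mol_k: float


@dataclass
class ThermoTable:
    rows: list[ThermoRow]
    arrhenius: ArrheniusFit | None
    fits: list[InactivationFit]
    rate_time_unit_for_dg: RateTimeUnit
    warnings: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature_C": [r.temperature_c for r in self.rows],
                "k_per_min": [r.k_per_min for r in self.rows],
                "t_half_min": [r.half_life_min for r in self.rows],
                "d_value_min": [r.d_value_min for r in self.rows],
                "dH_kJ_mol": [r.delta_h_kj_mol for r in self.rows],
                "dG_kJ_mol": [r.delta_g_kj_mol for r in self.rows],
                "dS_kJ_mol_K": [r.delta_s_kj_mol_k for r in self.rows],
            }
        )


def fit_inactivation_rate(
    course: DecayTimeCourse, force_zero_intercept: bool = False
) -> InactivationFit:
    """Fit ln(A/A0) = -k t by ordinary least squares and report k = -slope.

    Points with activity <= 0 are excluded (their logarithm is undefined)
    and counted in ``points_dropped``. With ``force_zero_intercept`` the
    regression is through the origin: slope = sum(t*y)/sum(t^2).
    """
    mask = course.activities_pct > 0
    dropped = int((~mask).sum())
    if dropped:
        warnings.warn(
            f"dropped {dropped} point(s) with activity <= 0 at "
            f"{course.temperature_c} degC",
            stacklevel=2,
        )
    t = course.times_min[mask]
    y = np.log(course.activities_pct[mask] / course.a0)
    if t.size < 3:
        raise InsufficientDataError(
            f"need >=3 points with positive activity, got {t.size}"
        )
    flags: list[str] = []
    if force_zero_intercept:
        denom = float(np.sum(t * t))
        if denom == 0.0:
            raise InsufficientDataError("all usable time points are zero")
        slope = float(np.sum(t * y)) / denom
        intercept = 0.0
        resid = y - slope * t
    else:
        res = stats.linregress(t, y)
        slope, intercept = float(res.slope), float(res.intercept)
        resid = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = math.nan
        flags.append("constant_response_r2_undefined")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    k = -slope
    if k < 0:
        flags.append("negative_rate_clipped_to_zero")
        k = 0.0
    return InactivationFit(
        k_per_min=k,
        intercept=intercept,
        r_squared=r2,
        points_used=int(t.size),
        points_dropped=dropped,
        flags=flags,
    )


def predict_residual_activity(k: float, t: float) -> float:
    """Residual activity fraction exp(-k t) under first-order decay."""
    if k < 0 or t < 0:
        raise ValueError("k and t must be nonnegative")
    return math.exp(-k * t)


def half_life(k: float) -> float:
    """Time for activity to fall to one-half of initial: ln(2)/k (min)."""
    if k <= 0:
        raise ValueError("half-life requires k > 0")
    return math.log(2.0) / k


def decimal_reduction_time(k: float) -> float:
    """Decimal-reduction time D = ln(10)/k (min)."""
    if k <= 0:
        raise ValueError("D-value requires k > 0")
    return math.log(10.0) / k


def fit_arrhenius(pairs: Sequence[tuple[float, float]]) -> ArrheniusFit:
    """OLS of ln(k) on 1/T over (temperature K, rate constant) pairs."""
    pairs = [(float(T), float(k)) for T, k in pairs]
    if any(k <= 0 for _, k in pairs):
        raise ValueError("all rate constants must be positive")
    if any(T <= 0 for T, _ in pairs):
        raise ValueError("temperatures must be positive kelvin")
    temps = {T for T, _ in pairs}
    if len(temps) < 2:
        raise InsufficientDataError("Arrhenius fit needs >=2 distinct temperatures")
    x = np.array([1.0 / T for T, _ in pairs])
    y = np.array([math.log(k) for _, k in pairs])
    res = stats.linregress(x, y)
    r2 = float(res.rvalue) ** 2
    return ArrheniusFit(
        ea_j_mol=-float(res.slope) * DEFAULT_CONSTANTS.gas_constant,
        c=float(res.intercept),
        r_squared=r2,
        pairs_used=pairs,
    )


def activation_enthalpy(
    ea_j_mol: float, temperature_k: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Activation enthalpy dH = Ea - R T, returned in kJ/mol."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive kelvin")
    return (ea_j_mol - constants.gas_constant * temperature_k) / 1000.0


def activation_free_energy(
    k_per_min: float,
    temperature_k: float,
    rate_time_unit: RateTimeUnit = "hour",
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Activation free energy dG = -R T ln(k h / (kb T)), in kJ/mol.

    ``k_per_min`` is converted to the reciprocal of ``rate_time_unit``
    before the Eyring expression is evaluated; see the module docstring
    for why the unit is an explicit choice.
    """
    if k_per_min <= 0:
        raise ValueError("rate constant must be positive")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive kelvin")
    k = k_per_min * _UNIT_MINUTES[rate_time_unit]
    arg = k * constants.planck / (constants.boltzmann * temperature_k)
    return -constants.gas_constant * temperature_k * math.log(arg) / 1000.0


def activation_entropy(
    delta_h_kj_mol: float, delta_g_kj_mol: float, temperature_k: float
) -> float:
    """Activation entropy dS = (dH - dG)/T, in kJ/(mol K)."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive kelvin")
    return (delta_h_kj_mol - delta_g_kj_mol) / temperature_k


def thermodynamic_table(
    courses: Sequence[DecayTimeCourse],
    rate_time_unit_for_dg: RateTimeUnit = "hour",
    force_zero_intercept: bool = False,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> ThermoTable:
    """Run the full inactivation chain over per-temperature time courses.

    Per temperature: k from ``fit_inactivation_rate``, then t1/2 and D.
    Globally: Ea from the Arrhenius fit, then per-row dH, dG, dS. With a
    single temperature the Arrhenius stage (and the thermodynamic columns
    that depend on Ea) are unavailable; k, t1/2 and D are still reported
    and the condition is recorded as a warning rather than an error.
    """
    if not courses:
        raise InsufficientDataError("no time courses supplied")
    notes: list[str] = [
        f"dG uses rate constants expressed per {rate_time_unit_for_dg}"
    ]
    fits = [
        fit_inactivation_rate(c, force_zero_intercept=force_zero_intercept)
        for c in courses
    ]
    pairs = [
        (c.temperature_k, f.k_per_min)
        for c, f in zip(courses, fits)
        if f.k_per_min > 0
    ]
    arrhenius: ArrheniusFit | None = None
    try:
        arrhenius = fit_arrhenius(pairs)
    except (InsufficientDataError, ValueError) as exc:
        notes.append(f"Arrhenius stage unavailable: {exc}")
    rows: list[ThermoRow] = []
    for course, fit in zip(courses, fits):
        k = fit.k_per_min
        T = course.temperature_k
        t_half = half_life(k) if k > 0 else math.inf
        d_val = decimal_reduction_time(k) if k > 0 else math.inf
        if arrhenius is not None and k > 0:
            dh = activation_enthalpy(arrhenius.ea_j_mol, T, constants)
            dg = activation_free_energy(k, T, rate_time_unit_for_dg, constants)
            ds = activation_entropy(dh, dg, T)
        else:
            dh = dg = ds = math.nan
        rows.append(
            ThermoRow(
                temperature_c=course.temperature_c,
                temperature_k=T,
                k_per_min=k,
                half_life_min=t_half,
                d_value_min=d_val,
                delta_h_kj_mol=dh,
                delta_g_kj_mol=dg,
                delta_s_kj_mol_k=ds,
            )
        )
    return ThermoTable(
        rows=rows,
        arrhenius=arrhenius,
        fits=fits,
        rate_time_unit_for_dg=rate_time_unit_for_dg,
        warnings=notes,
    )


def read_courses_tsv(path) -> list[DecayTimeCourse]:
    """Read long-format TSV (temperature_C, time_min, activity_pct)."""
    df = pd.read_csv(path, sep="\t")
    required = {"temperature_C", "time_min", "activity_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    courses = []
    for temp, grp in df.groupby("temperature_C", sort=True):
        grp = grp.sort_values("time_min")
        courses.append(
            DecayTimeCourse(
                temperature_c=float(temp),
                times_min=grp["time_min"].to_numpy(),
                activities_pct=grp["activity_pct"].to_numpy(),
            )
        )
    return courses
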