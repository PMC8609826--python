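"""Enzyme assay fitting: Michaelis-Menten kinetics, DSF melt curves, pH optima.

Michaelis-Menten: v0 = kcat [E]0 [S]0 / ([S]0 + Km), fitted by bounded
nonlinear least squares over (kcat, Km). Substrate is in mg/ml; catalytic
efficiency kcat/Km is converted to M^-1 s^-1 via the monomer molecular
weight of the released sugar (mg/ml equals g/L, so Km_molar = Km / MW).

DSF melt curves: the standard Boltzmann sigmoid
F(T) = Fmin + (Fmax - Fmin) / (1 + exp((Tm - T)/slope)), with Tm the
midpoint temperature and slope the transition width in degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "KineticsDataset",
    "MMFit",
    "MeltCurve",
    "MeltFit",
    "PhActivityProfile",
    "FittingError",
    "mm_velocity",
    "fit_michaelis_menten",
    "boltzmann_fluorescence",
    "fit_boltzmann_melt",
    "ph_optimum",
]

XYLOSE_MW = 150.0  # g/mol, monomer released by xylanase


class FittingError(RuntimeError):
    """Nonlinear fit failed or the data are degenerate."""


@dataclass
class KineticsDataset:
    """Substrate-velocity observations at fixed enzyme concentration."""

    substrate_mg_ml: np.ndarray
    velocity: np.ndarray  # e.g. uM/s; any product-per-time unit
    enzyme_conc_m: float
    monomer_mw: float = XYLOSE_MW

    def __post_init__(self) -> None:
        self.substrate_mg_ml = np.asarray(self.substrate_mg_ml, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.substrate_mg_ml.shape != self.velocity.shape:
            raise ValueError("substrate and velocity must have equal length")
        if np.any(self.substrate_mg_ml < 0):
            raise ValueError("substrate concentrations must be nonnegative")
        if self.enzyme_conc_m <= 0:
            raise ValueError("enzyme concentration must be positive")


@dataclass
class MMFit:
    kcat: float  # s^-1 (velocity unit / E0 unit, per the data's time base)
    km_mg_ml: float
    efficiency_m_s: float  # kcat / Km after molar conversion via monomer_mw
    kcat_se: float
    km_se: float
    r_squared: float


@dataclass
class MeltCurve:
    temperature_c: np.ndarray
    fluorescence: np.ndarray
    buffer_label: str = ""
    ph: float | None = None

    def __post_init__(self) -> None:
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature_c.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence must have equal length")
        if np.any(np.diff(self.temperature_c) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class MeltFit:
    tm_c: float
    slope_c: float
    f_min: float
    f_max: float
    r_squared: float
    quality_warning: bool = False


@dataclass
class PhActivityProfile:
    ph: np.ndarray
    activity: np.ndarray  # replicates allowed: repeated pH values averaged

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.ph.shape != self.activity.shape:
            raise ValueError("pH and activity must have equal length")
        if self.ph.size == 0:
            raise ValueError("empty pH profile")


def mm_velocity(kcat: float, e0: float, km: float, s) -> np.ndarray | float:
    """Michaelis-Menten initial velocity kcat*E0*S/(S+Km)."""
    if km <= 0:
        raise ValueError("Km must be positive")
    s_arr = np.asarray(s, dtype=float)
    v = kcat * e0 * s_arr / (s_arr + km)
    return float(v) if np.isscalar(s) or s_arr.ndim == 0 else v


def fit_michaelis_menten(data: KineticsDataset, max_restarts: int = 5) -> MMFit:
    """Bounded nonlinear least squares for (kcat, Km).

    Initial guesses: Vmax0 = max velocity (so kcat0 = Vmax0/E0) and
    Km0 = median positive substrate. On non-convergence the starting
    point is perturbed geometrically a few times before giving up.
    """
    s = data.substrate_mg_ml
    v = data.velocity
    if len(np.unique(s)) < 4:
        raise FittingError("need >=4 distinct substrate levels")
    if np.all(v == 0):
        raise FittingError("all velocities are zero; nothing to fit")
    e0 = data.enzyme_conc_m
    # fit on a unit-scaled response: raw velocities can be ~1e-5 in
    # absolute terms, small enough to trip the optimizer's cost tolerance
    v_scale = float(np.abs(v).max())
    v_scaled = v / v_scale

    def model(s_, kcat, km):
        return kcat * e0 * s_ / (s_ + km) / v_scale

    kcat0 = max(float(v.max()) / e0, 1e-12)
    km0 = max(float(np.median(s[s > 0])), 1e-12)
    last_err: Exception | None = None
    for attempt in range(max_restarts):
        factor = 2.0**attempt
        try:
            popt, pcov = curve_fit(
                model,
                s,
                v_scaled,
                p0=[kcat0 * factor, km0 * factor],
                bounds=([0.0, 1e-12], [np.inf, np.inf]),
                x_scale=[kcat0, km0],
                maxfev=20000,
            )
            break
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            last_err = exc
    else:  # pragma: no cover
        raise FittingError(f"Michaelis-Menten fit did not converge: {last_err}")
    kcat, km = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov))
    resid = v - model(s, *popt) * v_scale
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan
    km_molar = km / data.monomer_mw  # mg/ml == g/L; g/L / (g/mol) = mol/L
    return MMFit(
        kcat=kcat,
        km_mg_ml=km,
        efficiency_m_s=kcat / km_molar,
        kcat_se=float(perr[0]),
        km_se=float(perr[1]),
        r_squared=r2,
    )


def boltzmann_fluorescence(t, tm, slope, f_min, f_max):
    """Boltzmann sigmoid F(T) used for DSF melt curves."""
    t = np.asarray(t, dtype=float)
    arg = np.clip((tm - t) / slope, -700.0, 700.0)  # avoid exp overflow
    return f_min + (f_max - f_min) / (1.0 + np.exp(arg))


def fit_boltzmann_melt(curve: MeltCurve, max_temperature_c: float | None = None) -> MeltFit:
    """Fit the Boltzmann sigmoid to a melt curve and report Tm.

    ``max_temperature_c`` optionally truncates the post-transition
    aggregation decline before fitting (common DSF practice); default is
    no truncation. A fit with r^2 < 0.5 is returned with
    ``quality_warning=True`` rather than raised.
    """
    t = curve.temperature_c
    f = curve.fluorescence
    if max_temperature_c is not None:
        keep = t <= max_temperature_c
        t, f = t[keep], f[keep]
    if t.size < 10:
        raise FittingError("need >=10 points spanning the transition")
    f_min0, f_max0 = float(f.min()), float(f.max())
    half = (f_min0 + f_max0) / 2.0
    tm0 = float(t[np.argmin(np.abs(f - half))])
    try:
        popt, _ = curve_fit(
            boltzmann_fluorescence,
            t,
            f,
            p0=[tm0, 1.0, f_min0, f_max0],
            bounds=([t.min() - 50, 1e-6, -np.inf, -np.inf], [t.max() + 50, np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FittingError(f"Boltzmann melt fit did not converge: {exc}") from exc
    resid = f - boltzmann_fluorescence(t, *popt)
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan
    return MeltFit(
        tm_c=float(popt[0]),
        slope_c=float(popt[1]),
        f_min=float(popt[2]),
        f_max=float(popt[3]),
        r_squared=r2,
        quality_warning=not (r2 >= 0.5),
    )


def ph_optimum(profile: PhActivityProfile) -> tuple[float, pd.DataFrame, bool]:
    """Optimum pH as argmax of mean activity, with full ranking.

    Replicate measurements at the same pH are averaged first. Ties break
    toward the lower pH; the returned flag is True when the optimum was
    tie-broken. The ranking table (pH, mean activity, rank) supports
    downstream comparisons of stability versus pH.
    """
    if np.unique(profile.ph).size < 3:
        raise ValueError("need >=3 distinct pH levels")
    df = (
        pd.DataFrame({"pH": profile.ph, "activity": profile.activity})
        .groupby("pH", as_index=False)["activity"]
        .mean()
        .sort_values(["activity", "pH"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    df["rank"] = np.arange(1, len(df) + 1)
    top = df.iloc[0]
    tie = bool((df["activity"] == top["activity"]).sum() > 1)
    return float(top["pH"]), df, tie
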