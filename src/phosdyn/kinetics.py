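"""Michaelis-Menten fitting, activation profiling and melt-curve Tm.

The velocity law is v = Vmax*S/(Km+S); the turnover number is kcat =
Vmax/[E] with [E] the (known) total enzyme concentration, and the
specificity constant kcat/Km underlies fold-change comparisons between
enzyme variants.  Melting temperatures are read off thermal-shift
fluorescence curves at the inflection point of the ascending transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .errors import DataFormatError, NumericalError


@dataclass
class KineticsFit:
    """Fitted Michaelis-Menten parameters for one enzyme variant."""

    vmax: float
    km: float
    kcat: float
    specificity: float  # kcat / Km
    enzyme_conc: float
    residual_norm: float
    converged: bool
    n_iterations: int

    def predict(self, substrate) -> np.ndarray:
        s = np.asarray(substrate, dtype=float)
        return self.vmax * s / (self.km + s)


def fit_michaelis_menten(rates: pd.DataFrame, enzyme_conc: float) -> KineticsFit:
    """Nonlinear least-squares fit of v = Vmax*S/(Km+S).

    Expects columns ``substrate_uM`` and ``velocity`` (replicate rows may
    repeat substrate levels).  Initialisation: Vmax0 = max observed
    velocity, Km0 = substrate at the grid point whose velocity is nearest
    Vmax0/2; convergence at relative parameter change < 1e-8 within 500
    iterations.  Non-convergence is flagged in the result, not hidden.
    """
    if enzyme_conc <= 0:
        raise DataFormatError(f"enzyme concentration must be > 0, got {enzyme_conc}")
    for col in ("substrate_uM", "velocity"):
        if col not in rates.columns:
            raise DataFormatError(f"rate table missing column {col!r}")
    s = rates["substrate_uM"].to_numpy(dtype=float)
    v = rates["velocity"].to_numpy(dtype=float)
    if np.any(s < 0):
        raise DataFormatError("substrate concentrations must be >= 0")
    if len(np.unique(s)) < 4:
        raise DataFormatError("need at least 4 distinct substrate levels")

    vmax0 = float(np.max(v))
    if vmax0 <= 0:
        raise NumericalError("all velocities non-positive; nothing to fit")
    half_idx = int(np.argmin(np.abs(v - vmax0 / 2)))
    km0 = float(s[half_idx]) if s[half_idx] > 0 else float(np.median(s[s > 0]))

    def resid(p):
        return p[0] * s / (p[1] + s) - v

    sol = least_squares(
        resid,
        x0=[vmax0, km0],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        xtol=1e-8,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=500,
    )
    vmax, km = float(sol.x[0]), float(sol.x[1])
    converged = bool(sol.success) and vmax > 0 and km > 0
    kcat = vmax / enzyme_conc
    return KineticsFit(
        vmax=vmax,
        km=km,
        kcat=kcat,
        specificity=kcat / km if km > 0 else float("nan"),
        enzyme_conc=enzyme_conc,
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=converged,
        n_iterations=int(sol.nfev),
    )


def specificity_fold_change(fit_a: KineticsFit, fit_b: KineticsFit) -> float:
    """Ratio of specificity constants, (kcat_a/Km_a) / (kcat_b/Km_b)."""
    if fit_b.specificity == 0:
        raise NumericalError("reference specificity is zero")
    return fit_a.specificity / fit_b.specificity


def initial_rate(time: np.ndarray, signal: np.ndarray, window: int = 5) -> float:
    """Initial velocity from a progress curve: least-squares slope of the
    first ``window`` points (the early linear segment)."""
    t = np.asarray(time, dtype=float)[:window]
    y = np.asarray(signal, dtype=float)[:window]
    if len(t) < 2:
        raise DataFormatError("need at least 2 points for an initial rate")
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)


def activation_profile(
    curve: pd.DataFrame, activatable_threshold: float = 1.5
) -> tuple[pd.DataFrame, float, bool]:
    """Fold activation over the zero-activator baseline.

    Expects columns ``activator_uM`` and ``signal`` including a 0-uM row.
    Returns (per-concentration fold table, max fold, activatable flag);
    the enzyme is called activatable when max fold >= threshold.
    """
    for col in ("activator_uM", "signal"):
        if col not in curve.columns:
            raise DataFormatError(f"activation curve missing column {col!r}")
    base_rows = curve[curve["activator_uM"] == 0]
    if base_rows.empty:
        raise DataFormatError("activation curve lacks a zero-activator baseline")
    baseline = float(base_rows["signal"].mean())
    if baseline <= 0:
        raise DataFormatError(f"baseline signal must be > 0, got {baseline}")
    out = curve.copy()
    out["fold"] = out["signal"] / baseline
    max_fold = float(out["fold"].max())
    return out, max_fold, max_fold >= activatable_threshold


@dataclass
class TmResult:
    """Melting temperature from a thermal-shift curve."""

    tm: float
    max_slope: float
    window: int


def find_tm(melt: pd.DataFrame, window: int = 5) -> TmResult:
    """Tm at the inflection point of the ascending fluorescence transition.

    The curve is restricted to the segment ending at the global
    fluorescence maximum (post-peak dye-release decay is discarded),
    smoothed with a centered moving quadratic fit of ``window`` points,
    and Tm is the temperature of maximal first derivative of the smoothed
    curve.  A curve with no positive slope raises
    :class:`NumericalError`.
    """
    for col in ("temperature_C", "fluorescence"):
        if col not in melt.columns:
            raise DataFormatError(f"melt curve missing column {col!r}")
    t = melt["temperature_C"].to_numpy(dtype=float)
    f = melt["fluorescence"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DataFormatError("temperature grid must be strictly increasing")
    if len(t) < 2 * window + 1:
        raise DataFormatError(f"need at least {2 * window + 1} points for window {window}")
    peak = int(np.argmax(f))
    if peak < 2 * window:
        raise NumericalError("fluorescence maximum too early; no ascending transition")
    t_seg, f_seg = t[: peak + 1], f[: peak + 1]
    win = window if window % 2 == 1 else window + 1
    smooth = savgol_filter(f_seg, win, polyorder=2)
    dfdt = np.gradient(smooth, t_seg)
    imax = int(np.argmax(dfdt))
    if dfdt[imax] <= 0:
        raise NumericalError("no positive slope found; curve has no melting transition")
    return TmResult(tm=float(t_seg[imax]), max_slope=float(dfdt[imax]), window=window)
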