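"""Quantitative assay fits: steady-state SPR, thermal melts, outliers, killing.

- :func:`fit_one_site` -- equilibrium one-site specific binding,
  R(C) = Rmax * C / (KD + C), fit by nonlinear least squares and normalised
  to the fitted Rmax (steady-state TCR-pMHC affinity measurement).
- :func:`fit_tm` -- melting temperature from a differential scanning
  fluorimetry trace, by smoothed-derivative maximum or Boltzmann sigmoid.
- :func:`rout_outliers` -- univariate ROUT-style outlier flagging: robust
  center/scale, then an FDR-controlled t-test over ranked residuals.
- :func:`specific_killing` -- percent specific killing from target/reference
  dye ratios in an in-vivo killing assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BindingCurve",
    "FitResult",
    "MeltCurve",
    "FitError",
    "NoTransitionError",
    "fit_one_site",
    "fit_tm",
    "rout_outliers",
    "specific_killing",
    "KillingResult",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge."""


class NoTransitionError(ValueError):
    """Melt curve shows no unfolding transition."""


@dataclass
class BindingCurve:
    """Analyte concentrations (uM) and steady-state responses (RU)."""

    concentrations: Sequence[float]
    responses: Sequence[float]

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.shape != r.shape:
            raise ValueError("concentrations and responses must pair up")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        order = np.argsort(c)
        self.concentrations = c[order]
        self.responses = r[order]


@dataclass
class FitResult:
    kd: float  # uM
    rmax: float  # response units
    residual_norm: float
    normalized_responses: np.ndarray  # responses / fitted Rmax

    def model(self, conc):
        conc = np.asarray(conc, dtype=float)
        return self.rmax * conc / (self.kd + conc)


def fit_one_site(curve: BindingCurve) -> FitResult:
    """Least-squares one-site specific binding fit.

    Initial guesses: Rmax = max response, KD = concentration nearest the
    half-maximal response; both parameters constrained positive.
    """
    c = np.asarray(curve.concentrations, dtype=float)
    r = np.asarray(curve.responses, dtype=float)
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    rmax0 = float(r.max())
    if rmax0 <= 0:
        rmax0 = 1.0
    kd0 = float(c[np.argmin(np.abs(r - rmax0 / 2))])

    def model(conc, rmax, kd):
        return rmax * conc / (kd + conc)

    try:
        popt, _ = optimize.curve_fit(
            model, c, r, p0=[rmax0, kd0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"one-site fit did not converge: {exc}") from exc
    rmax, kd = float(popt[0]), float(popt[1])
    resid = r - model(c, rmax, kd)
    return FitResult(
        kd=kd,
        rmax=rmax,
        residual_norm=float(np.linalg.norm(resid)),
        normalized_responses=r / rmax,
    )


@dataclass
class MeltCurve:
    """A thermal unfolding trace: temperature (degC) vs fluorescence (a.u.)."""

    temperatures: Sequence[float]
    fluorescence: Sequence[float]

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape:
            raise ValueError("temperatures and fluorescence must pair up")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        self.temperatures = t
        self.fluorescence = f


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="valid")
    return out[: len(x)]


def fit_tm(melt: MeltCurve, method: str = "derivative", window: int = 5) -> float:
    """Melting temperature of an unfolding transition.

    ``derivative``: temperature of the maximum of the smoothed dF/dT
    (moving average, centered).  ``boltzmann``: midpoint of a fitted
    sigmoid F = f_low + (f_high - f_low) / (1 + exp((Tm - T)/width)).
    A flat trace (no transition) raises :class:`NoTransitionError`.
    """
    t = np.asarray(melt.temperatures, dtype=float)
    f = np.asarray(melt.fluorescence, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 points spanning the transition")
    span = float(f.max() - f.min())
    scale = max(abs(f).max(), 1.0)
    if span < 1e-9 * scale:
        raise NoTransitionError("fluorescence trace is flat")
    smooth = _moving_average(f, window)
    dfdt = np.gradient(smooth, t)
    if dfdt.max() <= 0:
        raise NoTransitionError("no rising transition in trace")
    if method == "derivative":
        return float(t[int(np.argmax(dfdt))])
    if method == "boltzmann":
        def model(T, f_low, f_high, tm, width):
            return f_low + (f_high - f_low) / (1.0 + np.exp((tm - T) / width))

        tm0 = float(t[int(np.argmax(dfdt))])
        width0 = max((t[-1] - t[0]) / 20.0, 0.5)
        try:
            popt, _ = optimize.curve_fit(
                model, t, f, p0=[float(f.min()), float(f.max()), tm0, width0],
                maxfev=10000,
            )
        except RuntimeError as exc:
            raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
        return float(popt[2])
    raise ValueError(f"unknown method {method!r}")


def rout_outliers(values: Sequence[float], q_percent: float = 1.0) -> np.ndarray:
    """Flag outliers in replicate measurements (univariate ROUT-style).

    Robust center = median; robust scale = the 68.27th percentile of
    absolute residuals with an n/(n-1) small-sample correction.  Each point
    gets a two-tailed p-value from the t distribution (df = n-1) of its
    scaled residual; Benjamini-Hochberg over the ranked residuals controls
    the false discovery rate at ``q_percent``.  Returns a boolean flag per
    value in input order; the flag set is order-invariant.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("need at least 3 values")
    if not 0 < q_percent < 100:
        raise ValueError("q_percent must be in (0, 100)")
    resid = v - np.median(v)
    absr = np.abs(resid)
    # lower order statistic: keeps extreme residuals out of the scale at small n
    rsdr = float(np.percentile(absr, 68.27, method="lower")) * n / (n - 1)
    if rsdr == 0.0:
        # >68% of points identical: anything off that value is an outlier
        return absr > 0
    tval = absr / rsdr
    pvals = 2.0 * stats.t.sf(tval, df=n - 1)
    order = np.argsort(pvals)  # most extreme first
    q = q_percent / 100.0
    flags = np.zeros(n, dtype=bool)
    thresh = q * (np.arange(1, n + 1)) / n
    passing = np.nonzero(pvals[order] <= thresh)[0]
    if len(passing):
        k = passing.max()
        flags[order[: k + 1]] = True
    return flags


@dataclass
class KillingResult:
    percent: float
    clipped: bool


def specific_killing(exp_ratio: float, ctrl_ratio: float) -> KillingResult:
    """Percent specific killing from dye ratios.

    ``ratio`` = target-pulsed / reference-pulsed cell counts; killing is
    100 * (1 - exp_ratio / ctrl_ratio), clipped to [0, 100] with a flag.
    """
    if ctrl_ratio <= 0:
        raise ValueError("control ratio must be positive")
    if exp_ratio < 0:
        raise ValueError("experimental ratio must be >= 0")
    raw = 100.0 * (1.0 - exp_ratio / ctrl_ratio)
    clipped = not (0.0 <= raw <= 100.0)
    return KillingResult(percent=float(min(max(raw, 0.0), 100.0)), clipped=clipped)
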