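"""Nonlinear least-squares fitting of titration and melting curves.

Three titration models are supported, matching how the corresponding
experiments are conventionally analysed:

* Hill, ``A * x^n / (kapp^n + x^n)`` — the normalised/inverted chelator
  competition curve, whose two-site luminescence weighting produces an
  apparently cooperative (sigmoidal) shape.
* Hyperbolic competition, ``I(M) = Iinf + (I0 - Iinf) * kapp/(kapp + M)``
  — luminescence decay as a competing metal displaces the bound Tb3+.
* One-site with depletion — anisotropy readout of exact 1:1 binding,
  ``r_free + (r_bound - r_free) * f_bound`` with the quadratic isotherm
  (the probe is not in vast excess, so depletion matters at ~100 nM).

Fits are unweighted least squares via lmfit.  ``melting_point_first_derivative``
extracts a melting temperature as the extremum of the smoothed
centered-difference derivative of a thermal unfolding curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from lmfit import Model

from .binding import fraction_bound_quadratic

__all__ = [
    "TitrationCurve",
    "FitResult",
    "normalize_invert",
    "hill_model",
    "competition_hyperbolic_model",
    "fit_hill",
    "fit_competition_hyperbolic",
    "fit_one_site",
    "melting_point_first_derivative",
]


@dataclass(frozen=True)
class TitrationCurve:
    """Titrant grid (mol/L, strictly increasing) with measured signal."""

    titrant: np.ndarray
    signal: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.titrant, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("titrant and signal must be 1-D of equal length")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("titrant must be non-negative and strictly increasing")
        object.__setattr__(self, "titrant", t)
        object.__setattr__(self, "signal", s)

    def __len__(self) -> int:
        return self.titrant.size


@dataclass(frozen=True)
class FitResult:
    """Parameter estimates with standard errors from a nonlinear fit."""

    estimates: Mapping[str, float]
    stderr: Mapping[str, float]
    residual_norm: float
    converged: bool
    n_points: int
    warnings: tuple[str, ...] = ()

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


def normalize_invert(curve: TitrationCurve) -> TitrationCurve:
    """Rescale the signal to [0, 1] and flip its orientation.

    Output = 1 - (s - min)/(max - min); a decaying luminescence trace
    becomes an increasing saturation-style curve suitable for a Hill fit.
    """
    s = curve.signal
    lo, hi = float(np.min(s)), float(np.max(s))
    if hi == lo:
        raise ValueError("constant signal: normalization undefined")
    out = 1.0 - (s - lo) / (hi - lo)
    return TitrationCurve(curve.titrant, out, {**curve.meta, "normalized_inverted": True})


def hill_model(x, amplitude, kapp, n):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        xn = np.where(x > 0, x, 0.0) ** n
    return amplitude * xn / (kapp**n + xn)


def competition_hyperbolic_model(m, i0, iinf, kapp):
    return iinf + (i0 - iinf) * kapp / (kapp + np.asarray(m, dtype=float))


def _package(result, n_points: int, warnings: tuple[str, ...] = ()) -> FitResult:
    converged = bool(result.success)
    est = {p: float(result.params[p].value) for p in result.params}
    if converged:
        err = {
            p: float(result.params[p].stderr)
            for p in result.params
            if result.params[p].stderr is not None
        }
    else:
        err = {}
    return FitResult(
        estimates=est,
        stderr=err,
        residual_norm=float(np.linalg.norm(result.residual)),
        converged=converged,
        n_points=n_points,
        warnings=warnings,
    )


def _half_signal_titrant(curve: TitrationCurve) -> float:
    """Titrant value where the signal crosses mid-range; robust kapp seed."""
    s = curve.signal
    target = 0.5 * (s[0] + s[-1])
    idx = int(np.argmin(np.abs(s - target)))
    x = float(curve.titrant[idx])
    if x <= 0:
        positive = curve.titrant[curve.titrant > 0]
        x = float(positive[0]) if positive.size else 1.0
    return x


def fit_hill(curve: TitrationCurve, init: Mapping[str, float] | None = None,
             fix_n: float | None = None) -> FitResult:
    """Fit the Hill equation; returns kapp (midpoint), n and amplitude.

    ``fix_n`` clamps the Hill coefficient (``fix_n=1`` gives the
    rectangular hyperbola).  By default n floats.
    """
    if len(curve) < 5:
        raise ValueError("need >= 5 points for a Hill fit")
    init = dict(init or {})
    model = Model(hill_model)
    params = model.make_params(
        amplitude=init.get("amplitude", float(np.max(curve.signal))),
        kapp=init.get("kapp", _half_signal_titrant(curve)),
        n=init.get("n", 1.5),
    )
    params["kapp"].set(min=0.0)
    params["amplitude"].set(min=0.0)
    if fix_n is not None:
        params["n"].set(value=fix_n, vary=False)
    else:
        params["n"].set(min=0.1, max=10.0)
    result = model.fit(curve.signal, params, x=curve.titrant)
    return _package(result, len(curve))


def fit_competition_hyperbolic(curve: TitrationCurve) -> FitResult:
    """Fit the displacement hyperbola; returns kapp, i0 and iinf."""
    if len(curve) < 5:
        raise ValueError("need >= 5 points for a competition fit")
    warnings: tuple[str, ...] = ()
    if curve.signal[-1] > curve.signal[0]:
        warnings = ("signal increases overall; expected a displacement decay",)
    model = Model(competition_hyperbolic_model)
    params = model.make_params(
        i0=float(curve.signal[0]),
        iinf=float(curve.signal[-1]),
        kapp=_half_signal_titrant(curve),
    )
    params["kapp"].set(min=0.0)
    result = model.fit(curve.signal, params, m=curve.titrant)
    return _package(result, len(curve), warnings)


def fit_one_site(curve: TitrationCurve, probe_total: float) -> FitResult:
    """Fit the depletion-exact 1:1 isotherm; returns kd, r_free, r_bound."""
    if probe_total <= 0:
        raise ValueError("probe_total must be > 0")
    if len(curve) < 5:
        raise ValueError("need >= 5 points for a one-site fit")
    amplitude = float(curve.signal[-1] - curve.signal[0])
    warnings: tuple[str, ...] = ()
    if abs(amplitude) < 1e-12 * max(1.0, abs(float(curve.signal[0]))):
        warnings = ("r_free == r_bound: kd is unidentifiable",)

    def model_fn(L, kd, r_free, r_bound):
        frac = np.array([fraction_bound_quadratic(probe_total, li, kd) for li in np.asarray(L, float)])
        return r_free + (r_bound - r_free) * frac

    model = Model(model_fn)
    params = model.make_params(
        kd=_half_signal_titrant(curve),
        r_free=float(curve.signal[0]),
        r_bound=float(curve.signal[-1]),
    )
    params["kd"].set(min=1e-15)
    result = model.fit(curve.signal, params, L=curve.titrant)
    return _package(result, len(curve), warnings)


def melting_point_first_derivative(
    temperature: np.ndarray, signal: np.ndarray, window: int = 5
) -> float:
    """Melting temperature from the first derivative of a melting curve.

    The centered-difference derivative is smoothed with a moving average
    of half-width ``window`` points; Tm is the temperature of the
    derivative's interior extremum.  A curve without a transition (flat
    or purely linear) has no interior extremum and raises ``ValueError``.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(signal, dtype=float)
    if t.ndim != 1 or t.shape != s.shape:
        raise ValueError("temperature and signal must be 1-D of equal length")
    if t.size < 11:
        raise ValueError("need >= 11 points to locate a melting transition")
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperature must be strictly increasing")
    deriv = np.gradient(s, t)
    if window > 0:
        kernel = np.ones(2 * window + 1) / (2 * window + 1)
        deriv = np.convolve(deriv, kernel, mode="same")
    # smoothing edge effects live in the first/last window+1 points
    interior = slice(window + 1, t.size - window - 1)
    mag = np.abs(deriv[interior])
    spread = float(np.max(mag) - np.min(mag))
    if spread <= 1e-9 * max(1.0, float(np.max(mag))):
        raise ValueError("derivative has no extremum: no melting transition found")
    idx = int(np.argmax(mag)) + interior.start
    if idx <= 0 or idx >= t.size - 1:
        raise ValueError("derivative extremum at the grid edge: transition not bracketed")
    return float(t[idx])
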