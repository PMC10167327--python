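"""Thermal-stability analysis of nanoDSF melting curves.

The instrument reports intrinsic tryptophan fluorescence at 330 and 350 nm
over a temperature ramp; the F350/F330 ratio undergoes a sigmoidal
transition at unfolding. Tm is extracted either as the peak of the smoothed
first derivative of the ratio (the instrument convention) or as the
midpoint parameter of a two-state van 't Hoff sigmoid with linear pre- and
post-transition baselines:

    ratio(T) = (bn + mn*T + (bu + mu*T) * K(T)) / (1 + K(T)),
    K(T) = exp(dH/R * (1/Tm - 1/T))        (T in kelvin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from spxlab.io import MeltingCurve, ValidationError

__all__ = ["MeltResult", "NoTransitionError", "extract_tm", "delta_tm", "two_state_ratio"]

GAS_CONSTANT_KJ = 8.314462618e-3  # kJ mol^-1 K^-1


class NoTransitionError(ValidationError):
    """The curve shows no detectable unfolding transition."""


@dataclass(frozen=True)
class MeltResult:
    """Extracted melting temperature with method tag and uncertainty (°C)."""

    Tm: float
    method: str
    uncertainty: float = 0.0

    def __post_init__(self) -> None:
        if not (15.0 <= self.Tm <= 95.0):
            raise ValidationError(f"Tm {self.Tm:.2f} outside the 15-95 degC window")
        if self.method not in ("derivative", "two_state_fit"):
            raise ValidationError(f"unknown method {self.method!r}")


def two_state_ratio(T_c, tm_c, dh_kj, bn, mn, bu, mu):
    """Two-state F350/F330 ratio model over temperature in °C."""
    T = np.asarray(T_c, float) + 273.15
    tm = tm_c + 273.15
    with np.errstate(over="ignore"):
        k = np.exp(dh_kj / GAS_CONSTANT_KJ * (1.0 / tm - 1.0 / T))
    frac_u = k / (1.0 + k)
    native = bn + mn * np.asarray(T_c, float)
    unfolded = bu + mu * np.asarray(T_c, float)
    return native * (1 - frac_u) + unfolded * frac_u


def _odd_window(window: int, n: int, polyorder: int) -> int:
    window = max(window, polyorder + 2)
    window = min(window, n - 1 if n % 2 == 0 else n)
    if window % 2 == 0:
        window += 1
    return window


def _check_transition(t: np.ndarray, r: np.ndarray) -> None:
    """Reject curves whose smoothed amplitude is indistinguishable from noise."""
    big = _odd_window(max(len(t) // 6, 11), len(t), 3)
    smooth = savgol_filter(r, window_length=big, polyorder=3)
    sigma = float(np.std(r - smooth))
    amplitude = float(np.ptp(smooth))
    floor = 1e-9 * max(abs(float(np.mean(r))), 1e-12)
    if amplitude <= 5.0 * sigma + floor:
        raise NoTransitionError("no unfolding transition detected in the ratio curve")


def _derivative_tm(curve: MeltingCurve, window: int, polyorder: int = 3):
    t = np.asarray(curve.temperature, float)
    r = curve.ratio
    _check_transition(t, r)
    window = _odd_window(window, len(t), polyorder)
    dt = float(np.median(np.diff(t)))
    # coarse pass: heavily smoothed derivative localizes the transition,
    # so the fine pass cannot lock onto an isolated noise spike
    big = _odd_window(max(len(t) // 6, window), len(t), polyorder)
    dr_coarse = savgol_filter(r, window_length=big, polyorder=polyorder, deriv=1, delta=dt)
    t0 = t[big // 2 + int(np.argmax(dr_coarse[big // 2 : len(t) - big // 2]))]
    dr = savgol_filter(r, window_length=window, polyorder=polyorder, deriv=1, delta=dt)
    interior = np.zeros(len(t), bool)
    interior[window // 2 : len(t) - window // 2] = True
    interior &= np.abs(t - t0) <= 5.0
    d_int = dr[interior]
    t_int = t[interior]
    # quadratic peak fit over the transition neighborhood, anchored at the
    # coarse peak; averaging many points keeps single noise excursions from
    # displacing the estimate
    half = 5.0
    near = np.abs(t_int - t0) <= half
    tm = float(t_int[int(np.argmax(d_int))])
    if near.sum() >= 5:
        a2, a1, _ = np.polyfit(t_int[near] - t0, d_int[near], 2)
        if a2 < 0:
            tm = t0 + float(np.clip(-a1 / (2 * a2), -half, half))
    return float(tm), dt / 2.0


def _two_state_tm(curve: MeltingCurve):
    t = np.asarray(curve.temperature, float)
    r = curve.ratio
    try:
        tm0, _ = _derivative_tm(curve, window=9)
    except NoTransitionError:
        raise
    n_edge = max(len(t) // 10, 3)
    bn0 = float(np.mean(r[:n_edge]))
    bu0 = float(np.mean(r[-n_edge:]))
    if abs(bu0 - bn0) < 1e-9 * max(abs(bn0), 1.0):
        raise NoTransitionError("pre- and post-transition baselines coincide")
    p0 = [tm0, 400.0, bn0, 0.0, bu0, 0.0]
    popt, pcov = curve_fit(
        two_state_ratio,
        t,
        r,
        p0=p0,
        bounds=([15.0, 10.0, -np.inf, -np.inf, -np.inf, -np.inf],
                [95.0, 5000.0, np.inf, np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    err = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else 0.0
    return float(popt[0]), err


def extract_tm(
    curve: MeltingCurve, method: str = "derivative", window: int = 9
) -> MeltResult:
    """Extract the melting temperature from an F350/F330 ratio curve.

    ``derivative``: peak of the Savitzky-Golay-smoothed first derivative
    (window of 9 points by default), refined by parabolic interpolation.
    ``two_state_fit``: Tm parameter of the two-state sigmoid with linear
    baselines. Flat curves raise :class:`NoTransitionError`. The result is
    invariant to rescaling both channels by a common positive constant.
    """
    if method == "derivative":
        tm, unc = _derivative_tm(curve, window=window)
    elif method == "two_state_fit":
        tm, unc = _two_state_tm(curve)
    else:
        raise ValidationError(f"unknown Tm extraction method {method!r}")
    return MeltResult(Tm=tm, method=method, uncertainty=unc)


def delta_tm(result_a: MeltResult, result_b: MeltResult) -> tuple[float, float]:
    """Tm(b) - Tm(a) in °C with propagated uncertainty.

    Both results must come from the same extraction method, so systematic
    offsets of the method cancel in the difference.
    """
    if result_a.method != result_b.method:
        raise ValidationError(
            f"method mismatch: {result_a.method} vs {result_b.method}"
        )
    dt = result_b.Tm - result_a.Tm
    return float(dt), float(np.hypot(result_a.uncertainty, result_b.uncertainty))
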