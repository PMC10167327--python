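"""Backbone 15N relaxation: mono-exponential T1/T2 fitting and hetNOE ratios.

Peak intensities measured over a series of relaxation delays are fitted to
I(t) = I0 * exp(-R * t), giving the relaxation rate R (s^-1) and its
covariance-based standard error; the time constant T1 or T2 is 1/R.
Heteronuclear NOE values are the saturated/reference intensity ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from spxlab.io import RelaxationSeries, ValidationError

__all__ = ["RelaxationFit", "NonDecayingError", "fit_decay", "het_noe"]


class NonDecayingError(ValidationError):
    """Intensities do not decay; no physical relaxation rate exists."""


@dataclass(frozen=True)
class RelaxationFit:
    """Mono-exponential decay fit: rate (s^-1), amplitude and rate error."""

    rate: float
    I0: float
    rate_error: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValidationError("relaxation rate must be positive")
        if self.rate_error < 0:
            raise ValidationError("rate error must be non-negative")

    @property
    def time_constant(self) -> float:
        """T1 or T2 in seconds (1/rate)."""
        return 1.0 / self.rate


def fit_decay(series: RelaxationSeries) -> RelaxationFit:
    """Least-squares mono-exponential fit of a relaxation decay.

    Raises :class:`NonDecayingError` when the best-fitting rate is not
    positive (e.g. constant or rising intensities).
    """
    t = np.asarray(series.delays, float)
    y = np.asarray(series.intensities, float)

    # log-linear initialization from positive intensities
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        r0, i0 = -slope, float(np.exp(intercept))
    else:
        r0, i0 = 1.0, float(np.max(np.abs(y)) or 1.0)
    if r0 <= 0:
        raise NonDecayingError(
            f"residue {series.residue_index}: intensities do not decay"
        )

    def model(tv, i0v, rv):
        return i0v * np.exp(-rv * tv)

    popt, pcov = curve_fit(model, t, y, p0=[i0, r0], maxfev=10000)
    i0_fit, rate = popt
    if rate <= 0:
        raise NonDecayingError(
            f"residue {series.residue_index}: fitted rate {rate:.3g} s^-1 is not positive"
        )
    rate_err = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else 0.0
    return RelaxationFit(rate=float(rate), I0=float(i0_fit), rate_error=rate_err)


def het_noe(
    sat_intensity,
    ref_intensity,
    sat_error=None,
    ref_error=None,
):
    """Heteronuclear NOE ratio(s) sat/ref with optional error propagation.

    Accepts scalars or aligned arrays; zero reference intensities yield NaN
    with a warning instead of failing. Returns the ratio, or a
    (ratio, error) pair when intensity errors are supplied.
    """
    sat = np.asarray(sat_intensity, float)
    ref = np.asarray(ref_intensity, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ref != 0, sat / ref, np.nan)
    if np.any(ref == 0):
        warnings.warn("zero reference intensity; NaN returned for those residues")
    if sat_error is None and ref_error is None:
        return ratio if ratio.ndim else float(ratio)
    se = np.asarray(sat_error if sat_error is not None else 0.0, float)
    re = np.asarray(ref_error if ref_error is not None else 0.0, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        err = np.abs(ratio) * np.sqrt((se / sat) ** 2 + (re / ref) ** 2)
    if ratio.ndim:
        return ratio, err
    return float(ratio), float(err)
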