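"""Ligand-depletion binding isotherms for microscale thermophoresis (MST).

The 1:1 equilibrium P + L <-> PL with total labeled-protein concentration
[P]_t and total titrant concentration [L]_t has the exact bound-complex
solution of the mass-action quadratic,

    [PL] = (([P]_t + [L]_t + K_D) - sqrt(([P]_t + [L]_t + K_D)^2
            - 4 [P]_t [L]_t)) / 2,

valid even when [P]_t is not negligible against K_D (ligand depletion).
The observed thermophoresis signal is the fluorescence-weighted average of
the free- and bound-state levels,

    S_obs = ([P] eps_P alpha_P + [PL] eps_PL alpha_PL)
            / ([P] eps_P + [PL] eps_PL),

with [P] = [P]_t - [PL]; alpha are the Fnorm levels of the two states and
eps their relative fluorescence intensities.

Fitting exploits that, conditional on K_D (and the eps ratio), S_obs is
linear in (alpha_P, alpha_PL): the nonlinear search runs over log10 K_D only
(variable projection). The 95 % confidence interval on K_D comes from the
profile likelihood; a profile that does not close on the weak-binding side
is reported as a lower limit, mirroring how MST affinities of nearly
abolished interactions are quoted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import f as f_dist

from spxlab.io import InsufficientDataError, TitrationSeries, ValidationError

__all__ = [
    "BindingModel",
    "BindingFit",
    "FitNotConvergedError",
    "bound_complex",
    "observed_signal",
    "fit_kd",
    "affinity_fold_change",
]


class FitNotConvergedError(ValidationError):
    """The binding fit failed; diagnostics are in the message."""


def bound_complex(P_t, L_t, K_D):
    """Exact bound-complex concentration [PL] (µM) of the 1:1 equilibrium.

    Accepts scalars or arrays for ``L_t``. The result satisfies
    0 <= [PL] <= min(P_t, L_t) on the whole valid domain.
    """
    if P_t <= 0 or K_D <= 0:
        raise ValidationError("P_t and K_D must be positive")
    L = np.asarray(L_t, dtype=float)
    if np.any(L < 0):
        raise ValidationError("L_t must be non-negative")
    b = P_t + L + K_D
    disc = b * b - 4.0 * P_t * L
    pl = (b - np.sqrt(np.maximum(disc, 0.0))) / 2.0
    pl = np.clip(pl, 0.0, np.minimum(P_t, L))
    return pl if pl.ndim else float(pl)


@dataclass(frozen=True)
class BindingModel:
    """Forward model of one MST titration (concentrations in µM)."""

    P_t: float
    K_D: float
    alpha_P: float
    alpha_PL: float
    eps_P: float = 1.0
    eps_PL: float = 1.0

    def __post_init__(self) -> None:
        if self.P_t <= 0 or self.K_D <= 0:
            raise ValidationError("P_t and K_D must be positive")
        if self.eps_P <= 0 or self.eps_PL <= 0:
            raise ValidationError("fluorescence weights must be positive")


def observed_signal(model: BindingModel, L_t):
    """Fluorescence-weighted observed Fnorm signal at total ligand L_t.

    Bounded between min(alpha_P, alpha_PL) and max(alpha_P, alpha_PL);
    equals alpha_P at L_t = 0.
    """
    pl = bound_complex(model.P_t, L_t, model.K_D)
    p = model.P_t - pl
    num = p * model.eps_P * model.alpha_P + pl * model.eps_PL * model.alpha_PL
    den = p * model.eps_P + pl * model.eps_PL
    return num / den


@dataclass(frozen=True)
class BindingFit:
    """Result of an MST K_D fit.

    ``lower_limit`` marks an open weak-binding profile: the point estimate
    is unreliable and the affinity should be quoted as K_D > ci95[0].
    """

    K_D: float
    ci95: tuple[float, float]
    alpha_P: float
    alpha_PL: float
    eps_ratio: float
    residuals: np.ndarray
    mode: str
    lower_limit: bool = False
    weak_binding: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not self.lower_limit and not (lo <= self.K_D <= hi):
            raise ValidationError("CI95 must bracket the point estimate")

    def describe(self) -> str:
        if self.lower_limit:
            return f"K_D > {self.ci95[0]:.3g} µM (lower limit)"
        return f"K_D = {self.K_D:.3g} µM ({self.ci95[0]:.3g}-{self.ci95[1]:.3g})"


def _linear_signal_fit(L, y, P_t, kd, eps_ratio):
    """RSS and (alpha_P, alpha_PL) minimizing the residuals at fixed K_D."""
    pl = bound_complex(P_t, L, kd)
    p = P_t - pl
    den = p + pl * eps_ratio
    w = p / den  # fluorescence-weighted fraction of the free-state signal
    X = np.column_stack([w, 1.0 - w])
    coef, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef, resid


def fit_kd(
    series: TitrationSeries,
    P_t: float,
    mode: str = "fnorm",
    fluorescence_series: TitrationSeries | None = None,
    eps_ratio: float | None = None,
    kd_bounds: tuple[float, float] | None = None,
) -> BindingFit:
    """Fit the ligand-depletion isotherm to one MST titration.

    Parameters
    ----------
    series:
        Titration (total titrant concentration µM vs. Fnorm observable).
    P_t:
        Total labeled protein concentration (µM); ~0.2 µM in a standard
        RED-tris-NTA labeling.
    mode:
        ``fnorm`` fits the raw thermophoresis signal; ``delta_fnorm``
        subtracts a per-replicate baseline (the lowest-concentration point)
        before fitting; ``global_fnorm_plus_fluorescence`` co-fits an
        initial-fluorescence-intensity titration sharing K_D, with the eps
        parameters estimated from the fluorescence data.
    eps_ratio:
        Fixed eps_PL / eps_P when known from fluorescence intensities;
        defaults to 1 in the non-global modes.
    """
    if mode not in ("fnorm", "delta_fnorm", "global_fnorm_plus_fluorescence"):
        raise ValidationError(f"unknown fit mode {mode!r}")
    if P_t <= 0:
        raise ValidationError("P_t must be positive")
    if series.concentrations.size < 6:
        raise InsufficientDataError("need >= 6 concentrations for a K_D fit")

    if mode == "delta_fnorm":
        obs = np.asarray(series.observable, float).copy()
        base = obs[0, :]  # per-replicate baseline at the lowest concentration
        obs = obs - base[None, :]
        series = TitrationSeries(
            series.concentrations, obs, series.replicate_ids, label=series.label
        )

    L, y = series.flat()
    n = len(y)
    if mode == "global_fnorm_plus_fluorescence":
        if fluorescence_series is None:
            raise ValidationError("global mode requires a fluorescence_series")
        Lf, yf = fluorescence_series.flat()
        scale_t = np.ptp(y) or 1.0
        scale_f = np.ptp(yf) or 1.0
        n_param = 5  # K_D, alpha_P, alpha_PL, eps_P-level, eps_PL-level
    else:
        ratio = 1.0 if eps_ratio is None else float(eps_ratio)
        n_param = 3

    lmax = float(series.concentrations[-1])
    lo_k = kd_bounds[0] if kd_bounds else 1e-6 * max(lmax, 1.0)
    hi_k = kd_bounds[1] if kd_bounds else 1e4 * lmax

    def rss_of(logk: float) -> float:
        kd = 10.0**logk
        if mode != "global_fnorm_plus_fluorescence":
            rss, _, _ = _linear_signal_fit(L, y, P_t, kd, ratio)
            return rss
        # fluorescence: F = eps_P*[P] + eps_PL*[PL], linear in the eps levels
        plf = bound_complex(P_t, Lf, kd)
        Xf = np.column_stack([P_t - plf, plf])
        coef_f, *_ = np.linalg.lstsq(Xf, yf, rcond=None)
        rf = yf - Xf @ coef_f
        eps_r = abs(coef_f[1] / coef_f[0]) if coef_f[0] != 0 else 1.0
        rss_t, _, _ = _linear_signal_fit(L, y, P_t, kd, eps_r)
        return rss_t / scale_t**2 + float(rf @ rf) / scale_f**2

    # coarse grid then local refinement on log10 K_D
    grid = np.linspace(np.log10(lo_k), np.log10(hi_k), 121)
    rss_grid = np.array([rss_of(g) for g in grid])
    g0 = grid[int(np.argmin(rss_grid))]
    res = minimize_scalar(
        rss_of,
        bounds=(max(g0 - 1.0, grid[0]), min(g0 + 1.0, grid[-1])),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise FitNotConvergedError(f"K_D search failed: {res.message}")
    logk_hat = float(res.x)
    kd_hat = 10.0**logk_hat
    rss_min = float(res.fun)

    # recover linear parameters at the optimum
    if mode == "global_fnorm_plus_fluorescence":
        plf = bound_complex(P_t, Lf, kd_hat)
        Xf = np.column_stack([P_t - plf, plf])
        coef_f, *_ = np.linalg.lstsq(Xf, yf, rcond=None)
        ratio = abs(float(coef_f[1] / coef_f[0])) if coef_f[0] != 0 else 1.0
    _, coef, resid = _linear_signal_fit(L, y, P_t, kd_hat, ratio)
    alpha_p, alpha_pl = float(coef[0]), float(coef[1])

    # profile-likelihood CI via the F-statistic threshold on the RSS profile
    dof = max(n - n_param, 1)
    f_crit = f_dist.ppf(0.95, 1, dof)
    thr = rss_min * (1.0 + f_crit / dof)

    def g(logk: float) -> float:
        return rss_of(logk) - thr

    log_lo, log_hi = np.log10(lo_k), np.log10(hi_k)
    ci_lo_log = log_lo
    if g(log_lo) > 0:
        ci_lo_log = brentq(g, log_lo, logk_hat, xtol=1e-8)
    lower_limit = False
    if g(log_hi) > 0:
        ci_hi_log = brentq(g, logk_hat, log_hi, xtol=1e-8)
    else:
        ci_hi_log = log_hi
        lower_limit = True  # the profile never closes on the weak side

    saturation = bound_complex(P_t, lmax, kd_hat) / P_t
    weak = bool(saturation < 0.2)
    if weak:
        warnings.warn(
            f"saturation at the top concentration is only {saturation:.1%}; "
            "the confidence interval is likely open (weak binding)"
        )

    return BindingFit(
        K_D=kd_hat,
        ci95=(10.0**ci_lo_log, 10.0**ci_hi_log),
        alpha_P=alpha_p,
        alpha_PL=alpha_pl,
        eps_ratio=float(ratio),
        residuals=resid,
        mode=mode,
        lower_limit=lower_limit,
        weak_binding=weak,
    )


@dataclass(frozen=True)
class FoldChange:
    """Affinity ratio K_D(condition)/K_D(reference) with propagated CI."""

    fold: float
    ci95: tuple[float, float]
    is_lower_bound: bool = False

    def describe(self) -> str:
        if self.is_lower_bound:
            return f"> {self.fold:.3g}-fold"
        return f"{self.fold:.3g}-fold ({self.ci95[0]:.3g}-{self.ci95[1]:.3g})"


def affinity_fold_change(fit_ref: BindingFit, fit_cond: BindingFit) -> FoldChange:
    """Fold-reduction of affinity between two fits (K_D cond / K_D ref).

    A lower-limit condition fit propagates to a ``> fold`` bound computed
    from its profile lower bound; a lower-limit reference is an error
    (the ratio would be undefined).
    """
    if fit_ref.lower_limit:
        raise ValidationError("reference fit is a lower limit; fold change undefined")
    if fit_cond.lower_limit:
        return FoldChange(
            fold=fit_cond.ci95[0] / fit_ref.K_D,
            ci95=(fit_cond.ci95[0] / fit_ref.K_D, np.inf),
            is_lower_bound=True,
        )
    fold = fit_cond.K_D / fit_ref.K_D
    # propagate on the log scale from the (possibly asymmetric) CI widths
    se_log_ref = (np.log(fit_ref.ci95[1]) - np.log(fit_ref.ci95[0])) / (2 * 1.959964)
    se_log_cond = (np.log(fit_cond.ci95[1]) - np.log(fit_cond.ci95[0])) / (2 * 1.959964)
    se_log = float(np.hypot(se_log_ref, se_log_cond))
    return FoldChange(
        fold=float(fold),
        ci95=(float(fold * np.exp(-1.959964 * se_log)), float(fold * np.exp(1.959964 * se_log))),
    )
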