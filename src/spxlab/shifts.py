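"""Chemical-shift analytics: secondary shifts, helices, CSP, titrations, H/D.

Secondary chemical shifts (SS) are the helix-sensitive combination

    SS(i) = [dCa(i) - rc_Ca(aa) - iso_Ca(aa)] - [dCb(i) - rc_Cb(aa) - iso_Cb(aa)]

where rc are random-coil reference shifts and iso the per-residue-type
deuterium isotope corrections, applied only for perdeuterated samples.
Glycine carries no Cb and uses the Ca term alone. Contiguous stretches of
positive SS mark alpha-helices; the mean SS relative to a full-helix
reference value (3.1 ppm by default) estimates the fractional helical
population ("propensity").

Chemical shift perturbations between two states use the standard combined
amide metric with the 15N dimension scaled down by 5:

    ddelta = sqrt((dH_ref - dH)^2 + (dN_ref/5 - dN/5)^2)

and are classified low/medium/high against mu + 0.2/0.8/1.5 sigma of the
observed perturbation distribution (sample standard deviation).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import t as student_t

from spxlab.io import (
    InsufficientDataError,
    ShiftTable,
    TitrationSeries,
    ValidationError,
)

__all__ = [
    "SS_FULLHELIX_PPM",
    "load_reference_table",
    "random_coil_table",
    "isotope_correction_table",
    "SecondaryShiftProfile",
    "HelixSegment",
    "CspProfile",
    "LangmuirFit",
    "secondary_shifts",
    "detect_helices",
    "compute_csp",
    "classify_csp",
    "fit_langmuir",
    "hd_protection",
]

#: SS value (ppm) assigned to a fully formed alpha-helix when converting mean
#: secondary shifts into fractional helical propensity.
SS_FULLHELIX_PPM = 3.1


def load_reference_table(path) -> dict[str, tuple[float, float | None]]:
    """Load an ``aa<TAB>Ca[<TAB>Cb]`` per-residue reference table."""
    table: dict[str, tuple[float, float | None]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split("\t")
            aa = toks[0]
            ca = float(toks[1])
            cb = float(toks[2]) if len(toks) > 2 and toks[2] != "" else None
            table[aa] = (ca, cb)
    return table


def _data_path(name: str):
    return importlib.resources.files("spxlab.data").joinpath(name)


def random_coil_table() -> dict[str, tuple[float, float | None]]:
    """Default random-coil Ca/Cb reference shifts (ppm)."""
    return load_reference_table(_data_path("random_coil_ca_cb.tsv"))


def isotope_correction_table() -> dict[str, tuple[float, float | None]]:
    """Default perdeuteration 2H isotope corrections for Ca/Cb (ppm)."""
    return load_reference_table(_data_path("deuterium_isotope_corrections.tsv"))


@dataclass(frozen=True)
class SecondaryShiftProfile:
    """Per-residue secondary shifts with bookkeeping of contributing nuclei."""

    residue_index: np.ndarray
    ss: np.ndarray
    used_cb: np.ndarray  # False where only the Ca term contributed (glycine, missing Cb)

    def __len__(self) -> int:
        return len(self.residue_index)

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.residue_index.tolist(), self.ss.tolist()))


@dataclass(frozen=True)
class HelixSegment:
    """An alpha-helical segment with its mean fractional helical population."""

    start: int
    end: int
    mean_propensity: float

    def __post_init__(self) -> None:
        if self.end < self.start + 3:
            raise ValidationError("helix segment must span at least one helical turn")
        if not (0.0 <= self.mean_propensity <= 1.0):
            raise ValidationError("propensity must lie in [0, 1]")


@dataclass(frozen=True)
class CspProfile:
    """Per-residue chemical shift perturbations with status and class labels.

    ``status`` is one of value / intermediate_exchange / unassigned;
    ``classification`` one of none / low / medium / high (assigned only by
    :func:`classify_csp`, only where a value exists).
    """

    residue_index: np.ndarray
    delta: np.ndarray  # NaN where no value
    status: tuple[str, ...]
    classification: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        d = np.asarray(self.delta)
        if np.any(d[np.isfinite(d)] < 0):
            raise ValidationError("CSP values must be non-negative")

    def values(self) -> np.ndarray:
        mask = np.array([s == "value" for s in self.status])
        return np.asarray(self.delta)[mask]


@dataclass(frozen=True)
class LangmuirFit:
    """Langmuir isotherm fit of an NMR titration: ddelta(L) = ddmax*L/(L+K_D)."""

    K_D: float
    ddmax: float
    K_D_ci95: tuple[float, float]
    residuals: np.ndarray
    at_bound: str | None = None  # 'lower'/'upper' if K_D pinned at a bound


# ---------------------------------------------------------------------------
# Secondary shifts & helices
# ---------------------------------------------------------------------------


def secondary_shifts(
    table: ShiftTable,
    rc_table: dict[str, tuple[float, float | None]] | None = None,
    isotope_corrections: dict[str, tuple[float, float | None]] | None = None,
) -> SecondaryShiftProfile:
    """Compute per-residue secondary chemical shifts from Ca/Cb.

    Isotope corrections are applied only when the table's ``isotope_scheme``
    is perdeuterated. Residues without a Ca shift are omitted.
    """
    rc = rc_table if rc_table is not None else random_coil_table()
    iso = isotope_corrections if isotope_corrections is not None else isotope_correction_table()
    apply_iso = table.isotope_scheme == "perdeuterated"

    idx, ss, used_cb = [], [], []
    for rec in table:
        if rec.dCa is None:
            continue
        if rec.aa not in rc:
            raise ValidationError(f"residue type {rec.aa!r} missing from random-coil table")
        if apply_iso and rec.aa not in iso:
            raise ValidationError(f"residue type {rec.aa!r} missing from isotope table")
        rc_ca, rc_cb = rc[rec.aa]
        iso_ca, iso_cb = iso[rec.aa] if apply_iso else (0.0, 0.0)
        d_ca = rec.dCa - rc_ca - (iso_ca or 0.0)
        if rec.aa != "G" and rec.dCb is not None and rc_cb is not None:
            d_cb = rec.dCb - rc_cb - ((iso_cb or 0.0) if apply_iso else 0.0)
            ss.append(d_ca - d_cb)
            used_cb.append(True)
        else:
            ss.append(d_ca)
            used_cb.append(False)
        idx.append(rec.residue_index)
    if not idx:
        raise ValidationError("no residue carries a Ca shift")
    return SecondaryShiftProfile(
        np.asarray(idx, int), np.asarray(ss, float), np.asarray(used_cb, bool)
    )


def detect_helices(
    profile: SecondaryShiftProfile,
    threshold_ppm: float = 0.7,
    min_len: int = 4,
    ss_fullhelix: float = SS_FULLHELIX_PPM,
    max_gap: int = 1,
) -> list[HelixSegment]:
    """Find maximal helical runs of SS above threshold.

    A run may bridge at most ``max_gap`` consecutive interior residues that
    fall below threshold (or are unobserved); runs shorter than ``min_len``
    observed helical residues are discarded. Each segment's propensity is
    its mean SS divided by the full-helix reference, clamped to [0, 1].
    """
    if len(profile) == 0:
        raise ValidationError("empty secondary-shift profile")
    above = {
        int(i): float(s)
        for i, s in zip(profile.residue_index, profile.ss)
        if s > threshold_ppm
    }
    if not above:
        return []
    ss_map = profile.as_dict()
    keys = sorted(above)
    segments: list[tuple[int, int]] = []
    start = prev = keys[0]
    for k in keys[1:]:
        if k - prev - 1 <= max_gap:
            prev = k
        else:
            segments.append((start, prev))
            start = prev = k
    segments.append((start, prev))

    out = []
    for s, e in segments:
        n_above = sum(1 for i in range(s, e + 1) if i in above)
        if n_above < min_len or e < s + 3:
            continue
        vals = [ss_map[i] for i in range(s, e + 1) if i in ss_map]
        prop = float(np.clip(np.mean(vals) / ss_fullhelix, 0.0, 1.0))
        out.append(HelixSegment(s, e, prop))
    return out


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------

#: Scaling divisor applied to the 15N dimension in the combined CSP metric.
N15_SCALE = 5.0


def compute_csp(
    ref: ShiftTable,
    perturbed: ShiftTable,
    broadened: set[int] | frozenset[int] = frozenset(),
) -> CspProfile:
    """Combined 1H/15N chemical shift perturbation between two states.

    Residues listed in ``broadened`` (peaks lost to intermediate exchange —
    a spectroscopist's call, supplied as input) are marked rather than
    computed; residues absent from either table are marked unassigned.
    """
    a = ref.by_residue()
    b = perturbed.by_residue()
    all_idx = sorted(set(a) | set(b) | set(broadened))
    idx, delta, status = [], [], []
    n_shared = 0
    for i in all_idx:
        idx.append(i)
        if i in broadened:
            delta.append(np.nan)
            status.append("intermediate_exchange")
            continue
        ra, rb = a.get(i), b.get(i)
        if (
            ra is None
            or rb is None
            or ra.dH is None
            or ra.dN is None
            or rb.dH is None
            or rb.dN is None
        ):
            delta.append(np.nan)
            status.append("unassigned")
            continue
        dd = float(
            np.sqrt((ra.dH - rb.dH) ** 2 + (ra.dN / N15_SCALE - rb.dN / N15_SCALE) ** 2)
        )
        delta.append(dd)
        status.append("value")
        n_shared += 1
    if n_shared == 0:
        raise ValidationError("the two states share no residue with 1H and 15N shifts")
    return CspProfile(
        np.asarray(idx, int),
        np.asarray(delta, float),
        tuple(status),
        tuple("none" for _ in idx),
    )


def classify_csp(profile: CspProfile) -> CspProfile:
    """Label perturbations low/medium/high against mu + 0.2/0.8/1.5 sigma.

    mu and sigma (sample standard deviation, ddof=1) are computed over the
    residues carrying a value; the highest exceeded tier wins. A degenerate
    distribution (sigma = 0) yields no classifications.
    """
    vals = profile.values()
    if vals.size < 3:
        raise InsufficientDataError("need >= 3 residues with CSP values to classify")
    mu = float(np.mean(vals))
    sigma = float(np.std(vals, ddof=1))
    labels = []
    for s, d in zip(profile.status, profile.delta):
        if s != "value" or sigma == 0.0:
            labels.append("none")
        elif d > mu + 1.5 * sigma:
            labels.append("high")
        elif d > mu + 0.8 * sigma:
            labels.append("medium")
        elif d > mu + 0.2 * sigma:
            labels.append("low")
        else:
            labels.append("none")
    return CspProfile(profile.residue_index, profile.delta, profile.status, tuple(labels))


# ---------------------------------------------------------------------------
# Langmuir titration fit
# ---------------------------------------------------------------------------


def fit_langmuir(series: TitrationSeries) -> LangmuirFit:
    """Least-squares fit of a Langmuir isotherm to an NMR titration.

    The observable is the per-point CSP (ppm); the 95 % interval on K_D is
    covariance-based with a Student-t quantile.
    """
    L, y = series.flat()
    if np.unique(L).size < 4:
        raise InsufficientDataError("need >= 4 distinct concentrations")

    def model(Lv, kd, ddmax):
        return ddmax * Lv / (Lv + kd)

    kd0 = max(np.median(L[L > 0]), 1e-6)
    dd0 = max(np.max(np.abs(y)), 1e-9)
    lower, upper = [1e-9, -np.inf], [1e9, np.inf]
    try:
        popt, pcov = curve_fit(
            model, L, y, p0=[kd0, dd0], bounds=(lower, upper), maxfev=10000
        )
    except RuntimeError as exc:
        raise SpxlabFitError(f"Langmuir fit did not converge: {exc}") from exc
    kd, ddmax = popt
    resid = y - model(L, *popt)
    dof = max(len(y) - 2, 1)
    tq = student_t.ppf(0.975, dof)
    kd_err = float(np.sqrt(pcov[0, 0]))
    at_bound = None
    if kd <= lower[0] * 1.01:
        at_bound = "lower"
    elif kd >= upper[0] * 0.99:
        at_bound = "upper"
    return LangmuirFit(
        K_D=float(kd),
        ddmax=float(ddmax),
        K_D_ci95=(float(kd - tq * kd_err), float(kd + tq * kd_err)),
        residuals=resid,
        at_bound=at_bound,
    )


class SpxlabFitError(ValidationError):
    """A nonlinear fit failed to converge (diagnostics in the message)."""


# ---------------------------------------------------------------------------
# H/D protection
# ---------------------------------------------------------------------------


def hd_protection(h2o: ShiftTable, d2o: ShiftTable) -> dict[int, float]:
    """Per-residue H/D exchange protection from amide peak intensities.

    ratio(i) = I_D2O(i) / I_H2O(i). Residues whose peak has vanished in
    D2O count as fully exchanged (ratio 0); residues with zero or missing
    H2O intensity are skipped with a warning.
    """
    ih = {r.residue_index: r.intensity for r in h2o if r.intensity is not None}
    id_ = {r.residue_index: r.intensity for r in d2o if r.intensity is not None}
    if not ih:
        raise ValidationError("H2O table carries no intensities")
    out: dict[int, float] = {}
    for i, inten in ih.items():
        if inten == 0:
            warnings.warn(f"residue {i}: zero H2O intensity; skipped")
            continue
        out[i] = id_.get(i, 0.0) / inten
    return out
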