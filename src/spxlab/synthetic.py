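"""Seeded synthetic-data generators: exact forward models of every analysis.

Each generator draws from the same forward model its consuming analysis
fits, so zero-noise round-trips invert exactly and noisy round-trips are
unbiased up to Monte-Carlo error. All randomness flows from the single seed
of a :class:`SimSpec` through a fixed per-generator substream, so an
identical spec yields bit-identical output.

Default noise levels (2 % of signal range for MST titrations, 1 % per
fluorescence channel for melting curves, 3 % of the initial intensity for
relaxation decays, 1 Hz for RDCs) are package conventions chosen to emulate
well-behaved instrument data; they are fields of the spec, not claims about
any particular instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from spxlab import binding, stability
from spxlab.io import (
    DomainRecord,
    MeltingCurve,
    RelaxationSeries,
    ShiftRecord,
    ShiftTable,
    TitrationSeries,
    ValidationError,
)
from spxlab.motif import ALPHABET
from spxlab.rdc import AlignmentTensor, RdcSet
from spxlab.shifts import SS_FULLHELIX_PPM, random_coil_table

__all__ = [
    "SimSpec",
    "sim_shift_tables",
    "sim_titration",
    "sim_melt",
    "sim_decay",
    "sim_rdc",
    "sim_unit_vectors",
    "sim_proteome",
]

# fixed substream ids so generators never share a random stream
_STREAM = {
    "shift": 1,
    "titration": 2,
    "melt": 3,
    "decay": 4,
    "rdc": 5,
    "vectors": 6,
    "proteome": 7,
}


@dataclass(frozen=True)
class SimSpec:
    """Seed and noise model shared by all generators.

    Fractional noise values are Gaussian standard deviations relative to the
    stated scale of each generator; ``rdc_noise_hz`` is absolute.
    """

    seed: int
    mst_noise_frac: float = 0.02  # of |alpha_PL - alpha_P|
    dsf_noise_frac: float = 0.01  # of each fluorescence channel value
    relax_noise_frac: float = 0.03  # of the initial intensity
    rdc_noise_hz: float = 1.0
    shift_noise_ppm: float = 0.0

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAM[stream]])

    def with_seed(self, seed: int) -> "SimSpec":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# Chemical-shift tables
# ---------------------------------------------------------------------------


def sim_shift_tables(
    spec: SimSpec,
    helix_layout: list[tuple[int, int, float]],
    n_residues: int = 201,
    pocket_residues: dict[int, float] | None = None,
    ss_fullhelix: float = SS_FULLHELIX_PPM,
) -> tuple[ShiftTable, ShiftTable]:
    """Reference and perturbed shift tables with planted helices.

    ``helix_layout`` lists (start, end, propensity) segments; within them the
    secondary shift is propensity * ss_fullhelix (plus optional noise), split
    symmetrically between the Ca and Cb deviations. ``pocket_residues`` maps
    residue index -> amide CSP magnitude (ppm) planted in the perturbed
    table (applied to the 1H dimension, so the combined CSP equals it).
    """
    rng = spec.rng("shift")
    spans = sorted((s, e) for s, e, _ in helix_layout)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValidationError(f"overlapping helices [{s1},{e1}] and [{s2},{e2}]")
    for s, e, p in helix_layout:
        if not (1 <= s <= e <= n_residues):
            raise ValidationError(f"helix [{s},{e}] outside 1..{n_residues}")
        if not (0.0 <= p <= 1.0):
            raise ValidationError("helix propensity must lie in [0, 1]")

    rc = random_coil_table()
    # helix interiors avoid G (no Cb) and P (no amide); elsewhere anything goes
    non_gp = [a for a in ALPHABET if a not in "GP"]
    seq = rng.choice(list(ALPHABET), size=n_residues)
    ss_truth = np.zeros(n_residues + 1)
    for s, e, p in helix_layout:
        ss_truth[s : e + 1] = p * ss_fullhelix
        seq[s - 1 : e] = rng.choice(non_gp, size=e - s + 1)

    pocket = pocket_residues or {}

    def make(perturbed: bool) -> ShiftTable:
        records = []
        for i in range(1, n_residues + 1):
            aa = str(seq[i - 1])
            if aa == "P":  # no amide proton; unassigned in HN-detected spectra
                continue
            rc_ca, rc_cb = rc[aa]
            ss = ss_truth[i] + (
                rng.normal(0.0, spec.shift_noise_ppm) if spec.shift_noise_ppm else 0.0
            )
            dH = 8.3 + 0.3 * np.sin(0.7 * i)
            dN = 118.0 + 6.0 * np.cos(0.3 * i)
            if perturbed and i in pocket:
                dH = dH + pocket[i]
            if aa == "G":
                records.append(
                    ShiftRecord(i, aa, dH=dH, dN=dN, dCa=rc_ca + ss, intensity=1.0)
                )
            else:
                records.append(
                    ShiftRecord(
                        i,
                        aa,
                        dH=dH,
                        dN=dN,
                        dCa=rc_ca + ss / 2.0,
                        dCb=rc_cb - ss / 2.0,
                        intensity=1.0,
                    )
                )
        return ShiftTable.from_records(
            records,
            sample_label="perturbed" if perturbed else "reference",
            isotope_scheme="protonated",
        )

    return make(False), make(True)


# ---------------------------------------------------------------------------
# MST titrations
# ---------------------------------------------------------------------------


def serial_dilution(top_uM: float, n_points: int, dilution: float = 2.0) -> np.ndarray:
    """Descending serial dilution from ``top_uM``, returned ascending."""
    conc = top_uM / dilution ** np.arange(n_points)
    return np.sort(conc)


def sim_titration(
    spec: SimSpec,
    K_D: float,
    P_t: float = 0.2,
    alpha_P: float = 800.0,
    alpha_PL: float = 900.0,
    eps_ratio: float = 1.0,
    n_points: int = 16,
    dilution: float = 2.0,
    replicates: int = 3,
    top_uM: float = 1000.0,
    label: str = "",
) -> TitrationSeries:
    """Simulate an MST titration from the ligand-depletion forward model.

    Concentrations follow a 1:1 serial dilution from ``top_uM``; Gaussian
    noise has sd ``mst_noise_frac * |alpha_PL - alpha_P|``.
    """
    if min(K_D, P_t, eps_ratio) <= 0 or replicates < 1:
        raise ValidationError("K_D, P_t, eps_ratio must be positive; replicates >= 1")
    rng = spec.rng("titration")
    conc = serial_dilution(top_uM, n_points, dilution)
    model = binding.BindingModel(
        P_t=P_t, K_D=K_D, alpha_P=alpha_P, alpha_PL=alpha_PL, eps_P=1.0, eps_PL=eps_ratio
    )
    clean = binding.observed_signal(model, conc)
    sd = spec.mst_noise_frac * abs(alpha_PL - alpha_P)
    obs = clean[:, None] + rng.normal(0.0, sd, size=(n_points, replicates)) if sd else (
        np.repeat(clean[:, None], replicates, axis=1)
    )
    reps = tuple(f"r{j + 1}" for j in range(replicates))
    return TitrationSeries(conc, np.asarray(obs, float), reps, label=label)


def sim_fluorescence_titration(
    spec: SimSpec,
    K_D: float,
    P_t: float = 0.2,
    eps_P: float = 1000.0,
    eps_PL: float = 1400.0,
    n_points: int = 16,
    dilution: float = 2.0,
    replicates: int = 3,
    top_uM: float = 1000.0,
) -> TitrationSeries:
    """Initial-fluorescence titration (companion observable for global fits)."""
    rng = spec.rng("titration")
    conc = serial_dilution(top_uM, n_points, dilution)
    pl = binding.bound_complex(P_t, conc, K_D)
    clean = eps_P * (P_t - pl) + eps_PL * pl
    sd = spec.mst_noise_frac * float(np.ptp(clean) or 1.0)
    obs = clean[:, None] + rng.normal(0.0, sd, size=(n_points, replicates))
    reps = tuple(f"r{j + 1}" for j in range(replicates))
    return TitrationSeries(conc, obs, reps, label="fluorescence")


# ---------------------------------------------------------------------------
# Melting curves
# ---------------------------------------------------------------------------


def sim_melt(
    spec: SimSpec,
    Tm: float,
    amplitude: float = 0.3,
    baseline: float = 0.85,
    baseline_slopes: tuple[float, float] = (0.0, 0.0),
    dh_kj: float = 450.0,
    t_min: float = 15.0,
    t_max: float = 95.0,
    t_step: float = 0.25,
    f330_level: float = 1000.0,
    capillary_id: str = "",
) -> MeltingCurve:
    """Two-state nanoDSF ratio curve with per-channel Gaussian noise.

    The noiseless F350/F330 ratio follows the van 't Hoff two-state model
    with native level ``baseline`` and unfolded level ``baseline +
    amplitude``; each channel receives fractional noise ``dsf_noise_frac``.
    """
    if not (t_min < Tm < t_max):
        raise ValidationError(f"Tm {Tm} outside the simulated ramp {t_min}-{t_max}")
    if amplitude == 0:
        raise ValidationError("amplitude must be nonzero")
    rng = spec.rng("melt")
    t = np.arange(t_min, t_max + t_step / 2, t_step)
    ratio = stability.two_state_ratio(
        t, Tm, dh_kj, baseline, baseline_slopes[0], baseline + amplitude, baseline_slopes[1]
    )
    f330 = np.full_like(t, f330_level)
    f350 = ratio * f330
    if spec.dsf_noise_frac:
        f330 = f330 * (1.0 + rng.normal(0.0, spec.dsf_noise_frac, size=t.size))
        f350 = f350 * (1.0 + rng.normal(0.0, spec.dsf_noise_frac, size=t.size))
    return MeltingCurve(t, f330, f350, capillary_id=capillary_id)


# ---------------------------------------------------------------------------
# Relaxation decays
# ---------------------------------------------------------------------------

#: The T2 and T1 delay grids used for backbone 15N relaxation (seconds).
T2_DELAYS_S = np.arange(0.0, 0.119 + 1e-9, 0.017)
T1_DELAYS_S = np.arange(0.0, 1.120 + 1e-9, 0.160)


def sim_decay(
    spec: SimSpec,
    rate: float,
    delays: np.ndarray | None = None,
    i0: float = 1.0,
    residue_index: int = 1,
    experiment: str = "T2",
) -> RelaxationSeries:
    """Mono-exponential decay I(t) = I0 exp(-rate t) with Gaussian noise."""
    if rate <= 0 or i0 <= 0:
        raise ValidationError("rate and I0 must be positive")
    if delays is None:
        delays = T2_DELAYS_S if experiment == "T2" else T1_DELAYS_S
    rng = spec.rng("decay")
    t = np.asarray(delays, float)
    y = i0 * np.exp(-rate * t)
    if spec.relax_noise_frac:
        y = y + rng.normal(0.0, spec.relax_noise_frac * i0, size=t.size)
    return RelaxationSeries(residue_index, t, y, experiment=experiment)


# ---------------------------------------------------------------------------
# RDC sets
# ---------------------------------------------------------------------------


def sim_unit_vectors(spec: SimSpec, n: int, start_residue: int = 1) -> dict[int, np.ndarray]:
    """Isotropically distributed unit N-H vectors keyed by residue index."""
    rng = spec.rng("vectors")
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return {start_residue + i: v[i] for i in range(n)}


def sim_rdc(
    spec: SimSpec,
    tensor: AlignmentTensor,
    vectors: dict[int, np.ndarray],
    j_iso_hz: float = 93.0,
) -> RdcSet:
    """Couplings generated from a known alignment tensor plus Gaussian noise."""
    from spxlab.rdc import back_calculate

    rng = spec.rng("rdc")
    idx = sorted(vectors)
    d = back_calculate(tensor, {i: vectors[i] for i in idx})
    noise = (
        rng.normal(0.0, spec.rdc_noise_hz, size=len(idx))
        if spec.rdc_noise_hz
        else np.zeros(len(idx))
    )
    j_iso = np.full(len(idx), float(j_iso_hz))
    j_aligned = j_iso + np.array([d[i] for i in idx]) + noise
    return RdcSet(np.asarray(idx, int), j_iso, j_aligned)


# ---------------------------------------------------------------------------
# Proteomes with planted motifs
# ---------------------------------------------------------------------------


def sim_proteome(
    spec: SimSpec,
    n_with_motif: int,
    n_without: int,
    motif: str,
    identity: float = 0.8,
    spx_len: int = 150,
    linker_len: int = 60,
    next_domain_len: int = 120,
) -> tuple[list[DomainRecord], dict[str, int]]:
    """Synthetic SPX proteins with (or without) a planted linker motif.

    Positive proteins carry one degenerate copy of ``motif`` (each position
    kept with probability ``identity``, otherwise substituted) at a random
    position in the interdomain linker. Returns the records and the planted
    1-based linker positions keyed by protein id.
    """
    if not (0.0 < identity <= 1.0):
        raise ValidationError("identity must lie in (0, 1]")
    if linker_len < len(motif):
        raise ValidationError("linker shorter than the motif")
    rng = spec.rng("proteome")
    letters = np.array(list(ALPHABET))

    def random_seq(n: int) -> str:
        return "".join(rng.choice(letters, size=n))

    def degenerate(m: str) -> str:
        out = []
        for aa in m:
            if rng.random() < identity:
                out.append(aa)
            else:
                alt = [a for a in ALPHABET if a != aa]
                out.append(str(rng.choice(alt)))
        return "".join(out)

    records: list[DomainRecord] = []
    truth: dict[str, int] = {}
    for k in range(n_with_motif + n_without):
        planted = k < n_with_motif
        pid = f"SPXP{k + 1:04d}" if planted else f"SPXN{k + 1:04d}"
        linker = random_seq(linker_len)
        if planted:
            copy = degenerate(motif)
            pos = int(rng.integers(0, linker_len - len(motif) + 1))
            linker = linker[:pos] + copy + linker[pos + len(copy) :]
            truth[pid] = pos + 1
        seq = random_seq(spx_len) + linker + random_seq(next_domain_len)
        domains = (
            ("SPX", 1, spx_len),
            ("TTM", spx_len + linker_len + 1, spx_len + linker_len + next_domain_len),
        )
        records.append(DomainRecord(pid, seq, domains))
    return records, truth
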