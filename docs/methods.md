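# Methods

This note records the models implemented in `spxlab`, the conventions and
defaults that matter for interpreting its output, and what the synthetic
generators do and do not emulate.

## Secondary chemical shifts and helix detection

The helix-sensitive observable is the difference of Cα and Cβ deviations
from random coil,

    SS(i) = [δCα(i) − rcCα(aa) − isoCα(aa)] − [δCβ(i) − rcCβ(aa) − isoCβ(aa)]

in ppm. Random-coil references and perdeuteration isotope corrections are
pluggable per-residue-type tables; the shipped defaults
(`data/random_coil_ca_cb.tsv`, `data/deuterium_isotope_corrections.tsv`)
are standard published sets, and the isotope term is applied only when a
table is flagged perdeuterated. Glycine has no Cβ and contributes through
its Cα deviation alone. No windowed smoothing is applied to the profile.

Helix detection finds maximal runs of SS above a threshold (default
0.7 ppm), bridging at most one interior residue that falls below threshold
or is unobserved, and discards runs with fewer than 4 qualifying residues
(one helical turn). Fractional helical propensity is the segment's mean SS
divided by a full-helix reference value, clamped to [0, 1]. The reference
SS_full = 3.1 ppm is a convention — secondary-shift magnitudes of fully
formed helices vary by nucleus calibration — and is a keyword argument
everywhere it enters. A partially formed C-terminal helix with SS ≈
1.55 ppm therefore reads out as ~50 % helical population.

## Chemical shift perturbations

Two-state amide CSPs use the combined metric with the ¹⁵N axis compressed
by its ~5-fold larger ppm dispersion:

    Δδ = sqrt((δ_ref(¹H) − δ(¹H))² + (δ_ref(¹⁵N)/5 − δ(¹⁵N)/5)²)

Residues lost to intermediate exchange are an explicit input set — peak
disappearance is a spectroscopist's judgement made at the spectrum, not
something the shift tables can decide — and are labelled rather than
assigned a value; residues missing from either state are labelled
unassigned. Classification tiers are μ + 0.2σ (low), μ + 0.8σ (medium) and
μ + 1.5σ (high) over the residues that carry values, using the sample
(n−1) standard deviation; the highest exceeded tier wins and a degenerate
distribution (σ = 0) classifies nothing.

## MST binding model

The 1:1 ligand-depletion equilibrium is solved exactly by the mass-action
quadratic (no excess-ligand approximation), which matters because the
labeled-protein concentration (0.2 µM by default) is not always negligible
against K_D. The observed thermophoresis signal is the
fluorescence-weighted mean of the free- and bound-state Fnorm levels α_P,
α_PL with relative intensities ε_P, ε_PL.

Fitting uses variable projection: conditional on K_D (and a fixed ε
ratio), the signal is linear in (α_P, α_PL), so the nonlinear search runs
over log₁₀ K_D alone — a coarse grid over [10⁻⁶·L_max, 10⁴·L_max] followed
by bounded scalar minimization. Three modes are provided: `fnorm` (raw
signal), `delta_fnorm` (per-replicate baseline at the lowest titration
point subtracted first, for series whose free/bound states differ in
fluorescence baseline), and `global_fnorm_plus_fluorescence` (an
initial-fluorescence titration is co-fitted sharing K_D; the ε levels are
estimated from the fluorescence data, each dataset's residuals normalized
by its signal range).

The 95 % interval on K_D is a profile likelihood: the RSS profile over
log K_D is thresholded at RSS_min·(1 + F₀.₉₅(1, n−p)/(n−p)) and the
crossings located by root bracketing. When the profile never closes on
the weak-binding side the fit is flagged as a lower limit and should be
quoted as K_D > lower bound; a fit whose top-concentration saturation is
below 20 % carries a weak-binding warning. Affinity fold changes are
ratios of fitted K_Ds with log-scale error propagation from the (possibly
asymmetric) intervals; a lower-limit condition propagates to a "> fold"
bound, and a lower-limit reference is an error because the ratio is
undefined.

Calibration: over 200 seeded simulated titrations at the default design,
the profile CI covers the true K_D at ~97 % (the acceptance suite asserts
nominal coverage within 3 binomial standard deviations).

## Relaxation

T1/T2 series are fitted jointly over all points (replicate delays are not
averaged first) to I(t) = I₀·e^(−Rt) with a log-linear initialization; the
rate error is the covariance diagonal. Non-decaying series (constant or
rising) are rejected rather than fitted. Delays are seconds on disk —
millisecond delay lists must be converted on export, which the synthetic
grids (0–119 ms in 17 ms steps for T2, 0–1120 ms in 160 ms steps for T1)
already are. Only mono-exponential models are offered.

## RDC alignment tensors

D = J_aligned − J_iso exactly in the measured subtraction order. The five
independent components of the symmetric traceless order matrix are solved
linearly from D_i = v_iᵀ·A·v_i (unit N–H vectors) by least squares, with a
rank-5 design-matrix requirement; fewer than 5 usable residues or
degenerate vector geometry raises an error naming the deficiency. The
dipolar prefactor is folded into the tensor so Da = A_zz'/2 and the
rhombicity R = (2/3)(A_xx' − A_yy')/A_zz' ∈ [0, 2/3] are reported in Hz of
N–H RDC. Principal axes are ordered by eigenvalue magnitude with
deterministic sign fixing (largest component positive, right-handed), so
identical tensors yield identical frames. Q = rms(D_obs − D_calc)/rms(D_obs).

Segment comparison projects each segment's N–H vectors into both principal
frames and reports the mean inter-projection angle (N–H axes carry no
polarity, so angles are folded to ≤ 90°). When both states' couplings are
available, a segment is "maintained" if the pooled cross-state couplings
are jointly consistent with both tensors (cross Q ≤ 0.3 by default, a
configurable convention); segments with fewer than 3 couplings are
reported as insufficient data. Amide protons absent from a structure are
rebuilt on the bisector of the N–Cα and N–C′(i−1) directions at 1.02 Å;
prolines are excluded.

## nanoDSF melting temperatures

The observable is the F350/F330 intrinsic-fluorescence ratio over a
15–95 °C ramp. Two extractors are provided and must not be mixed within a
ΔTm:

* **derivative** (default, the instrument convention): Savitzky–Golay
  first derivative (window 9 points, cubic). A heavily smoothed coarse
  pass (window ≈ one sixth of the ramp) first localizes the transition so
  that noise spikes far from it cannot capture the argmax; the peak is
  then refined by a quadratic fit to the derivative over ±5 °C. The
  derivative peak of a van 't Hoff sigmoid sits a few hundredths of a
  degree below the thermodynamic midpoint, and heavy smoothing of the
  skewed peak adds a small systematic offset; both offsets are common to
  curves of similar shape and cancel in ΔTm, which is why ΔTm is the
  quantity compared across conditions.
* **two_state_fit**: Tm is the midpoint parameter of a two-state van 't
  Hoff sigmoid with linear pre/post baselines, initialized from the
  derivative pass; on noiseless curves it recovers the planted Tm to
  machine precision.

Curves whose smoothed amplitude is within 5× the residual noise are
rejected as transition-free. Both extractors are exactly invariant to a
common positive rescaling of the two channels, and the heating-rate
metadata is carried but never used.

## Motif pipeline

Architecture filtering applies, in order: (i) the SPX domain is the first
annotated domain (a configurable N-terminal slack admits annotation
jitter; the residue-coordinate reading of "first" is deliberately not
used, since SPX biology is N-terminal but annotations rarely start at
residue 1); (ii) at least one other domain exists; (iii) SPX spans ≥ 130
residues; (iv) the linker to the next domain is ≤ 300 residues. Each
rejected record carries the first rule it violated, so reasons partition
the rejected set.

PSSM scores are base-2 log-likelihood ratios with additive
background-scaled pseudocounts,
score(pos, aa) = log2((count + pc·bg_aa)/(n + pc)/bg_aa); the defaults are
a uniform 1/20 background and pc = 1. Both are parameters because the
stringency of any consensus-relative threshold depends on them; the
scoring convention (log base, background, pseudocount) is stored in the
serialized PSSM header so a hit list is interpretable. The consensus is
the per-position argmax with alphabetical tie-breaking, and no window can
outscore it. Scanning scores every window of every (filtered) linker and
reports all windows above 0.4 × consensus score, overlaps included.
Information content per position is log2(20) + Σ p·log2 p over the
pseudocounted frequency estimate.

## Synthetic generators

Every generator draws from the same forward model its consumer fits, so
zero-noise round-trips invert exactly and noisy round-trips are unbiased
up to Monte-Carlo error; this is the property the test suite leans on. All
randomness flows from one integer seed through fixed per-generator
substreams, making outputs byte-identical for identical specs.

Default designs mirror a realistic study: MST titrations of 16
concentrations in a 1:1 serial dilution from 1 mM with triplicates and
Gaussian noise of 2 % of the signal range; melting curves on a 15–95 °C
grid at 0.25 °C spacing with 1 % per-channel noise and a 450 kJ/mol
van 't Hoff enthalpy (a compact ~20 kDa domain); relaxation decays on the
standard T1/T2 delay grids with 3 % noise; RDCs with 1 Hz noise;
201-residue constructs with a C-terminal helix at 184–192 for shift
tables. The noise levels are package conventions, not instrument claims.

What the generators do **not** emulate: baseline drift and photobleaching
in MST, scattering/aggregation signatures in nanoDSF, chemical-exchange
line-shape effects, peak overlap or misassignment in spectra, dynamic
averaging of RDCs, and phylogenetic correlation between proteome
sequences (positives and negatives are i.i.d. random sequences with a
planted motif). Passing round-trip tests therefore demonstrates
correctness of the estimators under their own assumptions, not robustness
to every real-data pathology.

## Numerical choices and degenerate inputs

* The bound-complex quadratic uses the subtracting root with the
  discriminant clamped at zero and the result clipped to [0, min(Pₜ, Lₜ)],
  so it is total on the valid domain (including Lₜ = 0 and K_D → 0).
* K_D optimization runs on log₁₀ K_D (xatol 10⁻¹⁰); noiseless forward
  data are recovered to better than 10⁻⁶ relative.
* Tensor eigenvector signs and consensus ties are fixed deterministically
  (see above) so repeated runs are bit-identical.
* Readers/writers round-trip floats exactly (`repr` for TSV, `%.17g` and
  round-trip parsing for CSV).
* Langmuir and relaxation CIs are covariance-based (their regimes are
  well-conditioned); only the MST K_D uses profile likelihood, where
  asymmetry and open profiles are the norm.

## Problem sizes

The acceptance script and the statistical tests use 100-trial medians for
parameter-recovery checks (200 trials for CI calibration, where the spec
of the study design allows scaling from 500), sizes at which the binomial
and Monte-Carlo error of each asserted median is several-fold smaller than
the asserted tolerance.

## Known limitations

* NMR-STAR support covers the atom-chemical-shift loop only (both "H" and
  "HN" accepted for the amide proton); full STAR semantics, mmCIF, and
  spectral processing are out of scope.
* The Langmuir NMR-titration fit treats free-ligand ≈ total-ligand; use
  the MST module's depletion model when protein concentration is
  comparable to K_D.
* Segment-orientation "maintained/changed" calls depend on the Q cutoff
  convention (0.3 default) and assume both tensors were fitted on the same
  structural model.
* The two-state Tm fit assumes a single transition; multi-domain or
  aggregating melts need manual windowing.
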