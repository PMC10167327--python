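"""Secondary shifts, helix detection, CSP, Langmuir titrations, H/D ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spxlab import shifts, synthetic
from spxlab.io import (
    InsufficientDataError,
    ShiftRecord,
    ShiftTable,
    TitrationSeries,
    ValidationError,
)


def table_from_ca_cb(entries, isotope_scheme="protonated"):
    """entries: {residue: (aa, dCa, dCb)}"""
    recs = [
        ShiftRecord(i, aa, dCa=ca, dCb=cb)
        for i, (aa, ca, cb) in sorted(entries.items())
    ]
    return ShiftTable(tuple(recs), isotope_scheme=isotope_scheme)


class TestSecondaryShifts:
    def test_random_coil_values_give_zero(self):
        rc = shifts.random_coil_table()
        entries = {
            i + 1: (aa, rc[aa][0], rc[aa][1])
            for i, aa in enumerate("ACDEFHIKLMNQRSTVWY")
        }
        prof = shifts.secondary_shifts(table_from_ca_cb(entries))
        np.testing.assert_allclose(prof.ss, 0.0, atol=1e-12)

    def test_perdeuterated_corrections_hand_computed(self):
        # 3 residues at random-coil values but marked perdeuterated:
        # SS = -(iso_Ca - iso_Cb) for each type, from the shipped table
        rc = shifts.random_coil_table()
        iso = shifts.isotope_correction_table()
        entries = {1: ("A", *rc["A"]), 2: ("L", *rc["L"]), 3: ("V", *rc["V"])}
        prof = shifts.secondary_shifts(
            table_from_ca_cb(entries, isotope_scheme="perdeuterated")
        )
        expected = [
            -(iso[aa][0] - iso[aa][1]) for aa in "ALV"
        ]
        np.testing.assert_allclose(prof.ss, expected, atol=1e-12)
        assert np.any(prof.ss != 0.0)

    def test_glycine_uses_ca_only(self):
        rc = shifts.random_coil_table()
        prof = shifts.secondary_shifts(
            table_from_ca_cb({1: ("G", rc["G"][0] + 2.0, None)})
        )
        assert prof.ss[0] == pytest.approx(2.0)
        assert not prof.used_cb[0]

    def test_planted_block_recovered_exactly(self, quiet_spec):
        ref, _ = synthetic.sim_shift_tables(quiet_spec, [(10, 20, 1.0)], n_residues=40)
        prof = shifts.secondary_shifts(ref)
        ss = prof.as_dict()
        for i in range(10, 21):
            if i in ss:
                assert ss[i] == pytest.approx(shifts.SS_FULLHELIX_PPM, abs=1e-9)
        outside = [v for k, v in ss.items() if not 10 <= k <= 20]
        np.testing.assert_allclose(outside, 0.0, atol=1e-9)


def brute_force_helices(ss_map, threshold, min_len, ss_fullhelix, max_gap=1):
    """Independent run detection: scan every candidate interval."""
    above = {i for i, v in ss_map.items() if v > threshold}
    segs = []
    i_sorted = sorted(above)
    used = set()
    for s in i_sorted:
        if s in used:
            continue
        e = s
        gap = 0
        j = s + 1
        while True:
            if j in above:
                e = j
                gap = 0
                j += 1
            elif gap < max_gap:
                gap += 1
                j += 1
            else:
                break
        members = {i for i in range(s, e + 1) if i in above}
        used |= members
        if len(members) >= min_len and e >= s + 3:
            vals = [ss_map[i] for i in range(s, e + 1) if i in ss_map]
            prop = min(max(np.mean(vals) / ss_fullhelix, 0.0), 1.0)
            segs.append((s, e, prop))
    return segs


class TestDetectHelices:
    def make_profile(self, ss_map):
        idx = np.array(sorted(ss_map))
        return shifts.SecondaryShiftProfile(
            idx, np.array([ss_map[i] for i in idx]), np.ones(idx.size, bool)
        )

    def test_zero_profile_no_segments(self):
        prof = self.make_profile({i: 0.0 for i in range(1, 30)})
        assert shifts.detect_helices(prof) == []

    def test_block_detected_with_full_propensity(self):
        ss = {i: (3.1 if 10 <= i <= 20 else 0.0) for i in range(1, 31)}
        segs = shifts.detect_helices(self.make_profile(ss), 0.7, 4)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (10, 20)
        assert segs[0].mean_propensity == pytest.approx(1.0)

    def test_half_helix_block_gives_half_propensity(self):
        ss = {i: (1.55 if 184 <= i <= 192 else 0.0) for i in range(150, 202)}
        segs = shifts.detect_helices(self.make_profile(ss), 0.7, 4)
        assert len(segs) == 1
        assert segs[0].mean_propensity == pytest.approx(0.5)

    def test_single_interior_gap_bridged(self):
        ss = {i: 3.0 for i in range(10, 21)}
        ss[15] = 0.0
        segs = shifts.detect_helices(self.make_profile({**ss, 5: 0.0, 25: 0.0}), 0.7, 4)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (10, 20)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(min_value=-1.0, max_value=4.0), min_size=8, max_size=40))
    def test_matches_brute_force_oracle(self, values):
        ss = {i + 1: v for i, v in enumerate(values)}
        segs = shifts.detect_helices(self.make_profile(ss), 0.7, 4)
        expected = brute_force_helices(ss, 0.7, 4, shifts.SS_FULLHELIX_PPM)
        assert [(s.start, s.end) for s in segs] == [(s, e) for s, e, _ in expected]
        for got, (_, _, prop) in zip(segs, expected):
            assert got.mean_propensity == pytest.approx(prop)
        # segments disjoint and sorted
        for a, b in zip(segs, segs[1:]):
            assert a.end < b.start


def hn_table(values, **kw):
    recs = [
        ShiftRecord(i, "A", dH=h, dN=n) for i, (h, n) in sorted(values.items())
    ]
    return ShiftTable(tuple(recs), **kw)


class TestCsp:
    def test_identical_tables_zero(self):
        t = hn_table({i: (8.0 + 0.01 * i, 115.0 + i) for i in range(1, 11)})
        prof = shifts.compute_csp(t, t)
        np.testing.assert_allclose(prof.delta, 0.0)

    def test_printed_formula_example(self):
        # dH difference 0.3 ppm, dN difference 2.0 ppm -> sqrt(0.09 + 0.16) = 0.5
        a = hn_table({1: (8.0, 115.0)})
        b = hn_table({1: (8.3, 117.0)})
        prof = shifts.compute_csp(a, b)
        assert prof.delta[0] == pytest.approx(0.5)

    def test_elementwise_oracle_50_residues(self, rng):
        vals_a = {i: (8 + rng.normal(), 115 + 5 * rng.normal()) for i in range(1, 51)}
        vals_b = {i: (8 + rng.normal(), 115 + 5 * rng.normal()) for i in range(1, 51)}
        prof = shifts.compute_csp(hn_table(vals_a), hn_table(vals_b))
        for i, d in zip(prof.residue_index, prof.delta):
            ha, na = vals_a[i]
            hb, nb = vals_b[i]
            assert d == pytest.approx(np.hypot(ha - hb, (na - nb) / 5.0))

    def test_symmetric_in_state_order(self, rng):
        a = hn_table({i: (8 + rng.normal(), 115 + rng.normal()) for i in range(1, 11)})
        b = hn_table({i: (8 + rng.normal(), 115 + rng.normal()) for i in range(1, 11)})
        np.testing.assert_allclose(
            shifts.compute_csp(a, b).delta, shifts.compute_csp(b, a).delta
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(-5, 5), st.floats(-20, 20))
    def test_referencing_offset_invariance(self, dh_off, dn_off):
        vals_a = {i: (8.0 + 0.1 * i, 110.0 + i) for i in range(1, 8)}
        vals_b = {i: (8.05 + 0.1 * i, 110.5 + i) for i in range(1, 8)}
        base = shifts.compute_csp(hn_table(vals_a), hn_table(vals_b)).delta
        shifted = shifts.compute_csp(
            hn_table({i: (h + dh_off, n + dn_off) for i, (h, n) in vals_a.items()}),
            hn_table({i: (h + dh_off, n + dn_off) for i, (h, n) in vals_b.items()}),
        ).delta
        np.testing.assert_allclose(base, shifted, atol=1e-9)

    def test_broadened_and_unassigned_status(self):
        a = hn_table({1: (8.0, 115.0), 2: (8.1, 116.0), 3: (8.2, 117.0)})
        b = hn_table({1: (8.0, 115.0), 2: (8.1, 116.0)})
        prof = shifts.compute_csp(a, b, broadened={2})
        by = dict(zip(prof.residue_index, prof.status))
        assert by[1] == "value" and by[2] == "intermediate_exchange"
        assert by[3] == "unassigned"

    def test_no_shared_residues_rejected(self):
        a = hn_table({1: (8.0, 115.0)})
        b = hn_table({2: (8.0, 115.0)})
        with pytest.raises(ValidationError, match="share"):
            shifts.compute_csp(a, b)


class TestClassifyCsp:
    def profile(self, deltas):
        idx = np.arange(1, len(deltas) + 1)
        return shifts.CspProfile(
            idx, np.asarray(deltas, float), tuple("value" for _ in deltas),
            tuple("none" for _ in deltas),
        )

    def test_degenerate_distribution_all_none(self):
        out = shifts.classify_csp(self.profile([0.2] * 8))
        assert set(out.classification) == {"none"}

    def test_outlier_classified_high(self):
        # eight 0.1 values and one 0.5: mu ~ 0.1444, sample sigma ~ 0.1333,
        # mu + 1.5 sigma ~ 0.3444 < 0.5
        out = shifts.classify_csp(self.profile([0.1] * 8 + [0.5]))
        assert out.classification[-1] == "high"
        assert set(out.classification[:-1]) == {"none"}

    def test_tier_bracketing_mu_plus_half_sigma_is_low(self):
        base = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        mu, sigma = base.mean(), base.std(ddof=1)
        target = mu + 0.5 * sigma
        # appending the target changes mu/sigma; iterate to a fixed point
        vals = np.append(base, target)
        for _ in range(200):
            mu, sigma = vals.mean(), vals.std(ddof=1)
            vals[-1] = mu + 0.5 * sigma
        out = shifts.classify_csp(self.profile(vals))
        assert out.classification[-1] == "low"

    def test_matches_independent_recomputation(self, rng):
        deltas = rng.gamma(2.0, 0.05, size=40)
        out = shifts.classify_csp(self.profile(deltas))
        mu, sigma = deltas.mean(), deltas.std(ddof=1)
        for d, label in zip(deltas, out.classification):
            if d > mu + 1.5 * sigma:
                assert label == "high"
            elif d > mu + 0.8 * sigma:
                assert label == "medium"
            elif d > mu + 0.2 * sigma:
                assert label == "low"
            else:
                assert label == "none"

    def test_too_few_values_rejected(self):
        with pytest.raises(InsufficientDataError):
            shifts.classify_csp(self.profile([0.1, 0.2]))


def langmuir_series(kd, ddmax, conc, noise=0.0, rng=None, reps=1):
    clean = ddmax * conc / (conc + kd)
    obs = np.repeat(clean[:, None], reps, axis=1)
    if noise and rng is not None:
        obs = obs + rng.normal(0, noise * ddmax, size=obs.shape)
    return TitrationSeries(conc, obs, tuple(f"r{i}" for i in range(reps)))


class TestFitLangmuir:
    conc = np.array([1.5625, 6.25, 25.0, 100.0, 400.0, 1600.0])

    def test_noiseless_exact_recovery(self):
        fit = shifts.fit_langmuir(langmuir_series(50.0, 0.4, self.conc))
        assert fit.K_D == pytest.approx(50.0, rel=1e-6)
        assert fit.ddmax == pytest.approx(0.4, rel=1e-6)

    def test_half_saturation_at_kd(self):
        # forward-model check: at L = K_D the observable is ddmax/2
        fit = shifts.fit_langmuir(langmuir_series(50.0, 0.4, self.conc))
        assert fit.ddmax * 50.0 / (50.0 + fit.K_D) == pytest.approx(0.2, rel=1e-6)

    def test_noisy_median_recovery_within_5_percent(self):
        kds = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = shifts.fit_langmuir(
                langmuir_series(50.0, 0.4, self.conc, noise=0.02, rng=rng, reps=3)
            )
            kds.append(fit.K_D)
        assert abs(np.median(kds) / 50.0 - 1.0) < 0.05


class TestHdProtection:
    def intensity_table(self, values):
        recs = [ShiftRecord(i, "A", intensity=v) for i, v in sorted(values.items())]
        return ShiftTable(tuple(recs))

    def test_identical_intensities_ratio_one(self):
        t = self.intensity_table({i: 5.0 for i in range(1, 6)})
        assert all(v == pytest.approx(1.0) for v in shifts.hd_protection(t, t).values())

    def test_vanished_peak_counts_as_exchanged(self):
        h = self.intensity_table({1: 5.0, 2: 5.0})
        d = self.intensity_table({1: 4.0})
        out = shifts.hd_protection(h, d)
        assert out[2] == 0.0

    def test_zero_h2o_intensity_skipped_with_warning(self):
        h = self.intensity_table({1: 0.0, 2: 5.0})
        d = self.intensity_table({1: 1.0, 2: 5.0})
        with pytest.warns(UserWarning, match="zero H2O"):
            out = shifts.hd_protection(h, d)
        assert 1 not in out

    def test_two_population_separation(self, rng):
        core = {i: 10.0 for i in range(1, 21)}
        loops = {i: 10.0 for i in range(21, 41)}
        h = self.intensity_table({**core, **loops})
        d = self.intensity_table(
            {**{i: 8.0 * (1 + 0.02 * rng.normal()) for i in core},
             **{i: 0.5 * (1 + 0.02 * rng.normal()) for i in loops}}
        )
        out = shifts.hd_protection(h, d)
        core_r = [out[i] for i in core]
        loop_r = [out[i] for i in loops]
        assert min(core_r) > 0.7 and max(loop_r) < 0.1
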