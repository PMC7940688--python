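import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from sweepkit import (
    SiteCounts,
    fst_site,
    hwe_exact,
    locus_metrics,
    pooled_hp,
    site_counts,
    site_pi,
    tajimas_d,
    window_diversity,
    window_fst,
)
from sweepkit.popgen import (
    hudson_components,
    is_defined,
    tajima_constants,
    wc_components,
)
from sweepkit.scan import Window
from sweepkit.variant_io import MISSING

from conftest import make_gm


def sc(n_hom_ref, n_het, n_hom_alt):
    alt = n_het + 2 * n_hom_alt
    ref = 2 * (n_hom_ref + n_het + n_hom_alt) - alt
    return SiteCounts(ref, alt, n_hom_ref, n_het, n_hom_alt)


class TestSiteCounts:
    def test_direct_tally(self):
        gm = make_gm([[0], [1], [2]])
        c = site_counts(gm, 0)
        assert (c.n_ref, c.n_alt) == (3, 3)
        assert (c.n_hom_ref, c.n_het, c.n_hom_alt) == (1, 1, 1)

    def test_all_missing_gives_zero_counts(self):
        gm = make_gm([[MISSING], [MISSING]])
        c = site_counts(gm, 0)
        assert c.n == 0

    def test_population_restriction_vs_naive_loop(self, small_cohort):
        gm, _, _ = small_cohort
        rng = np.random.default_rng(0)
        for j in rng.integers(0, gm.n_variants, size=20):
            for pop in gm.populations:
                c = site_counts(gm, int(j), pop)
                naive = [0, 0, 0]
                for i, s in enumerate(gm.sample_ids):
                    if gm.pop_of[s] == pop and gm.calls[i, j] != MISSING:
                        naive[gm.calls[i, j]] += 1
                assert (c.n_hom_ref, c.n_het, c.n_hom_alt) == tuple(naive)

    def test_unknown_population_errors(self, small_cohort):
        gm, _, _ = small_cohort
        with pytest.raises(KeyError):
            site_counts(gm, 0, "nope")


class TestSitePi:
    @pytest.mark.parametrize(
        "n_ref,n_alt,expected",
        [(2, 2, 2 * 2 * 2 / (4 * 3)), (4, 0, 0.0), (1, 1, 1.0)],
    )
    def test_known_values(self, n_ref, n_alt, expected):
        pi = site_pi(_counts_from_alleles(n_ref, n_alt))
        assert pi == pytest.approx(expected, abs=1e-12)

    def test_undefined_below_two_alleles(self):
        assert math.isnan(site_pi(_counts_from_alleles(0, 0)))

    def test_matches_pair_enumeration_exhaustively(self):
        # every diploid-representable allele configuration with n <= 12
        for n in range(2, 13, 2):
            for n_alt in range(n + 1):
                got = site_pi(_counts_from_alleles(n - n_alt, n_alt))
                want = oracles.pi_by_pair_enumeration(n - n_alt, n_alt)
                assert got == pytest.approx(want, abs=1e-12)


def _counts_from_alleles(n_ref, n_alt):
    # express alleles as diploid genotypes: one het if both counts are odd
    het = n_ref % 2
    hom_ref = (n_ref - het) // 2
    hom_alt = (n_alt - het) // 2
    return SiteCounts(n_ref, n_alt, hom_ref, het, hom_alt)


class TestTajimasD:
    def test_zero_numerator(self):
        k = tajima_constants(10)
        s = 5
        assert tajimas_d(s, 10, s / k["a1"]) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_cases(self):
        assert math.isnan(tajimas_d(0, 10, 0.0))
        assert math.isnan(tajimas_d(3, 1, 1.0))

    @pytest.mark.parametrize("n,s", [(10, 5), (4, 1), (30, 40), (61, 7)])
    def test_matches_exact_rational_transcription(self, n, s):
        rng = np.random.default_rng(n * 100 + s)
        pi_sum = float(rng.uniform(0, 2 * s))
        got = tajimas_d(s, n, pi_sum)
        want = oracles.tajima_d_transcription(s, n, pi_sum)
        assert got == pytest.approx(want, abs=1e-12)

    def test_sign_property(self):
        # star-like data: every variant a singleton -> D < 0
        n_samp, m = 12, 40
        calls = np.zeros((n_samp, m), dtype=np.int8)
        for j in range(m):
            calls[j % n_samp, j] = 1
        gm = make_gm(calls, positions=list(range(1000, 1000 + m)))
        d_star = window_diversity(gm, Window("1", 0, 10_000), None).tajimas_d
        assert d_star < 0
        # intermediate frequencies at every site -> D > 0
        calls = np.zeros((n_samp, m), dtype=np.int8)
        calls[: n_samp // 2, :] = 2
        gm = make_gm(calls, positions=list(range(1000, 1000 + m)))
        d_bal = window_diversity(gm, Window("1", 0, 10_000), None).tajimas_d
        assert d_bal > 0


class TestWindowDiversity:
    def test_empty_window(self, small_cohort):
        gm, _, _ = small_cohort
        st_ = window_diversity(gm, Window("1", 600_000, 700_000), "pop1")
        assert st_.pi_per_bp == 0 and st_.s == 0 and st_.theta_w_per_bp == 0
        assert math.isnan(st_.tajimas_d)

    def test_single_site_window(self):
        gm = make_gm([[0, ], [1, ], [1, ]], positions=[500])
        st_ = window_diversity(gm, Window("1", 0, 1000), None)
        assert st_.pi_per_bp == pytest.approx(site_pi(site_counts(gm, 0)) / 1000)

    def test_zero_length_window_rejected(self, small_cohort):
        gm, _, _ = small_cohort
        with pytest.raises(ValueError):
            window_diversity(gm, Window("1", 100, 100), "pop1")

    def test_against_per_site_loop(self, small_cohort):
        """Windowed theta_pi/S equal an independent per-site recount."""
        gm, _, _ = small_cohort
        w = Window("1", 0, 500_000)
        st_ = window_diversity(gm, w, "pop2")
        pi_sum, s = 0.0, 0
        rows = [i for i, smp in enumerate(gm.sample_ids) if gm.pop_of[smp] == "pop2"]
        for j, v in enumerate(gm.variants):
            alleles = [a for i in rows for a in _expand(gm.calls[i, j])]
            n = len(alleles)
            k = sum(alleles)
            if 0 < k < n:
                s += 1
            if n >= 2:
                pi_sum += oracles.pi_by_pair_enumeration(n - k, k)
        assert st_.pi_per_bp == pytest.approx(pi_sum / 500_000, rel=1e-10)
        assert st_.s == s


def _expand(call):
    return [] if call == MISSING else ([0, 0], [0, 1], [1, 1])[call]


class TestFst:
    def test_fixed_difference_is_one(self):
        c1 = sc(10, 0, 0)
        c2 = sc(0, 0, 10)
        num, den = fst_site([c1, c2], "hudson")
        assert num / den == pytest.approx(1.0)

    def test_no_differentiation_nonpositive(self):
        c = sc(5, 10, 5)
        num, den = fst_site([c, c], "hudson")
        assert num <= 0

    def test_wc_matches_equation_transcription(self):
        c1 = sc(3, 2, 0)
        c2 = sc(0, 2, 3)
        num, den = fst_site([c1, c2], "weir_cockerham")
        a, abc = oracles.wc_transcription((3, 2, 0), (0, 2, 3))
        assert num == pytest.approx(a, abs=1e-12)
        assert den == pytest.approx(abc, abs=1e-12)

    def test_empty_population_skipped_not_raised(self):
        c1 = sc(0, 0, 0)
        c2 = sc(5, 0, 5)
        num, den = fst_site([c1, c2], "hudson")
        assert math.isnan(num) and math.isnan(den)

    def test_window_fst_fixed_difference(self):
        calls = np.array([[0] * 12] * 4 + [[2] * 12] * 4, dtype=np.int8)
        gm = make_gm(calls, pops=["a"] * 4 + ["b"] * 4)
        val = window_fst(gm, Window("1", 0, 20_000), ("a", "b"), min_snps=10)
        assert val == pytest.approx(1.0)

    def test_window_fst_self_contrast_nonpositive(self, small_cohort):
        # identical groups carry no differentiation: the estimator is at or
        # below zero (negative sampling-correction bias, retained unclipped)
        gm, _, _ = small_cohort
        w = Window("1", 0, 500_000)
        assert window_fst(gm, w, ("pop1", "pop1"), min_snps=1) <= 1e-12

    def test_min_snps_gate(self, small_cohort):
        gm, _, _ = small_cohort
        w = Window("1", 0, 500_000)
        assert math.isnan(window_fst(gm, w, ("pop1", "pop2"), min_snps=10**6))

    def test_hudson_and_wc_agree_on_balanced_design(self):
        from sweepkit import SimConfig, simulate_cohort

        for F in (0.05, 0.1, 0.2):
            cfg = SimConfig(n_pops=2, n_per_pop=30, n_snps=2_000,
                            chrom_lengths={"1": 2_000_000}, fst_param=F,
                            sweep_regions=[], seed=int(F * 100))
            gm, _ = simulate_cohort(cfg)
            w = Window("1", 0, 2_000_000)
            h = window_fst(gm, w, ("pop1", "pop2"), "hudson")
            wc = window_fst(gm, w, ("pop1", "pop2"), "weir_cockerham")
            assert abs(h - wc) < 0.02


class TestPooledHp:
    def test_symmetric_single_snp(self):
        gm = make_gm([[1]] * 10, positions=[100])
        assert pooled_hp(gm, Window("1", 0, 1000)) == pytest.approx(0.5)

    def test_skewed_single_snp(self):
        # 15 major / 5 minor alleles -> 2*15*5/400
        gm = make_gm([[0]] * 5 + [[1]] * 5, positions=[100])
        assert pooled_hp(gm, Window("1", 0, 1000)) == pytest.approx(0.375)

    def test_monomorphic_window_zero(self):
        gm = make_gm([[0, 0], [0, 0]], positions=[100, 200])
        assert pooled_hp(gm, Window("1", 0, 1000)) == 0.0

    def test_bounded_and_ref_alt_invariant(self, small_cohort):
        gm, _, _ = small_cohort
        w = Window("1", 0, 500_000)
        hp = pooled_hp(gm, w)
        assert 0 <= hp <= 0.5
        flipped = make_gm(
            np.where(gm.calls == MISSING, MISSING, 2 - gm.calls),
            positions=[v.pos for v in gm.variants],
            pops=[gm.pop_of[s] for s in gm.sample_ids],
        )
        assert pooled_hp(flipped, w) == pytest.approx(hp, abs=1e-12)


class TestLocusMetrics:
    @pytest.mark.parametrize(
        "hom_ref,het,hom_alt,he,ne,pic",
        [
            (5, 10, 5, 0.5, 2.0, 0.375),
            (10, 0, 0, 0.0, 1.0, 0.0),
            (7, 2, 1, 0.32, 1 / 0.68, 1 - 0.68 - 2 * 0.64 * 0.04),  # p = 0.8
        ],
    )
    def test_closed_forms(self, hom_ref, het, hom_alt, he, ne, pic):
        m = locus_metrics(sc(hom_ref, het, hom_alt))
        assert m.he == pytest.approx(he, abs=1e-12)
        assert m.ne == pytest.approx(ne, abs=1e-12)
        assert m.pic == pytest.approx(pic, abs=1e-12)

    def test_second_route_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            counts = rng.integers(0, 20, size=3)
            if counts.sum() == 0:
                continue
            m = locus_metrics(sc(*counts))
            he, ne, pic = oracles.locus_metrics_second_route(m.allele_freqs[0])
            assert m.he == pytest.approx(he, abs=1e-12)
            assert m.ne == pytest.approx(ne, abs=1e-12)
            assert m.pic == pytest.approx(pic, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            counts = rng.integers(0, 15, size=3)
            if counts.sum() < 1:
                continue
            m = locus_metrics(sc(*counts))
            assert 0 <= m.he <= 0.5 + 1e-12
            assert 1 <= m.ne <= 2 + 1e-12
            assert 0 <= m.pic <= 0.375 + 1e-12
            assert 0 < m.hwe_p <= 1


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact(0, 0, 20) == 1.0

    def test_full_enumeration_example(self):
        assert hwe_exact(5, 0, 5) == pytest.approx(oracles.hwe_enumeration(5, 0, 5), abs=0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact(-1, 2, 3)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.integers(0, 25), st.integers(0, 25), st.integers(0, 25)
    )
    def test_equals_enumeration_for_small_tables(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact(a, h, b) == pytest.approx(oracles.hwe_enumeration(a, h, b), abs=1e-12)
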