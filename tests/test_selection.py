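"""EHH/iHS, H12, ZHp, windowed pi and Tajima's D."""

import math

import numpy as np
import pandas as pd
import pytest

from flockscan.selection import (
    _ihh_kernel,
    EHH_CUTOFF,
    ehh_decay,
    h12_scan,
    hp_value,
    ihs_scan,
    standardize_ihs,
    tajima_d,
    window_frequency_stats,
    zhp_scan,
)

from conftest import make_haps, make_matrix
from _oracles import (
    ehh_pairwise,
    h12_string_count,
    ihh_pairwise,
    pi_pairwise,
    tajima_d_direct,
)


class TestEHH:
    def test_identical_carriers_stay_at_one(self):
        haps = np.zeros((6, 20), dtype=np.int8)
        haps[:4, 10] = 1  # derived carriers, all identical elsewhere
        h = make_haps(haps)
        prof = ehh_decay(h, 10, 1)
        assert all(v == 1.0 for _, v in prof)

    def test_immediate_split_closed_form(self):
        """Carriers splitting into two equal groups adjacent to the focal
        site drop to 2*C(n/2,2)/C(n,2)."""
        n = 8
        haps = np.zeros((n, 5), dtype=np.int8)
        haps[:, 2] = 1  # all carry the focal allele
        haps[: n // 2, 3] = 1  # right neighbour splits them in half
        h = make_haps(haps)
        prof = dict(ehh_decay(h, 2, 1))
        expected = 2 * math.comb(n // 2, 2) / math.comb(n, 2)
        assert prof[10_000] == pytest.approx(expected)

    def test_singleton_carrier_rejected(self):
        haps = np.zeros((4, 5), dtype=np.int8)
        haps[0, 2] = 1
        with pytest.raises(ValueError):
            ehh_decay(make_haps(haps), 2, 1)

    def test_matches_pairwise_oracle(self):
        """Group-splitting EHH equals O(n^2) pairwise identity counting on
        a random 20-gamete fixture, at every site."""
        rng = np.random.default_rng(40)
        haps = (rng.random((20, 40)) < 0.5).astype(np.int8)
        h = make_haps(haps)
        focal = 20
        for allele in (0, 1):
            got = ehh_decay(h, focal, allele)
            want = ehh_pairwise(haps, h.positions_bp, focal, allele)
            assert len(got) == len(want)
            for (d1, v1), (d2, v2) in zip(sorted(got), want):
                assert d1 == d2
                assert v1 == pytest.approx(v2, abs=1e-12)

    def test_monotone_nonincreasing_outward(self):
        rng = np.random.default_rng(41)
        haps = (rng.random((16, 60)) < 0.4).astype(np.int8)
        h = make_haps(haps)
        prof = ehh_decay(h, 30, 0)
        left = [v for d, v in prof if d <= 0][::-1]
        right = [v for d, v in prof if d >= 0]
        for seq in (left, right):
            # non-increasing until (and including) the truncation point
            assert all(a >= b - 1e-12 for a, b in zip(seq, seq[1:]))

    def test_kernel_integral_matches_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        haps = (rng.random((18, 50)) < 0.5).astype(np.int8)
        pos = (10_000 + 10_000 * np.arange(50)).astype(np.float64)
        focal = 25
        for allele in (0, 1):
            carr = np.ascontiguousarray(haps[haps[:, focal] == allele])
            left, okl = _ihh_kernel(carr, pos, focal, -1, EHH_CUTOFF)
            right, okr = _ihh_kernel(carr, pos, focal, +1, EHH_CUTOFF)
            want, trunc = ihh_pairwise(haps, pos.astype(int), focal, allele)
            assert left + right == pytest.approx(want, abs=1e-9)
            assert (okl and okr) == trunc


class TestIHS:
    def test_mirror_symmetric_alleles_score_zero(self):
        """When ancestral and derived carriers share identical haplotype
        structure the integrated ratio is exactly 1 -> raw iHS 0."""
        rng = np.random.default_rng(43)
        half = (rng.random((6, 30)) < 0.5).astype(np.int8)
        haps = np.vstack([half, half.copy()])
        focal = 15
        haps[:6, focal] = 0
        haps[6:, focal] = 1
        h = make_haps(haps)
        df = ihs_scan(h, maf_min=0.05)
        row = df[df["pos"] == h.positions_bp[focal]]
        assert len(row) == 1
        assert row["raw"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_standardization_zscores_each_bin(self, neutral_panel):
        raw = pd.concat(
            [ihs_scan(h) for h in neutral_panel.haplotypes], ignore_index=True
        )
        std = standardize_ihs(raw, freq_bin=0.05)
        assert len(std) > 100
        grp = std.assign(b=(std["derived_allele_freq"] / 0.05).astype(int)).groupby(
            ["chrom", "b"]
        )["standardized"]
        means, sds = grp.mean(), grp.std(ddof=0)
        assert np.allclose(means, 0.0, atol=1e-9)
        assert np.allclose(sds, 1.0, atol=1e-9)

    def test_neutral_tail_calibration(self, neutral_panel):
        """|standardized iHS| > 2 at ~4.6% of sites under neutrality."""
        raw = pd.concat(
            [ihs_scan(h) for h in neutral_panel.haplotypes], ignore_index=True
        )
        std = standardize_ihs(raw)
        frac = (std["standardized"].abs() > 2).mean()
        assert frac == pytest.approx(0.046, abs=0.02)

    def test_low_maf_sites_excluded(self):
        rng = np.random.default_rng(44)
        haps = (rng.random((40, 30)) < 0.5).astype(np.int8)
        haps[:, 10] = 0
        haps[0, 10] = 1  # MAF 2.5% < 5%
        h = make_haps(haps)
        df = ihs_scan(h, maf_min=0.05)
        assert int(h.positions_bp[10]) not in set(df["pos"])


class TestH12:
    def test_uniform_gametes_give_one(self):
        h = make_haps(np.zeros((10, 30), dtype=np.int8))
        scores = h12_scan(h, window_snps=25)
        assert all(s.value == 1.0 for s in scores)

    def test_closed_forms(self):
        # two haplotypes at 0.5/0.5 pool to 1; (0.4,0.3,0.2,0.1) -> 0.54
        base = np.zeros((10, 25), dtype=np.int8)
        base[5:] = 1
        assert h12_scan(make_haps(base), 25)[0].value == pytest.approx(1.0)

        hap_bank = np.array(
            [[0] * 25, [1] * 25, [0, 1] * 12 + [0], [1, 0] * 12 + [1]], dtype=np.int8
        )
        counts = [4, 3, 2, 1]
        rows = np.vstack([np.tile(hap_bank[i], (c, 1)) for i, c in enumerate(counts)])
        got = h12_scan(make_haps(rows), 25)[0].value
        assert got == pytest.approx(0.7**2 + 0.2**2 + 0.1**2)

    def test_matches_string_counting_oracle(self):
        rng = np.random.default_rng(45)
        haps = (rng.random((30, 60)) < 0.5).astype(np.int8)
        h = make_haps(haps)
        for s in h12_scan(h, window_snps=25, step_snps=1):
            j0 = int(np.searchsorted(h.positions_bp, s.start_bp))
            want = h12_string_count(haps[:, j0 : j0 + 25])
            assert s.value == pytest.approx(want, abs=1e-12)
        assert len(h12_scan(h, 25)) == 60 - 25 + 1

    def test_short_chromosome_yields_nothing(self):
        h = make_haps(np.zeros((4, 10), dtype=np.int8))
        assert h12_scan(h, window_snps=25) == []


class TestZHp:
    def test_closed_form(self):
        assert hp_value(80, 20) == pytest.approx(0.32)

    def test_fixed_windows_score_minimal(self):
        rng = np.random.default_rng(46)
        calls = rng.integers(0, 3, size=(20, 40)).astype(np.int8)
        calls[:, :12] = 0  # a fixed stretch
        g = make_matrix(calls, spacing=20_000)
        scores = zhp_scan(g, window_bp=200_000, min_snps=5)
        assert scores, "windows expected"
        first = [s for s in scores if s.start_bp == 0]
        assert min(scores, key=lambda s: s.value).value == min(x.value for x in first)

    def test_all_windows_identical_is_error(self):
        calls = np.tile(np.array([[0], [2]], dtype=np.int8), (1, 40))
        g = make_matrix(calls, spacing=20_000)
        with pytest.raises(ValueError, match="ZHp undefined"):
            zhp_scan(g, window_bp=200_000, min_snps=5)

    def test_sparse_windows_dropped(self):
        rng = np.random.default_rng(47)
        calls = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
        g = make_matrix(calls, spacing=150_000)  # ~1.3 SNPs per 200 kb
        assert zhp_scan(g, window_bp=200_000, min_snps=10) == []


class TestPiTajima:
    def test_monomorphic_window(self):
        calls = np.zeros((10, 20), dtype=np.int8)
        g = make_matrix(calls, spacing=10_000)
        pi_scores, d_scores = window_frequency_stats(g, window_bp=300_000, min_snps=5)
        assert pi_scores and all(s.value == 0.0 for s in pi_scores)
        assert d_scores == []

    def test_singleton_case_matches_constant_oracle(self):
        """N=10 copies, 5 singleton sites: pairwise sum 1.0, D ~ -1.74."""
        calls = np.zeros((5, 5), dtype=np.int8)
        for j in range(5):
            calls[j, j] = 1  # one heterozygote per site
        g = make_matrix(calls, spacing=10_000)
        pi_scores, d_scores = window_frequency_stats(g, window_bp=300_000, min_snps=5)
        assert pi_scores[0].value == pytest.approx(1.0 / 300_000)
        assert d_scores[0].value == pytest.approx(-1.7411, abs=1e-3)
        assert d_scores[0].value == pytest.approx(tajima_d_direct(1.0, 5, 10), abs=1e-12)

    def test_tajima_d_function_vs_oracle(self):
        for pi_sum, s, n in ((1.0, 5, 10), (12.5, 40, 60), (3.3, 9, 24)):
            assert tajima_d(pi_sum, s, n) == pytest.approx(
                tajima_d_direct(pi_sum, s, n), abs=1e-12
            )

    def test_window_pi_matches_pairwise_counter(self):
        rng = np.random.default_rng(48)
        calls = rng.integers(0, 3, size=(12, 25)).astype(np.int8)
        g = make_matrix(calls, spacing=10_000)
        pi_scores, _ = window_frequency_stats(g, window_bp=300_000, min_snps=5)
        assert len(pi_scores) == 1
        want = pi_pairwise(calls) / 300_000
        assert pi_scores[0].value == pytest.approx(want, abs=1e-12)

    def test_sweep_depresses_diversity_near_site(self, sweep_panel, neutral_panel):
        """Windows overlapping the sweep rank in the low tail of Hp and the
        high tail of H12; the neutral twin's mean D stays near zero."""
        g = sweep_panel.genotypes
        sweep_pos = sweep_panel.truth["sweep_position_bp"]
        zhp = zhp_scan(g)
        over = [s for s in zhp if s.chrom == "1" and s.start_bp <= sweep_pos < s.end_bp]
        allv = sorted(s.value for s in zhp)
        assert min(o.value for o in over) <= allv[max(len(allv) // 20 - 1, 0)]

        h12 = h12_scan(sweep_panel.haplotypes[0]) + h12_scan(sweep_panel.haplotypes[1])
        overh = [s for s in h12 if s.chrom == "1" and s.start_bp <= sweep_pos <= s.end_bp]
        top5 = sorted((s.value for s in h12), reverse=True)[max(len(h12) // 20, 1) - 1]
        assert max(o.value for o in overh) >= top5

    def test_tajima_d_centered_under_neutral_sfs(self):
        """Mean windowed D is near zero when allele counts follow the
        neutral 1/i frequency spectrum (no ascertainment)."""
        rng = np.random.default_rng(49)
        n, m = 30, 1200  # 60 allele copies
        i_vals = np.arange(1, 2 * n)
        probs = (1.0 / i_vals) / (1.0 / i_vals).sum()
        calls = np.zeros((n, m), dtype=np.int8)
        for j in range(m):
            count = rng.choice(i_vals, p=probs)
            copies = np.zeros(2 * n, dtype=np.int8)
            copies[rng.choice(2 * n, size=count, replace=False)] = 1
            calls[:, j] = copies[0::2] + copies[1::2]
        g = make_matrix(calls, spacing=10_000)
        _, d_scores = window_frequency_stats(g, window_bp=300_000, min_snps=10)
        assert len(d_scores) >= 30
        mean_d = np.mean([s.value for s in d_scores])
        assert -0.5 < mean_d < 0.5

    def test_array_ascertainment_shifts_d_positive(self, neutral_panel):
        """MAF-ascertained array-like data lack rare variants, so windowed
        D sits above zero genome-wide even without selection."""
        _, d_neutral = window_frequency_stats(neutral_panel.genotypes)
        assert np.mean([s.value for s in d_neutral]) > 0
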