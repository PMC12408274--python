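"""ROH detection, length classes, and the four inbreeding coefficients."""

import numpy as np
import pytest

from flockscan.genotype_io import MISSING
from flockscan.roh import (
    ROHParams,
    ROHSegment,
    classify_roh,
    covered_autosome_bp,
    detect_roh,
    inbreeding_coefficients,
    l_parameter,
)
from flockscan.simulate import DemographyConfig, PopulationConfig, simulate

from conftest import make_matrix
from _oracles import roh_runlength


class TestLParameter:
    def test_reference_panel_value(self):
        """log(0.05 / (39685*238)) / log(1-0.35) = 44.24 -> ceil 45."""
        assert l_parameter(39_685, 238, mean_het=0.35, alpha=0.05) == 45

    def test_monotone_increasing_in_heterozygosity(self):
        # lower het -> homozygous runs arise by chance more easily -> need
        # MORE snps; i.e. L decreases as het falls?  verify sign numerically
        ls = [l_parameter(40_000, 240, mean_het=h) for h in (0.05, 0.15, 0.25, 0.35, 0.45)]
        # log(1-h) shrinks (more negative) with h, so L shrinks with h
        assert ls == sorted(ls, reverse=True)

    def test_degenerate_ratio_clamps_to_two(self):
        assert l_parameter(1, 1, mean_het=0.5, alpha=1.0) == 2

    @pytest.mark.parametrize("het", [0.0, 1.0])
    def test_boundary_heterozygosity_rejected(self, het):
        with pytest.raises(ValueError):
            l_parameter(1000, 10, mean_het=het)


def _hom_only_matrix(pos, calls_row):
    """Single-sample matrix; companion rows keep frequencies polymorphic."""
    import pandas as pd

    from flockscan.genotype_io import GenotypeMatrix, SampleRecord, VARIANT_COLUMNS

    m = len(pos)
    rng = np.random.default_rng(0)
    filler = rng.integers(0, 3, size=(2, m)).astype(np.int8)
    calls = np.vstack([np.asarray(calls_row, dtype=np.int8), filler])
    variants = pd.DataFrame(
        {"chrom": "1", "pos": pos, "id": [f"v{j}" for j in range(m)], "a1": "A", "a2": "C"}
    )[VARIANT_COLUMNS]
    samples = [SampleRecord(f"s{i}", "P") for i in range(3)]
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


class TestDetectROH:
    def test_all_heterozygous_no_segments(self):
        calls = np.ones((2, 200), dtype=np.int8)
        g = make_matrix(calls, spacing=30_000)
        assert detect_roh(g, ROHParams(min_snps=10)) == []

    def test_uniform_run_matches_runlength_oracle(self):
        """100 homozygous SNPs at 30 kb spacing form one ~3 Mb segment."""
        pos = 1_000_000 + 30_000 * np.arange(100)
        g = _hom_only_matrix(pos, np.zeros(100))
        params = ROHParams(min_snps=50)
        segs = [s for s in detect_roh(g, params) if s.sample_id == "s0"]
        oracle = roh_runlength(np.zeros(100), pos, 50, 1000, 1000, 150)
        assert [(s.start_bp, s.end_bp, s.n_snps) for s in segs] == oracle
        assert len(segs) == 1
        assert segs[0].n_snps == 100
        assert segs[0].length_mb == pytest.approx(2.97, abs=0.01)

    def test_gap_splits_run(self):
        """A 1.2 Mb gap (> --homozyg-gap) breaks the run in two."""
        pos = np.concatenate(
            [1_000_000 + 30_000 * np.arange(50),
             1_000_000 + 30_000 * 49 + 1_200_000 + 30_000 * np.arange(1, 51)]
        )
        g = _hom_only_matrix(pos, np.zeros(100))
        params = ROHParams(min_snps=40)
        segs = [s for s in detect_roh(g, params) if s.sample_id == "s0"]
        oracle = roh_runlength(np.zeros(100), pos, 40, 1000, 1000, 150)
        assert [(s.start_bp, s.end_bp, s.n_snps) for s in segs] == oracle
        assert len(segs) == 2

    def test_missing_calls_tolerated_inside_run(self):
        row = np.zeros(100, dtype=np.int8)
        row[50] = MISSING
        pos = 1_000_000 + 30_000 * np.arange(100)
        g = _hom_only_matrix(pos, row)
        segs = [s for s in detect_roh(g, ROHParams(min_snps=50)) if s.sample_id == "s0"]
        assert len(segs) == 1 and segs[0].n_snps == 100

    def test_short_chromosome_uses_truncated_window(self):
        """Chromosomes shorter than the scan window are still scanned."""
        pos = 1_000_000 + 40_000 * np.arange(30)
        g = _hom_only_matrix(pos, np.zeros(30))
        segs = [s for s in detect_roh(g, ROHParams(min_snps=20)) if s.sample_id == "s0"]
        assert len(segs) == 1 and segs[0].n_snps == 30

    def test_reported_segments_reverify_constraints(self, roh_runs):
        """Every emitted segment satisfies the length/count/density/gap/
        heterozygosity contract when re-checked directly."""
        g = roh_runs.genotypes
        params = ROHParams(min_snps=20)
        segs = detect_roh(g, params)
        assert segs, "planted tracts should be found"
        pos = g.variants["pos"].to_numpy()
        ids = {s.sample_id: i for i, s in enumerate(g.samples)}
        for seg in segs:
            sel = (pos >= seg.start_bp) & (pos <= seg.end_bp)
            row = g.calls[ids[seg.sample_id], sel]
            assert (row != 1).all()  # no heterozygote inside a run
            assert seg.n_snps >= params.min_snps
            length_kb = (seg.end_bp - seg.start_bp + 1) / 1000
            assert length_kb >= params.min_length_kb
            assert length_kb / seg.n_snps <= params.density_kb_per_snp
            gaps = np.diff(pos[sel])
            assert (gaps <= params.max_gap_kb * 1000).all()

    def test_planted_tracts_recovered_per_class(self, roh_runs):
        """The 3/7/12/18/25 Mb planted tracts land one per length class."""
        g = roh_runs.genotypes
        segs = [s for s in detect_roh(g, ROHParams(min_snps=20)) if s.sample_id == "roh0"]
        classes = classify_roh(segs)
        assert (classes.loc["roh0"] > 0).all()


class TestClassify:
    def test_single_segment(self):
        seg = ROHSegment("s", "1", 1_000_000, 3_999_999, 100)
        df = classify_roh([seg])
        assert df.loc["s", "1-5"] == pytest.approx(3.0)
        assert df.loc["s", ">20"] == 0.0

    def test_boundary_is_left_closed(self):
        """4.9 Mb stays in 1-5; exactly 5.0 Mb moves to 5-10."""
        segs = [
            ROHSegment("s", "1", 1, 4_900_000, 50),
            ROHSegment("s", "2", 1, 5_000_000, 50),
        ]
        df = classify_roh(segs)
        assert df.loc["s", "1-5"] == pytest.approx(4.9)
        assert df.loc["s", "5-10"] == pytest.approx(5.0)

    def test_totals_conserved(self):
        rng = np.random.default_rng(11)
        segs = [
            ROHSegment("s", "1", 1, int(rng.uniform(1.0, 30.0) * 1e6), 50)
            for _ in range(40)
        ]
        df = classify_roh(segs)
        assert df.loc["s"].sum() == pytest.approx(sum(s.length_mb for s in segs))


class TestInbreeding:
    def test_tiling_segments_give_froh_one(self):
        pos = 1_000_000 + 30_000 * np.arange(100)
        calls = np.zeros((2, 100), dtype=np.int8)
        calls[1] = 2  # second sample fully homozygous for the other allele
        g = make_matrix(calls, spacing=30_000, start=1_000_000)
        seg = ROHSegment("s0", "1", int(pos[0]), int(pos[-1]), 100)
        table = inbreeding_coefficients(g, [seg]).set_index("sample_id")
        assert table.loc["s0", "F_ROH"] == pytest.approx(1.0)
        assert table.loc["s0", "Ho"] == 0.0

    def test_froh_zero_without_segments_and_monotone(self):
        rng = np.random.default_rng(12)
        g = make_matrix(rng.integers(0, 3, size=(3, 50)).astype(np.int8), spacing=100_000)
        t0 = inbreeding_coefficients(g, []).set_index("sample_id")
        assert (t0["F_ROH"] == 0).all()
        seg1 = [ROHSegment("s0", "1", 10_000, 1_200_000, 12)]
        seg2 = seg1 + [ROHSegment("s0", "1", 2_000_000, 3_100_000, 11)]
        t1 = inbreeding_coefficients(g, seg1).set_index("sample_id")
        t2 = inbreeding_coefficients(g, seg2).set_index("sample_id")
        assert 0 < t1.loc["s0", "F_ROH"] < t2.loc["s0", "F_ROH"]

    def test_fgrm_closed_form_at_half_frequency(self):
        """Single SNP at p=0.5: hets score -1, homozygotes +1."""
        g_het = make_matrix(np.array([[1], [1]], dtype=np.int8))
        t_het = inbreeding_coefficients(g_het, [])
        assert t_het["F_GRM"].tolist() == pytest.approx([-1.0, -1.0])

        g_hom = make_matrix(np.array([[0], [2]], dtype=np.int8))
        t_hom = inbreeding_coefficients(g_hom, [])
        assert t_hom["F_GRM"].tolist() == pytest.approx([1.0, 1.0])

    def test_fhom_and_fis_match_direct_formulas(self):
        rng = np.random.default_rng(13)
        calls = rng.integers(0, 3, size=(8, 400)).astype(np.int8)
        g = make_matrix(calls)
        table = inbreeding_coefficients(g, []).set_index("sample_id")
        p = g.allele_frequencies()
        poly = (p > 0) & (p < 1)
        e_het = 2 * p[poly] * (1 - p[poly])
        for i in range(8):
            x = calls[i, poly]
            m = len(x)
            o_hom = (x != 1).sum()
            e_hom = (1 - e_het).sum()
            assert table.iloc[i]["F_HOM"] == pytest.approx((o_hom - e_hom) / (m - e_hom))
        ho = (calls == 1).mean(axis=1)
        fis_expected = 1 - ho.mean() / e_het.mean()
        assert table["F_IS"].iloc[0] == pytest.approx(fis_expected)
        assert table["F_IS"].nunique() == 1  # population-level value

    def test_single_sample_population_fis_nan(self):
        calls = np.array([[0, 1, 2, 1]], dtype=np.int8)
        g = make_matrix(calls, populations=["LONE"])
        table = inbreeding_coefficients(g, [])
        assert np.isnan(table["F_IS"].iloc[0])

    def test_fgrm_centers_near_zero_under_random_mating(self):
        """Mean F_GRM over a Hardy-Weinberg population is ~0."""
        rng = np.random.default_rng(14)
        p = rng.beta(0.5, 0.5, 10_000).clip(0.02, 0.98)
        calls = rng.binomial(2, p, size=(100, 10_000)).astype(np.int8)
        g = make_matrix(calls, spacing=3_000)
        table = inbreeding_coefficients(g, [])
        assert abs(table["F_GRM"].mean()) < 0.02

    def test_covered_length_sums_chromosome_spans(self):
        calls = np.zeros((2, 6), dtype=np.int8)
        g = make_matrix(calls, chrom=["1", "1", "1", "2", "2", "2"], spacing=50_000)
        pos = g.variants["pos"].to_numpy()
        expected = (pos[2] - pos[0] + 1) + (pos[5] - pos[3] + 1)
        assert covered_autosome_bp(g) == expected


class TestConsanguinitySimulation:
    def test_small_flock_mating_raises_froh(self):
        """Persistent small flocks (local Ne ~ 10) for 30 generations leave
        more of the genome in long ROH than random mating at equal census
        size and identical marker density."""
        results = {}
        for mating in ("small_flock", "random"):
            cfg = DemographyConfig(
                populations=[PopulationConfig("P", 60, 20)],
                generations=30,
                seed=21,
                n_chromosomes=2,
                chrom_length_bp=20_000_000,
                target_snps=2_000,
                migration=0.0,
                mating=mating,
                flock_size=10,
            )
            r = simulate(cfg)
            segs = detect_roh(r.genotypes, ROHParams(min_snps=25))
            table = inbreeding_coefficients(r.genotypes, segs)
            results[mating] = table["F_ROH"].mean()
        assert results["small_flock"] > results["random"]
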