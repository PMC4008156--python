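import math

import numpy as np
import pytest

from oimet.occupancy import (
    GenomicInterval,
    OccupancyResult,
    PeakSet,
    PromoterSet,
    aggregate_peaks,
    compare_occupancy,
    overlap_pairs,
    peak_cooccupancy_from_counts,
    peak_occupancy,
    peak_pair_cooccupancy,
    promoter_cooccupancy_from_counts,
    promoter_occupancy,
    promoter_pair_cooccupancy,
    read_bed,
    read_promoters,
    write_bed,
)
from oimet.synthdata import GenomeConfig, gen_genome


def random_instance(rng, n_prom=60, n_peak=150, span=20_000, widths=(50, 400)):
    proms = [
        GenomicInterval("chr1", s, s + int(rng.integers(*widths)), f"p{i}")
        for i, s in enumerate(rng.integers(0, span, n_prom))
    ]
    peaks = [
        GenomicInterval("chr1", s, s + int(rng.integers(*widths)))
        for s in rng.integers(0, span, n_peak)
    ]
    return PromoterSet(proms), PeakSet(peaks, tf="X", tissue_class="MET")


def quadratic_oracle(promoters, peaks, min_overlap=1):
    out = set()
    for pid, prom in zip(promoters.ids, promoters.intervals):
        for j, peak in enumerate(peaks.intervals):
            if prom.chrom != peak.chrom:
                continue
            if min(prom.end, peak.end) - max(prom.start, peak.start) >= min_overlap:
                out.add((pid, j))
    return out


class TestBedIO:
    def test_parse_simple_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\nchr1\t100\t200\tp1\n# comment\nchr2\t5\t9\n")
        ivs = read_bed(p)
        assert ivs[0] == GenomicInterval("chr1", 100, 200, "p1")
        assert len(ivs) == 2

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("chr1\t100\t200\nchr1\t300\t250\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(p)

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assert read_bed(p) == []

    def test_round_trip_preserves_intervals(self, tmp_path):
        rng = np.random.default_rng(1)
        proms, _ = random_instance(rng)
        p = tmp_path / "d.bed"
        write_bed(proms.intervals, p)
        assert read_bed(p) == sorted(
            proms.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 200)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)


class TestOverlap:
    def test_abutting_half_open_do_not_overlap(self):
        proms = PromoterSet([GenomicInterval("chr1", 100, 200, "p")])
        peaks = PeakSet([GenomicInterval("chr1", 200, 300)])
        assert overlap_pairs(proms, peaks) == set()

    def test_nested_peak_overlaps(self):
        proms = PromoterSet([GenomicInterval("chr1", 100, 200, "p")])
        peaks = PeakSet([GenomicInterval("chr1", 150, 160)])
        assert overlap_pairs(proms, peaks) == {("p", 0)}

    def test_min_overlap_threshold(self):
        proms = PromoterSet([GenomicInterval("chr1", 100, 200, "p")])
        peaks = PeakSet([GenomicInterval("chr1", 195, 300)])
        assert overlap_pairs(proms, peaks, min_overlap=5) == {("p", 0)}
        assert overlap_pairs(proms, peaks, min_overlap=6) == set()

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            proms, peaks = random_instance(rng)
            assert overlap_pairs(proms, peaks) == quadratic_oracle(proms, peaks)

    def test_oracle_agreement_at_extremes(self):
        # zero overlap: distinct chromosomes
        proms = PromoterSet([GenomicInterval("chr1", 0, 100, "p")])
        peaks = PeakSet([GenomicInterval("chr2", 0, 100)])
        assert overlap_pairs(proms, peaks) == set()
        # full cover: one giant peak
        rng = np.random.default_rng(6)
        proms, _ = random_instance(rng)
        cover = PeakSet([GenomicInterval("chr1", 0, 10**6)])
        assert overlap_pairs(proms, cover) == quadratic_oracle(proms, cover)


class TestOccupancy:
    def test_rates_from_reference_counts(self):
        assert OccupancyResult("promoter", 277, 75474).rate == pytest.approx(
            0.00367, abs=5e-6
        )
        assert OccupancyResult("promoter", 503, 120679).rate == pytest.approx(
            0.00417, abs=5e-6
        )
        assert OccupancyResult("peak", 287, 75474).rate == pytest.approx(0.0038, abs=5e-5)

    def test_full_cover_rate_one(self):
        rng = np.random.default_rng(2)
        proms, _ = random_instance(rng, n_prom=30)
        peaks = PeakSet([GenomicInterval("chr1", 0, 10**6) for _ in range(30)])
        assert promoter_occupancy(proms, peaks).rate == 1.0
        assert peak_occupancy(proms, peaks).rate == 1.0

    def test_zero_peaks_is_error(self):
        with pytest.raises(ValueError):
            OccupancyResult("promoter", 0, 0)

    def test_compare_matches_reference_jun(self):
        fold, p = compare_occupancy(
            OccupancyResult("promoter", 277, 75474),
            OccupancyResult("promoter", 503, 120679),
        )
        assert fold == pytest.approx(1.14, abs=0.005)
        assert p == pytest.approx(0.0966, abs=0.005)

    def test_compare_symmetry_and_identity(self):
        a = OccupancyResult("promoter", 119, 20695)
        b = OccupancyResult("promoter", 43, 3282)
        fold_ab, p_ab = compare_occupancy(a, b)
        fold_ba, p_ba = compare_occupancy(b, a)
        assert fold_ab == pytest.approx(2.28, abs=0.005)
        assert p_ab == pytest.approx(p_ba)
        assert fold_ab == pytest.approx(1 / fold_ba)
        fold_id, p_id = compare_occupancy(a, a)
        assert fold_id == 1.0 and p_id == 1.0

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_occupancy(
                OccupancyResult("promoter", 1, 10), OccupancyResult("peak", 1, 10)
            )


class TestCoOccupancy:
    @pytest.mark.parametrize(
        "n_a,n_b,both,expected,fold",
        [
            (503, 436, 228, 53.46, 4.26),
            (161, 398, 100, 15.62, 6.40),
        ],
    )
    def test_promoter_level_reference_rows(self, n_a, n_b, both, expected, fold):
        r = promoter_cooccupancy_from_counts(n_a, n_b, both, 4102)
        assert r.both_expected == pytest.approx(expected, abs=0.01)
        assert r.fold == pytest.approx(fold, abs=0.01)
        assert r.p_value < 1e-4

    @pytest.mark.parametrize(
        "ha,pa,hb,pb,both,expected,fold",
        [
            (796, 120679, 305, 19030, 152, 0.43, 350.51),
            (251, 37162, 910, 80131, 253, 0.31, 804.10),
        ],
    )
    def test_peak_level_reference_rows(self, ha, pa, hb, pb, both, expected, fold):
        r = peak_cooccupancy_from_counts(ha, pa, hb, pb, both, 4102)
        assert r.both_expected == pytest.approx(expected, abs=0.01)
        assert r.fold == pytest.approx(fold, rel=1e-3)
        assert r.p_value < 1e-4

    def test_expected_bounded_by_singles(self):
        r = promoter_cooccupancy_from_counts(503, 436, 228, 4102)
        assert r.both_expected <= min(503, 436)
        assert r.both_observed <= min(503, 436)

    def test_zero_occupancy_warns(self):
        with pytest.warns(UserWarning):
            r = promoter_cooccupancy_from_counts(0, 10, 0, 100)
        assert math.isnan(r.fold)

    def test_peak_pair_symmetric_in_tfs(self):
        cfg = GenomeConfig(
            n_chroms=2, chrom_length=1_000_000, n_promoters=100,
            tfs={("A", "MET"): (800, 0.05), ("B", "MET"): (600, 0.08)},
        )
        genome, _ = gen_genome(cfg, 13)
        a, b = genome.peaks[("A", "MET")], genome.peaks[("B", "MET")]
        r1 = peak_pair_cooccupancy(genome.promoters, a, b)
        r2 = peak_pair_cooccupancy(genome.promoters, b, a)
        assert r1.both_expected == pytest.approx(r2.both_expected)
        assert r1.fold == pytest.approx(r2.fold)

    def test_expected_equals_hypergeometric_permutation_mean(self):
        """The independence expectation n_a*n_b/N matches a label-permutation null."""
        rng = np.random.default_rng(21)
        N, n_a, n_b = 60, 25, 18
        means = []
        for _ in range(10_000):
            a = np.zeros(N, bool)
            a[rng.choice(N, n_a, replace=False)] = True
            b = np.zeros(N, bool)
            b[rng.choice(N, n_b, replace=False)] = True
            means.append(int((a & b).sum()))
        expected = n_a * n_b / N
        assert np.mean(means) == pytest.approx(expected, rel=0.02)

    def test_null_coupling_fold_near_one(self):
        folds = []
        for seed in range(15):
            cfg = GenomeConfig(
                n_chroms=2, chrom_length=2_000_000, n_promoters=300,
                tfs={("A", "MET"): (1500, 0.15), ("B", "MET"): (1500, 0.15)},
            )
            genome, _ = gen_genome(cfg, seed)
            r = promoter_pair_cooccupancy(
                genome.promoters, genome.peaks[("A", "MET")], genome.peaks[("B", "MET")]
            )
            folds.append(r.fold)
        mean = np.mean(folds)
        se = np.std(folds, ddof=1) / np.sqrt(len(folds))
        assert abs(mean - 1.0) < 3 * se + 0.02


class TestAggregation:
    def test_concatenates_without_merging(self, tmp_path):
        a = tmp_path / "a.bed"
        b = tmp_path / "b.bed"
        a.write_text("chr1\t0\t100\nchr1\t50\t150\n")
        b.write_text("chr1\t0\t100\n")  # duplicate of an interval in a
        ps = aggregate_peaks([a, b], tf="JUN", tissue_class="MET")
        assert ps.n_peaks == 3
        assert ps.tf == "JUN"

    def test_single_file_identity(self, tmp_path):
        a = tmp_path / "a.bed"
        a.write_text("chr1\t0\t100\nchr2\t5\t50\n")
        assert aggregate_peaks([a], "X", "MET").intervals == read_bed(a)

    def test_missing_file_named(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.bed"):
            aggregate_peaks([tmp_path / "nope.bed"], "X", "MET")

    def test_empty_path_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_peaks([], "X", "MET")
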