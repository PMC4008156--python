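"""ChIP-Seq peak / promoter overlap and TF co-occupancy enrichment.

Coordinates are 0-based half-open (BED native) throughout; an overlap needs
at least one shared base, so abutting intervals do not overlap. Strand is
ignored. Two occupancy summaries are used, both normalised by the *peak*
count (the denominator convention of the source tables):

* promoter occupancy — number of promoters overlapped by >= 1 peak;
* peak occupancy — number of peaks overlapping >= 1 promoter.

For a TF pair on a shared promoter set of size ``N_p``, the independence
expectation is ``n_a * n_b / N_p`` co-occupied promoters at promoter level,
and ``rate_a * rate_b * N_p`` at peak level; the reported fold is observed
over expected. Occupancy-rate comparisons between tissue classes use a
two-proportion z-test with continuity correction; promoter-level pairs use
Fisher's exact test on the 2x2 occupancy table; peak-level pairs use a
Poisson test against the expectation. Peak files aggregated across cell
lines are concatenated without merging, so overlapping peaks keep their
separate identities and the peak totals are plain sums.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree
from scipy import stats as sps

from .stats import poisson_test, two_proportion_ztest


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"start must be < end: {self}")

    def __len__(self) -> int:
        return self.end - self.start


class _IntervalSet:
    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.intervals = list(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for i, iv in enumerate(self.intervals):
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
        return trees


class PromoterSet(_IntervalSet):
    """Named promoter intervals; ids must be unique."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        super().__init__(intervals)
        self.ids = [
            iv.name if iv.name else f"{iv.chrom}:{iv.start}-{iv.end}"
            for iv in self.intervals
        ]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate promoter ids")

    @property
    def n_promoters(self) -> int:
        return len(self.intervals)


class PeakSet(_IntervalSet):
    """Peaks for one TF in one tissue class (not_cancer / MET / non_MET)."""

    def __init__(self, intervals: Sequence[GenomicInterval], tf: str = "",
                 tissue_class: str = ""):
        super().__init__(intervals)
        self.tf = tf
        self.tissue_class = tissue_class

    @property
    def n_peaks(self) -> int:
        return len(self.intervals)


@dataclass
class OccupancyResult:
    mode: str  # promoter | peak
    n_hits: int
    n_peaks: int
    rate: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_peaks <= 0:
            raise ValueError("occupancy rate undefined with zero peaks")
        self.rate = self.n_hits / self.n_peaks


@dataclass
class CoOccupancyResult:
    level: str  # promoter | peak
    n_only_a: int
    n_only_b: int
    both_expected: float
    both_observed: int
    fold: float
    p_value: float


def read_bed(path) -> list[GenomicInterval]:
    """Parse a 3-6 column BED file; track/browser/comment lines are skipped."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not intervals:
        warnings.warn(f"empty BED file: {path}")
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                fields.append(iv.name or ".")
            if iv.strand is not None:
                fields += ["0", iv.strand]
            fh.write("\t".join(fields) + "\n")


def read_promoters(path) -> PromoterSet:
    return PromoterSet(read_bed(path))


def read_peaks(path, tf: str = "", tissue_class: str = "") -> PeakSet:
    return PeakSet(read_bed(path), tf=tf, tissue_class=tissue_class)


def aggregate_peaks(bed_paths: Sequence, tf: str, tissue_class: str) -> PeakSet:
    """Concatenate per-cell-line BED files for one TF/class; no merging."""
    if not bed_paths:
        raise ValueError("at least one BED file required")
    intervals: list[GenomicInterval] = []
    for p in bed_paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"missing peak file: {p}")
        intervals.extend(read_bed(p))
    return PeakSet(intervals, tf=tf, tissue_class=tissue_class)


def overlap_pairs(
    promoters: PromoterSet, peaks: PeakSet, min_overlap: int = 1
) -> set[tuple[str, int]]:
    """All (promoter id, peak index) pairs overlapping by >= ``min_overlap`` bp."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees = promoters.by_chrom()
    out: set[tuple[str, int]] = set()
    for j, peak in enumerate(peaks.intervals):
        tree = trees.get(peak.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(peak.start, peak.end):
            if min(hit.end, peak.end) - max(hit.begin, peak.start) >= min_overlap:
                out.add((promoters.ids[hit.data], j))
    return out


def promoter_occupancy(promoters: PromoterSet, peaks: PeakSet) -> OccupancyResult:
    """Promoters with >= 1 peak, per total peak count."""
    pairs = overlap_pairs(promoters, peaks)
    return OccupancyResult("promoter", len({p for p, _ in pairs}), peaks.n_peaks)


def peak_occupancy(promoters: PromoterSet, peaks: PeakSet) -> OccupancyResult:
    """Peaks overlapping >= 1 promoter, per total peak count."""
    pairs = overlap_pairs(promoters, peaks)
    return OccupancyResult("peak", len({j for _, j in pairs}), peaks.n_peaks)


def compare_occupancy(
    baseline: OccupancyResult, test: OccupancyResult
) -> tuple[float, float]:
    """Fold change (test / baseline rate) and two-proportion z-test p-value."""
    if baseline.mode != test.mode:
        raise ValueError("cannot compare occupancy of different modes")
    if baseline.rate == 0:
        warnings.warn("baseline rate is zero; fold reported as +inf")
        fold = math.inf
    else:
        fold = test.rate / baseline.rate
    _, p = two_proportion_ztest(
        baseline.n_hits, baseline.n_peaks, test.n_hits, test.n_peaks
    )
    return fold, p


def promoter_cooccupancy_from_counts(
    n_a: int, n_b: int, both_observed: int, n_promoters: int
) -> CoOccupancyResult:
    """Promoter-level pair enrichment from occupancy counts.

    ``n_a``, ``n_b``: promoters with >= 1 peak of each TF; expectation under
    independent binding is ``n_a * n_b / N_p``. Fisher's exact test on the
    (both, a-only, b-only, neither) table supplies the p-value.
    """
    expected = n_a * n_b / n_promoters
    if expected == 0:
        warnings.warn("an occupancy count is zero; fold undefined")
        fold = math.nan
        p = 1.0
    else:
        fold = both_observed / expected
        table = [
            [both_observed, n_a - both_observed],
            [n_b - both_observed, n_promoters - n_a - n_b + both_observed],
        ]
        p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return CoOccupancyResult(
        "promoter", n_a - both_observed, n_b - both_observed,
        expected, both_observed, fold, p,
    )


def peak_cooccupancy_from_counts(
    hits_a: int, peaks_a: int, hits_b: int, peaks_b: int,
    both_observed: int, n_promoters: int,
) -> CoOccupancyResult:
    """Peak-level pair enrichment from occupancy counts.

    Expectation is ``rate_a * rate_b * N_p`` where the rates are peak
    occupancy rates; the p-value is a Poisson test of the observed count
    against that expectation.
    """
    rate_a = hits_a / peaks_a
    rate_b = hits_b / peaks_b
    expected = rate_a * rate_b * n_promoters
    if expected == 0:
        warnings.warn("a peak occupancy rate is zero; fold undefined")
        fold = math.nan
        p = 1.0
    else:
        fold = both_observed / expected
        p = poisson_test(both_observed, expected)
    return CoOccupancyResult(
        "peak", hits_a - both_observed, hits_b - both_observed,
        expected, both_observed, fold, p,
    )


def promoter_pair_cooccupancy(
    promoters: PromoterSet, peaks_a: PeakSet, peaks_b: PeakSet
) -> CoOccupancyResult:
    """Promoter-level co-occupancy of two TFs against independence."""
    occ_a = {p for p, _ in overlap_pairs(promoters, peaks_a)}
    occ_b = {p for p, _ in overlap_pairs(promoters, peaks_b)}
    return promoter_cooccupancy_from_counts(
        len(occ_a), len(occ_b), len(occ_a & occ_b), promoters.n_promoters
    )


def peak_pair_cooccupancy(
    promoters: PromoterSet,
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    both_observed_mode: str = "pairs",
) -> CoOccupancyResult:
    """Peak-level co-occupancy of two TFs against independence.

    The observed count is ambiguous at peak level; two definitions are
    supported. ``"pairs"`` (default) counts (peak_a, peak_b) pairs that
    overlap a common promoter; ``"peaks"`` counts peaks of either TF lying
    in promoters co-occupied by both TFs.
    """
    pairs_a = overlap_pairs(promoters, peaks_a)
    pairs_b = overlap_pairs(promoters, peaks_b)
    by_prom_a: dict[str, set[int]] = {}
    for p, j in pairs_a:
        by_prom_a.setdefault(p, set()).add(j)
    by_prom_b: dict[str, set[int]] = {}
    for p, j in pairs_b:
        by_prom_b.setdefault(p, set()).add(j)
    co_promoters = set(by_prom_a) & set(by_prom_b)
    if both_observed_mode == "pairs":
        observed = 0
        seen: set[tuple[int, int]] = set()
        for p in co_promoters:
            for ja in by_prom_a[p]:
                for jb in by_prom_b[p]:
                    seen.add((ja, jb))
        observed = len(seen)
    elif both_observed_mode == "peaks":
        peaks_in_a = {j for p in co_promoters for j in by_prom_a[p]}
        peaks_in_b = {j for p in co_promoters for j in by_prom_b[p]}
        observed = len(peaks_in_a) + len(peaks_in_b)
    else:
        raise ValueError(f"unknown both_observed_mode {both_observed_mode!r}")
    return peak_cooccupancy_from_counts(
        len({j for _, j in pairs_a}), peaks_a.n_peaks,
        len({j for _, j in pairs_b}), peaks_b.n_peaks,
        observed, promoters.n_promoters,
    )


def chipbase_csv_to_bed(
    path, out_path, chrom_col: str = "chrom", start_col: str = "start",
    end_col: str = "end", name_col: str | None = None, sep: str = ",",
) -> int:
    """Convert a ChIPBase-style CSV (1-based inclusive) to BED (0-based half-open).

    Returns the number of intervals written. The start shift (``start - 1``)
    is the only coordinate transformation.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=sep)
    intervals = [
        GenomicInterval(
            str(r[chrom_col]), int(r[start_col]) - 1, int(r[end_col]),
            str(r[name_col]) if name_col else None,
        )
        for _, r in df.iterrows()
    ]
    write_bed(intervals, out_path)
    return len(intervals)
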