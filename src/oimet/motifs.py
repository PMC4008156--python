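"""Promoter motif over-representation and motif-pair enrichment.

Motif *families* (Genomatix-style labels such as ``V$AP1F`` or ``V$EBOX``)
are opaque column labels on a boolean promoter-by-motif hit matrix; the
genome-wide expected proportion of promoters carrying each family is an
input (``MotifBackground``). Single-family over-representation compares the
observed proportion of promoters with at least one match to that background
proportion. For a family pair, the *expected* pair enrichment under random
placement is the product of the two single-family folds; the interesting
quantity is the difference between the observed pair fold and that product.

A small position-weight-matrix scanner is included for generating and
checking synthetic hit matrices from sequence; it scores log-odds against a
uniform base composition, on both strands, with ``N`` contributing zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import EnrichmentResult, chi2_2x2

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PairEnrichment:
    motif_i: str
    motif_j: str
    observed_enrichment: float
    expected_enrichment: float
    difference: float
    n_pair_obs: int
    p_value: float


class MotifHitMatrix:
    """Boolean promoter-by-motif matrix (1 = at least one match)."""

    def __init__(self, data: pd.DataFrame):
        self.data = data.astype(bool)

    @classmethod
    def from_tsv(cls, path) -> "MotifHitMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.data.astype(int).to_csv(path, sep="\t")

    @property
    def promoters(self) -> list[str]:
        return list(self.data.index)

    @property
    def motifs(self) -> list[str]:
        return list(self.data.columns)

    def n_with(self, motif: str) -> int:
        return int(self.data[motif].sum())

    def n_pair(self, motif_i: str, motif_j: str) -> int:
        return int((self.data[motif_i] & self.data[motif_j]).sum())


def read_jaspar_pwm(path) -> np.ndarray:
    """Read the first motif from a JASPAR 4-row count file as a 4xL PWM.

    Counts are normalised per column to probabilities (rows A, C, G, T).
    """
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        motif = bio_motifs.read(fh, "jaspar")
    counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
    return counts / counts.sum(axis=0, keepdims=True)


def _validate_pwm(pwm: np.ndarray) -> np.ndarray:
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[0] != 4:
        raise ValueError("PWM must be a 4xL matrix (rows A, C, G, T)")
    if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("PWM columns must sum to 1")
    return pwm


def _logodds(pwm: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2(pwm / 0.25)


def scan_pwm(sequence: str, pwm: np.ndarray, threshold: float) -> list[tuple[int, str, float]]:
    """All positions (both strands) scoring at least ``threshold`` log-odds.

    Positions are 0-based starts on the forward sequence; a minus-strand hit
    at position ``k`` means the reverse complement of ``sequence[k:k+L]``
    matches. ``N`` contributes zero log-odds.
    """
    pwm = _validate_pwm(pwm)
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError(f"sequence alphabet outside ACGTN: {sorted(set(seq) - set('ACGTN'))}")
    lo = _logodds(pwm)
    L = pwm.shape[1]
    hits: list[tuple[int, str, float]] = []
    if len(seq) < L:
        return hits
    # integer-encode; N -> 4 indexes a zero row
    enc = np.fromiter((_BASE_INDEX.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))
    lo5 = np.vstack([lo, np.zeros((1, L))])
    rc = seq.translate(_COMPLEMENT)[::-1]
    enc_rc = np.fromiter((_BASE_INDEX.get(c, 4) for c in rc), dtype=np.int8, count=len(rc))
    n_pos = len(seq) - L + 1
    idx = np.arange(L)
    for strand, e in (("+", enc), ("-", enc_rc)):
        windows = e[np.arange(n_pos)[:, None] + idx]
        scores = lo5[windows, idx].sum(axis=1)
        for pos in np.nonzero(scores >= threshold)[0]:
            fwd_pos = int(pos) if strand == "+" else len(seq) - L - int(pos)
            hits.append((fwd_pos, strand, float(scores[pos])))
    hits.sort()
    return hits


def single_motif_enrichment(n_with: int, n_total: int, expected_prop: float) -> EnrichmentResult:
    """Observed vs genome-wide proportion of promoters with the motif.

    Two-sided exact binomial test of ``n_with`` out of ``n_total`` at the
    background proportion.
    """
    if not 0 <= n_with <= n_total:
        raise ValueError("require 0 <= n_with <= n_total")
    if not 0 < expected_prop < 1:
        raise ValueError("expected proportion must be in (0, 1)")
    res = EnrichmentResult.from_background_prop(
        "", n_with, n_total, expected_prop, method="binomial"
    )
    test = sps.binomtest(n_with, n_total, expected_prop, alternative="two-sided")
    res.statistic = float(test.statistic)
    res.p_value = float(test.pvalue)
    return res


def pair_expected_enrichment(fold_i: float, fold_j: float) -> float:
    """Expected pair fold under random placement: the product of single folds."""
    if fold_i <= 0 or fold_j <= 0:
        raise ValueError("folds must be positive")
    return fold_i * fold_j


def pair_enrichment_test(
    matrix: MotifHitMatrix,
    background: dict,
    motif_i: str,
    motif_j: str,
) -> PairEnrichment:
    """Observed pair fold vs the product-of-folds expectation.

    ``background`` maps each motif label to its expected single proportion
    and, optionally under key ``(motif_i, motif_j)`` (either order), the
    expected pair proportion. The chi-square compares the with-pair /
    without-pair split against the background-expected pair count (1 df).
    """
    for m in (motif_i, motif_j):
        if m not in matrix.data.columns:
            raise ValueError(f"motif {m!r} not in matrix")
        if m not in background:
            raise ValueError(f"motif {m!r} not in background")
    n_total = len(matrix.data)
    n_pair = matrix.n_pair(motif_i, motif_j)
    fold_i = (matrix.n_with(motif_i) / n_total) / background[motif_i]
    fold_j = (matrix.n_with(motif_j) / n_total) / background[motif_j]
    expected = pair_expected_enrichment(fold_i, fold_j)

    pair_bg = background.get((motif_i, motif_j), background.get((motif_j, motif_i)))
    if pair_bg is None:
        warnings.warn(
            f"no background pair proportion for ({motif_i}, {motif_j}); "
            "observed enrichment unavailable, reporting counts only"
        )
        return PairEnrichment(motif_i, motif_j, math.nan, expected, math.nan, n_pair, math.nan)

    observed = (n_pair / n_total) / pair_bg if pair_bg > 0 else 0.0
    expected_count = pair_bg * n_total
    _, p = chi2_2x2(
        [[n_pair, n_total - n_pair],
         [expected_count, n_total - expected_count]]
    )
    return PairEnrichment(
        motif_i, motif_j, observed, expected, observed - expected, n_pair, p
    )
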