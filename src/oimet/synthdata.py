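"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the statistical shape of one input family — two-model
differential-expression tables, gene-by-term literature hit tables, a
promoter set with per-TF ChIP-Seq peak sets, and a TF-target edge list —
with full bookkeeping of what was planted, so selection, enrichment, overlap
and network stages can be verified offline against known truth.

Default sizes mirror the study conditions the pipeline targets: a 739-gene
shared signature inside 1,622- and 2,692-gene model signatures over a
~20,000-gene assay, a 36,973-symbol literature universe, 4,102 promoters,
and peak sets in the 10^4–10^5 range; every size is configurable and the
test suite runs on much smaller instances.

A single root seed expands into fixed per-component substreams, so any one
component can be regenerated independently and reruns are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .litminer import HitTable
from .motifs import MotifHitMatrix
from .network import InteractionEdge
from .occupancy import GenomicInterval, PeakSet, PromoterSet

# substream offsets: one per component
_STREAMS = {"expression": 1, "literature": 2, "genome": 3, "network": 4}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[component]])


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ExpressionConfig:
    n_genes: int = 20_000
    de_fraction: dict = field(default_factory=lambda: {"BC": 0.0811, "PC": 0.1346})
    shared_fraction: float = 0.4556  # of the smaller model's DE count -> ~739 genes
    concordance: float = 0.66
    isoform_weights: tuple = (0.6, 0.3, 0.1)  # P(1), P(2), P(3) isoforms
    switch_fraction: float = 0.10  # of multi-isoform DE genes per model
    fc_log2_sigma: float = 1.0  # spread of DE magnitudes beyond the 2-fold floor
    decoy_fraction: float = 0.01  # non-"OK" records with DE-like fold changes


@dataclass
class LiteratureConfig:
    universe_size: int = 36_973
    set_size: int = 739
    terms: dict = field(default_factory=lambda: {"MET": (0.027, 4.5)})
    # label -> (background base rate, enrichment fold inside the planted set)


@dataclass
class GenomeConfig:
    n_chroms: int = 4
    chrom_length: int = 50_000_000
    n_promoters: int = 4_102
    promoter_width: int = 1_000
    peak_width: int = 300
    tfs: dict = field(
        default_factory=lambda: {
            ("JUN", "MET"): (120_679, 0.0066),
            ("MYC", "MET"): (19_030, 0.0160),
            ("FOS", "MET"): (3_282, 0.0104),
        }
    )
    # (tf, tissue_class) -> (n_peaks, promoter-targeting rate theta)
    pair_coupling: dict = field(default_factory=dict)
    # (tf_a, tf_b, tissue_class) -> rho: probability a tf_b peak is co-placed
    # into a promoter already hit by tf_a
    motifs: dict = field(default_factory=lambda: {"V$AP1F": 0.34, "V$EBOX": 0.56})
    motif_pair_coupling: dict = field(default_factory=dict)  # (m1, m2) -> rho


@dataclass
class NetworkConfig:
    n_regulators: int = 5
    fan_in_hist: dict = field(default_factory=lambda: {2: 20, 3: 4, 4: 1})
    n_extra_nodes: int = 30
    extra_edge_density: float = 0.05


@dataclass
class SimulationConfig:
    seed: int = 0
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    literature: LiteratureConfig = field(default_factory=LiteratureConfig)
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)


@dataclass
class GroundTruth:
    de_genes: dict = field(default_factory=dict)  # model -> set of symbols
    shared_genes: set = field(default_factory=set)
    concordant_genes: set = field(default_factory=set)
    switch_genes: dict = field(default_factory=dict)  # model -> set of symbols
    enriched_terms: dict = field(default_factory=dict)  # label -> (base, fold)
    hit_set: set = field(default_factory=set)
    theta: dict = field(default_factory=dict)
    rho: dict = field(default_factory=dict)
    motif_props: dict = field(default_factory=dict)
    fan_in_hist: dict = field(default_factory=dict)
    regulators: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# expression tables


def _de_fold(rng: np.random.Generator, up: bool, sigma: float) -> float:
    mag = 2.0 ** (1.0 + abs(rng.normal(0.0, sigma)))  # >= 2-fold
    fc = mag if up else 1.0 / mag
    return float(min(10.0, max(0.0, fc)))


def _null_fold(rng: np.random.Generator, toward_up: bool | None = None) -> float:
    # strictly inside the (0.55, 1.8) band: can never pass 2.0 / 0.5 selection
    log2 = rng.normal(0.0, 0.25)
    log2 = float(np.clip(log2, np.log2(0.56), np.log2(1.79)))
    if toward_up is True:
        log2 = abs(log2)
    elif toward_up is False:
        log2 = -abs(log2)
    return float(2.0 ** log2)


def gen_expression(
    config: ExpressionConfig, seed: int
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Two-model DE tables with a planted shared signature and isoform switches.

    Every planted DE gene passes selection ("OK", FDR <= 0.05, fold beyond
    2.0 / 0.5) in at least one treatment; every non-planted gene is
    constructed to fail it (fold inside (0.55, 1.8), or a non-"OK" status
    decoy). Direction under the double-OVOL treatment is assigned so that
    exactly ``round(concordance * n_shared)`` shared genes move the same way
    in both models.
    """
    rng = _rng(seed, "expression")
    cfg = config
    models = sorted(cfg.de_fraction)
    genes = np.array([f"G{i:06d}" for i in range(cfg.n_genes)])
    n_de = {m: int(round(cfg.de_fraction[m] * cfg.n_genes)) for m in models}
    n_shared = int(round(cfg.shared_fraction * min(n_de.values())))
    if n_shared > min(n_de.values()):
        raise ValueError("shared fraction infeasible for the per-model DE counts")
    if sum(n_de.values()) - n_shared > cfg.n_genes:
        raise ValueError("DE fractions exceed the gene universe")

    perm = rng.permutation(cfg.n_genes)
    shared = list(genes[perm[:n_shared]])
    cursor = n_shared
    de_sets: dict[str, list[str]] = {}
    for m in models:
        extra = n_de[m] - n_shared
        de_sets[m] = shared + list(genes[perm[cursor:cursor + extra]])
        cursor += extra

    # per-gene direction of the double-OVOL response, per model
    n_conc = int(round(cfg.concordance * n_shared))
    direction: dict[str, dict[str, bool]] = {m: {} for m in models}
    for i, g in enumerate(shared):
        up = bool(rng.random() < 0.5)
        if i < n_conc:
            for m in models:
                direction[m][g] = up
        else:
            direction[models[0]][g] = up
            direction[models[1]][g] = not up
    for m in models:
        for g in de_sets[m][n_shared:]:
            direction[m][g] = bool(rng.random() < 0.5)

    n_iso = rng.choice(
        np.arange(1, len(cfg.isoform_weights) + 1), size=cfg.n_genes,
        p=np.asarray(cfg.isoform_weights) / np.sum(cfg.isoform_weights),
    )
    iso_count = dict(zip(genes, n_iso))

    switch_genes: dict[str, set[str]] = {}
    for m in models:
        multi = [g for g in de_sets[m] if iso_count[g] >= 2]
        k = int(round(cfg.switch_fraction * len(multi)))
        switch_genes[m] = set(multi[:k])  # de_sets order is already random

    treatments = ("OVOL1", "OVOL2", "OVOL1and2")
    tables: dict[str, pd.DataFrame] = {}
    n_decoys = int(round(cfg.decoy_fraction * cfg.n_genes))
    for m in models:
        de = set(de_sets[m])
        decoys = set(genes[perm[::-1][:n_decoys]]) - de
        rows = []
        for g in genes:
            is_de = g in de
            up = direction[m].get(g)
            # responsive treatments: always OVOL1and2, each single with p=0.6
            responsive = {"OVOL1and2"} | {
                t for t in treatments[:2] if rng.random() < 0.6
            }
            gene_folds = {}
            for t in treatments:
                if is_de and t in responsive:
                    fc = _de_fold(rng, up, cfg.fc_log2_sigma)
                    fdr = float(rng.uniform(0.0, 0.05))
                elif is_de:
                    fc = _null_fold(rng, toward_up=up)
                    fdr = float(rng.uniform(0.0, 1.0))
                else:
                    fc = _null_fold(rng)
                    fdr = float(rng.uniform(0.0, 1.0))
                status = "OK"
                if g in decoys:
                    fc = _de_fold(rng, bool(rng.random() < 0.5), cfg.fc_log2_sigma)
                    fdr = float(rng.uniform(0.0, 0.05))
                    status = "NOTEST"
                gene_folds[t] = fc
                rows.append((g, "gene", g, m, t, fc, fdr, status))
            k = iso_count[g]
            if k >= 2:
                planted_switch = g in switch_genes[m]
                for j in range(k):
                    for ti, t in enumerate(treatments):
                        if planted_switch and ti == 2:
                            # one isoform clearly up, another clearly down
                            if j == 0:
                                fc = float(rng.uniform(2.0, 6.0))
                            elif j == 1:
                                fc = float(rng.uniform(0.1, 0.5))
                            else:
                                fc = _null_fold(rng)
                        elif is_de:
                            fc = gene_folds[t] * float(rng.uniform(0.9, 1.1))
                            if up:
                                fc = max(fc, 1.0)
                            else:
                                fc = min(fc, 1.0)
                            fc = float(min(10.0, fc))
                        else:
                            fc = float(rng.uniform(0.75, 1.35))
                        fdr = float(rng.uniform(0.0, 0.05)) if is_de else float(rng.uniform(0.0, 1.0))
                        rows.append((f"{g}.i{j+1}", "isoform", g, m, t, fc, fdr, "OK"))
        tables[m] = pd.DataFrame(
            rows,
            columns=[
                "feature_id", "level", "gene_symbol", "model", "treatment",
                "fold_change", "fdr", "status",
            ],
        )

    truth = GroundTruth(
        de_genes={m: set(de_sets[m]) for m in models},
        shared_genes=set(shared),
        concordant_genes=set(shared[:n_conc]),
        switch_genes=switch_genes,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# literature hit tables


def gen_hit_table(config: LiteratureConfig, seed: int) -> tuple[HitTable, GroundTruth]:
    """Bernoulli gene-by-term hits with a designated enriched set.

    Background genes hit each term at its base rate; genes in the planted
    set at ``base_rate * enrichment_fold`` (capped at 1, with a warning).
    """
    rng = _rng(seed, "literature")
    cfg = config
    if cfg.set_size > cfg.universe_size:
        raise ValueError("set_size exceeds universe_size")
    universe = [f"G{i:06d}" for i in range(cfg.universe_size)]
    hit_set = set(universe[: cfg.set_size])
    in_set = np.zeros(cfg.universe_size, dtype=bool)
    in_set[: cfg.set_size] = True
    cols = {}
    for label, (base, fold) in cfg.terms.items():
        set_rate = base * fold
        if set_rate > 1:
            import warnings

            warnings.warn(f"term {label!r}: set rate capped at 1")
            set_rate = 1.0
        p = np.where(in_set, set_rate, base)
        cols[label] = rng.random(cfg.universe_size) < p
    table = HitTable(pd.DataFrame(cols, index=universe))
    truth = GroundTruth(enriched_terms=dict(cfg.terms), hit_set=hit_set)
    return table, truth


# ---------------------------------------------------------------------------
# genome: promoters, peaks, motif hits


@dataclass
class GenomeData:
    promoters: PromoterSet
    peaks: dict  # (tf, tissue_class) -> PeakSet
    motif_matrix: MotifHitMatrix
    motif_background: dict  # motif -> true marginal proportion


def _place_promoters(rng: np.random.Generator, cfg: GenomeConfig) -> list[GenomicInterval]:
    slot = 2 * cfg.promoter_width
    per_chrom = np.full(cfg.n_chroms, cfg.n_promoters // cfg.n_chroms)
    per_chrom[: cfg.n_promoters % cfg.n_chroms] += 1
    n_slots = cfg.chrom_length // slot
    if per_chrom.max() > n_slots:
        raise ValueError("promoters do not fit in the genome without overlap")
    out = []
    pid = 0
    for c in range(cfg.n_chroms):
        starts = np.sort(rng.choice(n_slots, size=per_chrom[c], replace=False)) * slot
        for s in starts:
            out.append(
                GenomicInterval(f"chr{c+1}", int(s), int(s) + cfg.promoter_width, f"p{pid:05d}")
            )
            pid += 1
    return out


def _peak_in_promoter(rng, prom: GenomicInterval, width: int) -> GenomicInterval:
    lo = max(0, prom.start - width + 1)
    start = int(rng.integers(lo, prom.end))  # guarantees >= 1 bp overlap
    return GenomicInterval(prom.chrom, start, start + width)


def _background_peak(rng, cfg: GenomeConfig, prom_by_chrom) -> GenomicInterval:
    while True:
        c = int(rng.integers(cfg.n_chroms))
        start = int(rng.integers(0, cfg.chrom_length - cfg.peak_width))
        end = start + cfg.peak_width
        starts, ends = prom_by_chrom[f"chr{c+1}"]
        i = np.searchsorted(starts, end)  # promoters starting before peak end
        if i > 0 and ends[i - 1] > start:
            continue  # overlaps a promoter; re-draw
        return GenomicInterval(f"chr{c+1}", start, end)


def gen_genome(config: GenomeConfig, seed: int) -> tuple[GenomeData, GroundTruth]:
    """Non-overlapping promoters plus per-TF/class peak sets and motif hits.

    Each peak lands inside a uniformly chosen promoter with probability
    theta (guaranteeing >= 1 bp overlap), otherwise uniformly in the
    promoter-free background. For a coupled pair ``(a, b, class)`` with
    coupling rho, each b peak is first, with probability rho, co-placed
    into a promoter already hit by a. Motif columns are Bernoulli per
    promoter; a coupled motif pair copies the first motif's indicator with
    probability rho, so the returned background holds the true marginals.
    """
    rng = _rng(seed, "genome")
    cfg = config
    promoters = _place_promoters(rng, cfg)
    prom_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in range(cfg.n_chroms):
        chrom = f"chr{c+1}"
        ivs = [p for p in promoters if p.chrom == chrom]
        prom_by_chrom[chrom] = (
            np.array([p.start for p in ivs]),
            np.array([p.end for p in ivs]),
        )
    prom_set = PromoterSet(promoters)

    coupled_b = {
        (b, cls): (a, rho) for (a, b, cls), rho in cfg.pair_coupling.items()
    }
    peaks: dict[tuple[str, str], PeakSet] = {}
    hit_promoters: dict[tuple[str, str], set[int]] = {}
    # generate uncoupled TFs first so coupling sources exist
    order = sorted(cfg.tfs, key=lambda key: (key in coupled_b, key))
    for key in order:
        tf, cls = key
        n_peaks, theta = cfg.tfs[key]
        source = coupled_b.get(key)
        src_hits: list[int] = []
        rho = 0.0
        if source is not None:
            src_key = (source[0], cls)
            if src_key not in hit_promoters:
                raise ValueError(f"coupling source {src_key} must be generated first")
            src_hits = sorted(hit_promoters[src_key])
            rho = source[1]
        ivs = []
        hits: set[int] = set()
        for _ in range(n_peaks):
            if src_hits and rng.random() < rho:
                idx = src_hits[int(rng.integers(len(src_hits)))]
                ivs.append(_peak_in_promoter(rng, promoters[idx], cfg.peak_width))
                hits.add(idx)
            elif rng.random() < theta:
                idx = int(rng.integers(cfg.n_promoters))
                ivs.append(_peak_in_promoter(rng, promoters[idx], cfg.peak_width))
                hits.add(idx)
            else:
                ivs.append(_background_peak(rng, cfg, prom_by_chrom))
        peaks[key] = PeakSet(ivs, tf=tf, tissue_class=cls)
        hit_promoters[key] = hits

    labels = sorted(cfg.motifs)
    cols: dict[str, np.ndarray] = {}
    marginals: dict[str, float] = {}
    coupled_m = {m2: (m1, rho) for (m1, m2), rho in cfg.motif_pair_coupling.items()}
    for m in labels:
        p = cfg.motifs[m]
        if m in coupled_m and coupled_m[m][0] in cols:
            m1, rho = coupled_m[m]
            copy = rng.random(cfg.n_promoters) < rho
            indep = rng.random(cfg.n_promoters) < p
            cols[m] = np.where(copy, cols[m1], indep)
            marginals[m] = rho * marginals[m1] + (1 - rho) * p
        else:
            cols[m] = rng.random(cfg.n_promoters) < p
            marginals[m] = p
    matrix = MotifHitMatrix(
        pd.DataFrame(cols, index=[p.name for p in promoters])
    )

    data = GenomeData(prom_set, peaks, matrix, marginals)
    truth = GroundTruth(
        theta={k: v[1] for k, v in cfg.tfs.items()},
        rho=dict(cfg.pair_coupling),
        motif_props=marginals,
    )
    return data, truth


# ---------------------------------------------------------------------------
# network edge lists


def gen_network(config: NetworkConfig, seed: int) -> tuple[list[InteractionEdge], GroundTruth]:
    """Random directed edge list with a planted regulator fan-in histogram.

    For each histogram entry ``k -> count``, ``count`` fresh target nodes
    each receive edges from ``k`` distinct regulators. Extra noise edges are
    drawn only among non-regulator nodes, so the planted fan-in profile is
    exact.
    """
    rng = _rng(seed, "network")
    cfg = config
    if max(cfg.fan_in_hist, default=0) > cfg.n_regulators:
        raise ValueError("fan-in exceeds the number of regulators")
    regulators = [f"TF{i+1}" for i in range(cfg.n_regulators)]
    edges: list[InteractionEdge] = []
    targets: list[str] = []
    t = 0
    for k in sorted(cfg.fan_in_hist):
        for _ in range(cfg.fan_in_hist[k]):
            name = f"T{t:03d}"
            targets.append(name)
            for r in rng.choice(cfg.n_regulators, size=k, replace=False):
                edges.append(InteractionEdge(regulators[r], name, kind="binding"))
            t += 1
    extras = [f"X{i:03d}" for i in range(cfg.n_extra_nodes)]
    pool = targets + extras
    for a in pool:
        for b in pool:
            if a != b and rng.random() < cfg.extra_edge_density:
                edges.append(InteractionEdge(a, b, kind="functional", trust="low"))
    truth = GroundTruth(
        fan_in_hist=dict(cfg.fan_in_hist), regulators=set(regulators)
    )
    return edges, truth


# ---------------------------------------------------------------------------
# one-stop simulator


class Simulator:
    """Generate every component from one root seed; write files on demand."""

    def __init__(self, config: SimulationConfig | None = None, seed: int | None = None):
        self.config = config or SimulationConfig()
        self.seed = self.config.seed if seed is None else int(seed)

    def expression(self):
        return gen_expression(self.config.expression, self.seed)

    def hit_table(self):
        return gen_hit_table(self.config.literature, self.seed)

    def genome(self):
        return gen_genome(self.config.genome, self.seed)

    def network(self):
        return gen_network(self.config.network, self.seed)

    def write_all(self, outdir) -> None:
        from .occupancy import write_bed

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables, _ = self.expression()
        for model, df in tables.items():
            df.to_csv(out / f"expression_{model}.tsv", sep="\t", index=False)
        table, _ = self.hit_table()
        table.to_tsv(out / "hit_table.tsv")
        genome, _ = self.genome()
        write_bed(genome.promoters.intervals, out / "promoters.bed")
        for (tf, cls), ps in genome.peaks.items():
            write_bed(ps.intervals, out / f"peaks_{tf}_{cls}.bed")
        genome.motif_matrix.to_tsv(out / "motif_hits.tsv")
        edges, _ = self.network()
        pd.DataFrame(
            [(e.source, e.target, e.kind, e.trust) for e in edges],
            columns=["source", "target", "kind", "trust"],
        ).to_csv(out / "edges.tsv", sep="\t", index=False)
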