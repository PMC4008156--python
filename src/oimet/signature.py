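"""Differential-expression signatures and regulation-pattern calls.

The OI-MET (OVOL-induced mesenchymal-to-epithelial transition) signature is
built from CuffDiff-style differential-expression tables for two cancer
models (breast, BC; prostate, PC), each treated by over-expressing OVOL1,
OVOL2, or both. A gene enters a model's signature when at least one of its
features passes, in at least one treatment, the selection thresholds
("OK" test status, FDR <= 0.05, linear fold change >= 2.0 or <= 0.5).
The cross-model signature is the intersection of the two model signatures;
its concordance is the fraction of intersection genes moving the same way
(both up or both down) under the double-OVOL treatment in both models.

Regulation calls on individual genes use looser descriptive thresholds
(up: any fold >= 1.5; down: any fold <= 0.67) and, for multi-isoform genes,
an isoform *switch* is called when one isoform is up while another is down
within the same treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

FC_CLAMP = (0.0, 10.0)  # reported linear ratios are capped at these bounds

#: canonical column order for differential-expression tables
DE_COLUMNS = [
    "feature_id",
    "level",
    "gene_symbol",
    "model",
    "treatment",
    "fold_change",
    "fdr",
    "status",
]

TREATMENTS = ("OVOL1", "OVOL2", "OVOL1and2")


@dataclass(frozen=True)
class Thresholds:
    """Signature-selection thresholds; ties are inclusive on every bound."""

    fdr_max: float = 0.05
    fc_high: float = 2.0
    fc_low: float = 0.5
    status_required: str = "OK"

    def __post_init__(self) -> None:
        if self.fdr_max <= 0 or self.fc_high <= 0 or self.fc_low <= 0:
            raise ValueError("thresholds must be positive")
        if not self.fc_low < 1 < self.fc_high:
            raise ValueError("require fc_low < 1 < fc_high")


@dataclass
class SignatureSet:
    model: str
    genes: set[str]
    thresholds: Thresholds


@dataclass
class IntersectionSignature:
    genes: set[str]
    concordance_fraction: float
    n_with_folds: int
    n_missing_folds: int


@dataclass
class RegulationCall:
    gene_symbol: str
    model: str
    call: str  # Up | Down | UpDown | Switch | none
    evidence: list[tuple[str, str, float]] = field(default_factory=list)


def clamp_fold(fc: float) -> float:
    lo, hi = FC_CLAMP
    return min(hi, max(lo, fc))


def read_diffexpr_table(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a differential-expression TSV into the canonical record layout.

    ``column_map`` renames source columns (e.g. a CuffDiff ``gene_exp.diff``
    dialect) onto the canonical names. A ``log2fc`` column, if present after
    mapping, is converted to a linear ratio and clamped to [0, 10] — CuffDiff
    reports log2 ratios natively, and infinite log ratios (zero numerator or
    denominator) land on the clamp bounds rather than being dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "gene_symbol": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    if "log2fc" in df.columns and "fold_change" not in df.columns:
        df["fold_change"] = (2.0 ** df["log2fc"].astype(float)).map(clamp_fold)
        df = df.drop(columns=["log2fc"])
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = df[DE_COLUMNS].copy()
    validate_records(df)
    return df


def validate_records(df: pd.DataFrame) -> None:
    bad_fc = df["fold_change"] < 0
    if bad_fc.any():
        ident = df.loc[bad_fc, "feature_id"].iloc[0]
        raise ValueError(f"negative fold change for feature {ident!r}")
    bad_fdr = (df["fdr"] < 0) | (df["fdr"] > 1)
    if bad_fdr.any():
        ident = df.loc[bad_fdr, "feature_id"].iloc[0]
        raise ValueError(f"FDR outside [0, 1] for feature {ident!r}")
    iso = df["level"] == "isoform"
    no_gene = iso & (df["gene_symbol"].isna() | (df["gene_symbol"] == ""))
    if no_gene.any():
        ident = df.loc[no_gene, "feature_id"].iloc[0]
        raise ValueError(f"isoform record {ident!r} lacks a gene symbol")


def select_de_features(records: pd.DataFrame, thresholds: Thresholds) -> set[str]:
    """Feature ids passing status, FDR and fold-change thresholds.

    A feature is selected when ``status == status_required`` and
    ``fdr <= fdr_max`` and the linear fold change is ``>= fc_high`` or
    ``<= fc_low`` (both comparisons inclusive).
    """
    if len(records) == 0:
        return set()
    validate_records(records)
    m = (
        (records["status"] == thresholds.status_required)
        & (records["fdr"] <= thresholds.fdr_max)
        & (
            (records["fold_change"] >= thresholds.fc_high)
            | (records["fold_change"] <= thresholds.fc_low)
        )
    )
    return set(records.loc[m, "feature_id"])


def build_model_signature(
    per_treatment_sets: Mapping[str, Iterable[str]],
    gene_map: Mapping[str, str],
    model: str = "",
    thresholds: Thresholds | None = None,
) -> SignatureSet:
    """Union of genes responsive to any treatment (feature ids mapped to genes)."""
    genes: set[str] = set()
    for treatment, features in per_treatment_sets.items():
        for fid in features:
            if fid not in gene_map:
                raise ValueError(f"feature {fid!r} ({treatment}) has no gene mapping")
            genes.add(gene_map[fid])
    return SignatureSet(model=model, genes=genes, thresholds=thresholds or Thresholds())


def intersect_signatures(
    sig_a: SignatureSet,
    sig_b: SignatureSet,
    ovol12_folds: Mapping[str, tuple[float, float]],
) -> IntersectionSignature:
    """Cross-model signature and its direction concordance.

    Concordance counts genes whose double-OVOL fold changes move the same way
    in both models (both > 1 or both < 1); genes without a fold pair are
    excluded from the denominator and counted separately. Direction is
    ignored for membership itself.
    """
    genes = sig_a.genes & sig_b.genes
    concordant = 0
    with_folds = 0
    for g in genes:
        pair = ovol12_folds.get(g)
        if pair is None:
            continue
        fa, fb = pair
        with_folds += 1
        if (fa > 1 and fb > 1) or (fa < 1 and fb < 1):
            concordant += 1
    frac = concordant / with_folds if with_folds else math.nan
    return IntersectionSignature(
        genes=genes,
        concordance_fraction=frac,
        n_with_folds=with_folds,
        n_missing_folds=len(genes) - with_folds,
    )


def call_regulation(
    gene_folds: Mapping[str, float] | Iterable[float],
    up_threshold: float = 1.5,
    down_threshold: float = 0.67,
) -> str:
    """Up / Down / UpDown / none from per-treatment fold changes at one level."""
    if isinstance(gene_folds, Mapping):
        folds = list(gene_folds.values())
    else:
        folds = list(gene_folds)
    if not folds:
        raise ValueError("at least one fold value required")
    if any(f < 0 for f in folds):
        raise ValueError("negative fold change")
    up = any(f >= up_threshold for f in folds)
    down = any(f <= down_threshold for f in folds)
    if up and down:
        return "UpDown"
    if up:
        return "Up"
    if down:
        return "Down"
    return "none"


def call_isoform_switch(
    isoform_folds: Mapping[str, Iterable[float]],
    up_threshold: float = 1.5,
    down_threshold: float = 0.67,
) -> str:
    """Switch iff, in some treatment, one isoform is up while another is down.

    Fold sequences are aligned by position (same treatment order for every
    isoform). Single-isoform genes can never switch.
    """
    series = {iso: list(folds) for iso, folds in isoform_folds.items()}
    if len(series) < 2:
        return "none"
    n_treat = {len(v) for v in series.values()}
    if len(n_treat) != 1:
        raise ValueError("isoforms must report the same treatments")
    for t in range(n_treat.pop()):
        ups = [iso for iso, v in series.items() if v[t] >= up_threshold]
        downs = [iso for iso, v in series.items() if v[t] <= down_threshold]
        if any(u != d for u in ups for d in downs):
            return "Switch"
    return "none"


def build_signature_pipeline(
    tables: Mapping[str, pd.DataFrame],
    thresholds: Thresholds | None = None,
    level: str = "gene",
) -> tuple[dict[str, SignatureSet], IntersectionSignature]:
    """End-to-end: two model tables -> per-model signatures -> intersection.

    ``tables`` maps a model label to its record table (all treatments
    stacked). Selection runs at ``level`` only ("test OK" is required at the
    level being selected). The double-OVOL gene-level fold changes feed the
    concordance computation.
    """
    thresholds = thresholds or Thresholds()
    sigs: dict[str, SignatureSet] = {}
    folds: dict[str, dict[str, float]] = {}
    for model, df in tables.items():
        sub = df[df["level"] == level]
        per_treatment = {
            t: select_de_features(sub[sub["treatment"] == t], thresholds)
            for t in sorted(sub["treatment"].unique())
        }
        gene_map = dict(zip(sub["feature_id"], sub["gene_symbol"]))
        sigs[model] = build_model_signature(per_treatment, gene_map, model, thresholds)
        g12 = df[(df["level"] == "gene") & (df["treatment"] == "OVOL1and2")]
        folds[model] = dict(zip(g12["gene_symbol"], g12["fold_change"]))
    if len(sigs) != 2:
        raise ValueError("expected exactly two model tables")
    (ma, sa), (mb, sb) = sigs.items()
    pair_folds = {
        g: (folds[ma][g], folds[mb][g])
        for g in sa.genes & sb.genes
        if g in folds[ma] and g in folds[mb]
    }
    return sigs, intersect_signatures(sa, sb, pair_folds)


def call_table(df: pd.DataFrame, up_threshold: float = 1.5, down_threshold: float = 0.67) -> pd.DataFrame:
    """Per-gene regulation calls (gene and isoform level) for one record table.

    Returns rows (gene, model, level, call); the isoform-level row reports
    Switch when the switch rule fires, otherwise the pooled isoform call.
    """
    out = []
    for (gene, model), grp in df.groupby(["gene_symbol", "model"], sort=True):
        g = grp[grp["level"] == "gene"].sort_values("treatment")
        if len(g):
            out.append(
                (gene, model, "gene", call_regulation(list(g["fold_change"]), up_threshold, down_threshold))
            )
        iso = grp[grp["level"] == "isoform"]
        if len(iso):
            per_iso = {
                fid: list(sub.sort_values("treatment")["fold_change"])
                for fid, sub in iso.groupby("feature_id")
            }
            call = call_isoform_switch(per_iso, up_threshold, down_threshold)
            if call == "none":
                call = call_regulation(
                    [f for v in per_iso.values() for f in v], up_threshold, down_threshold
                )
            out.append((gene, model, "isoform", call))
    return pd.DataFrame(out, columns=["gene", "model", "level", "call"])
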