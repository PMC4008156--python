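"""Literature co-occurrence enrichment.

A gene set is scored against a gene-by-term *hit table*: a boolean matrix
over a gene universe (HGNC symbols) where a cell is 1 when at least one
publication co-mentions the gene symbol and the term. Enrichment is tested
two ways:

* a resampling empirical p-value — draw ``n_iter`` random gene sets of the
  same size from the universe (without replacement within a draw) and rank
  the observed hit proportion among the null proportions; and
* a 2x2 contingency chi-square of the set's hits against the hits in the
  rest of the universe.

Query strings for NCBI E-utilities follow a fixed grammar: three case
variants of the HGNC symbol OR-ed as ``[Text Word]``, AND-ed with the term's
clauses (``[Text Word]`` or ``[MeSH Terms]``). The live client is optional
and disk-cached; hit tables on disk are the default path.
"""

from __future__ import annotations

import json
import math
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import EnrichmentResult, chi2_2x2


@dataclass(frozen=True)
class TermSpec:
    """A literature term: one or more (phrase, field) clauses OR-ed together."""

    label: str
    clauses: tuple[tuple[str, str], ...]  # (phrase, "TextWord" | "MeSH")
    database: str = "PubMed"  # PubMed | PMC

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError("a term needs at least one clause")
        for phrase, fld in self.clauses:
            if not phrase:
                raise ValueError("empty phrase in term clause")
            if fld not in ("TextWord", "MeSH"):
                raise ValueError(f"unknown clause field {fld!r}")


@dataclass
class ResamplingNull:
    n_iter: int
    set_size: int
    seed: int | None
    null_props: np.ndarray

    def __post_init__(self) -> None:
        if len(self.null_props) != self.n_iter:
            raise ValueError("null_props length must equal n_iter")


class HitTable:
    """Boolean gene-by-term co-occurrence matrix over an ordered gene universe."""

    def __init__(self, data: pd.DataFrame):
        df = data.astype(bool)
        if df.index.has_duplicates:
            raise ValueError("duplicate gene symbols in universe")
        self.data = df

    @property
    def universe(self) -> list[str]:
        return list(self.data.index)

    @property
    def terms(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_tsv(cls, path) -> "HitTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.data.astype(int).to_csv(path, sep="\t")

    def _check_genes(self, gene_set: Iterable[str]) -> list[str]:
        genes = list(gene_set)
        missing = sorted(set(genes) - set(self.data.index))
        if missing:
            raise ValueError(f"genes outside universe: {missing[:10]}" +
                             (" ..." if len(missing) > 10 else ""))
        return genes


def symbol_variants(symbol: str) -> list[str]:
    """Distinct case variants, in query order: as-given, UPPER, lower, Capitalized."""
    out: list[str] = []
    for v in (symbol, symbol.upper(), symbol.lower(), symbol.capitalize()):
        if v not in out:
            out.append(v)
    return out


def build_query(gene_symbol: str, term: TermSpec) -> str:
    """Render the E-utilities query for one gene symbol against one term."""
    if not gene_symbol:
        raise ValueError("empty gene symbol")
    sym = " OR ".join(f'"{v}"[Text Word]' for v in symbol_variants(gene_symbol))
    fields = {"TextWord": "Text Word", "MeSH": "MeSH Terms"}
    clauses = " OR ".join(f'"{p}"[{fields[f]}]' for p, f in term.clauses)
    return f"({sym}) AND ({clauses})"


def count_cooccurrence(table: HitTable, gene_set: Iterable[str], term: str) -> int:
    """Number of set genes with at least one publication hit for ``term``."""
    genes = table._check_genes(gene_set)
    if term not in table.data.columns:
        raise ValueError(f"unknown term {term!r}")
    return int(table.data.loc[genes, term].sum())


def resampling_pvalue(
    table: HitTable,
    observed_set: Iterable[str],
    term: str,
    n_iter: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, ResamplingNull, float]:
    """Empirical p-value of the observed hit proportion against random sets.

    Random sets are drawn uniformly from the full universe, without
    replacement within each draw and independently across the ``n_iter``
    draws. The estimator is ``(1 + #{null >= observed}) / (n_iter + 1)``;
    ties count toward the null (conservative), and p can never be exactly 0.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    genes = table._check_genes(observed_set)
    k = len(genes)
    universe = table.data.index
    if k > len(universe):
        raise ValueError("observed set larger than universe")
    col = table.data[term].to_numpy()
    observed_prop = float(col[table.data.index.get_indexer(genes)].mean()) if k else 0.0
    if rng is None:
        rng = np.random.default_rng(seed)
    null_props = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.choice(len(universe), size=k, replace=False)
        null_props[i] = col[idx].mean()
    p = (1 + int((null_props >= observed_prop).sum())) / (n_iter + 1)
    return observed_prop, ResamplingNull(n_iter, k, seed, null_props), p


def contingency_enrichment(k_set: int, n_set: int, k_bg: int, n_bg: int) -> EnrichmentResult:
    """Chi-square enrichment of set hits against the rest of the universe.

    ``(k_bg, n_bg)`` are whole-background counts (set included); the fold is
    the ratio of the set proportion to the whole-background proportion, as
    conventionally reported, while the 2x2 test contrasts the set with its
    complement to avoid double counting.
    """
    if min(k_set, n_set, k_bg, n_bg) < 0:
        raise ValueError("counts must be non-negative")
    if k_set > k_bg or n_set > n_bg:
        raise ValueError("set counts exceed background counts")
    res = EnrichmentResult.from_counts("", k_set, n_set, k_bg, n_bg, method="chisq")
    table = [
        [k_set, n_set - k_set],
        [k_bg - k_set, (n_bg - n_set) - (k_bg - k_set)],
    ]
    res.statistic, res.p_value = chi2_2x2(table)
    return res


class EntrezClient:
    """Minimal, rate-limited, disk-cached esearch client (optional live path).

    Hits ``esearch.fcgi`` with ``rettype=count``; at most ``max_per_second``
    requests per second. Responses are cached as JSON under ``cache_dir`` so
    repeated runs never re-query. Not exercised by the test suite.
    """

    BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"
    DATABASES = {"PubMed": "pubmed", "PMC": "pmc"}

    def __init__(self, cache_dir: str | Path = "~/.cache/oimet-eutils",
                 api_key: str | None = None, max_per_second: float = 3.0):
        self.cache_dir = Path(cache_dir).expanduser()
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        self.api_key = api_key
        self.min_interval = 1.0 / max_per_second
        self._last = 0.0

    def count(self, gene_symbol: str, term: TermSpec) -> int:
        query = build_query(gene_symbol, term)
        key = urllib.parse.quote_plus(f"{term.database}:{query}")[:200]
        cached = self.cache_dir / f"{key}.json"
        if cached.exists():
            return json.loads(cached.read_text())["count"]
        params = {
            "db": self.DATABASES[term.database],
            "term": query,
            "rettype": "count",
            "retmode": "json",
        }
        if self.api_key:
            params["api_key"] = self.api_key
        wait = self.min_interval - (time.monotonic() - self._last)
        if wait > 0:
            time.sleep(wait)
        url = f"{self.BASE}?{urllib.parse.urlencode(params)}"
        with urllib.request.urlopen(url, timeout=30) as fh:
            payload = json.load(fh)
        self._last = time.monotonic()
        n = int(payload["esearchresult"]["count"])
        cached.write_text(json.dumps({"count": n, "query": query}))
        return n

    def hit_table(self, genes: Sequence[str], terms: Sequence[TermSpec]) -> HitTable:
        data = {
            t.label: [self.count(g, t) > 0 for g in genes] for t in terms
        }
        return HitTable(pd.DataFrame(data, index=list(genes)))
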