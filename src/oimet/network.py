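"""Parsimonious seed-gene networks over a directed interaction edge list.

Given a set of seed genes and a TF-target edge list, the builder keeps every
direct seed-to-seed edge and then connects additional seed pairs through at
most one non-seed intermediate, mirroring a shortest-paths construction with
a one-step cap. Intermediates are chosen greedily: at each step the
candidate connecting the most still-unconnected seed pairs is added
(lexicographic label order breaks ties, for determinism). Seeds that end up
with no qualifying connection are reported rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class InteractionEdge:
    source: str
    target: str
    kind: str = ""
    trust: str = ""


@dataclass
class TFNetwork:
    seed_nodes: set[str]
    intermediate_nodes: set[str]
    edges: set[InteractionEdge]
    disconnected_seeds: set[str]
    graph: nx.DiGraph = field(default_factory=nx.DiGraph, repr=False)


def read_edge_list(path) -> list[InteractionEdge]:
    """Edge list TSV with columns source, target and optional kind, trust."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("source", "target"):
        if col not in df.columns:
            raise ValueError(f"edge list missing column {col!r}")
    return [
        InteractionEdge(r["source"], r["target"], r.get("kind", ""), r.get("trust", ""))
        for _, r in df.iterrows()
    ]


def build_parsimonious_network(
    seeds: Iterable[str],
    edges: Iterable[InteractionEdge],
    max_intermediate: int = 1,
    directed: bool = True,
) -> TFNetwork:
    """Connect seeds with direct edges plus greedily chosen 1-step bridges.

    With ``max_intermediate=0`` the result is exactly the seed-induced
    subgraph. With ``directed=False`` edges are treated as undirected when
    looking for bridges (an s-u-t path may use the edges in either
    orientation).
    """
    seed_set = set(seeds)
    if not seed_set:
        raise ValueError("seeds must be non-empty")
    if max_intermediate not in (0, 1):
        raise ValueError("max_intermediate must be 0 or 1")
    edge_list = list(edges)
    self_loops = [e for e in edge_list if e.source == e.target]
    if self_loops:
        import warnings

        warnings.warn(f"{len(self_loops)} self-loop edge(s) present")

    kept: set[InteractionEdge] = {
        e for e in edge_list if e.source in seed_set and e.target in seed_set
    }
    intermediates: set[str] = set()

    if max_intermediate == 1:
        # candidate bridge u: seed -> u and u -> seed (any orientation when
        # undirected); it covers the unordered seed pairs it joins
        in_from: dict[str, set[str]] = {}
        out_to: dict[str, set[str]] = {}
        for e in edge_list:
            if e.source in seed_set and e.target not in seed_set:
                in_from.setdefault(e.target, set()).add(e.source)
            if e.target in seed_set and e.source not in seed_set:
                out_to.setdefault(e.source, set()).add(e.target)
        coverage: dict[str, set[frozenset[str]]] = {}
        for u in set(in_from) | set(out_to):
            srcs = in_from.get(u, set())
            dsts = out_to.get(u, set())
            if directed:
                pairs = {frozenset((s, t)) for s in srcs for t in dsts if s != t}
            else:
                touched = srcs | dsts
                pairs = {frozenset((s, t)) for s in touched for t in touched if s != t}
            if pairs:
                coverage[u] = pairs
        already = {frozenset((e.source, e.target)) for e in kept if e.source != e.target}
        uncovered = set().union(*coverage.values()) - already if coverage else set()
        while uncovered:
            best = max(
                sorted(coverage),
                key=lambda u: (len(coverage[u] & uncovered), ),
            )
            # max() keeps the first of equal keys; sorted() gives lexicographic ties
            gain = coverage[best] & uncovered
            if not gain:
                break
            intermediates.add(best)
            uncovered -= gain
            for e in edge_list:
                if (e.source == best and e.target in seed_set) or (
                    e.target == best and e.source in seed_set
                ):
                    kept.add(e)

    graph = nx.DiGraph()
    graph.add_nodes_from(seed_set, role="seed")
    graph.add_nodes_from(intermediates, role="intermediate")
    for e in kept:
        graph.add_edge(e.source, e.target, kind=e.kind, trust=e.trust)
    connected = {
        s for e in kept for s in (e.source, e.target) if s in seed_set
        if e.source != e.target
    }
    return TFNetwork(
        seed_nodes=seed_set,
        intermediate_nodes=intermediates,
        edges=kept,
        disconnected_seeds=seed_set - connected,
        graph=graph,
    )


def regulator_fanout(
    edges: Iterable[InteractionEdge] | TFNetwork,
    regulators: Iterable[str],
) -> tuple[dict[str, int], dict[int, int]]:
    """Distinct-regulator counts per target and the k -> #targets histogram.

    Only direct regulator -> target edges count; regulator nodes themselves
    are excluded from the targets. Targets with no regulating TF are not
    reported.
    """
    if isinstance(edges, TFNetwork):
        edge_list = list(edges.edges)
    else:
        edge_list = list(edges)
    reg_set = set(regulators)
    nodes = {e.source for e in edge_list} | {e.target for e in edge_list}
    missing = reg_set - nodes
    if missing:
        import warnings

        warnings.warn(f"regulators absent from edge list: {sorted(missing)}")
    per_target: dict[str, set[str]] = {}
    for e in edge_list:
        if e.source in reg_set and e.target not in reg_set:
            per_target.setdefault(e.target, set()).add(e.source)
    counts = {t: len(rs) for t, rs in per_target.items()}
    hist: dict[int, int] = {}
    for k in counts.values():
        hist[k] = hist.get(k, 0) + 1
    return counts, hist


def to_graphml(network: TFNetwork, path) -> None:
    nx.write_graphml(network.graph, path)
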