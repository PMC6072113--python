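"""Characterization of an inferred ceRNA network: degree/power-law fit,
multilevel modularity clustering, module gene-set enrichment, hub calling,
and overlap counting against external interaction sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .cerna_infer import CeRNAPair, hypergeom_shared_pvalue
from .core_io import GeneSetCollection, InteractionTable
from .preprocess import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "build_network",
    "powerlaw_loglog_fit",
    "loglog_degree_fit",
    "detect_modules",
    "enrich_modules",
    "call_hubs",
    "overlap_with_interactions",
    "gene_set_hypergeom",
    "node_table",
]


def build_network(pairs: list[CeRNAPair] | list[tuple[str, str]]) -> nx.Graph:
    """Undirected simple graph from final ceRNA pairs."""
    g = nx.Graph()
    for p in pairs:
        if isinstance(p, CeRNAPair):
            g.add_edge(p.rna_i, p.rna_j)
        else:
            a, b = p
            g.add_edge(a, b)
    return g


def powerlaw_loglog_fit(network: nx.Graph) -> tuple[float, float, float]:
    """Least-squares line through (ln k, ln p(k)) over observed degrees.

    p(k) is the empirical degree probability #{nodes of degree k} / #nodes,
    degree-0 nodes excluded.  Returns (slope, intercept, r_squared).
    """
    degrees = np.array([d for _, d in network.degree() if d > 0])
    ks, counts = np.unique(degrees, return_counts=True)
    if ks.size < 3:
        raise ValueError("need at least 3 distinct positive degrees")
    pk = counts / network.number_of_nodes()
    return loglog_degree_fit(ks, pk)


def loglog_degree_fit(ks, pks) -> tuple[float, float, float]:
    """Least-squares line through (ln k, ln p(k)) for given degree
    probabilities (the kernel behind :func:`powerlaw_loglog_fit`)."""
    ks = np.asarray(ks, dtype=float)
    pks = np.asarray(pks, dtype=float)
    if ks.size < 3:
        raise ValueError("need at least 3 distinct degrees")
    x = np.log(ks)
    y = np.log(pks)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def detect_modules(network: nx.Graph, seed: int = 0) -> dict[str, int]:
    """Multilevel (Louvain) modularity clustering.

    Asserts that modularity does not decrease across merge levels and that
    the final partition is at least as modular as all-singletons.
    Deterministic under a fixed seed.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if network.number_of_edges() == 0:
        return {n: i for i, n in enumerate(sorted(network.nodes))}
    prev_q = -np.inf
    partition = None
    for level in nx.community.louvain_partitions(network, seed=seed):
        q = nx.community.modularity(network, level)
        assert q >= prev_q - 1e-12, "modularity decreased across levels"
        prev_q = q
        partition = level
    singleton_q = nx.community.modularity(
        network, [{n} for n in network.nodes]
    )
    assert prev_q >= singleton_q - 1e-12
    modules = sorted(partition, key=lambda c: sorted(c)[0])
    return {n: i for i, comm in enumerate(modules) for n in comm}


def enrich_modules(
    assignment: dict[str, int],
    sets: GeneSetCollection,
    universe: set[str],
    min_module_size: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set in each
    module of size >= min_module_size, BH-adjusted across all tests jointly.
    """
    members = set(assignment)
    if not members <= universe:
        raise ValueError("universe must contain every module member")
    modules: dict[int, set[str]] = {}
    for node, mid in assignment.items():
        modules.setdefault(mid, set()).add(node)
    rows = []
    n_universe = len(universe)
    for mid, mod in sorted(modules.items()):
        if len(mod) < min_module_size:
            continue
        for name in sets.names():
            gene_set = set(sets.members(name)) & universe
            if not gene_set:
                logger.warning("gene set %r disjoint from universe; skipped", name)
                continue
            overlap = len(mod & gene_set)
            if overlap == 0:
                p = 1.0
            else:
                p = hypergeom_shared_pvalue(
                    n_universe, len(mod), len(gene_set), overlap
                )
            rows.append(
                {
                    "module_id": mid,
                    "set_name": name,
                    "overlap_count": overlap,
                    "module_size": len(mod),
                    "set_size": len(gene_set),
                    "universe_size": n_universe,
                    "p": p,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "module_id", "set_name", "overlap_count", "module_size",
            "set_size", "universe_size", "p",
        ],
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["p_adj"] < alpha if len(out) else []
    return out


def call_hubs(network: nx.Graph, quantile: float = 0.90) -> set[str]:
    """Nodes whose degree is at or above the given quantile of the distinct
    degree values (so a star's leaves are never hubs, and an all-equal-degree
    graph makes every node a hub)."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes, degrees = zip(*network.degree())
    threshold = np.quantile(np.unique(np.array(degrees, dtype=float)), quantile)
    return {n for n, d in zip(nodes, degrees) if d >= threshold}


def overlap_with_interactions(
    network: nx.Graph, other: InteractionTable
) -> tuple[int, float]:
    """Count network edges present (as unordered pairs) in another
    interaction set; also return the fraction of network edges covered."""
    other_pairs = {frozenset(p) for p in other.pairs}
    count = sum(1 for e in network.edges if frozenset(e) in other_pairs)
    n_edges = network.number_of_edges()
    return count, (count / n_edges if n_edges else 0.0)


def gene_set_hypergeom(
    hits: set[str], category: set[str], universe: set[str]
) -> float:
    """Over-representation p of ``hits`` in ``category`` within ``universe``
    (same kernel as the shared-miRNA test)."""
    if not hits <= universe or not category <= universe:
        raise ValueError("hits and category must be subsets of the universe")
    overlap = len(hits & category)
    if overlap == 0:
        return 1.0
    return hypergeom_shared_pvalue(len(universe), len(hits), len(category), overlap)


def node_table(
    network: nx.Graph,
    assignment: dict[str, int] | None = None,
    hubs: set[str] | None = None,
    kinds: dict[str, str] | None = None,
) -> pd.DataFrame:
    assignment = assignment or {}
    hubs = hubs or set()
    kinds = kinds or {}
    rows = [
        {
            "node": n,
            "kind": kinds.get(n, ""),
            "degree": d,
            "module_id": assignment.get(n, -1),
            "is_hub": n in hubs,
        }
        for n, d in sorted(network.degree())
    ]
    return pd.DataFrame(
        rows, columns=["node", "kind", "degree", "module_id", "is_hub"]
    )
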