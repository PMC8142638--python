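"""Protein-interaction connectivity analysis of gene groups.

Given a confidence-filtered undirected interaction network and a gene set:
count the edges and connected members of the induced subgraph, compare the
edge count with its expectation under a degree-sequence-preserving random
graph null (configuration model), and report a p-value — analytically via
a Poisson upper tail on the configuration-model expectation, or by
degree-preserving Monte-Carlo rewiring (double-edge swaps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import StressmetaError

__all__ = [
    "NetworkStats",
    "filter_edges",
    "to_graph",
    "induced_subgraph_stats",
    "connectivity_test",
]

logger = logging.getLogger(__name__)


@dataclass
class NetworkStats:
    set_size: int
    n_in_network: int
    observed_edges: int
    n_connected: int
    expected_edges: float
    p_value: float
    method: str
    n_samples: int = 0
    seed: int | None = None
    expected_edges_uncapped: float | None = None
    note: str = ""

    def as_dict(self) -> dict:
        out = {
            "set_size": self.set_size,
            "n_in_network": self.n_in_network,
            "observed_edges": self.observed_edges,
            "n_connected": self.n_connected,
            "expected_edges": self.expected_edges,
            "p_value": self.p_value,
            "method": self.method,
            "n_samples": self.n_samples,
            "seed": self.seed,
        }
        if self.expected_edges_uncapped is not None:
            out["expected_edges_uncapped"] = self.expected_edges_uncapped
        if self.note:
            out["note"] = self.note
        return out


def filter_edges(edges: pd.DataFrame, min_confidence: float = 0.9) -> pd.DataFrame:
    """Keep edges with confidence >= min_confidence."""
    if ((edges["confidence"] < 0) | (edges["confidence"] > 1)).any():
        raise StressmetaError("edge confidences must lie in [0, 1]")
    return edges[edges["confidence"] >= min_confidence].reset_index(drop=True)


def to_graph(edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from(zip(edges["node_a"], edges["node_b"]))
    if any(g.has_edge(n, n) for n in g):
        raise StressmetaError("edge list contains a self-loop")
    return g


def induced_subgraph_stats(edges: pd.DataFrame | nx.Graph, gene_set) -> tuple[int, int]:
    """(edges within the set, members with >= 1 within-set edge)."""
    g = edges if isinstance(edges, nx.Graph) else to_graph(edges)
    sub = g.subgraph(set(gene_set) & set(g.nodes))
    observed = sub.number_of_edges()
    connected = sum(1 for n in sub if sub.degree(n) > 0)
    return observed, connected


def _analytic_expected(g: nx.Graph, members: list, cap: bool = True) -> float:
    """Degree-sequence-null expected within-set edges.

    Per-pair expectation is the configuration-model term k_i k_j / (2m),
    rescaled so the whole-graph expectation equals m exactly — the
    degree-preserving null conserves the edge count, and the raw pair
    formula sums to m - sum(k^2)/(4m) instead.  ``cap`` limits each pair's
    expectation at 1 (a simple graph holds at most one edge per pair).
    """
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    k_all = np.array([d for _, d in g.degree()], dtype=float)
    total_pair_mass = m - (k_all ** 2).sum() / (4.0 * m)
    k = np.array([g.degree(n) for n in members], dtype=float)
    per_pair_scale = (m / total_pair_mass) / (2.0 * m) if total_pair_mass > 0 else 1.0 / (2.0 * m)
    if not cap:
        return float(((k.sum() ** 2 - (k ** 2).sum()) / 2.0) * per_pair_scale)
    total = 0.0
    n = len(k)
    chunk = 2000  # bound the outer-product block to ~16 MB
    cols = np.arange(n)[None, :]
    for start in range(0, n, chunk):
        block = k[start:start + chunk]
        prod = np.minimum(1.0, np.outer(block, k) * per_pair_scale)
        rows = np.arange(start, start + len(block))[:, None]
        total += prod[cols > rows].sum()
    return float(total)


def connectivity_test(
    edges: pd.DataFrame | nx.Graph,
    gene_set,
    method: str = "analytic",
    n_samples: int = 1000,
    n_swaps: int | None = None,
    seed: int | None = None,
) -> NetworkStats:
    """Test whether a gene set is more connected than its degrees predict.

    analytic: expected = sum over member pairs of min(1, k_i*k_j / 2m);
    p = Poisson upper tail P(X >= observed) at that mean.  The uncapped sum
    is reported alongside when it differs by more than 1%.

    montecarlo: expectation and p estimated from ``n_samples``
    degree-preserving rewirings of the full network (``n_swaps`` double-edge
    swaps between consecutive samples, default 2m); falls back to analytic
    when the graph cannot be rewired.
    """
    g = edges if isinstance(edges, nx.Graph) else to_graph(edges)
    gene_set = set(gene_set)
    members = sorted(gene_set & set(g.nodes))
    if not members:
        raise StressmetaError("gene set shares no nodes with the network")
    if method not in ("analytic", "montecarlo"):
        raise StressmetaError(f"method must be analytic|montecarlo, got {method!r}")
    observed, connected = induced_subgraph_stats(g, members)

    capped = _analytic_expected(g, members, cap=True)
    uncapped = _analytic_expected(g, members, cap=False)
    report_uncapped = uncapped if capped > 0 and abs(uncapped - capped) / capped > 0.01 else None

    if method == "analytic":
        p = float(stats.poisson.sf(observed - 1, capped)) if capped > 0 else (
            1.0 if observed == 0 else 0.0)
        return NetworkStats(
            set_size=len(gene_set), n_in_network=len(members),
            observed_edges=observed, n_connected=connected,
            expected_edges=capped, p_value=p, method="analytic",
            expected_edges_uncapped=report_uncapped,
        )

    if n_samples < 100:
        logger.warning("montecarlo with n_samples=%d < 100 is unreliable", n_samples)
    m = g.number_of_edges()
    swaps = n_swaps if n_swaps is not None else max(1, 2 * m)
    rng_seed = (int(seed) & 0x7FFFFFFF) if seed is not None else None
    h = nx.Graph(g)
    counts = np.empty(n_samples)
    try:
        for i in range(n_samples):
            nx.double_edge_swap(h, nswap=swaps, max_tries=swaps * 100,
                                seed=None if rng_seed is None else rng_seed + i)
            counts[i], _ = induced_subgraph_stats(h, members)
    except nx.NetworkXError as exc:
        logger.warning("rewiring failed (%s); falling back to analytic", exc)
        result = connectivity_test(g, gene_set, method="analytic")
        result.note = f"montecarlo rewiring failed ({exc}); analytic fallback"
        return result
    expected = float(counts.mean())
    p = float((1 + (counts >= observed).sum()) / (n_samples + 1))
    return NetworkStats(
        set_size=len(gene_set), n_in_network=len(members),
        observed_edges=observed, n_connected=connected,
        expected_edges=expected, p_value=p, method="montecarlo",
        n_samples=n_samples, seed=seed,
        expected_edges_uncapped=report_uncapped,
    )
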