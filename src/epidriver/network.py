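"""Protein-interaction network handling and neighborhood enrichment.

Each candidate gene is scored by asking whether its direct neighbors in
the interaction network are over-represented in the EI/ES gene set,
using the one-sided Fisher exact test on the 2x2 table

    [[a, b], [K - a, N - K - b]]

with a = neighbors in the set, b = other neighbors, K = set members in
the network, N = network genes. The p-value is the upper hypergeometric
tail P(X >= a) with population N, K successes and a+b draws, computed
exactly through log-gamma factorials. Drivers are genes with adjusted
p < 0.05 and an EI/ES neighbor proportion a/(a+b) strictly above 10%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from math import exp, lgamma

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .differential import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DriverCriteria:
    fdr_threshold: float = 0.05
    proportion_threshold: float = 0.10

    def __post_init__(self) -> None:
        for v in (self.fdr_threshold, self.proportion_threshold):
            if not 0 < v < 1:
                raise ValueError("criteria thresholds must lie in (0, 1)")


@dataclass
class NeighborEnrichment:
    """One row of the driver-selection table."""

    gene_id: str
    ei_neighbors: int  # a
    other_neighbors: int  # b
    background_set_size: int  # K
    network_size: int  # N
    proportion: float
    p_value: float
    q_value: float = float("nan")
    degree_zero: bool = False


def load_network(path: str | Path) -> nx.Graph:
    """Read a two-column (or wider, HIPPIE-style) tab-separated edge
    list into an undirected simple graph.

    Duplicate edges and reversed duplicates collapse; self-loops are
    dropped and counted. Extra columns (scores, evidence) are ignored.
    """
    net = nx.Graph()
    self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{lineno}: expected at least two columns")
            u, v = fields[0], fields[1]
            if u == v:
                self_loops += 1
                continue
            net.add_edge(u, v)
    if self_loops:
        logger.info("load_network: dropped %d self-loop(s)", self_loops)
    if net.number_of_nodes() == 0:
        logger.warning("load_network: empty network from %s", path)
    return net


def induced_subnetwork(net: nx.Graph, genes) -> tuple[nx.Graph, dict]:
    """Subgraph on the given genes (intersected with network nodes),
    keeping only edges internal to the subset.

    Returns the subgraph and a summary with node count, edge count and
    mean within-subgraph degree.
    """
    nodes = [g for g in genes if net.has_node(g)]
    sub = nx.Graph(net.subgraph(nodes))
    n = sub.number_of_nodes()
    summary = {
        "n_nodes": n,
        "n_edges": sub.number_of_edges(),
        "mean_degree": (2 * sub.number_of_edges() / n) if n else 0.0,
    }
    return sub, summary


def fisher_enrichment_tail(a: int, b: int, K: int, N: int) -> float:
    """Upper hypergeometric tail P(X >= a), X ~ Hypergeom(N, K, a + b).

    Exact via log-factorial (log-gamma) accumulation of the pmf over
    x = a .. min(K, a + b); no normal or chi-square approximation.
    """
    a, b, K, N = int(a), int(b), int(K), int(N)
    n = a + b  # draws = degree
    if min(a, b, K, N) < 0 or a > K or n > N or K > N or b > N - K:
        raise ValueError(f"inconsistent margins: a={a} b={b} K={K} N={N}")
    if a == 0:
        return 1.0  # P(X >= 0) covers the whole distribution
    hi = min(K, n)
    log_pmf_a = (
        lgamma(K + 1) - lgamma(a + 1) - lgamma(K - a + 1)
        + lgamma(N - K + 1) - lgamma(n - a + 1) - lgamma(N - K - (n - a) + 1)
        - (lgamma(N + 1) - lgamma(n + 1) - lgamma(N - n + 1))
    )
    if log_pmf_a < -600.0:
        # far tail: accumulate in log space to dodge underflow
        x = np.arange(a, hi + 1)
        log_pmf = (
            gammaln(K + 1) - gammaln(x + 1) - gammaln(K - x + 1)
            + gammaln(N - K + 1) - gammaln(n - x + 1) - gammaln(N - K - (n - x) + 1)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
        )
        return float(min(1.0, np.exp(logsumexp(log_pmf))))
    # pmf(x+1)/pmf(x) is an exact small rational; accumulate relative to pmf(a)
    total = 1.0
    term = 1.0
    for x in range(a, hi):
        term *= (K - x) * (n - x) / ((x + 1) * (N - K - n + x + 1))
        total += term
    return float(min(1.0, exp(log_pmf_a) * total))


def neighborhood_enrichment(
    net: nx.Graph,
    background_set,
    test_genes=None,
    adjust: str = "fdr_bh",
) -> list[NeighborEnrichment]:
    """Per-gene Fisher enrichment of the background set among direct
    neighbors.

    The tested gene never counts as its own neighbor (self-loops are
    removed at load time). Degree-zero test genes get proportion 0 and
    p = 1, flagged. q-values are adjusted over all tested genes
    (``fdr_bh`` default, ``bonferroni`` selectable).
    """
    background = {g for g in background_set if net.has_node(g)}
    dropped = len(set(background_set)) - len(background)
    if dropped:
        logger.info(
            "neighborhood_enrichment: %d background gene(s) not in network", dropped
        )
    N = net.number_of_nodes()
    K = len(background)
    if test_genes is None:
        test_genes = sorted(g for g in background if net.degree(g) >= 1)
    else:
        test_genes = [g for g in test_genes if net.has_node(g)]
    results = []
    for gene in test_genes:
        neighbors = set(net.neighbors(gene)) - {gene}
        a = len(neighbors & background)
        b = len(neighbors) - a
        if a + b == 0:
            results.append(
                NeighborEnrichment(gene, 0, 0, K, N, 0.0, 1.0, degree_zero=True)
            )
            continue
        p = fisher_enrichment_tail(a, b, K, N)
        results.append(NeighborEnrichment(gene, a, b, K, N, a / (a + b), p))
    if results:
        q = bh_adjust([r.p_value for r in results], method=adjust)
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results


def select_drivers(
    results: list[NeighborEnrichment], criteria: DriverCriteria = DriverCriteria()
) -> list[NeighborEnrichment]:
    """Genes with q < fdr_threshold AND proportion > proportion_threshold
    (both strict), sorted by ascending p."""
    selected = [
        r
        for r in results
        if r.q_value < criteria.fdr_threshold
        and r.proportion > criteria.proportion_threshold
    ]
    return sorted(selected, key=lambda r: (r.p_value, r.gene_id))


def degree_distribution(net: nx.Graph) -> dict[int, int]:
    """Exact histogram degree -> node count; counts sum to |nodes|."""
    hist: dict[int, int] = {}
    for _, d in net.degree():
        hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items()))


def enrichment_table(results: list[NeighborEnrichment], criteria=None) -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene_id,
            "ei_neighbors": r.ei_neighbors,
            "other_neighbors": r.other_neighbors,
            "background_size": r.background_set_size,
            "network_size": r.network_size,
            "proportion": r.proportion,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "selected": bool(
                criteria
                and r.q_value < criteria.fdr_threshold
                and r.proportion > criteria.proportion_threshold
            ),
        }
        for r in sorted(results, key=lambda r: (r.p_value, r.gene_id))
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "ei_neighbors", "other_neighbors", "background_size",
            "network_size", "proportion", "p_value", "q_value", "selected",
        ],
    )
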