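"""Key-connector analysis by dynamic neighbourhood search (DNS).

On an undirected network, a key connector of a target gene set G is a gene
whose bounded-hop neighbourhood is hypergeometrically enriched for G.  The
search first restricts to the subnetwork N_G of nodes within L hops of G
(L=2 by default), then for each gene g and each layer h = 1..H (H=2)
tests the genes within h hops of g (excluding g) for enrichment in G, with
the genes of N_G as background.  The per-gene p-value is the minimum over
layers, Bonferroni-corrected over the genes tested; genes with corrected
p <= 0.05 are reported as key connectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from scipy.stats import hypergeom

from .io import GeneNetwork

KEY_ALPHA = 0.05


@dataclass(frozen=True)
class KeyConnectorResult:
    gene: str
    min_p: float
    p_bonferroni: float
    is_key: bool
    layer_sizes: tuple[int, ...]


def build_kca_subnetwork(net: GeneNetwork, G, L: int = 2) -> GeneNetwork:
    """Induced subgraph on all nodes within L hops of the target set G."""
    targets = frozenset(g for g in G if g in net)
    if not targets:
        raise ValueError("no target gene maps onto the network")
    keep = set(targets)
    if L > 0:
        frontier = set(targets)
        for _ in range(L):
            frontier = {nb for v in frontier for nb in net.neighbors(v)} - keep
            if not frontier:
                break
            keep |= frontier
    return net.subgraph(keep).copy()


def kca(
    net: GeneNetwork,
    G,
    L: int = 2,
    H: int = 2,
    alpha: float = KEY_ALPHA,
) -> list[KeyConnectorResult]:
    """Rank every gene of the L-hop subnetwork by neighbourhood enrichment.

    For each gene g and layer h <= H the 'draw' is the set of genes within
    h hops of g in the subnetwork, excluding g; the hypergeometric
    population is the subnetwork minus g, and successes are the target
    genes in it (g itself never counts as a success: self-membership is not
    connecting).  One-sided upper-tail p, minimum over layers, Bonferroni
    over genes tested.  Results sorted by corrected p then gene symbol.
    """
    sub = build_kca_subnetwork(net, G, L=L)
    targets = frozenset(g for g in G if g in sub)
    n_nodes = sub.number_of_nodes()
    results = []
    for g in sorted(sub.nodes()):
        pop = n_nodes - 1
        successes = len(targets - {g})
        lengths = nx.single_source_shortest_path_length(sub, g, cutoff=H)
        min_p = 1.0
        layer_sizes = []
        for h in range(1, H + 1):
            hood = frozenset(v for v, d in lengths.items() if 0 < d <= h)
            layer_sizes.append(len(hood))
            if not hood:
                continue
            k = len(hood & targets)
            # upper-tail P(X >= k)
            p = float(hypergeom.sf(k - 1, pop, successes, len(hood)))
            min_p = min(min_p, p)
        results.append((g, min_p, tuple(layer_sizes)))
    n_tested = len(results)
    out = [
        KeyConnectorResult(
            gene=g,
            min_p=p,
            p_bonferroni=min(1.0, p * n_tested),
            is_key=min(1.0, p * n_tested) <= alpha,
            layer_sizes=sizes,
        )
        for g, p, sizes in results
    ]
    out.sort(key=lambda r: (r.min_p, r.gene))
    return out
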