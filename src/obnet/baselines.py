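"""Comparison methods: shortest-path proximity and direct gene-set overlap.

The shortest-path method scores a (trait, disease, module) triple by the
mean unweighted shortest-path length over all trait-gene x disease-gene
pairs inside the module's subnetwork, then ranks diseases by the minimum
mean distance across modules (smaller = closer).  The overlap method ranks
diseases directly by the Jaccard coefficient of their gene sets with the
query trait's.  A literature-co-occurrence Jaccard on abstract-identifier
counts builds the gold trait list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .io import TraitGeneMap
from .modules import FunctionalModule

logger = logging.getLogger(__name__)

GOLD_JACCARD_THRESHOLD = 0.004


@dataclass(frozen=True)
class ProximityResult:
    """Mean shortest-path proximity of two gene sets within one module."""

    disease_id: str
    module_id: str
    mean_sp: float
    n_pairs_finite: int


def obsp_module_distance(
    m: FunctionalModule,
    obesity_genes,
    disease_genes,
    disease_id: str = "",
    include_shared: bool = True,
) -> ProximityResult:
    """Average hop distance between all trait/disease gene pairs in a module.

    Distances are unweighted BFS hop counts on the module subnetwork.
    Pairs in different components are excluded from the mean (an
    infinity-contaminated mean would make every disconnected module worst);
    ``n_pairs_finite`` records how many pairs contributed.  Genes in both
    sets contribute distance-0 self-pairs unless ``include_shared=False``,
    which skips the (g, g) pairs while keeping the genes.
    """
    genes = m.genes
    ob = sorted(frozenset(obesity_genes) & genes)
    dis = sorted(frozenset(disease_genes) & genes)
    total, n_finite, n_inf = 0.0, 0, 0
    ob_set = set(ob)
    for d in dis:
        lengths = nx.single_source_shortest_path_length(m.subnetwork, d)
        for o in ob_set:
            if not include_shared and o == d:
                continue
            if o in lengths:
                total += lengths[o]
                n_finite += 1
            else:
                n_inf += 1
    if n_inf:
        logger.debug("obsp: %d unreachable pair(s) in module %s", n_inf, m.module_id)
    mean = total / n_finite if n_finite else math.inf
    return ProximityResult(disease_id=disease_id, module_id=m.module_id, mean_sp=mean, n_pairs_finite=n_finite)


def obsp_rank(per_module: list[ProximityResult]) -> pd.DataFrame:
    """Rank diseases by their minimum mean distance across modules."""
    best: dict[str, ProximityResult] = {}
    for res in per_module:
        cur = best.get(res.disease_id)
        if cur is None or (res.mean_sp, res.module_id) < (cur.mean_sp, cur.module_id):
            best[res.disease_id] = res
    rows = [
        {"disease_id": d, "min_mean_sp": r.mean_sp, "best_module_id": r.module_id}
        for d, r in best.items()
    ]
    return pd.DataFrame(rows).sort_values(
        ["min_mean_sp", "disease_id"], kind="mergesort", ignore_index=True
    )


def jaccard(set_a, set_b) -> float:
    """|a & b| / |a | b|; errors when both sets are empty."""
    a, b = frozenset(set_a), frozenset(set_b)
    if not a and not b:
        raise ValueError("jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def oboverlap_rank(traits: TraitGeneMap, query_trait: str) -> pd.DataFrame:
    """Rank diseases by direct gene-set Jaccard with the query trait."""
    q = traits[query_trait]
    rows = [
        {"disease_id": d, "jaccard": jaccard(q, genes)}
        for d, genes in traits.traits.items()
        if d != query_trait
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["jaccard", "disease_id"], ascending=[False, True], kind="mergesort", ignore_index=True
    )


def gold_set_from_counts(
    per_disease: dict[str, tuple[int, int]],
    ids_with_obesity: int,
    threshold: float = GOLD_JACCARD_THRESHOLD,
    manual_additions=(),
) -> frozenset[str]:
    """Literature-co-occurrence gold list from pre-counted abstract IDs.

    ``per_disease`` maps disease -> (number of abstracts naming the
    disease, number naming both the disease and the query term);
    ``ids_with_obesity`` is the count naming the query term.  Diseases with
    co-occurrence Jaccard ``n_both / (n_disease + n_query - n_both)`` at or
    above ``threshold`` are included, then curated ``manual_additions``
    are unioned in.
    """
    gold = set(manual_additions)
    for disease, (n_dis, n_both) in per_disease.items():
        union = n_dis + ids_with_obesity - n_both
        if union <= 0:
            continue
        if n_both / union >= threshold:
            gold.add(disease)
    return frozenset(gold)
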