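"""Functional modules: gene sets mapped onto the reference interactome.

A *modularized network* is the subgraph of the reference network induced by
one functional gene set (a GO biological process or KEGG pathway).  An
*expanded* modularized network grows that core by the highest-probability
neighbours under a restart walk seeded at the core, until it reaches five
times the core size or 500 genes, whichever is smaller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .io import GeneNetwork, GeneSetCollection
from .rwr import TransitionMatrix, normalize_adjacency, rank_by_probability, rwr

logger = logging.getLogger(__name__)

#: largest raw gene-set size admitted as a module (strict upper bound)
MAX_SET_SIZE = 500
#: expansion multiplier and hard cap on the expanded gene count
EXPANSION_FACTOR = 5
EXPANSION_CAP = 500


@dataclass(frozen=True)
class FunctionalModule:
    """A gene set realised on the reference network.

    ``core_genes`` are the set's members present on the network;
    ``expanded_genes`` is the superset after RWR expansion (equal to the
    core when unexpanded).  ``subnetwork`` is the reference subgraph induced
    on :attr:`genes`.
    """

    module_id: str
    core_genes: frozenset[str]
    expanded_genes: frozenset[str]
    subnetwork: GeneNetwork

    @property
    def genes(self) -> frozenset[str]:
        """The module's current gene universe (expanded if it was expanded)."""
        return self.expanded_genes

    @property
    def is_expanded(self) -> bool:
        return self.expanded_genes != self.core_genes


def build_modules(
    net: GeneNetwork,
    sets: GeneSetCollection,
    max_set_size: int = MAX_SET_SIZE,
) -> list[FunctionalModule]:
    """One module per eligible gene set.

    Sets with ``max_set_size`` genes or more are skipped (overly large sets
    blur the functional signal), as are sets with no gene on the network;
    both with a logged reason.
    """
    nodes = set(net.nodes())
    out = []
    for set_id, genes in sets.entries.items():
        if len(genes) >= max_set_size:
            logger.info("build_modules: %s skipped (too large: %d genes)", set_id, len(genes))
            continue
        core = frozenset(genes & nodes)
        if not core:
            logger.info("build_modules: %s skipped (no gene on network)", set_id)
            continue
        sub = net.subgraph(core).copy()
        out.append(FunctionalModule(module_id=set_id, core_genes=core, expanded_genes=core, subnetwork=sub))
    return out


def whole_network_module(net: GeneNetwork, module_id: str = "whole") -> FunctionalModule:
    """The whole reference network as a single never-expanded module."""
    nodes = frozenset(net.nodes())
    return FunctionalModule(module_id=module_id, core_genes=nodes, expanded_genes=nodes, subnetwork=net.copy())


def expand_module(
    net: GeneNetwork,
    m: FunctionalModule,
    factor: int = EXPANSION_FACTOR,
    cap: int = EXPANSION_CAP,
    r: float = 0.5,
    tm: TransitionMatrix | None = None,
) -> FunctionalModule:
    """Grow a module's gene set by restart-walk proximity on the reference.

    The walk is seeded at the core genes on the *whole* reference network
    (expansion must reach genes outside the core).  Non-core genes are
    admitted in order of walk probability (ties lexicographic) until the
    gene count reaches ``min(factor * |core|, cap)``; a target at or below
    the core size makes expansion a no-op.

    Pass a precomputed ``tm`` of ``net`` when expanding many modules.
    """
    if not m.core_genes:
        raise ValueError(f"module {m.module_id} has an empty core")
    target = min(factor * len(m.core_genes), cap)
    if target <= len(m.core_genes):
        return replace(m, expanded_genes=m.core_genes)
    if tm is None:
        tm = normalize_adjacency(net)
    profile = rwr(tm, m.core_genes, r=r)
    ranked = rank_by_probability(profile, exclude=m.core_genes)
    added = ranked[: target - len(m.core_genes)]
    expanded = frozenset(m.core_genes | set(added))
    sub = net.subgraph(expanded).copy()
    return replace(m, expanded_genes=expanded, subnetwork=sub)


def eligible_for_scoring(
    m: FunctionalModule,
    trait_genes,
    disease_genes,
    min_each: int = 5,
) -> bool:
    """True when both gene sets map >= ``min_each`` genes into the module.

    A walk seeded on too few genes gives unstable rankings, so modules with
    fewer than five genes from either side are not scored.
    """
    genes = m.genes
    return (
        len(frozenset(trait_genes) & genes) >= min_each
        and len(frozenset(disease_genes) & genes) >= min_each
    )
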