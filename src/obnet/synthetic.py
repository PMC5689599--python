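"""Synthetic benchmarks with planted trait-disease network signal.

The generator emulates the data a trait-disease reachability study runs
on: a reference interaction network, a collection of functional gene
sets, a trait catalogue with one query trait (obesity) plus a disease
catalogue, and a gold list of the diseases planted to be network-proximal
to the query trait.  Everything is reproducible from a single integer
seed.

The planted signal works through network neighbourhoods: each planted
disease draws a fraction ``proximity_effect`` of its genes from the <=2-hop
neighbourhood of the query-trait genes inside the trait's home modules,
and the remainder uniformly; non-planted diseases draw all genes
uniformly.  With ``proximity_effect = 0`` planted and background diseases
are exchangeable and a ranking method should be at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneNetwork, GeneSetCollection, TraitGeneMap
from .validation import ExpressionMatrix

QUERY_TRAIT = "obesity"


@dataclass
class FixtureSpec:
    """Parameters of one synthetic benchmark.

    Defaults give a compact but non-trivial study shaped like a
    trait-interactome analysis: a 1000-gene stochastic-block network
    (modular topology keeps functional modules non-vacuous), 8 functional
    sets of 80-120 genes anchored to blocks — so a five-fold expansion
    stays well below the network size, as real pathway sets do against an
    interactome — a 40-gene query trait concentrated in two home modules,
    and 18 diseases of 60 genes, 6 of them planted proximal.
    """

    n_genes: int = 1000
    network_model: str = "stochastic_block"  # or "erdos_renyi", "barabasi_albert"
    model_params: dict[str, Any] = field(default_factory=dict)
    n_modules: int = 8
    module_size_range: tuple[int, int] = (80, 120)
    n_diseases: int = 18
    n_planted_ord: int = 6
    proximity_effect: float = 0.8
    n_obesity_genes: int = 40
    n_disease_genes: int = 60
    expression_rho_in: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted_ord > self.n_diseases:
            raise ValueError("planted diseases cannot exceed total diseases")
        if not 0.0 <= self.proximity_effect <= 1.0:
            raise ValueError("proximity_effect must be in [0, 1]")
        if self.module_size_range[1] > self.n_genes:
            raise ValueError("module larger than network")
        for v in (self.n_genes, self.n_modules, self.n_diseases, self.n_obesity_genes, self.n_disease_genes):
            if v <= 0:
                raise ValueError("all counts must be positive")


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _sample_network(spec: FixtureSpec, rng: np.random.Generator) -> tuple[GeneNetwork, list[int]]:
    """Sample the reference network; returns (network, block id per gene)."""
    n = spec.n_genes
    gseed = int(rng.integers(2**31 - 1))
    if spec.network_model == "erdos_renyi":
        p = spec.model_params.get("p", 0.05)
        g = nx.gnp_random_graph(n, p, seed=gseed)
        blocks = [0] * n
    elif spec.network_model == "barabasi_albert":
        m = spec.model_params.get("m", 3)
        g = nx.barabasi_albert_graph(n, m, seed=gseed)
        blocks = [0] * n
    elif spec.network_model == "stochastic_block":
        n_blocks = spec.model_params.get("n_blocks", max(2, spec.n_modules // 2))
        p_in = spec.model_params.get("p_in", 0.04)
        p_out = spec.model_params.get("p_out", 0.004)
        sizes = [n // n_blocks] * n_blocks
        sizes[-1] += n - sum(sizes)
        probs = [[p_in if i == j else p_out for j in range(n_blocks)] for i in range(n_blocks)]
        g = nx.stochastic_block_model(sizes, probs, seed=gseed)
        blocks = [b for b, s in enumerate(sizes) for _ in range(s)]
    else:
        raise ValueError(f"unknown network model {spec.network_model!r}")
    names = _gene_names(n)
    net: GeneNetwork = nx.Graph()
    net.add_nodes_from(names)
    net.add_edges_from((names[u], names[v]) for u, v in g.edges() if u != v)
    return net, blocks


def _sample_modules(
    spec: FixtureSpec, rng: np.random.Generator, genes: list[str], blocks: list[int]
) -> GeneSetCollection:
    """Gene sets anchored to network blocks (80% in-block, 20% elsewhere)."""
    by_block: dict[int, list[str]] = {}
    for g, b in zip(genes, blocks):
        by_block.setdefault(b, []).append(g)
    n_blocks = len(by_block)
    entries, descriptions = {}, {}
    for i in range(spec.n_modules):
        size = int(rng.integers(spec.module_size_range[0], spec.module_size_range[1] + 1))
        anchor = i % n_blocks
        n_in = min(int(round(0.8 * size)), len(by_block[anchor]))
        members = set(rng.choice(by_block[anchor], size=n_in, replace=False).tolist())
        outside = [g for g in genes if g not in members]
        n_out = min(size - n_in, len(outside))
        if n_out > 0:
            members |= set(rng.choice(outside, size=n_out, replace=False).tolist())
        set_id = f"M{i + 1:03d}"
        entries[set_id] = frozenset(members)
        descriptions[set_id] = f"synthetic functional set anchored to block {anchor}"
    return GeneSetCollection(entries=entries, descriptions=descriptions, source_tag="synthetic")


def generate_benchmark(spec: FixtureSpec):
    """Sample one benchmark: network, gene sets, trait catalogue, gold list.

    Returns ``(net, sets, traits, gold, truth)`` where ``truth`` records
    every hidden assignment (block memberships, the query trait's home
    modules, planted disease ids and each disease's proximal gene count),
    enough to compute exact expected labels downstream.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    net, blocks = _sample_network(spec, rng)
    genes = _gene_names(spec.n_genes)
    sets = _sample_modules(spec, rng, genes, blocks)

    # query trait lives in two "home" functional sets
    module_ids = sorted(sets.entries)
    home = [module_ids[i] for i in rng.choice(len(module_ids), size=min(2, len(module_ids)), replace=False)]
    home_pool = sorted(frozenset().union(*(sets.entries[m] for m in home)))
    n_ob = min(spec.n_obesity_genes, len(home_pool))
    obesity = frozenset(rng.choice(home_pool, size=n_ob, replace=False).tolist())

    # <=2-hop neighbourhood of the trait genes, restricted to the home sets
    hood = set()
    for g in obesity:
        hood.add(g)
        for nb in net.neighbors(g):
            hood.add(nb)
            hood.update(net.neighbors(nb))
    proximal_pool = (hood & set(home_pool)) - obesity
    fallback_pool = sorted(proximal_pool or (set(home_pool) - obesity))
    ob_sorted = sorted(obesity)

    def draw_proximal() -> str | None:
        """One gene reached by a 1-2 step walk from a random trait gene.

        Sampling through short walks concentrates planted genes on the
        trait genes' direct interaction partners (a diffuse uniform draw
        over the whole 2-hop set would dilute the planted proximity in a
        dense community); the result always lies in the <=2-hop
        neighbourhood restricted to the home sets.
        """
        for _ in range(20):  # rejection: land in the home pool, off the trait
            cur = ob_sorted[int(rng.integers(len(ob_sorted)))]
            for _ in range(1 + int(rng.integers(2))):
                nbrs = sorted(net.neighbors(cur))
                if not nbrs:
                    break
                cur = nbrs[int(rng.integers(len(nbrs)))]
            if cur in proximal_pool:
                return cur
        return fallback_pool[int(rng.integers(len(fallback_pool)))] if fallback_pool else None

    traits: dict[str, frozenset[str]] = {QUERY_TRAIT: obesity}
    planted_ids = [f"D{i + 1:02d}" for i in range(spec.n_planted_ord)]
    background_ids = [f"D{i + 1:02d}" for i in range(spec.n_planted_ord, spec.n_diseases)]
    per_disease_proximal = {}
    for did in planted_ids:
        members: set[str] = set()
        n_prox = 0
        while len(members) < spec.n_disease_genes:
            pick = draw_proximal() if rng.random() < spec.proximity_effect else None
            if pick is None:
                pick = genes[int(rng.integers(len(genes)))]
            else:
                n_prox += pick not in members
            members.add(pick)
        traits[did] = frozenset(members)
        per_disease_proximal[did] = n_prox
    for did in background_ids:
        members = set(rng.choice(genes, size=spec.n_disease_genes, replace=False).tolist())
        traits[did] = frozenset(members)
        per_disease_proximal[did] = 0

    gold = frozenset(planted_ids)
    truth = {
        "blocks": dict(zip(genes, blocks)),
        "home_modules": home,
        "obesity_genes": obesity,
        "planted_diseases": planted_ids,
        "background_diseases": background_ids,
        "proximal_gene_counts": per_disease_proximal,
        "proximal_pool_size": len(proximal_pool),
    }
    return net, sets, TraitGeneMap(traits=traits), gold, truth


def generate_expression(
    modules: dict[str, frozenset[str]],
    n_samples_a: int,
    n_samples_b: int,
    rho_in_a: float,
    rho_in_b: float,
    seed: int | np.random.Generator | None = None,
    cond_a: str = "tumor",
    cond_b: str = "normal",
    n_background_genes: int = 0,
) -> ExpressionMatrix:
    """Equicorrelated module expression with condition-specific correlation.

    Within each module and condition, gene values share a per-sample latent
    factor: ``x = sqrt(rho) * f + sqrt(1 - rho) * eps`` gives every gene
    pair correlation ``rho``.  Background genes (and genes outside all
    modules) are independent standard normals.
    """
    for rho in (rho_in_a, rho_in_b):
        if not 0.0 <= rho < 1.0:
            raise ValueError("correlations must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = [f"A{i:03d}" for i in range(n_samples_a)] + [f"B{i:03d}" for i in range(n_samples_b)]
    condition = pd.Series([cond_a] * n_samples_a + [cond_b] * n_samples_b, index=samples)
    all_genes = sorted(frozenset().union(*modules.values())) if modules else []
    all_genes += [f"BG{i:04d}" for i in range(n_background_genes)]
    values = pd.DataFrame(
        rng.standard_normal((len(all_genes), len(samples))), index=all_genes, columns=samples
    )
    for genes in modules.values():
        members = sorted(g for g in genes if g in values.index)
        for cond, rho, n_s in ((cond_a, rho_in_a, n_samples_a), (cond_b, rho_in_b, n_samples_b)):
            cols = [s for s in samples if condition[s] == cond]
            factor = rng.standard_normal(len(cols))
            noise = rng.standard_normal((len(members), len(cols)))
            values.loc[members, cols] = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * noise
    return ExpressionMatrix(values=values, condition=condition)
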