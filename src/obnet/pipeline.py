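"""End-to-end ranking pipelines over a trait catalogue.

Glue between the per-module operations and the disease-level rankings:
build (and optionally expand) the functional modules once, score every
eligible (disease, module) pair against the query trait, adjust and rank.
Per-pair permutation seeds are spawned deterministically from the single
pipeline seed, so results do not depend on iteration order and two runs
with the same seed are byte-identical.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .baselines import obsp_module_distance, obsp_rank
from .io import GeneNetwork, GeneSetCollection, TraitGeneMap
from .modules import (
    FunctionalModule,
    build_modules,
    eligible_for_scoring,
    expand_module,
    whole_network_module,
)
from .rwr import normalize_adjacency
from .scoring import (
    DEFAULT_BETA,
    DEFAULT_N_PERM,
    DEFAULT_RESTART,
    permutation_pvalue,
    rank_diseases,
)

logger = logging.getLogger(__name__)

MODES = ("modularized", "expanded", "whole")


def prepare_modules(
    net: GeneNetwork,
    sets: GeneSetCollection,
    mode: str = "expanded",
    factor: int = 5,
    cap: int = 500,
    r: float = DEFAULT_RESTART,
) -> list[FunctionalModule]:
    """Build the module list for one scoring mode."""
    if mode == "whole":
        return [whole_network_module(net)]
    mods = build_modules(net, sets)
    if mode == "modularized":
        return mods
    if mode == "expanded":
        tm = normalize_adjacency(net)
        return [expand_module(net, m, factor=factor, cap=cap, r=r, tm=tm) for m in mods]
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def score_disease_catalogue(
    net: GeneNetwork,
    sets: GeneSetCollection,
    traits: TraitGeneMap,
    query_trait: str,
    mode: str = "expanded",
    beta: float = DEFAULT_BETA,
    r: float = DEFAULT_RESTART,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_each: int = 5,
    adjust: str = "bh_within_disease",
    include_seeds: bool = True,
    classic_increments: bool = True,
    p_method: str = "empirical",
    modules: list[FunctionalModule] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every disease against the query trait on every eligible module.

    Returns ``(results, ranking)``: the per-(disease, module) table with
    enrichment scores and (adjusted) permutation p-values, and the
    disease ranking by minimum adjusted p.  Diseases with no eligible
    module are absent from both.
    """
    if query_trait not in traits:
        raise ValueError(f"query trait {query_trait!r} not in catalogue")
    query_genes = traits[query_trait]
    if modules is None:
        modules = prepare_modules(net, sets, mode=mode, r=r)
    tms = {m.module_id: normalize_adjacency(m.subnetwork) for m in modules}

    diseases = sorted(d for d in traits.traits if d != query_trait)
    # one independent child seed per (disease, module), index-addressed so
    # ordering of the loops cannot change the draws
    children = np.random.SeedSequence(seed).spawn(len(diseases) * len(modules))
    results = []
    for di, disease in enumerate(diseases):
        dgenes = traits[disease]
        for mi, m in enumerate(modules):
            if not eligible_for_scoring(m, query_genes, dgenes, min_each=min_each):
                continue
            rng = np.random.default_rng(children[di * len(modules) + mi])
            res = permutation_pvalue(
                m, query_genes, dgenes,
                n_perm=n_perm, seed=rng, trait_id=query_trait, disease_id=disease,
                r=r, beta=beta, include_seeds=include_seeds,
                classic_increments=classic_increments, tm=tms[m.module_id],
                min_each=min_each, p_method=p_method,
            )
            results.append(res)
    if not results:
        raise ValueError("no eligible (disease, module) pair; nothing to rank")
    ranking = rank_diseases(results, adjust=adjust)
    res_df = pd.DataFrame(
        [
            {
                "disease_id": x.disease_id,
                "module_id": x.module_id,
                "es_beta": x.es_beta,
                "z": x.z,
                "p": x.p,
                "p_adjusted": x.p_adjusted,
                "n_permutations": x.n_permutations,
            }
            for x in results
        ]
    ).sort_values(["disease_id", "module_id"], kind="mergesort", ignore_index=True)
    return res_df, ranking


def obsp_disease_ranking(
    net: GeneNetwork,
    sets: GeneSetCollection,
    traits: TraitGeneMap,
    query_trait: str,
    mode: str = "modularized",
    min_each: int = 5,
    modules: list[FunctionalModule] | None = None,
) -> pd.DataFrame:
    """Shortest-path baseline ranking over the same module universe."""
    query_genes = traits[query_trait]
    if modules is None:
        modules = prepare_modules(net, sets, mode=mode)
    per_module = []
    for disease in sorted(d for d in traits.traits if d != query_trait):
        dgenes = traits[disease]
        for m in modules:
            if eligible_for_scoring(m, query_genes, dgenes, min_each=min_each):
                per_module.append(obsp_module_distance(m, query_genes, dgenes, disease_id=disease))
    if not per_module:
        raise ValueError("no eligible (disease, module) pair; nothing to rank")
    return obsp_rank(per_module)


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a result table with a stable float format (reproducible bytes)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
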