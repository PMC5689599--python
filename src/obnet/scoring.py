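"""Mutual-reachability scoring of two gene sets on a functional module.

The statistic is a bidirectional combination of restart-walk diffusion and
a running-sum enrichment score.  For a module with gene universe of size
``N`` and a target set of size ``G``: seed the walk at one gene set, sort
the module's genes by the converged walk probability, traverse the sorted
list accumulating a hit increment per target gene and a miss decrement
otherwise, and take the peak (maximum) of the running sum as the
directional enrichment score.

``ES1`` seeds the walk at the disease genes and uses the query-trait
(obesity) genes as targets; ``ES2`` is the mirror image.  The combined
score is the convex combination

    ES_beta = beta * ES1 + (1 - beta) * ES2,   0 < beta < 1,

with ``beta = 0.1`` by default.  Significance comes from a permutation
null: the query-trait genes in the module are redrawn uniformly from the
module's gene universe and the combined score recomputed.

Two increment conventions exist for the running sum:

* the balanced zero-sum form ``+1/G`` per hit, ``-1/(N - G)`` per miss
  (the classic Kolmogorov-Smirnov running statistic of gene set
  enrichment analysis) — the default, whose peak measures enrichment of
  targets at the *top* of the ranking;
* the per-step-rescaled form ``+(N - G)/G`` per hit, ``-G/(N - G)`` per
  miss (:func:`running_sum_es`; ``classic_increments=False``).  Its
  traversal ends at ``(N - G) - G`` rather than 0, so the running sum
  drifts upward whenever ``G < N/2`` and its peak degenerates into a
  statistic of where the *last* target sits — kept for comparison, not
  recommended for scoring.

By default the seed genes stay in the traversal (``include_seeds=True``):
keeping the ranked list's composition identical between the observed
statistic and every permutation means the null differs from the observed
score only through the walk seeding and target placement, never through
which genes are removed from the list.  (Removing seeds instead makes the
observed statistic drop the query trait's well-connected genes from the
top of the list while the null drops random ones — a degree artifact that
dominates the result; the ``include_seeds=False`` variant is kept for
comparison.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .modules import FunctionalModule, eligible_for_scoring
from .rwr import TransitionMatrix, normalize_adjacency, rank_by_probability, rwr, rwr_batch

logger = logging.getLogger(__name__)

DEFAULT_BETA = 0.1
DEFAULT_RESTART = 0.5
DEFAULT_N_PERM = 100


@dataclass(frozen=True)
class EnrichmentScore:
    """Directional and combined enrichment scores for one module."""

    es1: float
    es2: float
    beta: float
    module_id: str
    N: int  # module gene count
    G: int  # target gene count (per-direction counts can differ; this is ES1's)

    @property
    def es_beta(self) -> float:
        return self.beta * self.es1 + (1.0 - self.beta) * self.es2


@dataclass
class ReachabilityResult:
    """Permutation-tested reachability of one (trait, disease, module) triple."""

    trait_id: str
    disease_id: str
    module_id: str
    es_beta: float
    z: float
    p: float
    n_permutations: int
    p_adjusted: float = field(default=float("nan"))


def running_sum_es(ranked_genes, targets, N: int, G: int) -> float:
    """Peak of the running enrichment sum over a ranked gene list.

    Adds ``(N - G)/G`` per target hit and ``-G/(N - G)`` per miss, returning
    the maximum of the running sum over all non-empty prefixes.
    """
    if G <= 0 or G >= N:
        raise ValueError(f"running_sum_es requires 0 < G < N, got G={G}, N={N}")
    targets = frozenset(targets)
    hit = (N - G) / G
    miss = -G / (N - G)
    total, peak = 0.0, -np.inf
    for g in ranked_genes:
        total += hit if g in targets else miss
        if total > peak:
            peak = total
    if peak == -np.inf:
        raise ValueError("ranked_genes is empty")
    return float(peak)


def _classic_running_sum_es(ranked_genes, targets, N: int, G: int) -> float:
    # zero-sum KS form: +1/G per hit, -1/(N-G) per miss
    if G <= 0 or G >= N:
        raise ValueError(f"requires 0 < G < N, got G={G}, N={N}")
    targets = frozenset(targets)
    total, peak = 0.0, -np.inf
    for g in ranked_genes:
        total += 1.0 / G if g in targets else -1.0 / (N - G)
        peak = max(peak, total)
    return float(peak)


def _directional_es(
    tm: TransitionMatrix,
    module_genes: frozenset[str],
    seeds: frozenset[str],
    targets: frozenset[str],
    N: int,
    r: float,
    include_seeds: bool,
    classic_increments: bool,
    cached_ranked: list[str] | None = None,
) -> tuple[float, int, list[str]]:
    """One direction of the score; returns (es, G_used, ranked_list).

    With ``include_seeds=False`` the seed genes are removed from the
    traversal (they trivially rank first) and from the target set.  If that
    removal empties the targets — the seed and target sets coincide — the
    seeds are re-included for this direction so the score stays defined.
    """
    eff_targets = targets - seeds if not include_seeds else targets
    keep_seeds = include_seeds or not eff_targets
    if keep_seeds:
        eff_targets = targets
    if cached_ranked is not None and not keep_seeds:
        ranked = cached_ranked
    else:
        profile = rwr(tm, seeds, r=r)
        ranked = rank_by_probability(profile, exclude=frozenset() if keep_seeds else seeds)
    G = len(eff_targets)
    fn = _classic_running_sum_es if classic_increments else running_sum_es
    return fn(ranked, eff_targets, N, G), G, ranked


def obnet_module_score(
    m: FunctionalModule,
    obesity_genes,
    disease_genes,
    r: float = DEFAULT_RESTART,
    beta: float = DEFAULT_BETA,
    include_seeds: bool = True,
    classic_increments: bool = True,
    tm: TransitionMatrix | None = None,
    min_each: int = 5,
) -> EnrichmentScore:
    """Bidirectional enrichment score of two gene sets on one module.

    ``ES1`` seeds the walk at the disease genes mapped into the module and
    scores the traversal against the query-trait (obesity) genes; ``ES2``
    mirrors it.  The module must be eligible (>= ``min_each`` genes mapped
    from each side).
    """
    if not 0 < beta < 1:
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    if not eligible_for_scoring(m, obesity_genes, disease_genes, min_each=min_each):
        raise ValueError(f"module {m.module_id} is not eligible for scoring")
    genes = m.genes
    ob = frozenset(obesity_genes) & genes
    dis = frozenset(disease_genes) & genes
    if tm is None:
        tm = normalize_adjacency(m.subnetwork)
    N = len(genes)
    es1, G1, _ = _directional_es(tm, genes, dis, ob, N, r, include_seeds, classic_increments)
    es2, _, _ = _directional_es(tm, genes, ob, dis, N, r, include_seeds, classic_increments)
    return EnrichmentScore(es1=es1, es2=es2, beta=beta, module_id=m.module_id, N=N, G=G1)


def _peak_from_hits(hits: np.ndarray, N: int, G: int, classic: bool) -> np.ndarray:
    """Row-wise running-sum peaks from boolean hit matrices (perms x list)."""
    if classic:
        inc_hit, inc_miss = 1.0 / G, -1.0 / (N - G)
    else:
        inc_hit, inc_miss = (N - G) / G, -G / (N - G)
    vals = np.where(hits, inc_hit, inc_miss)
    return np.cumsum(vals, axis=1).max(axis=1)


def _batched_null(
    tm: TransitionMatrix,
    ranked_with_dis: list[str],
    dis: frozenset[str],
    perm_sets: list[frozenset[str]],
    N: int,
    r: float,
    beta: float,
    classic: bool,
) -> np.ndarray:
    """Vectorized null scores for the seeds-included configuration.

    The ranked list of ES1 is fixed (the disease-seeded walk does not
    change under the null), so all permutations reduce to boolean target
    masks over one ordering; ES2's hundred walks share the transition
    matrix and converge together in one block power iteration.
    """
    n_perm = len(perm_sets)
    index = tm.index
    k = len(perm_sets[0])

    member = np.zeros((n_perm, tm.n), dtype=bool)
    for i, s in enumerate(perm_sets):
        member[i, [index[g] for g in s]] = True
    ranked_idx = np.fromiter((index[g] for g in ranked_with_dis), dtype=int, count=len(ranked_with_dis))
    es1 = _peak_from_hits(member[:, ranked_idx], N, k, classic)

    P0 = np.zeros((tm.n, n_perm))
    for i, s in enumerate(perm_sets):
        idx = [index[g] for g in s]
        P0[idx, i] = 1.0 / len(idx)
    P = rwr_batch(tm, P0, r=r)
    # stable argsort on -p keeps ascending node index among ties, and
    # node_order is sorted, so ties break lexicographically as in the
    # scalar path
    orders = np.argsort(-P, axis=0, kind="stable")
    dis_mask = np.zeros(tm.n, dtype=bool)
    dis_mask[[index[g] for g in dis]] = True
    hits2 = dis_mask[orders.T]  # n_perm x n
    es2 = _peak_from_hits(hits2, N, len(dis), classic)
    return beta * es1 + (1.0 - beta) * es2


def permutation_pvalue(
    m: FunctionalModule,
    obesity_genes,
    disease_genes,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
    trait_id: str = "obesity",
    disease_id: str = "",
    r: float = DEFAULT_RESTART,
    beta: float = DEFAULT_BETA,
    include_seeds: bool = True,
    classic_increments: bool = True,
    tm: TransitionMatrix | None = None,
    min_each: int = 5,
    p_method: str = "empirical",
) -> ReachabilityResult:
    """Permutation test of a module's combined enrichment score.

    The null redraws the query-trait gene set uniformly (without
    replacement) from the module's gene universe ``n_perm`` times and
    recomputes the combined score.  The observed score is standardised
    against the null mean and sd into a z-score; the reported p-value is,
    by default, the add-one empirical upper-tail probability
    ``(r + 1)/(n_perm + 1)`` (``p_method='empirical'``), which is
    calibrated for any null shape.  ``p_method='normal'`` instead takes
    the one-sided upper-tail normal probability of z — the parametric
    extrapolation that resolves p-values far below ``1/n_perm`` at the
    cost of calibration, since the null of a running-sum peak is
    right-skewed.  Deterministic given ``seed``.
    """
    if p_method not in ("empirical", "normal"):
        raise ValueError(f"unknown p_method {p_method!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if tm is None:
        tm = normalize_adjacency(m.subnetwork)
    genes = m.genes
    ob = frozenset(obesity_genes) & genes
    dis = frozenset(disease_genes) & genes
    obs = obnet_module_score(
        m, ob, dis, r=r, beta=beta, include_seeds=include_seeds,
        classic_increments=classic_increments, tm=tm, min_each=min_each,
    )
    N = len(genes)

    # ES1's walk is seeded at the (fixed) disease genes: rank once, reuse.
    dis_profile = rwr(tm, dis, r=r)
    ranked_no_dis = rank_by_probability(dis_profile, exclude=dis)
    ranked_with_dis = rank_by_probability(dis_profile)

    fn = _classic_running_sum_es if classic_increments else running_sum_es

    if include_seeds:
        # stratified draw preserving the observed overlap with the disease
        # seeds: genes shared with the seeds sit at the top of both ranked
        # lists, so a null that redrew the overlap freely would not be
        # exchangeable with the observed set
        n_shared = len(ob & dis)
        pool_dis = sorted(dis)
        pool_rest = sorted(genes - dis)
        k_rest = len(ob) - n_shared
        perm_sets = []
        for _ in range(n_perm):
            drawn = rng.choice(pool_rest, size=k_rest, replace=False).tolist()
            if n_shared:
                drawn += rng.choice(pool_dis, size=n_shared, replace=False).tolist()
            perm_sets.append(frozenset(drawn))
    else:
        # the observed statistic dropped disease seeds from ES1's targets,
        # so the null draws avoid them and match the effective target count
        universe = sorted(genes - dis)
        k = len(ob - dis) or len(ob)
        perm_sets = [
            frozenset(rng.choice(universe, size=k, replace=False).tolist()) for _ in range(n_perm)
        ]
    if include_seeds:
        null = _batched_null(tm, ranked_with_dis, dis, perm_sets, N, r, beta, classic_increments)
    else:
        null = np.empty(n_perm)
        for i, perm_ob in enumerate(perm_sets):
            t1 = perm_ob - dis
            if t1:
                es1 = fn(ranked_no_dis, t1, N, len(t1))
            else:
                es1 = fn(ranked_with_dis, perm_ob, N, len(perm_ob))
            es2, _, _ = _directional_es(
                tm, genes, perm_ob, dis, N, r, include_seeds, classic_increments
            )
            null[i] = beta * es1 + (1.0 - beta) * es2

    mean, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0.0:
        logger.warning(
            "permutation_pvalue: degenerate null (sd=0) for module %s", m.module_id
        )
        if obs.es_beta <= mean:
            z, p = 0.0, 1.0
        else:
            z, p = np.inf, float(np.nextafter(0, 1))
    else:
        z = (obs.es_beta - mean) / sd
        p = float(norm.sf(z))
    if p_method == "empirical" and sd > 0.0:
        p = (int(np.sum(null >= obs.es_beta)) + 1) / (n_perm + 1)
    return ReachabilityResult(
        trait_id=trait_id, disease_id=disease_id, module_id=m.module_id,
        es_beta=obs.es_beta, z=float(z), p=p, n_permutations=n_perm,
    )


def rank_diseases(
    results: list[ReachabilityResult],
    adjust: str = "bh_within_disease",
) -> pd.DataFrame:
    """Adjust module p-values and rank diseases by their minimum.

    ``adjust='bh_within_disease'`` applies Benjamini-Hochberg across the
    modules of each disease separately (default); ``'bh_global'`` adjusts
    across all disease x module pairs at once.  Each result's
    ``p_adjusted`` is filled in place.

    Returns a DataFrame with one row per disease: ``disease_id``,
    ``min_adjusted_p``, ``best_module_id``, sorted ascending by p (ties by
    disease id).
    """
    if not results:
        raise ValueError("no results to rank")
    if adjust == "bh_global":
        padj = multipletests([r.p for r in results], method="fdr_bh")[1]
        for res, q in zip(results, padj):
            res.p_adjusted = float(q)
    elif adjust == "bh_within_disease":
        by_disease: dict[str, list[ReachabilityResult]] = {}
        for res in results:
            by_disease.setdefault(res.disease_id, []).append(res)
        for group in by_disease.values():
            padj = multipletests([r.p for r in group], method="fdr_bh")[1]
            for res, q in zip(group, padj):
                res.p_adjusted = float(q)
    else:
        raise ValueError(f"unknown adjust method {adjust!r}")

    rows = []
    by_disease = {}
    for res in results:
        by_disease.setdefault(res.disease_id, []).append(res)
    for disease_id, group in by_disease.items():
        best = min(group, key=lambda r: (r.p_adjusted, r.module_id))
        rows.append(
            {"disease_id": disease_id, "min_adjusted_p": best.p_adjusted, "best_module_id": best.module_id}
        )
    df = pd.DataFrame(rows).sort_values(
        ["min_adjusted_p", "disease_id"], kind="mergesort", ignore_index=True
    )
    return df
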