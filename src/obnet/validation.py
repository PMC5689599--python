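"""Expression-based validation: differential connectivity and module overlap.

Module differential connectivity (MDC) asks whether a gene module's
co-expression tightens or loosens between two conditions: connectivity of
a gene pair is the absolute Pearson correlation within a condition's
samples, and MDC is the ratio of the mean pairwise connectivity in
condition A to that in condition B.  MDC > 1 means the module gains
connectivity going from B to A.  Significance comes from shuffling the
condition labels over samples.

Module-overlap tests compare two module collections (e.g. network-derived
modules against co-expression modules) pair by pair with one-sided
Fisher's exact tests, Benjamini-Hochberg adjusted, and a size-preserving
gene-label permutation study calibrates how many significant overlaps
would arise by chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a per-sample condition label."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids
    condition: pd.Series  # index = sample ids

    def samples_of(self, cond: str) -> list[str]:
        return [s for s in self.values.columns if self.condition[s] == cond]


@dataclass(frozen=True)
class OverlapTest:
    module_a: str
    module_b: str
    overlap: int
    p: float
    p_adjusted: float


def _mean_connectivity(sub: np.ndarray, power: float) -> float:
    """Mean |Pearson r|^power over distinct gene pairs (genes x samples)."""
    corr = np.corrcoef(sub)
    iu = np.triu_indices_from(corr, k=1)
    vals = np.abs(corr[iu]) ** power
    return float(np.nanmean(vals))


def mdc(
    expr: ExpressionMatrix,
    module_genes,
    cond_a: str,
    cond_b: str,
    power: float = 1.0,
) -> float:
    """Ratio of mean pairwise connectivity between two conditions.

    ``power`` soft-thresholds the adjacency (|r|^power); the default 1
    uses the absolute correlation directly.  Swapping the two conditions
    inverts the ratio exactly.
    """
    genes = [g for g in expr.values.index if g in frozenset(module_genes)]
    if len(genes) < 2:
        raise ValueError("MDC needs at least two module genes present in the matrix")
    sa, sb = expr.samples_of(cond_a), expr.samples_of(cond_b)
    if len(sa) < 3 or len(sb) < 3:
        raise ValueError("MDC needs at least 3 samples per condition")
    ka = _mean_connectivity(expr.values.loc[genes, sa].to_numpy(), power)
    kb = _mean_connectivity(expr.values.loc[genes, sb].to_numpy(), power)
    if kb == 0:
        raise ValueError("zero mean connectivity in the denominator condition")
    return ka / kb


def mdc_significance(
    expr: ExpressionMatrix,
    modules: dict[str, frozenset[str]],
    cond_a: str,
    cond_b: str,
    n_perm: int = 100,
    seed: int | np.random.Generator | None = None,
    power: float = 1.0,
) -> pd.DataFrame:
    """Permutation significance of each module's MDC.

    The null shuffles condition labels over samples ``n_perm`` times; the
    empirical p is two-sided on |log MDC| (the scale on which swapping the
    conditions is a sign flip) with add-one correction
    ``(r + 1)/(n_perm + 1)``, then BH-adjusted across modules.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = expr.condition.loc[list(expr.values.columns)].to_numpy()
    cols = np.array(expr.values.columns)
    observed = {m: mdc(expr, genes, cond_a, cond_b, power=power) for m, genes in modules.items()}

    null_logs = {m: np.empty(n_perm) for m in modules}
    for i in range(n_perm):
        perm = rng.permutation(labels)
        shuffled = ExpressionMatrix(values=expr.values, condition=pd.Series(perm, index=cols))
        for m, genes in modules.items():
            null_logs[m][i] = np.log(mdc(shuffled, genes, cond_a, cond_b, power=power))

    rows = []
    for m in modules:
        obs_log = abs(np.log(observed[m]))
        r = int(np.sum(np.abs(null_logs[m]) >= obs_log))
        rows.append({"module": m, "mdc": observed[m], "p": (r + 1) / (n_perm + 1)})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def overlap_fisher(
    modules_a: dict[str, frozenset[str]],
    modules_b: dict[str, frozenset[str]],
    universe=None,
) -> list[OverlapTest]:
    """One-sided Fisher's exact test on every module pair's gene overlap.

    The 2x2 table classifies the ``universe`` genes (default: the union of
    all genes in both collections) by membership in each module;
    alternative='greater' tests for enrichment.  BH adjustment spans all
    pairs.
    """
    if universe is None:
        universe = frozenset().union(*modules_a.values(), *modules_b.values())
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    tests = []
    for ma in sorted(modules_a):
        a = modules_a[ma] & universe
        for mb in sorted(modules_b):
            b = modules_b[mb] & universe
            ov = len(a & b)
            table = [
                [ov, len(a) - ov],
                [len(b) - ov, len(universe) - len(a) - len(b) + ov],
            ]
            _, p = fisher_exact(table, alternative="greater")
            tests.append((ma, mb, ov, float(p)))
    padj = multipletests([t[3] for t in tests], method="fdr_bh")[1]
    return [
        OverlapTest(module_a=ma, module_b=mb, overlap=ov, p=p, p_adjusted=float(q))
        for (ma, mb, ov, p), q in zip(tests, padj)
    ]


def count_significant_a_modules(tests: list[OverlapTest], alpha: float = 0.05) -> int:
    """Number of first-collection modules significantly overlapping any pair."""
    return len({t.module_a for t in tests if t.p_adjusted < alpha})


def normal_upper_p(observed: float, mean: float, sd: float) -> tuple[float, float]:
    """z and one-sided upper-tail normal p of an observed permutation count."""
    z = (observed - mean) / sd
    return float(z), float(norm.sf(z))


@dataclass
class PermutationStudy:
    observed: int
    mean_hits: float
    sd_hits: float
    z: float
    p_observed: float
    null_counts: np.ndarray


def overlap_permutation_study(
    modules_a: dict[str, frozenset[str]],
    modules_b: dict[str, frozenset[str]],
    selector,
    n_perm: int = 1000,
    top_k: int = 10,
    seed: int | np.random.Generator | None = None,
    universe=None,
    alpha: float = 0.05,
) -> PermutationStudy:
    """Size-preserving label-shuffle calibration of module-overlap counts.

    ``selector(modules)`` returns the labels of the ``top_k`` modules of a
    (possibly permuted) second collection — typically the most
    differentially connected by MDC.  Observed statistic: the number of
    first-collection modules significantly overlapping (BH FDR < ``alpha``)
    any selected module.  Each permutation reassigns the second
    collection's genes to its labels uniformly, preserving every module's
    size, and recomputes the count.  The observed count is compared to the
    permutation mean and sd through an upper-tail normal approximation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def hits(mods_b: dict[str, frozenset[str]]) -> int:
        top = {m: mods_b[m] for m in selector(mods_b)[:top_k]}
        return count_significant_a_modules(overlap_fisher(modules_a, top, universe=universe), alpha=alpha)

    observed = hits(modules_b)
    labels = sorted(modules_b)
    sizes = {m: len(modules_b[m]) for m in labels}
    pool = np.array(sorted(set().union(*modules_b.values())))
    disjoint = sum(sizes.values()) == len(pool)
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        mods = {}
        if disjoint:
            # partition shuffle: one permutation of the pool, cut to sizes
            shuffled = rng.permutation(pool)
            start = 0
            for m in labels:
                mods[m] = frozenset(shuffled[start : start + sizes[m]].tolist())
                start += sizes[m]
        else:
            # overlapping collection: redraw each module independently
            for m in labels:
                mods[m] = frozenset(rng.choice(pool, size=sizes[m], replace=False).tolist())
        assert all(len(mods[m]) == sizes[m] for m in labels)
        null[i] = hits(mods)
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    z, p = normal_upper_p(observed, mean, sd) if sd > 0 else (np.inf if observed > mean else 0.0, 0.5)
    if sd == 0:
        p = 0.5 if observed == mean else (0.0 if observed > mean else 1.0)
        z = float(z)
    return PermutationStudy(
        observed=observed, mean_hits=mean, sd_hits=sd, z=float(z), p_observed=float(p), null_counts=null
    )
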