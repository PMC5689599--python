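"""Random walk with restart on a column-normalized adjacency matrix.

The walk models network proximity to a seed gene set: a walker at node *j*
moves to a uniformly chosen neighbour with probability ``1 - r`` and
teleports back to the seeds with probability ``r``.  Its stationary
distribution ``p`` solves the fixed point

    p = (1 - r) A' p + r p0,

where ``A'`` is the adjacency matrix normalized column-wise so each
non-isolated column is a probability distribution over neighbours, and
``p0`` places mass ``1/m`` on each of the ``m`` seed genes.  The fixed point
is reached by power iteration, stopped when the L1 difference between
successive iterates falls below ``tol``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import GeneNetwork

logger = logging.getLogger(__name__)


@dataclass
class TransitionMatrix:
    """Column-stochastic walk matrix with its node indexing.

    ``matrix[i, j]`` is the probability of stepping to node ``i`` from node
    ``j``; columns of isolated nodes are all-zero.
    """

    matrix: sp.csc_matrix
    node_order: list[str]
    index: dict[str, int] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.node_order)


@dataclass
class RWRProfile:
    """Converged walk probabilities over ``node_order``."""

    p: np.ndarray
    node_order: list[str]
    seeds: frozenset[str]
    r: float
    iterations: int

    def probability(self, gene: str) -> float:
        return float(self.p[self.node_order.index(gene)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.node_order, self.p.tolist()))


def normalize_adjacency(net: GeneNetwork) -> TransitionMatrix:
    """Build the column-normalized transition matrix of an unweighted network.

    Every edge counts 1 regardless of any confidence attribute (confidences
    are used only for the upstream edge-list cut).  Columns of isolated
    nodes are left all-zero and handled downstream.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot normalize an empty network")
    node_order = sorted(net.nodes())
    A = nx_adjacency(net, node_order)
    colsum = np.asarray(A.sum(axis=0)).ravel()
    inv = np.divide(1.0, colsum, out=np.zeros_like(colsum, dtype=float), where=colsum > 0)
    Ap = (A @ sp.diags(inv)).tocsc()
    return TransitionMatrix(matrix=Ap, node_order=node_order, index={g: i for i, g in enumerate(node_order)})


def nx_adjacency(net: GeneNetwork, node_order: list[str]) -> sp.csc_matrix:
    import networkx as nx

    return nx.to_scipy_sparse_array(net, nodelist=node_order, weight=None, format="csc").astype(float)


def seed_vector(tm: TransitionMatrix, seeds) -> tuple[np.ndarray, frozenset[str]]:
    """Uniform probability vector over the seeds present on the network.

    Off-network seeds are dropped with a warning; an error is raised only
    when none remain.
    """
    on_net = frozenset(s for s in seeds if s in tm.index)
    dropped = frozenset(seeds) - on_net
    if dropped:
        logger.warning("rwr: %d seed gene(s) not on network, dropped", len(dropped))
    if not on_net:
        raise ValueError("no seed gene maps onto the network")
    p0 = np.zeros(tm.n)
    p0[[tm.index[s] for s in on_net]] = 1.0 / len(on_net)
    return p0, on_net


def rwr(
    tm: TransitionMatrix,
    seeds,
    r: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> RWRProfile:
    """Iterate the restart walk to its fixed point.

    Parameters
    ----------
    r
        Restart probability, ``0 < r < 1``. Default 0.5.
    tol
        L1 convergence threshold on successive iterates. Default 1e-6.

    Notes
    -----
    All-zero columns of isolated nodes leak probability mass; the converged
    vector is renormalized to sum 1 (rank order is unaffected) and the
    leaked fraction logged.
    """
    if not 0 < r < 1:
        raise ValueError(f"restart probability must be in (0, 1), got {r}")
    p0, on_net = seed_vector(tm, seeds)
    A = tm.matrix
    p = p0.copy()
    for it in range(1, max_iter + 1):
        p_next = (1.0 - r) * (A @ p) + r * p0
        if np.abs(p_next - p).sum() < tol:
            p = p_next
            break
        p = p_next
    else:
        resid = float(np.abs((1.0 - r) * (A @ p) + r * p0 - p).sum())
        raise RuntimeError(f"rwr did not converge in {max_iter} iterations; last residual {resid:.3g}")
    total = p.sum()
    if abs(total - 1.0) > 1e-12 and total > 0:
        logger.debug("rwr: renormalizing, leaked fraction %.3g", 1.0 - total)
        p = p / total
    return RWRProfile(p=p, node_order=tm.node_order, seeds=on_net, r=r, iterations=it)


def rwr_batch(
    tm: TransitionMatrix,
    seed_matrix: np.ndarray,
    r: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Converge many restart walks on the same matrix simultaneously.

    ``seed_matrix`` holds one initial probability vector per column; the
    power iteration runs on the whole block until every column's L1
    difference is below ``tol``.  Columns are renormalized to sum 1 after
    convergence (mass can leak through all-zero columns of isolated
    nodes).  Used by the permutation null, where a hundred walks differ
    only in their seed vector.
    """
    A = tm.matrix
    P0 = seed_matrix
    P = P0.copy()
    for _ in range(max_iter):
        P_next = (1.0 - r) * (A @ P) + r * P0
        if np.abs(P_next - P).sum(axis=0).max() < tol:
            P = P_next
            break
        P = P_next
    else:
        raise RuntimeError(f"batched rwr did not converge in {max_iter} iterations")
    return P / P.sum(axis=0, keepdims=True)


def rwr_direct(tm: TransitionMatrix, seeds, r: float = 0.5) -> np.ndarray:
    """Fixed point by direct linear solve of ``(I - (1-r)A') p = r p0``.

    Exact reference for the iterative solver; dense, intended for
    small networks.
    """
    p0, _ = seed_vector(tm, seeds)
    n = tm.n
    M = np.eye(n) - (1.0 - r) * tm.matrix.toarray()
    p = np.linalg.solve(M, r * p0)
    return p / p.sum()


def rank_by_probability(profile: RWRProfile, exclude=frozenset()) -> list[str]:
    """Genes sorted by walk probability, descending; ties lexicographic.

    ``exclude`` genes (typically the seeds) are omitted from the ranking.
    """
    exclude = frozenset(exclude)
    prob = dict(zip(profile.node_order, profile.p))
    return sorted((g for g in profile.node_order if g not in exclude), key=lambda g: (-prob[g], g))
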