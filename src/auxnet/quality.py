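"""Connectivity-profile distance diagnostics and partition comparison.

The block-model parameters describe edges, not vertices, so cluster
homogeneity and separability are assessed directly from the adjacency
information.  The distance between proteins i and j,

    D(i, j) = sum_k |x_ik - x_jk| / N,

quantifies the difference of their connectivity profiles (rows of the
adjacency matrix); on a binary matrix it is the Sokal-Michener distance,
the proportion of mismatching entries.  Protein-to-cluster distances
D(i, q) average over the (possibly soft) members of q, cluster-to-cluster
distances D(q, l) over member pairs, and within-/between-cluster
distances summarize each cluster; a cluster is well defined ("strong
definition") when its within distance is smaller than its distances to
every other cluster.  The k-sum includes all N columns (diagonal entries
absent from the model are imputed as 0), keeping distances comparable
across networks.

Distance accumulations use exactly rounded summation (``math.fsum``) so
that the deterministic-assignment formulas and the soft formulas agree
bitwise whenever tau is 0/1.  Rosters here never exceed a few hundred
proteins, so the exact path costs nothing that matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ClusterDiagnostics",
    "profile_distance_matrix",
    "protein_cluster_distances",
    "protein_cluster_distances_hard",
    "cluster_distance_matrix",
    "partition_match",
    "membership_table",
]


@dataclass
class ClusterDiagnostics:
    """Distance summaries of a clustering.

    ``protein_cluster`` is the N x Q matrix D(i, q); ``cluster_cluster``
    the symmetric Q x Q matrix D(q, l) whose diagonal holds the
    within-cluster distances; ``within``/``between`` the per-cluster
    summaries; ``n_q`` the (soft) cluster sizes.  Undefined entries
    (zero-mass or singleton clusters) are NaN and listed in ``flags``.
    """

    protein_cluster: np.ndarray
    cluster_cluster: np.ndarray
    within: np.ndarray
    between: np.ndarray
    n_q: np.ndarray
    flags: list[str]


def profile_distance_matrix(A: np.ndarray, impute_diagonal: float = 0.0) -> np.ndarray:
    """Pairwise connectivity-profile distances D(i, j).

    Works for valued and binary adjacencies alike: for a 0/1 matrix the
    mean absolute row difference equals the proportion of mismatching
    columns.  The diagonal of ``A`` is replaced by ``impute_diagonal``
    before comparing rows.
    """
    A = np.array(A, dtype=float, copy=True)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    np.fill_diagonal(A, impute_diagonal)
    N = A.shape[0]
    D = np.empty((N, N))
    for i in range(N):
        D[i, i] = 0.0
        for j in range(i + 1, N):
            D[i, j] = D[j, i] = math.fsum(np.abs(A[i] - A[j])) / N
    return D


def _as_tau(tau: np.ndarray) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    if tau.ndim == 1:  # labels given; expand to one-hot
        labels = tau.astype(int)
        Q = labels.max() + 1
        out = np.zeros((labels.size, Q))
        out[np.arange(labels.size), labels] = 1.0
        return out
    return tau


def protein_cluster_distances(D: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Soft protein-to-cluster distances.

    D(i, q) = sum_{j != i} tau_jq D(i, j) / sum_{j != i} tau_jq.  With a
    hard tau this reduces to the usual mean over the members of q, with
    denominator n_q - 1 when i belongs to q (itself excluded) and n_q
    otherwise.  Clusters with zero mass (excluding i) give NaN.
    """
    tau = _as_tau(tau)
    D = np.asarray(D, dtype=float)
    N, Q = tau.shape
    out = np.full((N, Q), np.nan)
    for q in range(Q):
        for i in range(N):
            den = math.fsum(tau[j, q] for j in range(N) if j != i)
            if den > 0:
                num = math.fsum(tau[j, q] * D[i, j] for j in range(N) if j != i)
                out[i, q] = num / den
    return out


def protein_cluster_distances_hard(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Deterministic-assignment formulas with n_q - 1 / n_q denominators."""
    labels = np.asarray(labels, dtype=int)
    D = np.asarray(D, dtype=float)
    N = labels.size
    Q = labels.max() + 1
    out = np.full((N, Q), np.nan)
    for q in range(Q):
        members = np.flatnonzero(labels == q)
        n_q = members.size
        for i in range(N):
            if labels[i] == q:
                if n_q > 1:
                    out[i, q] = math.fsum(D[i, j] for j in members if j != i) / (n_q - 1)
            elif n_q > 0:
                out[i, q] = math.fsum(D[i, j] for j in members) / n_q
    return out


def cluster_distance_matrix(D: np.ndarray, tau: np.ndarray) -> ClusterDiagnostics:
    """Within- and between-cluster distance summaries.

    D(q, q) averages over within-cluster unordered pairs (denominator
    n_q (n_q - 1)), D(q, l) over cross pairs (denominator n_q n_l), and
    D_between(q) over pairs straddling q (denominator n_q (N - n_q)); the
    soft generalization replaces counts by tau masses and reduces to the
    printed formulas for 0/1 tau.  Singleton (or zero-mass) clusters have
    undefined within distance and are flagged.
    """
    tau = _as_tau(tau)
    D = np.asarray(D, dtype=float)
    N, Q = tau.shape
    n_q = np.array([math.fsum(tau[:, q]) for q in range(Q)])
    flags: list[str] = []

    cc = np.full((Q, Q), np.nan)
    for q in range(Q):
        for l in range(q, Q):
            num = math.fsum(tau[i, q] * tau[j, l] * D[i, j]
                            for i in range(N) for j in range(N) if i != j)
            if q == l:
                den = n_q[q] ** 2 - math.fsum(tau[i, q] ** 2 for i in range(N))
                if den > 1e-12:
                    cc[q, q] = num / den
                else:
                    flags.append(f"cluster {q}: within-distance undefined "
                                 "(singleton or empty)")
            else:
                den = n_q[q] * n_q[l]
                if den > 1e-12:
                    cc[q, l] = cc[l, q] = num / den
                else:
                    flags.append(f"cluster pair ({q},{l}): distance undefined")

    between = np.full(Q, np.nan)
    for q in range(Q):
        den = n_q[q] * (N - n_q[q])
        if den > 1e-12:
            num = math.fsum(tau[i, q] * (1.0 - tau[j, q]) * D[i, j]
                            for i in range(N) for j in range(N) if i != j)
            between[q] = num / den
    pc = protein_cluster_distances(D, tau)
    return ClusterDiagnostics(
        protein_cluster=pc,
        cluster_cluster=cc,
        within=np.diag(cc).copy(),
        between=between,
        n_q=n_q,
        flags=flags,
    )


def partition_match(p1, p2) -> tuple[int, int]:
    """Best agreement between two partitions of the same roster.

    Maximizes the number of items on which the partitions agree over all
    injective matchings of cluster labels (optimal assignment on the
    confusion matrix).  Returns ``(percent, count)`` with the percentage
    rounded to the nearest integer; identical partitions of 46 proteins
    give ``(100, 46)``.
    """
    a = np.asarray(p1)
    b = np.asarray(p2)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be equal-length label vectors")
    _, ia = np.unique(a, return_inverse=True)
    _, ib = np.unique(b, return_inverse=True)
    C = np.zeros((ia.max() + 1, ib.max() + 1), dtype=int)
    np.add.at(C, (ia, ib), 1)
    r, c = linear_sum_assignment(-C)
    count = int(C[r, c].sum())
    percent = int(round(100.0 * count / a.size))
    return percent, count


def membership_table(roster, tau: np.ndarray, D: np.ndarray) -> pd.DataFrame:
    """Per-protein cluster membership sorted by centrality.

    One row per protein with its assigned cluster and D(i, q) to that
    cluster; within each cluster, members are listed most central first
    (ascending D(i, q)).
    """
    tau = _as_tau(tau)
    labels = np.argmax(tau, axis=1)
    pc = protein_cluster_distances(D, tau)
    rows = [{"protein": p, "cluster": int(labels[i]),
             "distance_to_cluster": pc[i, labels[i]]}
            for i, p in enumerate(roster.proteins)]
    table = pd.DataFrame(rows)
    return (table.sort_values(["cluster", "distance_to_cluster", "protein"])
                 .reset_index(drop=True))
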