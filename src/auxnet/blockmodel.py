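"""Mixture models for undirected random graphs (stochastic block models).

Each vertex i belongs to an unobserved cluster among Q, with membership
probabilities alpha_q.  Conditionally on memberships, edges are
independent with a law that depends only on the endpoint clusters:

* ``bernoulli``            Z_ij | i in q, j in l  ~  B(pi_ql)
* ``gaussian``             X_ij | i in q, j in l  ~  N(mu_ql, sigma^2)
* ``gaussian_regression``  X_ij | ...  ~  N(mu_ql + Y_ij' b_ql, sigma^2)

where Y_ij is a vector of d edge covariates (here: sequence
dissimilarities between dimerisation domains) and b_ql a per-cluster-pair
coefficient vector.  The variance sigma^2 is a single scalar shared by
all cluster pairs.  The graph is undirected with no self-loops: all edge
sums run over unordered pairs i < j and the adjacency diagonal is
ignored.

Inference is by variational EM.  The E-step approximates the membership
posterior by a mean-field distribution tau_iq updated with the fixed
point

    tau_iq  propto  alpha_q  prod_{j != i} prod_l (phi_ij^{ql})^{tau_jl},

computed in the log domain; rows are updated sequentially, which is
coordinate ascent on the lower bound

    J = sum_iq tau_iq log alpha_q
      + sum_{i<j} sum_{q,l} tau_iq tau_jl log phi_ij^{ql}
      - sum_iq tau_iq log tau_iq

and therefore monotone.  The M-step solves tau-weighted least squares
per unordered cluster pair.  The number of clusters is chosen by the ICL
criterion with its double penalty (memberships on the n vertices,
edge parameters on the n(n-1)/2 edges):

    ICL = J - (Q-1)/2 log n - Q^2 (d+1)/2 log(n(n-1)/2),

with (Q-1) + Q^2 (d+1) independent parameters overall.  A difference of
ICL of at least log(100) ~= 4.6 (Jeffreys' rule of thumb) is needed to
deem the higher-ICL model substantially better.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .covariates import CovariateSet

__all__ = [
    "FAMILIES",
    "JEFFREYS_THRESHOLD",
    "BlockParameters",
    "BlockModelFit",
    "NetworkBlockModel",
    "e_step",
    "m_step",
    "lower_bound",
    "fit_blockmodel",
    "icl_score",
    "n_parameters",
    "jeffreys_substantial",
    "model_scan",
]

FAMILIES = ("bernoulli", "gaussian", "gaussian_regression")

#: ICL gap deemed "substantial" evidence (Jeffreys): log(100).
JEFFREYS_THRESHOLD: float = math.log(100.0)

_PI_EPS = 1e-12
_SIGMA2_FLOOR = 1e-12


@dataclass
class BlockParameters:
    """Parameters of one block model.

    ``mu`` holds the interaction probabilities pi_ql for the bernoulli
    family and the mean edge weights mu_ql for the valued families;
    ``beta`` is (Q, Q, d) or ``None``; ``sigma2`` is the shared residual
    variance (``None`` for bernoulli).  All cluster-pair matrices are
    symmetric in (q, l).
    """

    family: str
    alpha: np.ndarray
    mu: np.ndarray
    beta: np.ndarray | None = None
    sigma2: float | None = None

    @property
    def Q(self) -> int:
        return len(self.alpha)

    @property
    def d(self) -> int:
        return 0 if self.beta is None else self.beta.shape[2]

    @property
    def pi(self) -> np.ndarray:
        """Bernoulli interaction probabilities (alias of ``mu``)."""
        if self.family != "bernoulli":
            raise AttributeError("pi is defined for the bernoulli family")
        return self.mu


@dataclass
class BlockModelFit:
    """Converged variational-EM fit of a block model."""

    params: BlockParameters
    tau: np.ndarray
    J: float
    icl: float
    n_params: int
    n_iter: int
    converged: bool
    seed: int | None = None

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.tau, axis=1)

    @property
    def Q(self) -> int:
        return self.params.Q


def _as_covariate_array(Y, n: int) -> np.ndarray | None:
    """Normalize covariates to shape (d, n, n) or None."""
    if Y is None:
        return None
    if isinstance(Y, CovariateSet):
        Y = Y.matrices
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 2:
        Y = Y[None]
    if Y.shape[1:] != (n, n):
        raise ValueError(f"covariates must be (d, {n}, {n})")
    return Y


def _log_phi(X: np.ndarray, Y: np.ndarray | None, params: BlockParameters) -> np.ndarray:
    """Log edge density log phi_ij^{ql}, shape (n, n, Q, Q), zero diagonal."""
    n = X.shape[0]
    if params.family == "bernoulli":
        p = np.clip(params.mu, _PI_EPS, 1 - _PI_EPS)
        Zb = X[:, :, None, None]
        lp = Zb * np.log(p)[None, None] + (1.0 - Zb) * np.log1p(-p)[None, None]
    else:
        pred = np.broadcast_to(params.mu[None, None], (n, n, params.Q, params.Q)).copy()
        if params.beta is not None and params.d:
            pred += np.einsum("dij,qld->ijql", Y, params.beta)
        sigma2 = max(float(params.sigma2), _SIGMA2_FLOOR)
        resid = X[:, :, None, None] - pred
        lp = -0.5 * math.log(2 * math.pi * sigma2) - resid ** 2 / (2 * sigma2)
    if not np.all(np.isfinite(lp[~np.eye(n, dtype=bool)])):
        bad = np.argwhere(~np.isfinite(lp))
        raise FloatingPointError(f"non-finite log edge density at pair {tuple(bad[0][:2])}")
    lp[np.arange(n), np.arange(n)] = 0.0  # self-pairs carry no likelihood
    return lp


def e_step(
    X: np.ndarray,
    Y,
    params: BlockParameters,
    tau_init: np.ndarray,
    max_sweeps: int = 100,
    tol: float = 1e-6,
) -> np.ndarray:
    """Mean-field posterior memberships by the fixed-point formula.

    Rows of tau are updated one at a time in the log domain and
    renormalized; sequential updates make each sweep an ascent on the
    variational bound.  Stops when the largest elementwise change falls
    below ``tol`` or after ``max_sweeps`` sweeps.
    """
    n = X.shape[0]
    Y = _as_covariate_array(Y, n)
    lp = _log_phi(X, Y, params)
    with np.errstate(divide="ignore"):
        log_alpha = np.where(params.alpha > 0, np.log(np.maximum(params.alpha, 1e-300)),
                             -np.inf)
    tau = np.array(tau_init, dtype=float, copy=True)
    for _ in range(max_sweeps):
        delta = 0.0
        for i in range(n):
            field = log_alpha + np.einsum("jql,jl->q", lp[i], tau)
            field -= logsumexp(field)
            new = np.exp(field)
            delta = max(delta, float(np.abs(new - tau[i]).max()))
            tau[i] = new
        if delta < tol:
            break
    return tau


def _pair_weights(tau: np.ndarray, q: int, l: int, iu) -> np.ndarray:
    """Soft weight of each unordered edge for the unordered cluster pair (q, l)."""
    i, j = iu
    if q == l:
        return tau[i, q] * tau[j, q]
    return tau[i, q] * tau[j, l] + tau[i, l] * tau[j, q]


def m_step(X: np.ndarray, Y, tau: np.ndarray, family: str,
           ridge: float = 1e-10) -> BlockParameters:
    """Maximum of the variational bound over the parameters.

    alpha_q is the mean membership; for each unordered cluster pair the
    (mu_ql, b_ql) solve the tau-weighted least-squares regression of edge
    weights on covariates over i < j; sigma^2 is pooled over all edges
    and cluster pairs.  For the bernoulli family pi_ql is the weighted
    edge density.  Cluster pairs with (near-)zero total weight are
    stabilized by a small ridge on the normal equations.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    n, Q = tau.shape
    Y = _as_covariate_array(Y, n)
    d = 0 if (Y is None or family != "gaussian_regression") else Y.shape[0]

    alpha = tau.mean(axis=0)
    iu = np.triu_indices(n, k=1)
    x = X[iu]
    mu = np.zeros((Q, Q))
    beta = np.zeros((Q, Q, d)) if d else None

    if family == "bernoulli":
        for q in range(Q):
            for l in range(q, Q):
                w = _pair_weights(tau, q, l, iu)
                sw = w.sum()
                p = float((w * x).sum() / sw) if sw > ridge else 0.5
                mu[q, l] = mu[l, q] = p
        return BlockParameters(family=family, alpha=alpha, mu=mu)

    A = np.empty((x.size, d + 1))
    A[:, 0] = 1.0
    for k in range(d):
        A[:, 1 + k] = Y[k][iu]
    rss = 0.0
    wsum = 0.0
    for q in range(Q):
        for l in range(q, Q):
            w = _pair_weights(tau, q, l, iu)
            Aw = A * w[:, None]
            G = A.T @ Aw
            G[np.diag_indices_from(G)] += ridge * (1.0 + np.trace(G))
            coef = np.linalg.solve(G, Aw.T @ x)
            mu[q, l] = mu[l, q] = coef[0]
            if d:
                beta[q, l] = beta[l, q] = coef[1:]
            resid = x - A @ coef
            rss += float(w @ resid ** 2)
            wsum += float(w.sum())
    sigma2 = max(rss / wsum, _SIGMA2_FLOOR) if wsum > 0 else 1.0
    return BlockParameters(family=family, alpha=alpha, mu=mu, beta=beta,
                           sigma2=sigma2)


def lower_bound(X: np.ndarray, Y, params: BlockParameters, tau: np.ndarray) -> float:
    """Variational lower bound J of the observed-data log-likelihood.

    The edge sum runs over unordered pairs i < j; 0 log 0 is taken as 0
    in both the membership and entropy terms.
    """
    n = X.shape[0]
    Y = _as_covariate_array(Y, n)
    lp = _log_phi(X, Y, params)
    with np.errstate(divide="ignore", invalid="ignore"):
        la = np.log(np.maximum(params.alpha, 1e-300))
        member = float(np.where(tau > 0, tau * la[None, :], 0.0).sum())
        entropy = -float(np.where(tau > 0, tau * np.log(np.maximum(tau, 1e-300)),
                                  0.0).sum())
    edges = 0.5 * float(np.einsum("iq,jl,ijql->", tau, tau, lp))
    return member + edges + entropy


def n_parameters(Q: int, d: int) -> int:
    """Independent parameter count (Q-1) + Q^2 (d+1)."""
    return (Q - 1) + Q * Q * (d + 1)


def icl_score(J: float, n: int, Q: int, d: int) -> float:
    """ICL with the double penalty on vertices and edges."""
    if n < 2:
        raise ValueError("need at least two vertices")
    return (J
            - (Q - 1) / 2.0 * math.log(n)
            - Q * Q * (d + 1) / 2.0 * math.log(n * (n - 1) / 2.0))


def jeffreys_substantial(icl_a: float, icl_b: float) -> bool:
    """Whether the ICL gap clears Jeffreys' substantial-evidence bar log(100)."""
    return abs(icl_a - icl_b) >= JEFFREYS_THRESHOLD


def _ward_init(X: np.ndarray, Q: int) -> np.ndarray:
    """Hard initial memberships from Ward clustering of adjacency rows."""
    n = X.shape[0]
    if Q == 1:
        return np.ones((n, 1))
    rows = np.array(X, dtype=float, copy=True)
    np.fill_diagonal(rows, 0.0)
    with warnings.catch_warnings():
        # rows are observations (connectivity profiles), not a distance matrix
        warnings.simplefilter("ignore")
        labels = fcluster(linkage(rows, method="ward"), t=Q, criterion="maxclust") - 1
    tau = np.zeros((n, Q))
    tau[np.arange(n), np.minimum(labels, Q - 1)] = 1.0
    return tau


def _validate_adjacency(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("adjacency must be square")
    off = ~np.eye(X.shape[0], dtype=bool)
    if not np.all(np.isfinite(X[off])):
        raise ValueError("adjacency has non-finite off-diagonal entries")
    if not np.allclose(X, X.T, equal_nan=True):
        raise ValueError("adjacency must be symmetric")
    X = np.array(X, copy=True)
    np.fill_diagonal(X, 0.0)
    return X


def fit_blockmodel(
    X,
    Y=None,
    family: str = "gaussian",
    Q: int = 2,
    n_restarts: int = 10,
    random_state: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    e_step_max_sweeps: int = 100,
    e_step_tol: float = 1e-6,
) -> BlockModelFit:
    """Variational EM over ``n_restarts`` initializations; best J wins.

    One start comes from Ward clustering of the adjacency rows, the rest
    are random soft memberships.  EM alternates M- and E-steps until the
    relative change of J falls below ``tol`` or ``max_iter`` iterations.
    Deterministic given ``random_state``.
    """
    X = _validate_adjacency(X)
    n = X.shape[0]
    if Q < 1 or n < Q:
        raise ValueError("need 1 <= Q <= n")
    if family == "bernoulli" and Y is not None:
        raise ValueError("the bernoulli family takes no covariates")
    Yarr = _as_covariate_array(Y, n)
    rng = np.random.default_rng(random_state)

    starts = [_ward_init(X, Q)]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.dirichlet(np.ones(Q), size=n))

    best: BlockModelFit | None = None
    for tau0 in starts:
        tau = np.asarray(tau0, dtype=float)
        J_prev = -np.inf
        n_iter = 0
        converged = False
        try:
            for n_iter in range(1, max_iter + 1):
                params = m_step(X, Yarr, tau, family)
                tau = e_step(X, Yarr, params, tau, max_sweeps=e_step_max_sweeps,
                             tol=e_step_tol)
                J = lower_bound(X, Yarr, params, tau)
                if np.isfinite(J_prev) and abs(J - J_prev) <= tol * (abs(J_prev) + 1e-12):
                    converged = True
                    J_prev = J
                    break
                J_prev = J
        except FloatingPointError:
            continue
        d = 0 if Yarr is None or family != "gaussian_regression" else Yarr.shape[0]
        fit = BlockModelFit(
            params=params,
            tau=tau,
            J=float(J_prev),
            icl=icl_score(float(J_prev), n, Q, d),
            n_params=n_parameters(Q, d),
            n_iter=n_iter,
            converged=converged,
            seed=random_state,
        )
        if best is None or fit.J > best.J:
            best = fit
    if best is None:
        raise RuntimeError("all EM restarts failed")
    return best


def model_scan(
    X,
    Y=None,
    family: str = "gaussian",
    Q_range=range(1, 8),
    n_restarts: int = 10,
    random_state: int | None = None,
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict[int, BlockModelFit]]:
    """Fit one model per cluster count and rank them by ICL.

    Returns a table with one row per Q (J, ICL, parameter count,
    posterior model probability as the exp-normalized ICL over the
    scanned models, best-model and Jeffreys-substantial flags) plus the
    fits themselves.  Failures for individual Q are recorded and the
    scan continues.
    """
    rows = []
    fits: dict[int, BlockModelFit] = {}
    for Q in Q_range:
        try:
            fit = fit_blockmodel(X, Y, family=family, Q=int(Q),
                                 n_restarts=n_restarts, random_state=random_state,
                                 **fit_kwargs)
        except Exception as exc:  # propagate per-Q failure into the table
            rows.append({"family": family, "Q": int(Q), "J": np.nan, "icl": np.nan,
                         "n_params": np.nan, "error": str(exc)})
            continue
        fits[int(Q)] = fit
        rows.append({"family": family, "Q": int(Q), "J": fit.J, "icl": fit.icl,
                     "n_params": fit.n_params, "error": ""})
    table = pd.DataFrame(rows)
    icl = table["icl"].to_numpy(dtype=float)
    ok = np.isfinite(icl)
    post = np.zeros(len(table))
    if ok.any():
        post[ok] = np.exp(icl[ok] - logsumexp(icl[ok]))
    table["post_proba"] = post
    table["best"] = False
    if ok.any():
        best_pos = int(np.nanargmax(np.where(ok, icl, -np.inf)))
        table.loc[table.index[best_pos], "best"] = True
        others = icl[ok][np.argsort(icl[ok])[::-1]]
        table["substantial"] = False
        if ok.sum() > 1:
            table.loc[table.index[best_pos], "substantial"] = bool(
                others[0] - others[1] >= JEFFREYS_THRESHOLD)
    else:
        table["substantial"] = False
    return table, fits


class NetworkBlockModel(ClusterMixin, BaseEstimator):
    """Block-model clustering of an undirected graph, sklearn-style.

    Parameters
    ----------
    family : {"bernoulli", "gaussian", "gaussian_regression"}
        Edge law conditional on the endpoint clusters.
    n_clusters : int
        Number of latent clusters Q.
    n_restarts : int
        EM initializations (one Ward start plus random soft starts).
    max_iter, tol : EM stopping rule (relative change of the bound J).
    e_step_max_sweeps, e_step_tol : fixed-point stopping rule.
    random_state : seed for the random restarts.

    Attributes
    ----------
    weights_ : (Q,) cluster membership probabilities alpha_q.
    means_ : (Q, Q) mean edge weights mu_ql (valued families) or
        interaction probabilities pi_ql (bernoulli).
    coef_ : (Q, Q, d) regression coefficients, or None.
    sigma2_ : shared residual variance, or None for bernoulli.
    responsibilities_ : (n, Q) variational posteriors tau_iq.
    labels_ : argmax cluster assignment per vertex.
    lower_bound_ : converged variational bound J.
    icl_ : ICL score of the fit.
    n_parameters_ : independent parameter count.
    """

    def __init__(self, family: str = "gaussian", n_clusters: int = 2,
                 n_restarts: int = 10, max_iter: int = 500, tol: float = 1e-8,
                 e_step_max_sweeps: int = 100, e_step_tol: float = 1e-6,
                 random_state: int | None = None):
        self.family = family
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.e_step_max_sweeps = e_step_max_sweeps
        self.e_step_tol = e_step_tol
        self.random_state = random_state

    def fit(self, X, y=None, covariates=None):
        """Fit to a symmetric adjacency matrix (diagonal ignored)."""
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        fit = fit_blockmodel(
            X, covariates, family=self.family, Q=self.n_clusters,
            n_restarts=self.n_restarts, random_state=self.random_state,
            max_iter=self.max_iter, tol=self.tol,
            e_step_max_sweeps=self.e_step_max_sweeps, e_step_tol=self.e_step_tol,
        )
        self.fit_ = fit
        self.weights_ = fit.params.alpha
        self.means_ = fit.params.mu
        self.coef_ = fit.params.beta
        self.sigma2_ = fit.params.sigma2
        self.responsibilities_ = fit.tau
        self.labels_ = fit.labels
        self.lower_bound_ = fit.J
        self.icl_ = fit.icl
        self.n_parameters_ = fit.n_params
        self.n_iter_ = fit.n_iter
        return self

    def score(self, X=None, y=None) -> float:
        """Variational lower bound of the fitted model."""
        check_is_fitted(self, "fit_")
        return self.lower_bound_
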