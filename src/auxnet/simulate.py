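"""Synthetic Y2H screens, covariates and block-model graphs with ground truth.

The generator mirrors the statistical structure the analysis assumes:
proteins carry a planted cluster membership; interaction status (or edge
weight) depends only on the endpoint clusters; per orientation, the
X-Gal reporter emits marks from interaction-conditional ordinal
distributions (interacting pairs skew to '+' and above) and the HIS3
reporter emits optical-density ratios from a three-component Gaussian
mixture whose top component is enriched for interacting pairs, matching
the shape seen in the real screen.  Optional sign-flip noise and missing
HIS3 values emulate experimental imperfections.  All randomness flows
through one seeded generator per call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binarize import BinaryNetwork
from .covariates import CovariateSet
from .standardize import ValuedNetwork
from .y2h import OrdinalScale, Roster

__all__ = [
    "SimulationConfig",
    "BlockGraphSample",
    "simulate_covariates",
    "simulate_blockmodel_graph",
    "simulate_y2h_dataset",
]

#: Mark distribution of a non-interacting ordered pair (codes 0..3).
_NEGATIVE_MARK_PROBS = np.array([0.55, 0.20, 0.15, 0.10])
#: Mark distribution of an interacting ordered pair (codes 4..6).
_POSITIVE_MARK_PROBS = np.array([0.50, 0.30, 0.20])

#: Three-component OD-ratio mixture emulating the empirical HIS3 sample:
#: two low components below the 0.45 threshold and a broad top component.
_OD_MEANS = np.array([0.12, 0.30, 1.00])
_OD_SDS = np.array([0.05, 0.08, 0.25])
_OD_LOW_WEIGHTS = np.array([0.7, 0.3])  # mixture of the two low components


@dataclass
class SimulationConfig:
    """Ground-truth settings for one simulated screen or graph.

    ``mu`` and ``beta`` may be full Q x Q (x d) arrays or scalars; the
    scalar shorthand ``mu=(within, between)`` fills the diagonal and
    off-diagonal cluster pairs.  ``y2h_noise`` holds the per-test
    false-positive/false-negative rates and the HIS3 missing rate.
    """

    n: int = 46
    Q: int = 3
    alpha: np.ndarray | None = None
    family: str = "gaussian"
    mu: object = (0.9, 0.3)
    beta: object = None
    sigma: float = 0.1
    pi: object = (0.7, 0.1)
    covariate_within: float = 0.3
    covariate_between: float = 1.0
    covariate_jitter: float = 0.3
    n_covariates: int = 0
    false_positive_rate: float = 0.0
    false_negative_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha is None:
            self.alpha = np.full(self.Q, 1.0 / self.Q)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if abs(self.alpha.sum() - 1.0) > 1e-9 or np.any(self.alpha < 0):
            raise ValueError("alpha must be a probability vector")
        for rate in (self.false_positive_rate, self.false_negative_rate,
                     self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class BlockGraphSample:
    """A simulated graph with its planted truth."""

    network: object  # ValuedNetwork or BinaryNetwork
    labels: np.ndarray
    covariates: CovariateSet | None
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore


def _expand_pairmatrix(value, Q: int, d: int = 0) -> np.ndarray:
    """Q x Q (x d) symmetric matrix from an array, scalar or (within, between)."""
    if d:
        arr = np.asarray(value, dtype=float)
        if arr.shape == (Q, Q, d):
            return arr
        if arr.shape == (d,):  # one (within==between) value per covariate
            return np.broadcast_to(arr, (Q, Q, d)).copy()
        raise ValueError(f"expected shape ({Q},{Q},{d}) or ({d},)")
    arr = np.asarray(value, dtype=float)
    if arr.shape == (Q, Q):
        return arr
    if arr.shape == ():
        return np.full((Q, Q), float(arr))
    if arr.shape == (2,):
        within, between = arr
        out = np.full((Q, Q), between)
        np.fill_diagonal(out, within)
        return out
    raise ValueError(f"cannot expand {arr.shape} to a {Q}x{Q} cluster-pair matrix")


def _roster(n: int) -> Roster:
    return Roster([f"P{k + 1:02d}" for k in range(n)])


def simulate_covariates(labels, within_mean: float, between_mean: float,
                        jitter: float, seed=None, names=None) -> CovariateSet:
    """Symmetric zero-diagonal covariate matrices with cluster-pair means.

    Each off-diagonal entry is drawn N(mean, jitter^2) truncated at 0,
    the mean chosen by whether the pair lies within or between true
    clusters.  ``seed`` may be an int or a Generator.
    """
    if within_mean < 0 or between_mean < 0:
        raise ValueError("means must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    names = list(names) if names is not None else ["Y1"]
    mats = []
    for _ in names:
        same = labels[:, None] == labels[None, :]
        mean = np.where(same, within_mean, between_mean)
        noise = rng.normal(0.0, 1.0, size=(n, n))
        noise = np.triu(noise, 1)
        noise = noise + noise.T
        mat = np.maximum(mean + jitter * noise, 0.0)
        np.fill_diagonal(mat, 0.0)
        mats.append(mat)
    return CovariateSet(names=names, matrices=np.stack(mats), roster=_roster(n))


def simulate_blockmodel_graph(config: SimulationConfig) -> BlockGraphSample:
    """Draw a graph from the block model with known memberships.

    Labels follow categorical(alpha); for the valued families each
    unordered edge weight is mu_ql (+ covariate term) plus N(0, sigma^2)
    noise; the bernoulli family draws 0/1 edges with probability pi_ql.
    Output is symmetric with an empty diagonal and reproducible per seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, Q = cfg.n, cfg.Q
    labels = rng.choice(Q, size=n, p=cfg.alpha)
    roster = _roster(n)

    covset = None
    Ysum = 0.0
    d = cfg.n_covariates
    if cfg.family == "gaussian_regression" and d == 0:
        d = 1
    if cfg.family == "gaussian_regression":
        names = [f"Y{k + 1}" for k in range(d)]
        covset = simulate_covariates(labels, cfg.covariate_within,
                                     cfg.covariate_between, cfg.covariate_jitter,
                                     seed=rng, names=names)
        beta = _expand_pairmatrix(cfg.beta if cfg.beta is not None else np.zeros(d),
                                  Q, d)
        Ysum = np.einsum("dij,ijd->ij", covset.matrices,
                         beta[labels[:, None], labels[None, :]])
    if cfg.family == "bernoulli":
        P = _expand_pairmatrix(cfg.pi, Q)[labels[:, None], labels[None, :]]
        U = rng.random((n, n))
        U = np.triu(U, 1)
        Z = (U < np.triu(P, 1))
        Z = Z | Z.T
        np.fill_diagonal(Z, False)
        net = BinaryNetwork(roster=roster, Z=Z,
                            configurations=np.where(Z, 1, 0))
    else:
        M = _expand_pairmatrix(cfg.mu, Q)[labels[:, None], labels[None, :]] + Ysum
        E = rng.normal(0.0, 1.0, size=(n, n))
        E = np.triu(E, 1)
        E = E + E.T
        X = M + cfg.sigma * E
        np.fill_diagonal(X, 0.0)
        net = ValuedNetwork(roster=roster, X=X, weights=(0.5, 0.5))
    return BlockGraphSample(network=net, labels=labels, covariates=covset,
                            config=cfg)


def _truncated_normal(rng, mean, sd, low, high, size) -> np.ndarray:
    """Rejection-sampled truncated normal (ranges here keep acceptance high)."""
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, size=todo.size)
        ok = (draw >= low) & (draw < high)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _draw_his3(rng, interacting: np.ndarray, threshold: float = 0.45) -> np.ndarray:
    """OD ratios from the 3-component mixture, conditioned on interaction.

    Interacting pairs draw from the top component truncated above the
    threshold; others draw from the two low components truncated below
    it, so a noise-free screen binarizes back to the planted truth.
    """
    m = interacting.size
    out = np.empty(m)
    pos = interacting
    n_pos = int(pos.sum())
    if n_pos:
        out[pos] = _truncated_normal(rng, _OD_MEANS[2], _OD_SDS[2], threshold,
                                     np.inf, n_pos)
    n_neg = m - n_pos
    if n_neg:
        comp = rng.choice(2, size=n_neg, p=_OD_LOW_WEIGHTS)
        draws = np.empty(n_neg)
        for c in (0, 1):
            sel = comp == c
            if sel.any():
                draws[sel] = _truncated_normal(rng, _OD_MEANS[c], _OD_SDS[c],
                                               0.0, threshold, int(sel.sum()))
        out[~pos] = draws
    return out


def simulate_y2h_dataset(config: SimulationConfig,
                         scale: OrdinalScale | None = None):
    """Simulate a full two-way Y2H record table with planted truth.

    A planted block structure (bernoulli connectivity ``pi``) defines the
    true interaction status of every unordered pair, homodimers
    included.  Each ordered pair then receives an X-Gal mark and a HIS3
    ratio from interaction-conditional distributions; with zero noise and
    zero missingness, thresholding and the decision configurations
    recover the planted network exactly.  Per-test sign flips occur at
    the configured false-positive/negative rates and HIS3 values go
    missing at ``missing_rate``.

    Returns ``(roster, records, truth)`` with ``truth`` the planted
    symmetric boolean adjacency (diagonal = homodimers).
    """
    cfg = config
    scale = scale or OrdinalScale()
    rng = np.random.default_rng(cfg.seed)
    n, Q = cfg.n, cfg.Q
    labels = rng.choice(Q, size=n, p=cfg.alpha)
    roster = _roster(n)

    P = _expand_pairmatrix(cfg.pi, Q)[labels[:, None], labels[None, :]]
    U = rng.random((n, n))
    upper = np.triu(U)  # diagonal included: homodimer statuses are planted too
    truth = np.triu(upper < np.triu(P), 0)
    truth = truth | truth.T

    # one record per ordered pair; homodimers appear once
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    status = truth[ii, jj]

    def flip(seen: np.ndarray) -> np.ndarray:
        """Apply per-test sign-flip noise to the planted status."""
        out = seen.copy()
        if cfg.false_positive_rate:
            fp = rng.random(seen.size) < cfg.false_positive_rate
            out = out | (~seen & fp)
        if cfg.false_negative_rate:
            fn = rng.random(seen.size) < cfg.false_negative_rate
            out = out & ~(seen & fn)
        return out

    xgal_status = flip(status)
    his3_status = flip(status)

    marks = np.empty(status.size, dtype=int)
    pos = xgal_status
    if pos.any():
        marks[pos] = 4 + rng.choice(3, size=int(pos.sum()), p=_POSITIVE_MARK_PROBS)
    if (~pos).any():
        marks[~pos] = rng.choice(4, size=int((~pos).sum()), p=_NEGATIVE_MARK_PROBS)

    his3 = _draw_his3(rng, his3_status)
    if cfg.missing_rate:
        gone = rng.random(status.size) < cfg.missing_rate
        his3[gone] = np.nan

    proteins = np.asarray(roster.proteins)
    records = pd.DataFrame({
        "bait": proteins[ii],
        "prey": proteins[jj],
        "xgal": marks,
        "his3": his3,
    })
    records.attrs["labels"] = labels  # planted memberships, for convenience
    return roster, records, truth
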