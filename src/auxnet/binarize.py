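"""Network binarisation: reporter thresholds and decision configurations.

A binary protein-interaction network is built from the two-way Y2H data
in three steps.  First, a univariate Gaussian mixture is fitted to the
pooled HIS3 optical-density ratios; the boundary between its components
(where successive posterior probabilities are equal) motivates the HIS3
positivity threshold, while the X-Gal threshold sits between the marks
'+?' and '+'.  Second, each ordered pair's two reporter outputs are
thresholded into positive/negative flags.  Third, the four flags of an
unordered pair (two reporters x two orientations) are classified into
one of five configurations; configurations 1-4 count as evidence of
interaction, configuration 5 (a single reporter positive in both
orientations) proved unreliable and is discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .y2h import OrdinalScale, Roster

__all__ = [
    "DEFAULT_XGAL_THRESHOLD",
    "DEFAULT_HIS3_THRESHOLD",
    "HIS3_THRESHOLD_PRESETS",
    "OdMixture",
    "BinaryNetwork",
    "fit_od_mixture",
    "component_boundaries",
    "binarize_tests",
    "classify_configuration",
    "build_binary_network",
]

logger = logging.getLogger(__name__)

#: Mark code of the weakest positive X-Gal mark ('+' on the default scale):
#: the threshold lies between '+?' and '+'.
DEFAULT_XGAL_THRESHOLD: int = OrdinalScale().code("+")
#: HIS3 OD-ratio positivity threshold used for the published network.
DEFAULT_HIS3_THRESHOLD: float = 0.45
#: Alternative HIS3 thresholds tested as a sensitivity check.
HIS3_THRESHOLD_PRESETS: dict[str, float] = {"low": 0.3, "default": 0.45, "high": 0.65}

#: Configuration code meaning "no evidence of interaction" (<= 1 positive test).
CONFIG_NONE: int = 0
#: Configurations that define edge presence (5 is discarded as unreliable).
EDGE_CONFIGS: frozenset[int] = frozenset({1, 2, 3, 4})


@dataclass(frozen=True)
class OdMixture:
    """Fitted univariate Gaussian mixture of HIS3 OD ratios.

    Components are sorted by increasing mean.  ``bic`` follows the
    log-likelihood convention ``logL - (p/2) log n`` with ``p = 3K - 1``
    free parameters, so larger is better.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    bic: float
    log_likelihood: float
    n_samples: int

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def __post_init__(self) -> None:
        if not math.isclose(float(np.sum(self.weights)), 1.0, abs_tol=1e-9):
            raise ValueError("component weights must sum to 1")
        if np.any(self.weights < 0) or np.any(self.variances <= 0):
            raise ValueError("invalid mixture parameters")


@dataclass
class BinaryNetwork:
    """Symmetric 0/1 adjacency over the roster.

    The diagonal carries homodimer calls; it is populated for reporting
    but excluded from block-model fitting (the model is defined on the
    ``n(n-1)/2`` protein pairs).  ``configurations`` stores the decision
    configuration per pair (0 = none).
    """

    roster: Roster
    Z: np.ndarray
    configurations: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.roster)
        if self.Z.shape != (n, n) or not np.array_equal(self.Z, self.Z.T):
            raise ValueError("Z must be a symmetric n x n matrix")

    def edges(self) -> list[tuple[str, str]]:
        """Off-diagonal edge list (protein_a, protein_b), a < b in roster order."""
        out = []
        for i in range(len(self.roster)):
            for j in range(i + 1, len(self.roster)):
                if self.Z[i, j]:
                    out.append((self.roster.proteins[i], self.roster.proteins[j]))
        return out


def fit_od_mixture(
    ratios,
    k_range=range(1, 7),
    n_restarts: int = 20,
    random_state: int | None = 0,
    tol: float = 1e-8,
) -> OdMixture:
    """Fit univariate Gaussian mixtures to OD ratios and select K by BIC.

    Mixtures with unequal variances are fitted by EM with ``n_restarts``
    random initializations per K; the BIC-best model is returned with
    components sorted by mean.  Deterministic given ``random_state``.

    Raises ``ValueError`` when fewer than 10 finite ratios are supplied or
    when the sample is degenerate (all values identical).
    """
    z = np.asarray(ratios, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 10:
        raise ValueError("need at least 10 finite OD ratios")
    if np.ptp(z) == 0:
        raise ValueError("degenerate OD-ratio sample: all values identical")
    ks = [int(k) for k in k_range]
    if not ks or min(ks) < 1 or max(ks) > 6:
        raise ValueError("k_range must be within 1..6")

    X = z.reshape(-1, 1)
    best: OdMixture | None = None
    for k in ks:
        if k > np.unique(z).size:
            continue
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_restarts,
            tol=tol,
            max_iter=2000,
            reg_covar=1e-10,
            random_state=random_state,
        ).fit(X)
        variances = gm.covariances_.reshape(-1)
        if np.any(variances <= 1e-12):
            continue  # collapsed component: treat this K as a failed fit
        loglik = float(gm.score(X) * z.size)
        p = 3 * k - 1
        bic = loglik - 0.5 * p * math.log(z.size)
        order = np.argsort(gm.means_.reshape(-1))
        cand = OdMixture(
            weights=gm.weights_[order].copy(),
            means=gm.means_.reshape(-1)[order].copy(),
            variances=variances[order].copy(),
            bic=bic,
            log_likelihood=loglik,
            n_samples=int(z.size),
        )
        if best is None or cand.bic > best.bic:
            best = cand
    if best is None:
        raise ValueError("all mixture fits degenerate")
    return best


def component_boundaries(mixture: OdMixture) -> list[float | None]:
    """Boundaries where posteriors of successive components are equal.

    Returns K-1 values; boundary k lies between the means of components k
    and k+1 and is found by root bracketing on the difference of weighted
    log densities.  ``None`` marks an absent boundary (no sign change in
    the bracket, e.g. when one component dominates throughout).
    """
    bounds: list[float | None] = []
    for k in range(mixture.n_components - 1):
        lo, hi = float(mixture.means[k]), float(mixture.means[k + 1])

        def g(zv, _k=k):
            a = math.log(mixture.weights[_k]) + norm.logpdf(
                zv, mixture.means[_k], math.sqrt(mixture.variances[_k]))
            b = math.log(mixture.weights[_k + 1]) + norm.logpdf(
                zv, mixture.means[_k + 1], math.sqrt(mixture.variances[_k + 1]))
            return a - b

        if lo == hi or g(lo) * g(hi) > 0:
            bounds.append(None)
        else:
            bounds.append(float(brentq(g, lo, hi, xtol=1e-12)))
    return bounds


def binarize_tests(
    xgal,
    his3,
    xgal_threshold: int = DEFAULT_XGAL_THRESHOLD,
    his3_threshold: float = DEFAULT_HIS3_THRESHOLD,
):
    """Positive/negative flags for one ordered pair's two reporters.

    X-Gal is positive for mark codes at or above ``xgal_threshold``
    (default: '+'); HIS3 is positive for ratios at or above
    ``his3_threshold`` (default 0.45).  A missing HIS3 value is scored
    negative (conservative).  Accepts scalars or arrays.
    """
    x = np.asarray(xgal)
    h = np.asarray(his3, dtype=float)
    xpos = x >= xgal_threshold
    hpos = np.where(np.isfinite(h), h >= his3_threshold, False)
    if x.ndim == 0:
        return bool(xpos), bool(hpos)
    return xpos, hpos


def classify_configuration(xgal_way1: bool, his3_way1: bool,
                           xgal_way2: bool, his3_way2: bool) -> int:
    """Decision configuration of one unordered pair's four test flags.

    way1 carries protein i as bait, way2 protein j as bait.  Returns:

    * 1 - all four tests positive;
    * 2 - exactly three positive;
    * 3 - exactly two positive, both in the same way;
    * 4 - two positive, one reporter in each way (different reporters);
    * 5 - two positive, the same reporter in both ways (discarded
      downstream as unreliable);
    * 0 (``CONFIG_NONE``) - at most one positive.
    """
    x1, h1, x2, h2 = (bool(xgal_way1), bool(his3_way1),
                      bool(xgal_way2), bool(his3_way2))
    n_pos = x1 + h1 + x2 + h2
    if n_pos == 4:
        return 1
    if n_pos == 3:
        return 2
    if n_pos == 2:
        if (x1 and h1) or (x2 and h2):
            return 3
        if (x1 and x2) or (h1 and h2):
            return 5
        return 4
    return CONFIG_NONE


def build_binary_network(
    records: pd.DataFrame,
    roster: Roster,
    xgal_threshold: int = DEFAULT_XGAL_THRESHOLD,
    his3_threshold: float = DEFAULT_HIS3_THRESHOLD,
) -> BinaryNetwork:
    """Threshold, classify and assemble the symmetric binary network.

    An off-diagonal edge is present iff the pair's configuration is in
    {1, 2, 3, 4}; configuration 5 and "none" yield absence.  Homodimer
    tests (i as both bait and prey) have a single orientation whose two
    flags are used for both ways; the call is stored on the diagonal
    only.  A missing orientation contributes two negative tests and is
    logged.
    """
    n = len(roster)
    idx = roster.index()
    flag_x = {}
    flag_h = {}
    for row in records.itertuples(index=False):
        xp, hp = binarize_tests(row.xgal, row.his3, xgal_threshold, his3_threshold)
        flag_x[(row.bait, row.prey)] = xp
        flag_h[(row.bait, row.prey)] = hp

    Z = np.zeros((n, n), dtype=bool)
    config = np.zeros((n, n), dtype=int)
    n_missing = 0
    for a, i in idx.items():
        for b, j in idx.items():
            if j < i:
                continue
            way1, way2 = (a, b), (b, a)
            if way1 not in flag_x and way2 not in flag_x:
                if records.shape[0]:
                    n_missing += 1
                continue
            if i == j:
                x1 = x2 = flag_x[way1]
                h1 = h2 = flag_h[way1]
            else:
                if way1 not in flag_x or way2 not in flag_x:
                    n_missing += 1
                x1 = flag_x.get(way1, False)
                h1 = flag_h.get(way1, False)
                x2 = flag_x.get(way2, False)
                h2 = flag_h.get(way2, False)
            c = classify_configuration(x1, h1, x2, h2)
            config[i, j] = config[j, i] = c
            if c in EDGE_CONFIGS:
                Z[i, j] = Z[j, i] = True
    if n_missing:
        logger.warning("%d pair(s) with a missing orientation scored negative",
                       n_missing)
    return BinaryNetwork(roster=roster, Z=Z, configurations=config)
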