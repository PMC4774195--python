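"""Rank standardization of Y2H outputs into a valued interaction network.

The X-Gal output is a distance on an ordinal scale and the HIS3 output a
ratio whose response is saturating (close to Michaelis-Menten kinetics),
so both are reduced to mid-ranks over a single pooled marginal per test
before being combined.  For a pair (i, j) with both orientations observed
the standardized distance is

    x_ij = w_XGal * (Rank(y_ij) + Rank(y_ji)) / (1 + N^2)
         + w_HIS3 * (Rank(z_ij) + Rank(z_ji)) / (1 + N^2),

where N is the roster size, the pooled marginal runs over all N^2
ordered pairs, and w_XGal + w_HIS3 = 1.  The mean rank is (1 + M)/2 for a
sample of M values, so with complete data the mean of x over all ordered
pairs is exactly 1.  When a directed value is missing its term is dropped
and each remaining rank is normalized by (1 + M_test)/2; when one test is
missing in both orientations the weights are renormalized over the
available test.  x is a likelihood-of-interaction surrogate, not a
binding affinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .y2h import Roster

__all__ = [
    "RankTable",
    "ValuedNetwork",
    "mid_ranks",
    "standardized_distance_matrix",
    "weight_presets",
]


@dataclass(frozen=True)
class RankTable:
    """Mid-ranks of a pooled marginal sample.

    Tied observations share the mean of the ranks they span, so the sum
    of ranks is always M(M+1)/2.
    """

    values: np.ndarray
    ranks: np.ndarray
    M: int


@dataclass
class ValuedNetwork:
    """Symmetric matrix of standardized interaction distances.

    ``missing`` flags pairs where every contributing test value was
    absent.  Diagonal (homodimer) entries are populated—they take part in
    the pooled rank marginals—but are excluded from block-model fitting.
    """

    roster: Roster
    X: np.ndarray
    weights: tuple[float, float]
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.roster)
        if self.X.shape != (n, n):
            raise ValueError("X must be n x n")
        if self.missing is None:
            self.missing = ~np.isfinite(self.X)
        w1, w2 = self.weights
        if not (0 <= w1 <= 1 and 0 <= w2 <= 1 and abs(w1 + w2 - 1) < 1e-9):
            raise ValueError("weights must be in [0,1] and sum to 1")


def mid_ranks(sample) -> RankTable:
    """Mid-ranks Rank(v) = 1/2 + sum_{u<v} f_u + f_v / 2 of a sample.

    ``f_u`` is the count of value ``u``; works for ordinal codes and for
    reals (ranked by sort order, exact ties mid-ranked).  Equivalent to
    average-tie ranking.
    """
    v = np.asarray(sample, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(v)):
        raise ValueError("sample contains non-finite values")
    _, inverse, counts = np.unique(v, return_inverse=True, return_counts=True)
    below = np.concatenate(([0.0], np.cumsum(counts)[:-1]))
    ranks = 0.5 + below[inverse] + counts[inverse] / 2.0
    return RankTable(values=v, ranks=ranks, M=int(v.size))


def _directed_matrices(records: pd.DataFrame, roster: Roster):
    """Ordered-pair matrices of X-Gal codes and HIS3 ratios (NaN = absent)."""
    n = len(roster)
    idx = roster.index()
    Y = np.full((n, n), np.nan)
    Zr = np.full((n, n), np.nan)
    for row in records.itertuples(index=False):
        i, j = idx[row.bait], idx[row.prey]
        Y[i, j] = float(row.xgal)
        Zr[i, j] = row.his3
    return Y, Zr


def _rank_matrix(values: np.ndarray):
    """Replace finite entries by their pooled mid-ranks; returns (ranks, M)."""
    mask = np.isfinite(values)
    M = int(mask.sum())
    R = np.full(values.shape, np.nan)
    if M:
        R[mask] = mid_ranks(values[mask]).ranks
    return R, M


def _pair_term(R: np.ndarray, M: int) -> np.ndarray:
    """Per-pair standardized term of one test.

    With both directed ranks present this is (R_ij + R_ji)/(1 + M); with
    one present, R/( (1+M)/2 ); with none, NaN.
    """
    if M == 0:
        return np.full(R.shape, np.nan)
    present = np.isfinite(R)
    count = present.astype(int) + present.T.astype(int)
    total = np.where(present, R, 0.0) + np.where(present.T, R.T, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        term = np.where(count > 0, (total / np.maximum(count, 1)) / ((1 + M) / 2.0),
                        np.nan)
    return term


def standardized_distance_matrix(
    records: pd.DataFrame,
    roster: Roster,
    weights: tuple[float, float] = (0.5, 0.5),
) -> ValuedNetwork:
    """Combine ranked X-Gal and HIS3 outputs into the valued network.

    A single pooled marginal per test (over all observed ordered pairs,
    diagonal included) feeds the mid-ranks.  Entries where both tests are
    missing in both orientations are flagged as missing (NaN).
    """
    w_xgal, w_his3 = weights
    Y, Zr = _directed_matrices(records, roster)
    RX, MX = _rank_matrix(Y)
    RH, MH = _rank_matrix(Zr)
    TX = _pair_term(RX, MX)
    TH = _pair_term(RH, MH)

    avail_x = np.isfinite(TX)
    avail_h = np.isfinite(TH)
    num = (w_xgal * np.where(avail_x, TX, 0.0)
           + w_his3 * np.where(avail_h, TH, 0.0))
    den = w_xgal * avail_x + w_his3 * avail_h
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return ValuedNetwork(roster=roster, X=X, weights=(w_xgal, w_his3))


def weight_presets() -> dict[str, tuple[float, float]]:
    """Published (w_XGal, w_HIS3) weightings of the two reporters."""
    return {
        "xgal-only": (1.0, 0.0),
        "A": (0.75, 0.25),
        "B": (0.5, 0.5),
        "C": (0.25, 0.75),
        "his3-only": (0.0, 1.0),
    }
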