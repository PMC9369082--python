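"""Evaluation statistics for affinity regression: CI, MSE and RMSE.

The concordance index (CI) is the rank statistic

    CI = (1/Z) * sum_{delta_i > delta_j} h(b_i - b_j)

over all ordered pairs whose TRUE affinities differ, where ``h`` is the
Heaviside step scoring 1 for a correctly ordered pair, 1/2 for a prediction
tie and 0 for an inverted pair, and Z counts the compared pairs.  Pairs with
tied true affinities are never compared.  CI is 1 for a perfect ranking and
1/2 for a random predictor.

All statistics are computed in double precision.  The CI runs in
O(n log n) via a Fenwick (binary indexed) tree over prediction ranks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "heaviside",
    "concordance_index",
    "mse",
    "rmse",
    "EvaluationReport",
    "UndefinedConcordanceError",
]


class UndefinedConcordanceError(ValueError):
    """Raised when every pair of true affinities is tied (Z = 0)."""


def heaviside(x: float) -> float:
    """Pairwise scoring step: 1.0 for x > 0, 0.5 for x == 0, 0.0 for x < 0."""
    if not np.isfinite(x):
        raise ValueError("heaviside requires a finite argument")
    if x > 0:
        return 1.0
    if x < 0:
        return 0.0
    return 0.5


class _Fenwick:
    """Prefix-sum counter over integer ranks 0..n-1."""

    def __init__(self, n: int) -> None:
        self.tree = [0] * (n + 1)

    def add(self, i: int) -> None:
        i += 1
        while i < len(self.tree):
            self.tree[i] += 1
            i += i & (-i)

    def prefix(self, i: int) -> int:
        """Count of inserted ranks <= i."""
        i += 1
        s = 0
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return s


def concordance_index(true_affinities, predictions) -> float:
    """Concordance index of ``predictions`` against ``true_affinities``.

    Parameters
    ----------
    true_affinities:
        The measured affinities (``delta``), length n >= 2.
    predictions:
        The model scores (``b``), same length.

    Raises
    ------
    UndefinedConcordanceError
        If all true affinities are tied, so no pair can be compared.
    """
    delta = np.asarray(true_affinities, dtype=np.float64)
    b = np.asarray(predictions, dtype=np.float64)
    if delta.ndim != 1 or delta.shape != b.shape:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if delta.size < 2:
        raise ValueError("need at least two observations")
    if not (np.isfinite(delta).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")

    order = np.argsort(delta, kind="stable")
    delta_s, b_s = delta[order], b[order]
    # prediction values -> dense ranks
    ranks = np.searchsorted(np.unique(b_s), b_s)
    n_ranks = int(ranks.max()) + 1

    tree = _Fenwick(n_ranks)
    score = 0.0
    z = 0
    inserted = 0
    i = 0
    n = delta.size
    while i < n:
        j = i
        while j < n and delta_s[j] == delta_s[i]:
            j += 1
        # elements i..j-1 share a true affinity: compare against all
        # previously inserted (strictly smaller delta) elements only
        for k in range(i, j):
            r = int(ranks[k])
            le = tree.prefix(r)
            lt = tree.prefix(r - 1) if r > 0 else 0
            score += lt + 0.5 * (le - lt)
            z += inserted
        for k in range(i, j):
            tree.add(int(ranks[k]))
        inserted += j - i
        i = j

    if z == 0:
        raise UndefinedConcordanceError(
            "all true affinities are tied; the concordance index is undefined"
        )
    return score / z


def mse(predictions, targets) -> float:
    """Mean squared error (1/n) * sum (p_i - y_i)^2."""
    p = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    if p.shape != y.shape or p.ndim != 1 or p.size < 1:
        raise ValueError("inputs must be equal-length non-empty vectors")
    if not (np.isfinite(p).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    return float(np.mean((p - y) ** 2))


def rmse(predictions, targets) -> float:
    """Root mean squared error, sqrt(MSE)."""
    return float(np.sqrt(mse(predictions, targets)))


@dataclass(frozen=True)
class EvaluationReport:
    """CI, MSE and RMSE over one prediction batch.

    ``ci`` is None when every true affinity in the batch is tied.
    """

    ci: float | None
    mse: float
    rmse: float

    def to_json(self) -> str:
        return json.dumps({"ci": self.ci, "mse": self.mse, "rmse": self.rmse})

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        d = json.loads(text)
        return cls(ci=d["ci"], mse=d["mse"], rmse=d["rmse"])

    @classmethod
    def from_batch(cls, predictions, targets) -> "EvaluationReport":
        ci: float | None = None
        if np.asarray(targets).size >= 2:
            try:
                ci = concordance_index(targets, predictions)
            except UndefinedConcordanceError:
                ci = None
        m = mse(predictions, targets)
        return cls(ci=ci, mse=m, rmse=float(np.sqrt(m)))
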