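"""Correspondence metrics between two signed ternary vectors.

Two complementary views: the Pearson correlation coefficient treats the
ternary values as numbers (zeros included) and reports linear agreement
in [-1, 1]; the signed Jaccard similarity treats each nonzero
(position, sign) entry as a set element and reports

    J = |{i : x_i = y_i != 0}| / |{i : x_i != 0 or y_i != 0}|

in [0, 1].  A sign-blind variant, counting co-nonzero positions
regardless of sign, is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vectors import SignedVector, UniverseMismatchError

__all__ = [
    "MetricValue",
    "pearson",
    "jaccard",
    "pearson_matrix",
    "jaccard_matrix",
]


@dataclass(frozen=True)
class MetricValue:
    """A metric outcome; ``defined`` is False when the metric degenerates
    (zero-variance Pearson, all-zero Jaccard), in which case ``value`` is 0
    and should be excluded from means."""

    name: str
    value: float
    defined: bool = True


def _check_universe(x: SignedVector, y: SignedVector) -> None:
    if x.universe != y.universe:
        raise UniverseMismatchError("vectors defined over different universes")


def pearson(x: SignedVector, y: SignedVector) -> MetricValue:
    """Pearson correlation over all positions, zeros included.

    If either vector is constant the coefficient is undefined; the result
    carries ``defined=False`` and value 0.
    """
    _check_universe(x, y)
    xv = x.values.astype(np.float64)
    yv = y.values.astype(np.float64)
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = float(np.sqrt(xc @ xc))
    sy = float(np.sqrt(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        return MetricValue("pearson", 0.0, defined=False)
    r = float(xc @ yc) / (sx * sy)
    return MetricValue("pearson", min(1.0, max(-1.0, r)))


def jaccard(
    x: SignedVector, y: SignedVector, *, sign_blind: bool = False
) -> MetricValue:
    """Signed Jaccard similarity between two ternary vectors.

    A shared element is a position with equal nonzero sign; the union is
    the positions nonzero in either vector.  ``sign_blind=True`` counts
    any co-nonzero position as shared instead.  Both vectors all-zero
    gives ``defined=False``.
    """
    _check_universe(x, y)
    xnz = x.values != 0
    ynz = y.values != 0
    union = int(np.count_nonzero(xnz | ynz))
    if union == 0:
        return MetricValue("jaccard", 0.0, defined=False)
    if sign_blind:
        shared = int(np.count_nonzero(xnz & ynz))
    else:
        shared = int(np.count_nonzero((x.values == y.values) & xnz))
    return MetricValue("jaccard", shared / union)


def pearson_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson correlations between rows of ``X`` and rows of ``Y``.

    Returns ``(values, defined)`` of shape ``(len(X), len(Y))``; entries
    with a constant row in either factor are 0 with ``defined`` False.
    Used to vectorise permutation tests: shuffling vector pairings only
    re-indexes this matrix.
    """
    Xc = X.astype(np.float64) - X.mean(axis=1, keepdims=True)
    Yc = Y.astype(np.float64) - Y.mean(axis=1, keepdims=True)
    nx = np.linalg.norm(Xc, axis=1)
    ny = np.linalg.norm(Yc, axis=1)
    defined = (nx[:, None] > 0) & (ny[None, :] > 0)
    denom = np.where(defined, nx[:, None] * ny[None, :], 1.0)
    vals = np.clip((Xc @ Yc.T) / denom, -1.0, 1.0)
    vals[~defined] = 0.0
    return vals, defined


def jaccard_matrix(
    X: np.ndarray, Y: np.ndarray, *, sign_blind: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise signed Jaccard between rows of ``X`` and rows of ``Y``.

    Same contract as :func:`pearson_matrix`; undefined where both rows
    are all-zero.
    """
    Xf = X.astype(np.float64)
    Yf = Y.astype(np.float64)
    xnz = (Xf != 0).astype(np.float64)
    ynz = (Yf != 0).astype(np.float64)
    both_nz = xnz @ ynz.T
    union = xnz.sum(axis=1)[:, None] + ynz.sum(axis=1)[None, :] - both_nz
    if sign_blind:
        shared = both_nz
    else:
        pos = (Xf > 0).astype(np.float64) @ (Yf > 0).astype(np.float64).T
        neg = (Xf < 0).astype(np.float64) @ (Yf < 0).astype(np.float64).T
        shared = pos + neg
    defined = union > 0
    vals = np.where(defined, shared / np.where(defined, union, 1.0), 0.0)
    return vals, defined
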