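"""Rank-correlation comparison against external stability rankings.

Temperature rankings can be compared with stability indices produced by
independent (e.g. phylogenetic) methods: Spearman correlation on the
paired vectors, and a recursive outlier-pruning regression that
repeatedly removes the point contributing the largest squared residual
to an ordinary least-squares fit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = ["PairedRanking", "spearman", "prune_regression"]

#: Largest n for which the Spearman P-value is computed by exact
#: enumeration of all n! pairings; beyond this the usual t-approximation
#: is used.
EXACT_PERMUTATION_MAX_N = 10


@dataclass(frozen=True)
class PairedRanking:
    """Paired (x, y) values for a common set of labeled features."""

    labels: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if not len(self.labels) == len(self.x) == len(self.y):
            raise ValueError("labels, x and y must have equal lengths")

    def __len__(self) -> int:
        return len(self.labels)

    def drop(self, index: int) -> "PairedRanking":
        keep = [i for i in range(len(self)) if i != index]
        return PairedRanking(
            labels=tuple(self.labels[i] for i in keep),
            x=self.x[keep], y=self.y[keep])


def _rankdata(v: np.ndarray) -> np.ndarray:
    return _sps.rankdata(v, method="average")


def spearman(pairs: PairedRanking) -> tuple[float, float]:
    """Spearman rank correlation with two-sided P-value.

    Ties receive average ranks.  For n <= 10 the P-value is exact, by
    enumeration of all n! pairings of the two rank vectors; for larger n
    the standard t-distribution approximation is used.
    """
    n = len(pairs)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx, ry = _rankdata(pairs.x), _rankdata(pairs.y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("Spearman undefined for a constant vector")
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, r)
    else:
        p = float(_sps.spearmanr(pairs.x, pairs.y).pvalue)
    return r, p


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray,
                         r_obs: float) -> float:
    """Two-sided exact P: fraction of permutations of ry with
    |correlation| >= |r_obs| (evaluated in chunks, Pearson on ranks)."""
    n = len(rx)
    rx_c = rx - rx.mean()
    denom_x = math.sqrt((rx_c ** 2).sum())
    total = math.factorial(n)
    count = 0
    chunk = []
    thr = abs(r_obs) - 1e-12
    for perm in itertools.permutations(ry):
        chunk.append(perm)
        if len(chunk) == 100_000:
            count += _chunk_count(np.array(chunk), rx_c, denom_x, thr)
            chunk = []
    if chunk:
        count += _chunk_count(np.array(chunk), rx_c, denom_x, thr)
    return count / total


def _chunk_count(perms: np.ndarray, rx_c: np.ndarray, denom_x: float,
                 thr: float) -> int:
    py = perms - perms.mean(axis=1, keepdims=True)
    num = py @ rx_c
    denom = denom_x * np.sqrt((py ** 2).sum(axis=1))
    return int((np.abs(num / denom) >= thr).sum())


def _ols_residuals(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    fit = _sps.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    return resid, float((resid ** 2).sum())


def prune_regression(pairs: PairedRanking, n_remove: int,
                     ) -> tuple[PairedRanking, list[str], list[float]]:
    """Recursive outlier pruning of an ordinary least-squares fit.

    At each step the OLS line is fit, the single point with the largest
    squared residual is removed, and the fit is repeated.  Residual ties
    are broken by label order.  Returns the pruned pairs, the removal
    order (labels), and the SSR trajectory (initial SSR followed by the
    SSR after each removal) — non-increasing by construction.
    """
    if n_remove < 0:
        raise ValueError("n_remove must be >= 0")
    if len(pairs) - n_remove < 3:
        raise ValueError(
            f"removing {n_remove} of {len(pairs)} points leaves fewer "
            "than 3")
    removed: list[str] = []
    _, ssr = _ols_residuals(pairs.x, pairs.y)
    ssr_path = [ssr]
    for _ in range(n_remove):
        resid, _ = _ols_residuals(pairs.x, pairs.y)
        sq = resid ** 2
        worst = int(np.argmax(sq))
        # break exact ties by label order
        ties = np.flatnonzero(sq == sq[worst])
        if len(ties) > 1:
            worst = min(ties, key=lambda i: pairs.labels[i])
        removed.append(pairs.labels[worst])
        pairs = pairs.drop(worst)
        _, ssr = _ols_residuals(pairs.x, pairs.y)
        ssr_path.append(ssr)
    return pairs, removed, ssr_path


def elbow_stop(ssr_path: list[float], min_rel_drop: float = 0.25) -> int:
    """Heuristic number of removals: stop when the relative SSR drop of a
    removal falls below ``min_rel_drop``.  Advisory only, never a default
    stopping rule."""
    for i in range(1, len(ssr_path)):
        prev = ssr_path[i - 1]
        if prev == 0 or (prev - ssr_path[i]) / prev < min_rel_drop:
            return i - 1
    return len(ssr_path) - 1
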