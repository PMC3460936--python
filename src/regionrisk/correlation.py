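"""Pearson and Spearman correlation with small-sample conventions.

Supports the grouped analyses of the disparity pipeline: mortality versus
each risk factor across all regions, and separately within each
geographic group (ZIP codes within a county).  Group sizes are tiny —
three to a dozen units — so the implementation is explicit about the
small-n edge cases:

* Pearson 95% CI via the Fisher z-transform, z = atanh(r) ± z_{1−α/2}/√(n−3);
  for n = 3 the variance 1/(n−3) is undefined and the interval is
  reported as [−1, 1].
* |r| = 1 is reported with p = 0 and a degenerate CI at r.
* Spearman uses mid-ranks (standard tie handling) and an *exact*
  permutation p-value for n ≤ 8 (full enumeration of all n!
  permutations); the t-approximation is used for larger n.
* Groups with fewer than 3 regions are reported as skipped, not errored.

p-values are two-sided throughout.  No multiple-testing adjustment is
applied by default; pass ``adjust="bonferroni"`` to
:func:`grouped_correlations` to enable one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import RegionTable, RegionTableError

__all__ = [
    "CorrelationResult",
    "SkippedGroup",
    "pearson_with_ci",
    "spearman",
    "grouped_correlations",
]

#: Smallest group size for which a correlation is reported.
MIN_GROUP_N = 3

#: Largest n for which the Spearman p-value is computed by full
#: permutation enumeration (8! = 40320 permutations).
EXACT_PERMUTATION_MAX_N = 8


class DegenerateInputError(ValueError):
    """A correlation is undefined (zero variance in an input)."""


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    estimate: float
    p_value: float
    n: int
    ci_low: float | None = None  # Pearson only
    ci_high: float | None = None
    pair: tuple[str, str] | None = None
    group_id: str | None = None


@dataclass(frozen=True)
class SkippedGroup:
    group_id: str
    n: int
    reason: str


def _check_xy(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise RegionTableError(
            f"x and y must be 1-d vectors of equal length, got {x.shape} vs {y.shape}"
        )
    if x.size < MIN_GROUP_N:
        raise RegionTableError(f"need at least {MIN_GROUP_N} observations, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise RegionTableError("non-finite values in correlation input")


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("correlation undefined: zero variance input")
    r = float(xc @ yc) / (sx * sy)
    r = min(1.0, max(-1.0, r))
    # roundoff on an exactly linear pair leaves r within a few ulp of +-1
    if 1.0 - abs(r) < 1e-12:
        r = math.copysign(1.0, r)
    return r


def _t_pvalue(r: float, n: int) -> float:
    """Two-sided p from t = r sqrt((n-2)/(1-r^2)) on n-2 df."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson_with_ci(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> CorrelationResult:
    """Sample Pearson correlation with a Fisher-z confidence interval.

    Parameters
    ----------
    x, y:
        Equal-length vectors, n ≥ 3, finite, non-zero variance.
    alpha:
        Two-sided CI level (default 0.05 → 95% interval).

    Notes
    -----
    The CI is atanh(r) ± z_{1−α/2}/√(n−3), back-transformed with tanh.
    For n = 3 it is the full [−1, 1]; for |r| = 1 it degenerates to
    [r, r] with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_xy(x, y)
    n = int(x.size)
    r = _pearson_r(x, y)
    if abs(r) >= 1.0:
        lo = hi = r
        p = 0.0
    elif n == 3:
        lo, hi = -1.0, 1.0
        p = _t_pvalue(r, n)
    else:
        zcrit = float(stats.norm.ppf(1.0 - alpha / 2.0))
        z = math.atanh(r)
        half = zcrit / math.sqrt(n - 3)
        lo, hi = math.tanh(z - half), math.tanh(z + half)
        p = _t_pvalue(r, n)
    return CorrelationResult(
        method="pearson", estimate=r, p_value=p, n=n, ci_low=lo, ci_high=hi
    )


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, observed: float) -> float:
    """Two-sided permutation p: fraction of all n! pairings at least as
    extreme (in |rho|) as observed.  Mid-ranks are permuted, so ties are
    handled consistently with the estimate."""
    n = rx.size
    xc = rx - rx.mean()
    sx = math.sqrt(float(xc @ xc))
    thresh = abs(observed) - 1e-12
    count = 0
    total = 0
    ylist = ry.tolist()
    ymean = ry.mean()
    sy = math.sqrt(float(((ry - ymean) ** 2).sum()))
    for perm in permutations(ylist):
        yp = np.asarray(perm) - ymean
        r = float(xc @ yp) / (sx * sy)
        if abs(r) >= thresh:
            count += 1
        total += 1
    return count / total


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with exact small-sample p-value.

    Mid-ranks are used for ties (equivalently: Pearson on the rank
    vectors, which carries the standard tie correction).  The two-sided
    p-value is exact by full permutation enumeration for n ≤ 8 and from
    the t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_xy(x, y)
    n = int(x.size)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _pearson_r(rx, ry)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = _t_pvalue(rho, n)
    return CorrelationResult(method="spearman", estimate=rho, p_value=p, n=n)


def _column_pair(
    records, fx: str, fy: str
) -> tuple[np.ndarray, np.ndarray]:
    """Paired complete cases for two factors over a record list."""
    xs, ys = [], []
    for rec in records:
        vx, vy = rec.values.get(fx), rec.values.get(fy)
        if vx is not None and vy is not None:
            xs.append(vx)
            ys.append(vy)
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


def grouped_correlations(
    table: RegionTable,
    pairs: Sequence[tuple[str, str]],
    group_key: str = "group_id",
    methods: Sequence[str] = ("pearson", "spearman"),
    alpha: float = 0.05,
    adjust: str | None = None,
) -> tuple[list[CorrelationResult], list[SkippedGroup]]:
    """Correlations per factor pair, within each group and pooled.

    For every pair in ``pairs`` this computes one result per geographic
    group (regions sharing a ``group_id``) plus a pooled result across
    all regions (``group_id=None`` in the output).  Groups with fewer
    than 3 complete cases are listed as skipped.

    ``adjust="bonferroni"`` multiplies each p-value by the number of
    reported tests (capped at 1); the default applies no adjustment.
    """
    if group_key != "group_id":
        raise RegionTableError(f"unknown group key {group_key!r}; only 'group_id' is supported")
    for fx, fy in pairs:
        table.factor(fx)
        table.factor(fy)
    for m in methods:
        if m not in ("pearson", "spearman"):
            raise RegionTableError(f"unknown correlation method {m!r}")

    results: list[CorrelationResult] = []
    skipped: list[SkippedGroup] = []
    groups: list[tuple[str | None, list]] = [(None, table.records)]
    groups += sorted(table.groups().items())

    for gid, records in groups:
        for fx, fy in pairs:
            xs, ys = _column_pair(records, fx, fy)
            if xs.size < MIN_GROUP_N:
                if gid is not None:
                    skipped.append(
                        SkippedGroup(gid, int(xs.size), f"n < {MIN_GROUP_N}")
                    )
                continue
            for m in methods:
                try:
                    res = (
                        pearson_with_ci(xs, ys, alpha=alpha)
                        if m == "pearson"
                        else spearman(xs, ys)
                    )
                except DegenerateInputError:
                    continue
                results.append(replace(res, pair=(fx, fy), group_id=gid))
    # de-duplicate skip entries arising from several pairs in one group
    seen: set[tuple[str, int, str]] = set()
    uniq = []
    for s in skipped:
        key = (s.group_id, s.n, s.reason)
        if key not in seen:
            seen.add(key)
            uniq.append(s)
    if adjust == "bonferroni" and results:
        k = len(results)
        results = [replace(r, p_value=min(1.0, r.p_value * k)) for r in results]
    elif adjust not in (None, "bonferroni"):
        raise RegionTableError(f"unknown adjustment {adjust!r}")
    return results, uniq
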