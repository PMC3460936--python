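"""Directional quartile ranks and the weighted integrated quartile score.

Each risk factor is binned into quartiles across regions; a region's
quartile score is an integer in {1, 2, 3, 4} with 4 always the
*highest-risk* quartile.  For direct factors (mortality, % uninsured, ...)
quartile 4 holds the largest raw values; for inverse factors (median
income, education) the numbering is reversed so quartile 4 holds the
smallest values.  The integrated quartile score of a region is the
weighted sum of its per-factor quartile scores — under the default
configuration incidence and mortality count double — and is the
prioritization metric: high score, high need.

Two binning methods are provided:

``cutpoint`` (default)
    Empirical 25/50/75th percentile cut-points (linear interpolation)
    on the raw values; a region's bin is determined by its value alone,
    so equal values always share a bin and bins may be unbalanced.

``equal_count``
    Sort ascending and split into four contiguous blocks with sizes as
    equal as possible, remainders going to the lowest bins first
    (n = 11 gives block sizes 3, 3, 3, 2).  Regions with exactly equal
    values share the lower of their blocks' bins, keeping the rank a
    pure function of the value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data import FactorSpec, RegionTable, RegionTableError

__all__ = [
    "QuartileAssignment",
    "QuartileRanges",
    "ScoreRow",
    "ScoreTable",
    "assign_quartiles",
    "integrated_score",
    "score_table",
    "score_from_ranks",
    "BINNING_METHODS",
]

BINNING_METHODS = ("cutpoint", "equal_count")


@dataclass(frozen=True)
class QuartileAssignment:
    region_id: str
    factor: str
    rank: int  # 1..4, 4 = highest risk
    raw_value: float


@dataclass(frozen=True)
class QuartileRanges:
    """Observed [lo, hi] value interval per quartile rank (1-4).

    A rank with no member regions maps to ``None``.  For an inverse
    factor quartile 4 spans the *lowest* raw values.
    """

    factor: str
    ranges: dict[int, tuple[float, float] | None]


@dataclass(frozen=True)
class ScoreRow:
    region_id: str
    ranks: dict[str, int]
    integrated_score: int
    priority_rank: int


@dataclass
class ScoreTable:
    rows: list[ScoreRow]
    factors: list[FactorSpec]
    method: str

    def row(self, region_id: str) -> ScoreRow:
        for r in self.rows:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    def scores(self) -> dict[str, int]:
        return {r.region_id: r.integrated_score for r in self.rows}


def _value_bins(values: np.ndarray, method: str) -> np.ndarray:
    """Ascending-direction bins in {1..4}; pure function of value."""
    n = values.size
    if method == "cutpoint":
        q1, q2, q3 = np.percentile(values, [25, 50, 75])
        bins = np.ones(n, dtype=int)
        bins[values > q1] = 2
        bins[values > q2] = 3
        bins[values > q3] = 4
        return bins
    if method == "equal_count":
        # Block sizes as equal as possible, remainder to the LOWEST bins.
        base, rem = divmod(n, 4)
        sizes = [base + (1 if b < rem else 0) for b in range(4)]
        order = np.argsort(values, kind="stable")
        positional = np.empty(n, dtype=int)
        pos = 0
        for b, size in enumerate(sizes, start=1):
            positional[order[pos:pos + size]] = b
            pos += size
        # Ties across a block boundary collapse to the lower bin.
        bins = np.empty(n, dtype=int)
        for v in np.unique(values):
            mask = values == v
            bins[mask] = positional[mask].min()
        return bins
    raise ValueError(f"unknown binning method {method!r}; use one of {BINNING_METHODS}")


def assign_quartiles(
    values: Mapping[str, float],
    direction: str = "direct",
    method: str = "cutpoint",
    factor: str = "",
) -> tuple[list[QuartileAssignment], QuartileRanges]:
    """Assign each region a directional quartile rank for one factor.

    Parameters
    ----------
    values:
        region_id → raw value; at least 4 regions, no missing values.
    direction:
        ``"direct"`` or ``"inverse"``; inverse reverses the final rank
        (rank ← 5 − rank) so that 4 is always highest risk.
    method:
        ``"cutpoint"`` or ``"equal_count"`` (see module docstring).
    factor:
        Factor name carried through to the outputs.

    Returns the per-region assignments plus the observed value range of
    each quartile.
    """
    if direction not in ("direct", "inverse"):
        raise ValueError(f"direction must be 'direct' or 'inverse', got {direction!r}")
    ids = list(values.keys())
    missing = [rid for rid in ids if values[rid] is None]
    if missing:
        raise RegionTableError(
            f"missing value(s) for region(s) {missing} in factor {factor or '?'!r}"
        )
    arr = np.asarray([float(values[rid]) for rid in ids], dtype=float)
    if arr.size < 4:
        raise RegionTableError(
            f"quartile assignment needs at least 4 regions, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise RegionTableError(f"non-finite value in factor {factor or '?'!r}")

    bins = _value_bins(arr, method)
    if direction == "inverse":
        bins = 5 - bins

    assignments = [
        QuartileAssignment(region_id=rid, factor=factor, rank=int(b), raw_value=float(v))
        for rid, b, v in zip(ids, bins, arr)
    ]
    ranges: dict[int, tuple[float, float] | None] = {}
    for q in (1, 2, 3, 4):
        member = arr[bins == q]
        ranges[q] = (float(member.min()), float(member.max())) if member.size else None
    return assignments, QuartileRanges(factor=factor, ranges=ranges)


def integrated_score(ranks: Mapping[str, int], specs: Sequence[FactorSpec]) -> int:
    """Weighted sum of per-factor quartile ranks: Σ_f w_f · q_f.

    Every configured factor must be present in ``ranks``; the result is a
    deterministic integer in [Σw, 4Σw].
    """
    total = 0
    for spec in specs:
        if spec.name not in ranks:
            raise RegionTableError(f"no quartile rank for configured factor {spec.name!r}")
        q = int(ranks[spec.name])
        if q not in (1, 2, 3, 4):
            raise RegionTableError(f"rank for {spec.name!r} must be in 1..4, got {q}")
        total += spec.weight * q
    return total


def _prioritize(
    ranks_by_region: Mapping[str, Mapping[str, int]],
    scores: Mapping[str, int],
    mortality_factor: str | None,
) -> list[str]:
    """Deterministic row order: score desc, mortality rank desc, id."""

    def sort_key(rid: str) -> tuple:
        mort = ranks_by_region[rid].get(mortality_factor, 0) if mortality_factor else 0
        return (-scores[rid], -mort, rid)

    return sorted(ranks_by_region, key=sort_key)


def _competition_ranks(ordered: Sequence[str], scores: Mapping[str, int]) -> dict[str, int]:
    """Equal scores share the minimum rank (1, 1, 3, ...)."""
    priority: dict[str, int] = {}
    for pos, rid in enumerate(ordered, start=1):
        prev = ordered[pos - 2] if pos > 1 else None
        if prev is not None and scores[rid] == scores[prev]:
            priority[rid] = priority[prev]
        else:
            priority[rid] = pos
    return priority


def score_from_ranks(
    ranks_by_region: Mapping[str, Mapping[str, int]],
    specs: Sequence[FactorSpec],
    mortality_factor: str | None = None,
) -> ScoreTable:
    """Build a :class:`ScoreTable` from an already-ranked quartile matrix.

    Used when the quartile ranks themselves are the input (e.g. a
    published rank matrix) rather than raw factor values.
    """
    specs = list(specs)
    if mortality_factor is None:
        mortality_factor = next(
            (s.name for s in specs if "mortality" in s.name.lower()), None
        )
    scores = {rid: integrated_score(r, specs) for rid, r in ranks_by_region.items()}
    ordered = _prioritize(ranks_by_region, scores, mortality_factor)
    priority = _competition_ranks(ordered, scores)
    rows = [
        ScoreRow(
            region_id=rid,
            ranks=dict(ranks_by_region[rid]),
            integrated_score=scores[rid],
            priority_rank=priority[rid],
        )
        for rid in ordered
    ]
    return ScoreTable(rows=rows, factors=specs, method="ranks")


def score_table(
    table: RegionTable,
    specs: Sequence[FactorSpec] | None = None,
    method: str = "cutpoint",
    mortality_factor: str | None = None,
) -> ScoreTable:
    """Score every region: per-factor quartiles, integrated score, priority.

    Regions are ordered by descending integrated score; ties share the
    minimum (best) priority rank.  Row order among ties is made
    deterministic by descending mortality rank (when a mortality factor is
    present) and then region_id.

    Requires complete values for every configured factor — scoring never
    imputes (a fabricated quartile rank would be worse than an error).
    """
    specs = list(specs) if specs is not None else list(table.factors)
    ranks_by_region: dict[str, dict[str, int]] = {rid: {} for rid in table.region_ids}
    for spec in specs:
        col = table.column(spec.name)
        assignments, _ = assign_quartiles(
            col, direction=spec.direction, method=method, factor=spec.name
        )
        for a in assignments:
            ranks_by_region[a.region_id][spec.name] = a.rank

    scores = {
        rid: integrated_score(ranks_by_region[rid], specs) for rid in table.region_ids
    }
    if mortality_factor is None:
        mortality_factor = next(
            (s.name for s in specs if "mortality" in s.name.lower()), None
        )
    ordered = _prioritize(ranks_by_region, scores, mortality_factor)
    priority = _competition_ranks(ordered, scores)

    rows = [
        ScoreRow(
            region_id=rid,
            ranks=dict(ranks_by_region[rid]),
            integrated_score=scores[rid],
            priority_rank=priority[rid],
        )
        for rid in ordered
    ]
    return ScoreTable(rows=rows, factors=specs, method=method)
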