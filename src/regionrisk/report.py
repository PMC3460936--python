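"""Pipeline orchestration, priority reports and GeoJSON property joins.

Composes the scoring and correlation stages into one deterministic run
and renders the outputs a community-health analyst needs: a priority
table ordered by integrated quartile score, with the quartile-4
("modifiable target") factors flagged per region, and an optional join
of the scores onto a GeoJSON FeatureCollection for choropleth mapping
in any GIS tool.  Geometries are never touched; only feature properties
are added.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .correlation import CorrelationResult, SkippedGroup, grouped_correlations
from .data import FactorSpec, RegionTable, read_factor_config, read_region_table
from .quartiles import ScoreTable, score_table

__all__ = [
    "PriorityReport",
    "PipelineResult",
    "run_pipeline",
    "join_geojson",
    "scores_to_frame",
    "correlations_to_frame",
]

logger = logging.getLogger("regionrisk")


@dataclass(frozen=True)
class PriorityEntry:
    region_id: str
    priority_rank: int
    integrated_score: int
    ranks: dict[str, int]
    top_quartile_factors: tuple[str, ...]  # the rank-4 "modifiable target" flags


@dataclass
class PriorityReport:
    """Regions ordered by descending integrated score with rank-4 flags."""

    entries: list[PriorityEntry]

    @classmethod
    def from_scores(cls, scores: ScoreTable) -> "PriorityReport":
        entries = [
            PriorityEntry(
                region_id=row.region_id,
                priority_rank=row.priority_rank,
                integrated_score=row.integrated_score,
                ranks=dict(row.ranks),
                top_quartile_factors=tuple(
                    f for f, q in row.ranks.items() if q == 4
                ),
            )
            for row in scores.rows
        ]
        return cls(entries=entries)


@dataclass
class PipelineResult:
    scores: ScoreTable
    correlations: list[CorrelationResult]
    skipped_groups: list[SkippedGroup]
    report: PriorityReport
    log: dict[str, object] = field(default_factory=dict)


def _default_pairs(table: RegionTable) -> list[tuple[str, str]]:
    """Mortality against every other factor, when a mortality column exists."""
    names = table.factor_names
    mort = next((n for n in names if "mortality" in n.lower()), None)
    if mort is None:
        return []
    return [(mort, other) for other in names if other != mort]


def run_pipeline(
    input_path: str | Path,
    factors_path: str | Path | None = None,
    *,
    factors: Sequence[FactorSpec] | None = None,
    method: str = "cutpoint",
    pairs: Sequence[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> PipelineResult:
    """Score regions, run grouped correlations, and build the report.

    ``factors`` may be passed directly or loaded from a YAML/JSON config
    at ``factors_path``.  Default correlation pairs are mortality versus
    every other configured factor.  The run is fully deterministic and
    the decisions taken (binning method, weight vector, skipped groups)
    are recorded in the result's ``log``.
    """
    if factors is None:
        if factors_path is None:
            raise ValueError("either factors or factors_path must be given")
        factors = read_factor_config(factors_path)
    table = read_region_table(input_path, factors)

    try:
        scores = score_table(table, factors, method=method)
    except Exception as exc:
        raise RuntimeError(f"scoring stage failed: {exc}") from exc

    pairs = list(pairs) if pairs is not None else _default_pairs(table)
    correlations: list[CorrelationResult] = []
    skipped: list[SkippedGroup] = []
    if pairs:
        try:
            correlations, skipped = grouped_correlations(table, pairs, alpha=alpha)
        except Exception as exc:
            raise RuntimeError(f"correlation stage failed: {exc}") from exc

    report = PriorityReport.from_scores(scores)
    log = {
        "input": str(input_path),
        "n_regions": len(table.records),
        "binning_method": method,
        "weights": {f.name: f.weight for f in factors},
        "directions": {f.name: f.direction for f in factors},
        "pairs": [list(p) for p in pairs],
        "skipped_groups": [
            {"group_id": s.group_id, "n": s.n, "reason": s.reason} for s in skipped
        ],
    }
    logger.info("pipeline: %s", json.dumps(log, sort_keys=True))
    return PipelineResult(
        scores=scores,
        correlations=correlations,
        skipped_groups=skipped,
        report=report,
        log=log,
    )


def scores_to_frame(scores: ScoreTable) -> pd.DataFrame:
    """Score table as a DataFrame: per-factor ranks, score, priority."""
    rows = []
    for r in scores.rows:
        row: dict[str, object] = {"region_id": r.region_id}
        row.update(r.ranks)
        row["integrated_score"] = r.integrated_score
        row["priority_rank"] = r.priority_rank
        rows.append(row)
    return pd.DataFrame(rows)


def correlations_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "group": r.group_id if r.group_id is not None else "(pooled)",
                "pair": f"{r.pair[0]}:{r.pair[1]}" if r.pair else "",
                "method": r.method,
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p_value,
                "n": r.n,
            }
        )
    return pd.DataFrame(rows)


def join_geojson(
    scores: ScoreTable,
    geo: Mapping[str, object],
    key: str = "region_id",
) -> tuple[dict, dict[str, list]]:
    """Annotate GeoJSON features with scores; never touch geometry.

    Each feature whose ``properties[key]`` matches a scored region gains
    ``integrated_score``, ``priority_rank`` and per-factor
    ``rank_<factor>`` properties.  Returns the annotated
    FeatureCollection plus a report of unmatched regions and features.

    Raises ``ValueError`` naming the feature index if any feature lacks
    the key property.
    """
    if geo.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    features = geo.get("features", [])
    by_region = {row.region_id: row for row in scores.rows}
    matched: set[str] = set()
    out_features = []
    unmatched_features: list[str] = []
    for i, feat in enumerate(features):
        props = dict(feat.get("properties") or {})
        if key not in props:
            raise ValueError(f"feature {i} lacks the key property {key!r}")
        rid = str(props[key])
        row = by_region.get(rid)
        if row is None:
            unmatched_features.append(rid)
        else:
            matched.add(rid)
            props["integrated_score"] = row.integrated_score
            props["priority_rank"] = row.priority_rank
            for fname, q in row.ranks.items():
                props[f"rank_{fname}"] = q
        out_features.append({**feat, "properties": props})
    joined = {**geo, "features": out_features}
    report = {
        "unmatched_regions": sorted(set(by_region) - matched),
        "unmatched_features": unmatched_features,
    }
    return joined, report
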