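"""Threshold filtering of hit records and per-query best-hit selection.

Filtering and ranking are separate passes so one expensive search can
feed many filterings at different stringencies.

Boundary semantics (documented for reproducibility):

* the E-value filter removes values *strictly greater* than the cutoff,
  so a hit at exactly the cutoff is retained;
* the three minimum filters pass at-or-above;
* ties on the ranking metric break by higher bitscore, then by earlier
  position in the input file (the search tool's own ranking order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .formats_io import HitRecord

__all__ = [
    "FilterCriteria",
    "RANKING_METRICS",
    "BestHitMap",
    "filter_hits",
    "select_best_hits",
    "stringency_sweep",
    "COMBINED_PRESETS",
    "SINGLE_METRIC_GRIDS",
]

DEFAULT_MAX_EVALUE = 1e-5

RANKING_METRICS = ("evalue", "bitscore", "alignment_length", "percent_identity")

#: aliases accepted on the command line
METRIC_ALIASES = {
    "evalue": "evalue",
    "bitscore": "bitscore",
    "length": "alignment_length",
    "alignment_length": "alignment_length",
    "pident": "percent_identity",
    "percent_identity": "percent_identity",
}


@dataclass(frozen=True)
class FilterCriteria:
    """Retention thresholds applied to each hit independently."""

    max_evalue: float = DEFAULT_MAX_EVALUE
    min_alignment_length: int = 0
    min_percent_identity: float = 0.0
    min_bitscore: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")
        if (self.min_alignment_length < 0 or self.min_percent_identity < 0
                or self.min_bitscore < 0):
            raise ValueError("minimum thresholds must be >= 0")

    def passes(self, hit: HitRecord) -> bool:
        return (hit.evalue <= self.max_evalue
                and hit.alignment_length >= self.min_alignment_length
                and hit.percent_identity >= self.min_percent_identity
                and hit.bitscore >= self.min_bitscore)


#: single-metric stringency grids used for sweep presets
SINGLE_METRIC_GRIDS: dict[str, list[FilterCriteria]] = {
    "evalue": [FilterCriteria(max_evalue=e, label=f"evalue<={e:g}")
               for e in (1e-5, 1e-10, 1e-15, 1e-20)],
    "alignment_length": [
        FilterCriteria(min_alignment_length=n, label=f"length>={n}")
        for n in (30, 50, 100, 150)],
    "percent_identity": [
        FilterCriteria(min_percent_identity=p, label=f"pident>={p}")
        for p in (10, 25, 33, 40)],
    "bitscore": [FilterCriteria(min_bitscore=b, label=f"bitscore>={b}")
                 for b in (33, 50, 60, 75)],
}

#: combined least -> most stringent presets; the two endpoints follow the
#: published grids exactly, the middle two walk the per-metric grids in step.
COMBINED_PRESETS: list[FilterCriteria] = [
    FilterCriteria(1e-5, 30, 10, 33, label="combined_1_least"),
    FilterCriteria(1e-5, 50, 25, 50, label="combined_2"),
    FilterCriteria(1e-5, 100, 33, 60, label="combined_3"),
    FilterCriteria(1e-5, 150, 40, 75, label="combined_4_most"),
]


@dataclass
class BestHitMap:
    """At most one winning hit per query, plus the provenance that produced it."""

    entries: dict[str, HitRecord]
    criteria: FilterCriteria | None = None
    metric: str = "evalue"

    def __len__(self) -> int:
        return len(self.entries)

    def subjects(self) -> dict[str, str]:
        return {q: h.subject_id for q, h in self.entries.items()}


def filter_hits(hits: Sequence[HitRecord],
                criteria: FilterCriteria) -> list[HitRecord]:
    """Return the subsequence of ``hits`` passing all four thresholds."""
    return [h for h in hits if criteria.passes(h)]


def _metric_key(metric: str):
    metric = METRIC_ALIASES.get(metric, metric)
    if metric not in RANKING_METRICS:
        raise ValueError(f"unknown ranking metric {metric!r}")
    if metric == "evalue":
        # lower is better; negate so "larger key wins" uniformly
        return metric, lambda h: -h.evalue
    return metric, lambda h: getattr(h, metric)


def select_best_hits(hits: Sequence[HitRecord],
                     metric: str = "evalue",
                     criteria: FilterCriteria | None = None) -> BestHitMap:
    """Pick one winner per query: best metric, then higher bitscore, then
    earlier input position.

    ``hits`` are assumed already filtered; pass ``criteria`` only to record
    provenance.  Queries keep the order of their first appearance.
    """
    canonical, key = _metric_key(metric)
    best: dict[str, tuple[float, float, HitRecord]] = {}
    for hit in hits:
        cand = (key(hit), hit.bitscore, hit)
        prev = best.get(hit.query_id)
        if prev is None or cand[:2] > prev[:2]:
            best[hit.query_id] = cand
    return BestHitMap(
        entries={q: t[2] for q, t in best.items()},
        criteria=criteria,
        metric=canonical,
    )


def stringency_sweep(hits: Sequence[HitRecord],
                     grid: Iterable[FilterCriteria],
                     metric: str = "evalue") -> pd.DataFrame:
    """Apply each criteria set and tabulate survivor counts.

    Returns one row per criteria set with columns ``label``,
    ``n_hits_passing`` and ``n_queries_with_hit``; counts come straight
    from :func:`filter_hits` / :func:`select_best_hits`.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("criteria grid is empty")
    rows = []
    for i, criteria in enumerate(grid):
        passing = filter_hits(hits, criteria)
        best = select_best_hits(passing, metric=metric, criteria=criteria)
        rows.append({
            "label": criteria.label or f"criteria_{i}",
            "max_evalue": criteria.max_evalue,
            "min_alignment_length": criteria.min_alignment_length,
            "min_percent_identity": criteria.min_percent_identity,
            "min_bitscore": criteria.min_bitscore,
            "n_hits_passing": len(passing),
            "n_queries_with_hit": len(best),
        })
    return pd.DataFrame(rows)
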