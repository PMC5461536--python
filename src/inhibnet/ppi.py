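"""Coverage of enzymatic annotations by protein-protein interaction data.

Annotated cleavages and inhibitions are functional claims; PPI databases
record physical association.  Two small accounting operations quantify how
the two relate: what fraction of annotated enzymatic pairs appears as a
physical edge (optionally above a confidence cutoff), and how a curated
set of PPIs breaks down into interpretation categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .catalog import PairKey


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class EdgeList:
    """Unordered protein-id pairs with optional per-edge confidence scores."""

    edges: set[tuple[str, str]]
    source_tag: str = ""
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        source_tag: str = "",
        scores: dict[tuple[str, str], float] | None = None,
    ) -> "EdgeList":
        canon = set()
        canon_scores: dict[tuple[str, str], float] = {}
        scores = scores or {}
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-edge {a!r}")
            key = _canon(a, b)
            canon.add(key)
            if (a, b) in scores:
                canon_scores[key] = scores[(a, b)]
            elif (b, a) in scores:
                canon_scores[key] = scores[(b, a)]
        return cls(edges=canon, source_tag=source_tag, scores=canon_scores)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _canon(*pair) in self.edges


@dataclass
class Coverage:
    n_annotated: int
    n_covered: int
    percent: int | None  # None when undefined (no annotated pairs)

    @property
    def percent_str(self) -> str:
        return "NA" if self.percent is None else f"{self.percent}%"


def overlap_coverage(
    annotated: Sequence[PairKey],
    edges: EdgeList,
    min_score: float | None = None,
    alias: dict[str, str] | None = None,
) -> Coverage:
    """Fraction of annotated pairs present as (unordered) PPI edges.

    ``min_score`` keeps only edges at or above a confidence cutoff; edges
    without a score are kept only when no cutoff is set.  ``alias`` maps
    identifiers before matching.  Percent is rounded to the nearest integer.
    """
    if min_score is None:
        usable = edges.edges
    else:
        usable = {e for e in edges.edges if edges.scores.get(e, float("-inf")) >= min_score}
    alias = alias or {}
    n_cov = 0
    seen: set[tuple[str, str]] = set()
    for pair in annotated:
        a = alias.get(pair.inhibitor_id, pair.inhibitor_id)
        b = alias.get(pair.protease_id, pair.protease_id)
        key = _canon(a, b)
        if key in seen:
            continue
        seen.add(key)
        if key in usable:
            n_cov += 1
    n_ann = len(seen)
    percent = None if n_ann == 0 else round(100.0 * n_cov / n_ann)
    return Coverage(n_annotated=n_ann, n_covered=n_cov, percent=percent)


@dataclass
class CategoryBreakdown:
    counts: dict[str, int]
    percents: dict[str, int]
    total: int

    def group_percent(self, categories: Iterable[str]) -> tuple[int, int]:
        """(count, percent) for a union of categories (e.g. all known-interaction kinds)."""
        count = sum(self.counts.get(c, 0) for c in categories)
        return count, round(100.0 * count / self.total) if self.total else 0


def category_breakdown(
    labeled: Sequence[tuple[PairKey, str]]
) -> CategoryBreakdown:
    """Per-category counts and nearest-integer percents for a curated pair list."""
    counts: dict[str, int] = {}
    for _pair, category in labeled:
        counts[category] = counts.get(category, 0) + 1
    total = len(labeled)
    percents = {c: round(100.0 * n / total) for c, n in counts.items()} if total else {}
    return CategoryBreakdown(counts=counts, percents=percents, total=total)
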