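"""Protein catalog, enzymatic-plausibility gold standard, and enrichment tables.

Proteases and their inhibitors are organised into catalytic classes
(aspartic, cysteine, metallo, serine, threonine) and sequence families
(e.g. "S1" serine proteases, "I4" serpins).  Inhibitor families are
chemically committed to one or a few target classes — a serpin cannot
inhibit a metalloprotease — which makes it possible to declare
class-incompatible inhibitor/protease pairs *true negatives* (TN) without
any experiment.  Annotated inhibitions are the true positives (TP);
everything else in the inhibitor x protease search space is unknown.

This module houses the catalog records, the canonical pair key, the
TP/TN/unknown partition builder, and the TP:TN enrichment-table arithmetic
used to account for filter cascades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple, Sequence


class Role(str, Enum):
    PROTEASE = "protease"
    INHIBITOR = "inhibitor"
    OTHER = "other"


class CatalyticClass(str, Enum):
    ASPARTIC = "aspartic"
    CYSTEINE = "cysteine"
    METALLO = "metallo"
    SERINE = "serine"
    THREONINE = "threonine"
    NONE = "none"


@dataclass(frozen=True)
class ProteinRecord:
    """One catalog entry.

    ``active=False`` marks catalytically dead homologs; they remain part of
    the search space (inactive proteases still appear in interaction data).
    """

    id: str
    role: Role
    catalytic_class: CatalyticClass
    family: str
    active: bool = True

    def __post_init__(self) -> None:
        if self.role is Role.PROTEASE and self.catalytic_class is CatalyticClass.NONE:
            raise ValueError(f"protease {self.id!r} must have a catalytic class")
        if self.role is Role.INHIBITOR:
            if self.catalytic_class is not CatalyticClass.NONE:
                raise ValueError(f"inhibitor {self.id!r} must have catalytic_class 'none'")
            if not self.family:
                raise ValueError(f"inhibitor {self.id!r} must have a family")


class PairKey(NamedTuple):
    """Canonical candidate-inhibition key: inhibitor first, protease second."""

    inhibitor_id: str
    protease_id: str


@dataclass(frozen=True)
class CompatibilityRule:
    """Which protease catalytic classes an inhibitor family can plausibly block."""

    inhibitor_family: str
    compatible_protease_classes: frozenset[CatalyticClass]

    def __post_init__(self) -> None:
        if not self.compatible_protease_classes:
            raise ValueError(
                f"rule for family {self.inhibitor_family!r} must allow >=1 class"
            )


@dataclass
class GoldStandard:
    """Disjoint TP / TN / unknown partition of the inhibitor x protease space."""

    tp: set[PairKey]
    tn: set[PairKey]
    unknown: set[PairKey]
    search_space_size: int
    conflicts: list[PairKey] = field(default_factory=list)

    @property
    def all_pairs(self) -> set[PairKey]:
        return self.tp | self.tn | self.unknown

    def validate(self) -> None:
        if self.tp & self.tn or self.tp & self.unknown or self.tn & self.unknown:
            raise ValueError("tp, tn and unknown must be disjoint")
        if len(self.tp) + len(self.tn) + len(self.unknown) != self.search_space_size:
            raise ValueError("partition does not cover the search space")


def build_gold_standard(
    catalog: Sequence[ProteinRecord],
    annotations: Iterable[PairKey],
    rules: Iterable[CompatibilityRule],
) -> GoldStandard:
    """Partition all inhibitor x protease pairs into TP / TN / unknown.

    TP: annotated inhibitions.  TN: unannotated pairs whose protease class is
    incompatible with the inhibitor family's rule.  Unknown: plausible but
    unproven pairs, and pairs whose inhibitor family has no rule.

    An annotated pair that violates its rule stays TP (curated data outranks
    the heuristic) but is recorded in ``conflicts`` and a warning is emitted.
    """
    by_id = {rec.id: rec for rec in catalog}
    inhibitors = [r for r in catalog if r.role is Role.INHIBITOR]
    proteases = [r for r in catalog if r.role is Role.PROTEASE]
    rule_map = {r.inhibitor_family: r.compatible_protease_classes for r in rules}

    annotated: set[PairKey] = set()
    for pair in annotations:
        if pair.inhibitor_id not in by_id or pair.protease_id not in by_id:
            raise KeyError(f"annotation references unknown protein: {pair}")
        annotated.add(PairKey(*pair))

    tp: set[PairKey] = set()
    tn: set[PairKey] = set()
    unknown: set[PairKey] = set()
    conflicts: list[PairKey] = []

    for inh in inhibitors:
        compatible = rule_map.get(inh.family)
        for prot in proteases:
            pair = PairKey(inh.id, prot.id)
            if pair in annotated:
                tp.add(pair)
                if compatible is not None and prot.catalytic_class not in compatible:
                    conflicts.append(pair)
                continue
            if compatible is not None and prot.catalytic_class not in compatible:
                tn.add(pair)
            else:
                unknown.add(pair)

    if conflicts:
        warnings.warn(
            f"{len(conflicts)} annotated pair(s) contradict compatibility rules; "
            "kept as TP",
            stacklevel=2,
        )
    gs = GoldStandard(
        tp=tp,
        tn=tn,
        unknown=unknown,
        search_space_size=len(inhibitors) * len(proteases),
        conflicts=conflicts,
    )
    gs.validate()
    return gs


# --------------------------------------------------------------------------
# Enrichment tables (TP:TN accounting per filter stage)
# --------------------------------------------------------------------------

class RatioMode(str, Enum):
    PERCENT = "percent_tp_over_tn"
    ONE_TO_N = "one_to_n"


@dataclass
class StageRow:
    label: str
    tp_count: int
    tn_count: int
    remaining_pairs: int
    ratio: str


@dataclass
class StageTable:
    rows: list[StageRow]
    ratio_mode: RatioMode

    def to_records(self) -> list[dict]:
        return [
            {
                "stage": r.label,
                "tp": r.tp_count,
                "tn": r.tn_count,
                "ratio": r.ratio,
                "remaining_pairs": r.remaining_pairs,
            }
            for r in self.rows
        ]


def format_ratio(tp: int, tn: int, mode: RatioMode) -> str:
    """Format a TP:TN enrichment cell.

    Percent mode prints 100*tp/tn to two decimals ("4.21%").  One-to-n mode
    prints "1:<tn/tp>" with one decimal below 10 and an integer at >=10
    ("1:4.5", "1:24") — the precision used in printed cascade tables.
    """
    if mode is RatioMode.PERCENT:
        if tn == 0:
            return "NA"
        return f"{100.0 * tp / tn:.2f}%"
    if tp == 0:
        return "NA"
    n = tn / tp
    if n >= 10:
        return f"1:{round(n):d}"
    return f"1:{n:.1f}"


def enrichment_table(
    gold: GoldStandard,
    stages: Sequence[tuple[str, set[PairKey]]],
    ratio_mode: RatioMode = RatioMode.PERCENT,
    require_nested: bool = False,
) -> StageTable:
    """Per-stage TP/TN/remaining counts with a formatted enrichment ratio.

    The first stage is the reference universe; every later stage must be a
    subset of it.  ``require_nested=True`` additionally demands each stage be
    contained in its predecessor (a strict filter cascade).  Breakdown-style
    tables, where later rows partition the universe rather than nest, use the
    default.
    """
    if not stages:
        raise ValueError("at least one stage required")
    universe = stages[0][1]
    prev = universe
    rows: list[StageRow] = []
    for label, pairs in stages:
        if not pairs <= universe:
            raise ValueError(f"stage {label!r} is not contained in the first stage")
        if require_nested and not pairs <= prev:
            raise ValueError(f"stage {label!r} is not nested in its predecessor")
        tp_n = len(pairs & gold.tp)
        tn_n = len(pairs & gold.tn)
        rows.append(
            StageRow(
                label=label,
                tp_count=tp_n,
                tn_count=tn_n,
                remaining_pairs=len(pairs),
                ratio=format_ratio(tp_n, tn_n, ratio_mode),
            )
        )
        prev = pairs
    return StageTable(rows=rows, ratio_mode=ratio_mode)


def enrichment_table_from_counts(
    rows: Sequence[tuple[str, int, int, int]],
    ratio_mode: RatioMode = RatioMode.PERCENT,
) -> StageTable:
    """Build a StageTable directly from (label, tp, tn, remaining) counts.

    Used to recompute published-table ratio cells from their printed counts.
    """
    return StageTable(
        rows=[
            StageRow(label, tp, tn, rem, format_ratio(tp, tn, ratio_mode))
            for label, tp, tn, rem in rows
        ],
        ratio_mode=ratio_mode,
    )
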