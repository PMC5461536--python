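"""Three-stage filter cascade producing candidate novel inhibitions.

Stages, in order: (1) coexpression above a threshold (strictly greater,
R > 0.6 by default) in a designated score matrix; (2) localization class in
an allowed set — colocalized, antilocalized, and unannotated pairs pass by
default, since dropping every unannotated pair would gut the search space;
(3) enzymatic family plausibility — keep a pair only when the inhibitor is
already known to block a protease of the same family, or the protease is
known to be blocked by an inhibitor of the same family.

Each surviving pair carries a :class:`FilterTrace`; the whole run yields a
:class:`PredictionSet` with a per-stage TP/TN enrichment table and the
novel predictions (known TPs are accounted for in the table but excluded
from the novel list).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .catalog import (
    GoldStandard,
    PairKey,
    ProteinRecord,
    RatioMode,
    StageTable,
    enrichment_table,
)
from .coexpression import ScoreMatrix
from .localization import LocClass

DEFAULT_ALLOWED_CLASSES = frozenset({LocClass.CO, LocClass.AT, LocClass.NA})

STAGE_COEXPRESSION = "coexpressed"
STAGE_LOCALIZATION = "localization"
STAGE_FAMILY = "family_plausible"


@dataclass(frozen=True)
class FilterTrace:
    pair: PairKey
    coexpression_score: float
    loc_class: LocClass
    family_evidence: str  # inhibitor_family_known_for_protease_family /
    #                       protease_family_known_for_inhibitor_family / both / none
    passed_stages: tuple[str, ...]


@dataclass
class PredictionSet:
    traces: list[FilterTrace]
    stage_table: StageTable
    novel: list[FilterTrace]
    parameters: dict


def filter_by_coexpression(
    candidates: set[PairKey], matrix: ScoreMatrix, threshold: float = 0.6
) -> set[PairKey]:
    """Pairs whose matrix score strictly exceeds the threshold.

    Missing scores never pass: a pair cannot clear an evidence filter
    without evidence.
    """
    if not -1.0 < threshold < 1.0:
        raise ValueError("threshold must be in (-1, 1)")
    vals = matrix.pair_values(sorted(candidates))
    keep = vals[vals > threshold]
    return {PairKey(*idx) for idx in keep.index}


def filter_by_localization(
    pairs: set[PairKey],
    loc_classes: Mapping[PairKey, LocClass],
    allowed: frozenset[LocClass] | set[LocClass] = DEFAULT_ALLOWED_CLASSES,
) -> set[PairKey]:
    """Pairs whose colocalization label is in the allowed set."""
    missing = [p for p in pairs if p not in loc_classes]
    if missing:
        raise KeyError(f"pairs without a localization label: {sorted(missing)[:5]}")
    return {p for p in pairs if loc_classes[p] in allowed}


def _family_of(catalog: Sequence[ProteinRecord]) -> dict[str, str]:
    return {rec.id: rec.family for rec in catalog}


def family_evidence(
    pair: PairKey,
    annotations: Iterable[PairKey],
    catalog: Sequence[ProteinRecord],
) -> str:
    """Which enzymatic-precedent clause supports a candidate pair.

    Clause (i): the inhibitor is annotated against some protease of the
    candidate protease's family.  Clause (ii): the protease is annotated as
    inhibited by some inhibitor of the candidate inhibitor's family.
    """
    fam = _family_of(catalog)
    if pair.inhibitor_id not in fam or pair.protease_id not in fam:
        raise KeyError(f"pair members missing from catalog: {pair}")
    target_family = fam[pair.protease_id]
    inhibitor_family = fam[pair.inhibitor_id]
    clause_i = clause_ii = False
    for ann in annotations:
        if ann.inhibitor_id == pair.inhibitor_id and fam.get(ann.protease_id) == target_family:
            clause_i = True
        if ann.protease_id == pair.protease_id and fam.get(ann.inhibitor_id) == inhibitor_family:
            clause_ii = True
        if clause_i and clause_ii:
            break
    if clause_i and clause_ii:
        return "both"
    if clause_i:
        return "inhibitor_family_known_for_protease_family"
    if clause_ii:
        return "protease_family_known_for_inhibitor_family"
    return "none"


def filter_enzymatic_family(
    pairs: set[PairKey],
    annotations: Sequence[PairKey],
    catalog: Sequence[ProteinRecord],
) -> set[PairKey]:
    """Keep pairs with family-level precedent on either side."""
    return {
        p for p in pairs if family_evidence(p, annotations, catalog) != "none"
    }


def run_cascade(
    gold: GoldStandard,
    matrix: ScoreMatrix,
    loc_classes: Mapping[PairKey, LocClass],
    annotations: Sequence[PairKey],
    catalog: Sequence[ProteinRecord],
    threshold: float = 0.6,
    allowed: frozenset[LocClass] | set[LocClass] = DEFAULT_ALLOWED_CLASSES,
    ratio_mode: RatioMode = RatioMode.ONE_TO_N,
) -> PredictionSet:
    """Apply coexpression -> localization -> family filters with accounting.

    The stage table starts from the full search space and tracks TP/TN/
    remaining counts through each nested stage.  Known TPs survive into the
    table's accounting but are removed from the novel-prediction list.
    """
    candidates = gold.all_pairs
    s1 = filter_by_coexpression(candidates, matrix, threshold)
    s2 = filter_by_localization(s1, loc_classes, allowed)
    s3 = filter_enzymatic_family(s2, annotations, catalog)

    stage_table = enrichment_table(
        gold,
        [
            ("all", candidates),
            (STAGE_COEXPRESSION, s1),
            (STAGE_LOCALIZATION, s2),
            (STAGE_FAMILY, s3),
        ],
        ratio_mode=ratio_mode,
        require_nested=True,
    )

    vals = matrix.pair_values(sorted(candidates))
    score_of = {PairKey(*idx): float(v) for idx, v in vals.items()}
    traces = []
    for pair in sorted(s3):
        passed = (STAGE_COEXPRESSION, STAGE_LOCALIZATION, STAGE_FAMILY)
        traces.append(
            FilterTrace(
                pair=pair,
                coexpression_score=score_of[pair],
                loc_class=loc_classes[pair],
                family_evidence=family_evidence(pair, annotations, catalog),
                passed_stages=passed,
            )
        )
    novel = [t for t in traces if t.pair not in gold.tp]
    return PredictionSet(
        traces=traces,
        stage_table=stage_table,
        novel=novel,
        parameters={
            "threshold": threshold,
            "allowed_loc_classes": sorted(c.value for c in allowed),
            "matrix_tag": matrix.method_tag,
        },
    )
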