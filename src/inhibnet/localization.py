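"""Subcellular-localization evidence filters and pair colocalization classes.

Localization annotations come from three heterogeneous sources — a curated
localization database (LocDB-style, with primary/secondary ranks),
antibody-based atlas calls (HPA-style, with a reliability grade), and GO
cellular-component annotation (with evidence codes).  Only well-supported
records survive filtering; the survivors are pooled per protein (union over
sources) and each candidate pair is then classified:

``CO``  colocalized — the proteins share a compartment term, or terms with
        a common non-root ancestor (sources annotate at different depth).
``AT``  antilocalized — one extracellular and the other cytosolic, or one
        in an organelle and the other cytosolic: compartments that merge
        upon cellular stimulus (secretion, organelle rupture), so the
        proteins can still meet.
``NC``  not colocalized — neither of the above.
``NA``  not annotated — at least one protein has no surviving annotation.

Precedence is NA > CO > AT > NC: a multi-compartment protein may satisfy
both CO and AT clauses, and sharing an annotation is the stronger statement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .catalog import PairKey

HPA_ACCEPTED = frozenset({"High", "Medium", "Supportive"})
GO_ACCEPTED = frozenset({"EXP", "IDA", "IPI", "IGI", "IMP", "IEP", "TAS"})
SOURCES = frozenset({"locdb", "hpa", "go"})


@dataclass(frozen=True)
class LocalizationRecord:
    protein_id: str
    term: str
    source: str
    evidence: str = ""


class LocClass(str, Enum):
    CO = "CO"
    AT = "AT"
    NC = "NC"
    NA = "NA"


@dataclass(frozen=True)
class PairLocClass:
    pair: PairKey
    label: LocClass


@dataclass
class CompartmentModel:
    """Compartment vocabulary with category sets and term ancestry.

    ``extracellular_terms``, ``cytosol_terms`` and ``organelle_terms`` are
    disjoint subsets of the vocabulary used by the antilocalization rule;
    ``ancestry`` maps each term to its (transitive) ancestor set, used to
    detect shared annotation at different granularity.  The root term (one
    with no ancestors that is an ancestor of everything) never counts as a
    shared compartment.
    """

    vocabulary: set[str]
    extracellular_terms: set[str]
    cytosol_terms: set[str]
    organelle_terms: set[str]
    ancestry: dict[str, set[str]] = field(default_factory=dict)
    root: str | None = None

    def __post_init__(self) -> None:
        cats = [self.extracellular_terms, self.cytosol_terms, self.organelle_terms]
        for i in range(len(cats)):
            for j in range(i + 1, len(cats)):
                if cats[i] & cats[j]:
                    raise ValueError("compartment category sets must be disjoint")
        for c in cats:
            if not c <= self.vocabulary:
                raise ValueError("category terms must belong to the vocabulary")
        # ancestry acyclicity: a term may not be its own (transitive) ancestor
        for term, anc in self.ancestry.items():
            if term in anc:
                raise ValueError(f"cyclic ancestry at term {term!r}")

    def check_terms(self, terms: Iterable[str]) -> None:
        for t in terms:
            if t not in self.vocabulary:
                raise KeyError(f"term {t!r} is not in the compartment vocabulary")

    def _expand(self, terms: set[str]) -> set[str]:
        out = set(terms)
        for t in terms:
            out |= self.ancestry.get(t, set())
        if self.root is not None:
            out.discard(self.root)
        return out

    def shares_compartment(self, terms_a: set[str], terms_b: set[str]) -> bool:
        return bool(self._expand(terms_a) & self._expand(terms_b))


def default_compartment_model() -> CompartmentModel:
    """Flat cellular-compartment vocabulary used by the synthetic generator."""
    organelles = {
        "nucleus",
        "mitochondrion",
        "lysosome",
        "endoplasmic_reticulum",
        "golgi_apparatus",
        "secretory_granule",
        "peroxisome",
    }
    vocab = {"cell", "extracellular_region", "cytosol", "plasma_membrane"} | organelles
    ancestry = {t: {"cell"} for t in vocab if t != "cell"}
    return CompartmentModel(
        vocabulary=vocab,
        extracellular_terms={"extracellular_region"},
        cytosol_terms={"cytosol"},
        organelle_terms=organelles,
        ancestry=ancestry,
        root="cell",
    )


def filter_records(records: Iterable[LocalizationRecord]) -> list[LocalizationRecord]:
    """Keep only well-supported annotations; collapse duplicates.

    HPA records need reliability High/Medium/Supportive; GO records need an
    experimental or curated evidence code (EXP, IDA, IPI, IGI, IMP, IEP,
    TAS); LocDB primary and secondary localizations are both kept.
    """
    kept: list[LocalizationRecord] = []
    seen: set[tuple[str, str]] = set()
    for rec in records:
        if rec.source not in SOURCES:
            raise ValueError(f"unknown localization source {rec.source!r}")
        if rec.source == "hpa" and rec.evidence not in HPA_ACCEPTED:
            continue
        if rec.source == "go" and rec.evidence not in GO_ACCEPTED:
            continue
        key = (rec.protein_id, rec.term)
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    return kept


def compartments_by_protein(
    records: Iterable[LocalizationRecord],
) -> dict[str, set[str]]:
    """Union of compartment terms per protein (sources pooled)."""
    out: dict[str, set[str]] = {}
    for rec in records:
        out.setdefault(rec.protein_id, set()).add(rec.term)
    return out


def classify_pair(
    pair: PairKey,
    compartments_a: set[str],
    compartments_b: set[str],
    model: CompartmentModel,
) -> PairLocClass:
    """Assign CO / AT / NC / NA to one candidate pair.

    Symmetric in the two proteins; raises on terms outside the vocabulary.
    """
    model.check_terms(compartments_a)
    model.check_terms(compartments_b)
    if not compartments_a or not compartments_b:
        return PairLocClass(pair, LocClass.NA)
    if model.shares_compartment(compartments_a, compartments_b):
        return PairLocClass(pair, LocClass.CO)
    ext_a = bool(compartments_a & model.extracellular_terms)
    ext_b = bool(compartments_b & model.extracellular_terms)
    cyt_a = bool(compartments_a & model.cytosol_terms)
    cyt_b = bool(compartments_b & model.cytosol_terms)
    org_a = bool(compartments_a & model.organelle_terms)
    org_b = bool(compartments_b & model.organelle_terms)
    anti = (ext_a and cyt_b) or (ext_b and cyt_a) or (org_a and cyt_b) or (org_b and cyt_a)
    if anti:
        return PairLocClass(pair, LocClass.AT)
    return PairLocClass(pair, LocClass.NC)


def classify_pairs(
    pairs: Sequence[PairKey],
    compartments: Mapping[str, set[str]],
    model: CompartmentModel,
) -> dict[PairKey, LocClass]:
    """Classify every candidate pair; proteins without terms count as unannotated."""
    out: dict[PairKey, LocClass] = {}
    for pair in pairs:
        ca = compartments.get(pair.inhibitor_id, set())
        cb = compartments.get(pair.protease_id, set())
        out[pair] = classify_pair(pair, ca, cb, model).label
    return out
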