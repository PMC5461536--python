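"""Plain TSV readers and writers for every pipeline artifact.

All dialects are tab-separated with a header row.  Score matrices are
persisted long-format (gene_a, gene_b, score) under a ``# method_tag=``
comment line so recipes survive a round trip.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    CatalyticClass,
    CompatibilityRule,
    PairKey,
    ProteinRecord,
    Role,
    StageTable,
)
from .coexpression import ExpressionMatrix, ScoreMatrix
from .localization import CompartmentModel, LocalizationRecord, LocClass
from .phylo import OrthologTable
from .ppi import EdgeList


# ---- catalog / annotations / rules ---------------------------------------

def write_catalog(path: str | Path, catalog: Sequence[ProteinRecord]) -> None:
    pd.DataFrame(
        [
            {
                "id": r.id,
                "role": r.role.value,
                "class": r.catalytic_class.value,
                "family": r.family,
                "active": int(r.active),
            }
            for r in catalog
        ]
    ).to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> list[ProteinRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ProteinRecord(
            id=row["id"],
            role=Role(row["role"]),
            catalytic_class=CatalyticClass(row["class"]),
            family=row["family"],
            active=bool(int(row["active"])),
        )
        for _, row in df.iterrows()
    ]


def write_annotations(
    path: str | Path, pairs: Sequence[PairKey], source: str = "annotated"
) -> None:
    pd.DataFrame(
        [
            {"inhibitor_id": p.inhibitor_id, "protease_id": p.protease_id, "source": source}
            for p in pairs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[PairKey]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [PairKey(r["inhibitor_id"], r["protease_id"]) for _, r in df.iterrows()]


def write_rules(path: str | Path, rules: Sequence[CompatibilityRule]) -> None:
    pd.DataFrame(
        [
            {
                "family": r.inhibitor_family,
                "classes": ",".join(
                    sorted(c.value for c in r.compatible_protease_classes)
                ),
            }
            for r in rules
        ]
    ).to_csv(path, sep="\t", index=False)


def read_rules(path: str | Path) -> list[CompatibilityRule]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        CompatibilityRule(
            r["family"],
            frozenset(CatalyticClass(c) for c in r["classes"].split(",")),
        )
        for _, r in df.iterrows()
    ]


# ---- expression -----------------------------------------------------------

def write_expression(
    prefix: str | Path, expr: ExpressionMatrix
) -> tuple[Path, Path]:
    prefix = Path(prefix)
    values_path = prefix.with_suffix(".values.tsv")
    meta_path = prefix.with_suffix(".samples.tsv")
    expr.values.to_csv(values_path, sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample": expr.samples, "tissue": [expr.tissue_of[s] for s in expr.samples]}
    ).to_csv(meta_path, sep="\t", index=False)
    return values_path, meta_path


def read_expression(values_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    tissue_of = pd.Series(meta["tissue"].to_numpy(), index=meta["sample"])
    return ExpressionMatrix(values, tissue_of)


# ---- score matrices -------------------------------------------------------

def write_score_matrix(path: str | Path, matrix: ScoreMatrix) -> None:
    genes = matrix.genes
    arr = matrix.scores.to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    df = pd.DataFrame(
        {
            "gene_a": np.asarray(genes)[iu[0]],
            "gene_b": np.asarray(genes)[iu[1]],
            "score": arr[iu],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# method_tag={matrix.method_tag}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_score_matrix(path: str | Path) -> ScoreMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        tag = first.removeprefix("# method_tag=") if first.startswith("#") else ""
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    genes = sorted(set(df["gene_a"]) | set(df["gene_b"]))
    mat = pd.DataFrame(np.nan, index=genes, columns=genes)
    for _, row in df.iterrows():
        mat.at[row["gene_a"], row["gene_b"]] = row["score"]
        mat.at[row["gene_b"], row["gene_a"]] = row["score"]
    np.fill_diagonal(mat.values, 1.0)
    return ScoreMatrix(mat, method_tag=tag)


# ---- orthologs ------------------------------------------------------------

def write_ortholog_table(path: str | Path, table: OrthologTable) -> None:
    rows = []
    inpara = table.inparalog_score
    bits = table.bit_score
    for g in table.genes:
        for s in table.species:
            sc = inpara.at[g, s]
            if sc > 0:  # absent pairs omitted
                rows.append(
                    {"gene": g, "species": s, "inparalog_score": sc, "bit_score": bits.at[g, s]}
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ortholog_table(
    path: str | Path,
    genes: Sequence[str] | None = None,
    species: Sequence[str] | None = None,
) -> OrthologTable:
    df = pd.read_csv(path, sep="\t")
    genes = list(genes) if genes is not None else sorted(df["gene"].unique())
    species = list(species) if species is not None else sorted(df["species"].unique())
    inpara = pd.DataFrame(0.0, index=genes, columns=species)
    bits = pd.DataFrame(0.0, index=genes, columns=species)
    for _, r in df.iterrows():
        inpara.at[r["gene"], r["species"]] = r["inparalog_score"]
        bits.at[r["gene"], r["species"]] = r["bit_score"]
    return OrthologTable(inpara, bits)


# ---- localization ---------------------------------------------------------

def write_localization(path: str | Path, records: Sequence[LocalizationRecord]) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "term": r.term,
                "source": r.source,
                "evidence": r.evidence,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_localization(path: str | Path) -> list[LocalizationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        LocalizationRecord(r["protein_id"], r["term"], r["source"], r["evidence"])
        for _, r in df.iterrows()
    ]


def write_compartment_model(path: str | Path, model: CompartmentModel) -> None:
    rows = []
    for term in sorted(model.vocabulary):
        if term in model.extracellular_terms:
            cat = "extracellular"
        elif term in model.cytosol_terms:
            cat = "cytosol"
        elif term in model.organelle_terms:
            cat = "organelle"
        else:
            cat = "other"
        parents = model.ancestry.get(term, set())
        rows.append(
            {"term": term, "category": cat, "parent": ";".join(sorted(parents))}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_compartment_model(path: str | Path, root: str | None = None) -> CompartmentModel:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    vocab, extr, cyto, org = set(), set(), set(), set()
    ancestry: dict[str, set[str]] = {}
    for _, r in df.iterrows():
        term = r["term"]
        vocab.add(term)
        if r["category"] == "extracellular":
            extr.add(term)
        elif r["category"] == "cytosol":
            cyto.add(term)
        elif r["category"] == "organelle":
            org.add(term)
        if r["parent"]:
            ancestry[term] = set(r["parent"].split(";"))
    if root is None:
        roots = vocab - set(ancestry)
        root = sorted(roots)[0] if len(roots) == 1 else None
    return CompartmentModel(vocab, extr, cyto, org, ancestry, root)


def write_pair_labels(path: str | Path, labels: Mapping[PairKey, LocClass]) -> None:
    pd.DataFrame(
        [
            {"inhibitor_id": p.inhibitor_id, "protease_id": p.protease_id, "label": l.value}
            for p, l in sorted(labels.items())
        ]
    ).to_csv(path, sep="\t", index=False)


# ---- PPI edges ------------------------------------------------------------

def write_edges(path: str | Path, edges: EdgeList) -> None:
    pd.DataFrame(
        [
            {
                "protein_a": a,
                "protein_b": b,
                "score": edges.scores.get((a, b), ""),
                "source": edges.source_tag,
            }
            for a, b in sorted(edges.edges)
        ]
    ).to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> EdgeList:
    df = pd.read_csv(path, sep="\t")
    pairs = list(zip(df["protein_a"].astype(str), df["protein_b"].astype(str)))
    scores = {}
    if "score" in df.columns:
        for (a, b), s in zip(pairs, df["score"]):
            if pd.notna(s) and s != "":
                scores[(a, b)] = float(s)
    tag = str(df["source"].iloc[0]) if "source" in df.columns and len(df) else ""
    return EdgeList.from_pairs(pairs, source_tag=tag, scores=scores)


# ---- stage tables / predictions -------------------------------------------

def write_stage_table(path: str | Path, table: StageTable) -> None:
    pd.DataFrame(table.to_records()).to_csv(path, sep="\t", index=False)


def write_predictions(path: str | Path, traces: Iterable) -> None:
    pd.DataFrame(
        [
            {
                "inhibitor_id": t.pair.inhibitor_id,
                "protease_id": t.pair.protease_id,
                "coexpression_score": t.coexpression_score,
                "loc_class": t.loc_class.value,
                "family_evidence": t.family_evidence,
            }
            for t in traces
        ]
    ).to_csv(path, sep="\t", index=False)
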