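"""Phylogenetic-profile similarity matrices.

A gene's phylogenetic profile is its pattern of ortholog presence/absence
across a panel of species; genes with similar profiles tend to be
functionally linked.  Profiles come as an ortholog score table (score 0
means absent) plus a cluster bit score.  Four similarity recipes are
supported on all gene pairs:

``agreement``
    fraction of species where both genes are present or both absent.
``pearson``
    Pearson correlation of the binarised 0/1 profiles.
``mutual_information``
    plug-in mutual information of the 2x2 presence/absence joint, in bits.
``bits``
    Pearson correlation of (ortholog score x bit score) vectors, retaining
    ortholog confidence and cluster similarity instead of binarising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coexpression import ScoreMatrix, _corrcoef_with_nan, _symmetric_from_array

METHODS = ("agreement", "pearson", "mutual_information", "bits")


@dataclass
class OrthologTable:
    """Gene x species ortholog scores plus cluster bit scores.

    ``inparalog_score`` is in [0, 1] with 0 meaning the ortholog is absent in
    that species; ``bit_score`` must be 0 exactly where the ortholog is absent.
    """

    inparalog_score: pd.DataFrame
    bit_score: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.inparalog_score.index.equals(self.bit_score.index):
            raise ValueError("score tables must share gene order")
        if not self.inparalog_score.columns.equals(self.bit_score.columns):
            raise ValueError("score tables must share species order")
        sc = self.inparalog_score.to_numpy()
        if ((sc < 0) | (sc > 1)).any():
            raise ValueError("inparalog scores must lie in [0, 1]")
        bits = self.bit_score.to_numpy()
        if (bits < 0).any():
            raise ValueError("bit scores must be nonnegative")
        if (bits[sc == 0] != 0).any():
            raise ValueError("bit score must be 0 where the ortholog is absent")

    @property
    def genes(self) -> list[str]:
        return list(self.inparalog_score.index)

    @property
    def species(self) -> list[str]:
        return list(self.inparalog_score.columns)


def _mi_bits_from_binary(x: np.ndarray, y: np.ndarray, base: float) -> float:
    """Plug-in MI of two binary vectors from their empirical 2x2 joint."""
    n = x.size
    mi = 0.0
    for a in (0, 1):
        px = np.mean(x == a)
        for b in (0, 1):
            pxy = np.mean((x == a) & (y == b))
            py = np.mean(y == b)
            if pxy > 0:  # 0 * log 0 = 0
                mi += pxy * (np.log(pxy) - np.log(px) - np.log(py))
    return max(mi / np.log(base), 0.0)


def phylo_similarity_matrix(
    table: OrthologTable,
    method: str = "agreement",
    exclude_species: Sequence[str] = (),
    mi_base: float = 2.0,
) -> ScoreMatrix:
    """All-pairs profile similarity under one of the four recipes.

    ``exclude_species`` drops columns before scoring (e.g. the reference
    species, trivially present for every gene).  Genes absent from every
    retained species are dropped with a warning.  Constant binary profiles
    produce missing correlation scores.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    keep = [s for s in table.species if s not in set(exclude_species)]
    if len(keep) < 2:
        raise ValueError("need >=2 species after exclusions")
    scores = table.inparalog_score[keep].to_numpy(dtype=float)
    bits = table.bit_score[keep].to_numpy(dtype=float)
    genes = np.asarray(table.genes)

    present = scores > 0
    everywhere_absent = ~present.any(axis=1)
    if everywhere_absent.any():
        warnings.warn(
            f"{int(everywhere_absent.sum())} gene(s) absent from every species dropped",
            stacklevel=2,
        )
        genes = genes[~everywhere_absent]
        present = present[~everywhere_absent]
        scores = scores[~everywhere_absent]
        bits = bits[~everywhere_absent]
    if genes.size < 2:
        raise ValueError("fewer than 2 genes with any ortholog")

    tag = f"Phylo_{method}"
    if method == "agreement":
        b = present.astype(float)
        n_sp = b.shape[1]
        # both present + both absent, counted via inner products
        both_present = b @ b.T
        both_absent = (1 - b) @ (1 - b).T
        out = (both_present + both_absent) / n_sp
        return _symmetric_from_array(out, genes, tag, {"n_species": n_sp})
    if method == "pearson":
        out = _corrcoef_with_nan(present.astype(float))
        return _symmetric_from_array(out, genes, tag, {"n_species": present.shape[1]})
    if method == "bits":
        out = _corrcoef_with_nan(scores * bits)
        return _symmetric_from_array(out, genes, tag, {"n_species": present.shape[1]})
    # mutual information
    b = present.astype(int)
    p = b.shape[0]
    out = np.zeros((p, p))
    for i in range(p):
        out[i, i] = _mi_bits_from_binary(b[i], b[i], mi_base)
        for j in range(i + 1, p):
            out[i, j] = out[j, i] = _mi_bits_from_binary(b[i], b[j], mi_base)
    return _symmetric_from_array(
        out, genes, tag, {"n_species": b.shape[1], "base": mi_base}
    )
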