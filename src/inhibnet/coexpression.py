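"""Coexpression matrices and matrix-comparison operations.

Expression across tissues separates two archetypes: housekeeping genes with
a broad pattern across tissues and tissue-specific genes expressed in one or
two tissues.  Pearson correlation on (log) expression is dominated by the
tissue-specific archetype — a shared spike in one tissue yields a high
coefficient — while Spearman demands concordance across the whole tissue
range.  The matrix suite therefore spans: plain Pearson/Spearman across all
samples, their element-wise maximum, full-order partial correlation,
per-tissue matrices and their average, and two meta-analytic recipes over
multiple datasets (merged and averaged).

All pairwise-score products are :class:`ScoreMatrix` objects: symmetric,
NaN-for-missing, tagged with the recipe that produced them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample expression values (RPKM-like) with a sample->tissue map."""

    values: pd.DataFrame
    tissue_of: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.tissue_of.index]
        if missing:
            raise ValueError(f"samples without tissue assignment: {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.tissue_of[s], None)
        return list(seen)

    def subset_tissue(self, tissue: str) -> "ExpressionMatrix":
        cols = [s for s in self.values.columns if self.tissue_of[s] == tissue]
        return ExpressionMatrix(self.values[cols], self.tissue_of[cols])


@dataclass
class ScoreMatrix:
    """Symmetric gene x gene score table (correlations or similarities).

    ``scores`` has NaN wherever a pair is unscored; the diagonal is never
    consulted by ranking or comparison operations.
    """

    scores: pd.DataFrame
    method_tag: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.scores.index.equals(self.scores.columns):
            raise ValueError("score matrix must have identical row/column gene order")

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    def get(self, a: str, b: str) -> float:
        return float(self.scores.at[a, b])

    def pair_values(self, pairs: Iterable[tuple[str, str]] | None = None) -> pd.Series:
        """Scores for a pair universe (default: all unordered off-diagonal pairs).

        Pairs whose members are absent from the matrix come back as NaN.
        """
        if pairs is None:
            genes = self.genes
            iu = np.triu_indices(len(genes), k=1)
            vals = self.scores.to_numpy()[iu]
            index = pd.MultiIndex.from_arrays(
                [np.asarray(genes)[iu[0]], np.asarray(genes)[iu[1]]]
            )
            return pd.Series(vals, index=index)
        gset = set(self.genes)
        keys, vals = [], []
        for a, b in pairs:
            keys.append((a, b))
            if a in gset and b in gset and a != b:
                vals.append(self.scores.at[a, b])
            else:
                vals.append(np.nan)
        return pd.Series(
            np.asarray(vals, dtype=float), index=pd.MultiIndex.from_tuples(keys)
        )


def _symmetric_from_array(
    arr: np.ndarray, genes: Sequence[str], tag: str, provenance: dict | None = None
) -> ScoreMatrix:
    df = pd.DataFrame(arr, index=list(genes), columns=list(genes))
    return ScoreMatrix(df, method_tag=tag, provenance=provenance or {})


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------

def preprocess_expression(
    expr: ExpressionMatrix, mode: str, floor: float = 0.01
) -> ExpressionMatrix:
    """Transform expression values.

    ``log10_floor``
        v -> log10(max(v, floor)); zeros at the default floor map to -2.
    ``tissue_mean``
        collapse samples to one column per tissue (arithmetic mean).
    ``zscore_by_gene``
        per-gene (v - mean) / sd; zero-variance genes become all-zero rows
        with a warning.
    """
    if mode == "log10_floor":
        if floor <= 0:
            raise ValueError("floor must be positive for log transformation")
        vals = np.log10(np.maximum(expr.values.to_numpy(dtype=float), floor))
        return ExpressionMatrix(
            pd.DataFrame(vals, index=expr.values.index, columns=expr.values.columns),
            expr.tissue_of,
        )
    if mode == "tissue_mean":
        tissues = expr.tissues
        cols = {
            t: expr.values[[s for s in expr.samples if expr.tissue_of[s] == t]].mean(
                axis=1
            )
            for t in tissues
        }
        df = pd.DataFrame(cols)[tissues]
        return ExpressionMatrix(df, pd.Series({t: t for t in tissues}))
    if mode == "zscore_by_gene":
        if len(expr.samples) < 2:
            raise ValueError("zscore requires >=2 samples")
        vals = expr.values.to_numpy(dtype=float)
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=1, keepdims=True)
        flat = (sd == 0).ravel()
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} zero-variance gene(s) set to all-zero in zscore",
                stacklevel=2,
            )
        out = np.zeros_like(vals)
        np.divide(vals - mu, sd, out=out, where=sd != 0)
        return ExpressionMatrix(
            pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns),
            expr.tissue_of,
        )
    raise ValueError(f"unknown preprocessing mode {mode!r}")


# --------------------------------------------------------------------------
# Correlation matrices
# --------------------------------------------------------------------------

def _rank_rows(vals: np.ndarray) -> np.ndarray:
    # average ranks per gene across samples (ties share their mean rank)
    return np.apply_along_axis(stats.rankdata, 1, vals)


def _corrcoef_with_nan(vals: np.ndarray) -> np.ndarray:
    sd = vals.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(vals)
    r = np.clip(r, -1.0, 1.0)
    flat = sd == 0
    r[flat, :] = np.nan
    r[:, flat] = np.nan
    return r

def correlation_matrix(
    expr: ExpressionMatrix, method: str = "pearson", tag: str | None = None
) -> ScoreMatrix:
    """All-pairs Pearson or Spearman correlation across samples.

    Spearman is Pearson applied to average-ranked values.  Genes with zero
    variance get missing scores against every partner.
    """
    if len(expr.samples) < 3:
        raise ValueError("correlation requires >=3 samples")
    vals = expr.values.to_numpy(dtype=float)
    if method == "spearman":
        vals = _rank_rows(vals)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    r = _corrcoef_with_nan(vals)
    return _symmetric_from_array(
        r,
        expr.genes,
        tag or f"All_{'Pcc' if method == 'pearson' else 'Scc'}",
        {"method": method, "n_samples": len(expr.samples)},
    )


def elementwise_max(ma: ScoreMatrix, mb: ScoreMatrix, absolute: bool = False) -> ScoreMatrix:
    """Per-pair signed maximum of two matrices (NaN treated as absent).

    With ``absolute=True`` the score larger in magnitude wins instead.
    """
    if list(ma.genes) != list(mb.genes):
        raise ValueError("gene sets must match for elementwise max")
    a = ma.scores.to_numpy()
    b = mb.scores.to_numpy()
    if absolute:
        pick_b = np.isnan(a) | (np.abs(b) > np.abs(a))
        out = np.where(pick_b & ~np.isnan(b), b, a)
    else:
        out = np.fmax(a, b)  # fmax takes the present side when one is NaN
    return _symmetric_from_array(
        out, ma.genes, f"Max({ma.method_tag},{mb.method_tag})",
        {"components": [ma.method_tag, mb.method_tag], "absolute": absolute},
    )


def _shrinkage_lambda(x: np.ndarray) -> float:
    """Analytic shrinkage intensity for the correlation matrix toward identity.

    Ratio of the summed estimated variances of the off-diagonal sample
    correlations to their summed squares (Schafer-Strimmer style), clipped to
    [0, 1].
    """
    p, n = x.shape
    xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    r = (xs @ xs.T) / (n - 1)
    # w_k,ij = xs_ik * xs_jk ; var(r_ij) = n/(n-1)^3 * sum_k (w_k,ij - wbar_ij)^2
    w_bar = r * (n - 1) / n
    num = 0.0
    den = 0.0
    for k in range(n):
        wk = np.outer(xs[:, k], xs[:, k])
        num_k = (wk - w_bar) ** 2
        iu = np.triu_indices(p, k=1)
        num += num_k[iu].sum()
    iu = np.triu_indices(p, k=1)
    den = (r[iu] ** 2).sum()
    if den == 0:
        return 1.0
    lam = (n / (n - 1) ** 3) * num / den
    return float(np.clip(lam, 0.0, 1.0))


def partial_correlation_matrix(
    expr: ExpressionMatrix,
    method: str = "pearson",
    shrinkage: float | str | None = "auto",
) -> ScoreMatrix:
    """Full-order partial correlation between all gene pairs.

    The pairwise correlation matrix R (Pearson, or on ranks for Spearman) is
    shrunk toward the identity, R* = (1-lam) R + lam I, inverted, and the
    precision entries are rescaled: pcor_ij = -P_ij / sqrt(P_ii P_jj).

    ``shrinkage`` is a fixed intensity in [0, 1], ``"auto"`` for the analytic
    estimate, or ``None`` for no shrinkage (raises if R is singular).  With
    only two genes the conditioning set is empty and the plain correlation is
    returned unchanged.
    """
    if len(expr.samples) < 3:
        raise ValueError("partial correlation requires >=3 samples")
    vals = expr.values.to_numpy(dtype=float)
    if method == "spearman":
        vals = _rank_rows(vals)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(expr.genes, sd) if s == 0]
        raise ValueError(f"zero-variance gene(s) for partial correlation: {bad[:5]}")
    p = vals.shape[0]
    r = np.clip(np.corrcoef(vals), -1.0, 1.0)
    if p == 2:
        return _symmetric_from_array(
            r, expr.genes, f"Partial_{method}", {"shrinkage": 0.0}
        )
    if shrinkage == "auto":
        lam = _shrinkage_lambda(vals)
    elif shrinkage is None:
        lam = 0.0
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must be in [0, 1]")
    r_shrunk = (1.0 - lam) * r + lam * np.eye(p)
    try:
        prec = np.linalg.inv(r_shrunk)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; rerun with shrinkage='auto' or a "
            "positive shrinkage intensity"
        ) from exc
    d = np.sqrt(np.diag(prec))
    pcor = -prec / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = np.clip((pcor + pcor.T) / 2.0, -1.0, 1.0)
    return _symmetric_from_array(
        pcor, expr.genes, f"Partial_{method}", {"shrinkage": lam}
    )


# --------------------------------------------------------------------------
# Tissue-specific and meta-analytic matrices
# --------------------------------------------------------------------------

def build_tissue_matrices(
    expr: ExpressionMatrix, method: str = "pearson", min_samples: int = 3
) -> list[ScoreMatrix]:
    """One correlation matrix per tissue with enough samples.

    Tissues below ``min_samples`` are skipped with a warning.
    """
    out: list[ScoreMatrix] = []
    for tissue in expr.tissues:
        sub = expr.subset_tissue(tissue)
        if len(sub.samples) < min_samples:
            warnings.warn(
                f"tissue {tissue!r} has {len(sub.samples)} samples (<{min_samples}); skipped",
                stacklevel=2,
            )
            continue
        m = correlation_matrix(sub, method, tag=f"Tissue_{tissue}_{method}")
        out.append(m)
    if not out:
        raise ValueError("no tissue has enough samples for a matrix")
    return out


def average_matrices(matrices: Sequence[ScoreMatrix], tag: str | None = None) -> ScoreMatrix:
    """Per-pair unweighted mean over matrices where the pair is scored."""
    if not matrices:
        raise ValueError("no matrices to average")
    genes = matrices[0].genes
    for m in matrices[1:]:
        if list(m.genes) != list(genes):
            raise ValueError("matrices must share an identical gene roster")
    stack = np.stack([m.scores.to_numpy() for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs stay NaN
        mean = np.nanmean(stack, axis=0)
    return _symmetric_from_array(
        mean, genes, tag or "Averaged", {"n_matrices": len(matrices)}
    )


def meta_coexpression(
    datasets: Sequence[ExpressionMatrix], mode: str = "merged", method: str = "pearson"
) -> ScoreMatrix:
    """Meta-analytic coexpression over several expression datasets.

    ``merged``: each dataset is z-scored per gene, columns are concatenated on
    the shared gene set, and one correlation matrix is computed.  ``averaged``:
    a correlation matrix per dataset, then the per-pair unweighted mean.
    """
    if len(datasets) < 2:
        raise ValueError("meta-analysis requires >=2 datasets")
    common = set(datasets[0].genes)
    for d in datasets[1:]:
        common &= set(d.genes)
    if len(common) < 2:
        raise ValueError("gene intersection across datasets is too small")
    genes = [g for g in datasets[0].genes if g in common]
    subs = [
        ExpressionMatrix(d.values.loc[genes], d.tissue_of) for d in datasets
    ]
    if mode == "merged":
        zparts = []
        for i, d in enumerate(subs):
            z = preprocess_expression(d, "zscore_by_gene")
            part = z.values.copy()
            part.columns = [f"ds{i}:{c}" for c in part.columns]
            zparts.append(part)
        merged_vals = pd.concat(zparts, axis=1)
        tissue = pd.Series(
            {
                f"ds{i}:{s}": d.tissue_of[s]
                for i, d in enumerate(subs)
                for s in d.samples
            }
        )
        merged = ExpressionMatrix(merged_vals, tissue)
        m = correlation_matrix(merged, method, tag="Merged")
        m.provenance["n_datasets"] = len(datasets)
        return m
    if mode == "averaged":
        mats = [correlation_matrix(d, method) for d in subs]
        out = average_matrices(mats, tag="Averaged")
        out.provenance["n_datasets"] = len(datasets)
        return out
    raise ValueError(f"unknown meta mode {mode!r}")


# --------------------------------------------------------------------------
# Matrix comparison
# --------------------------------------------------------------------------

def matrix_agreement(ma: ScoreMatrix, mb: ScoreMatrix) -> float:
    """Pearson correlation between two matrices' common pair scores.

    Computed over all off-diagonal pairs scored in both; returns NaN with a
    warning if fewer than 3 such pairs exist or either vector is constant.
    """
    common = [g for g in ma.genes if g in set(mb.genes)]
    if len(common) < 2:
        raise ValueError("matrices share fewer than 2 genes")
    a = ma.scores.loc[common, common].to_numpy()
    b = mb.scores.loc[common, common].to_numpy()
    iu = np.triu_indices(len(common), k=1)
    va, vb = a[iu], b[iu]
    ok = ~(np.isnan(va) | np.isnan(vb))
    va, vb = va[ok], vb[ok]
    if va.size < 3:
        raise ValueError("fewer than 3 common scored pairs")
    if va.std() == 0 or vb.std() == 0:
        warnings.warn("constant score vector; agreement undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


@dataclass
class ThresholdOverlap:
    threshold_a: float
    threshold_b: float
    n_above_a: int
    n_above_b: int
    overlap: int


def threshold_overlap(
    ma: ScoreMatrix,
    mb: ScoreMatrix,
    k: float = 2.0,
    pairs: Iterable[tuple[str, str]] | None = None,
) -> ThresholdOverlap:
    """Overlap of pairs above mean + k*sd in both matrices.

    Each matrix gets its own threshold from its own non-missing pair scores;
    the overlap counts pairs above both thresholds.
    """
    if pairs is not None:
        pairs = list(pairs)
    va = ma.pair_values(pairs)
    vb = mb.pair_values(pairs)
    va, vb = va.align(vb)
    ta = float(va.mean() + k * va.std(ddof=1))
    tb = float(vb.mean() + k * vb.std(ddof=1))
    above_a = va >= ta
    above_b = vb >= tb
    return ThresholdOverlap(
        threshold_a=ta,
        threshold_b=tb,
        n_above_a=int(above_a.sum()),
        n_above_b=int(above_b.sum()),
        overlap=int((above_a & above_b).sum()),
    )
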