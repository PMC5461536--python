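"""Scoring matrices against the gold standard.

The evaluator treats any ScoreMatrix as a ranking of candidate pairs and
asks how well it separates annotated inhibitions (TP) from enzymatically
implausible pairs (TN).  Because TNs vastly outnumber TPs, ROC AUC and
top-fraction accuracy are computed over repeated class-balanced subsamples:
TNs are drawn without replacement down to the number of scoreable TPs, many
times, and the distribution of the statistic is reported.  The restriction
to scoreable pairs (both genes present and the pair non-missing in the
matrix) is surfaced as ``n_tp_used`` — the effective TP count can shrink
relative to the full annotation set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import GoldStandard, PairKey
from .coexpression import ScoreMatrix


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Probability that a random positive outranks a random negative.

    Mann-Whitney formulation: ties contribute 1/2.  Raises if either class
    is empty.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs at least one positive and one negative")
    ranks = stats.rankdata(s)  # average ranks handle ties with 1/2 credit
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _scoreable(
    matrix: ScoreMatrix, pairs: set[PairKey]
) -> tuple[list[PairKey], np.ndarray]:
    vals = matrix.pair_values(sorted(pairs))
    ok = vals.notna()
    kept = [PairKey(*idx) for idx in vals.index[ok]]
    return kept, vals[ok].to_numpy()


@dataclass
class AucDistribution:
    matrix_tag: str
    auc_values: list[float]
    n_tp_used: int
    n_subsamples: int
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.auc_values))

    def quartiles(self) -> tuple[float, float, float]:
        q1, q2, q3 = np.percentile(self.auc_values, [25, 50, 75])
        return float(q1), float(q2), float(q3)


def subsampled_auc(
    matrix: ScoreMatrix,
    gold: GoldStandard,
    n_subsamples: int = 200,
    seed: int = 0,
) -> AucDistribution:
    """AUC distribution over class-balanced TN subsamples.

    Restricts to scoreable pairs, then per repeat draws as many TNs as there
    are scoreable TPs (without replacement) and computes the Mann-Whitney
    AUC.  One RNG seeded once drives all repeats sequentially.
    """
    tp_pairs, tp_scores = _scoreable(matrix, gold.tp)
    tn_pairs, tn_scores = _scoreable(matrix, gold.tn)
    n_tp = len(tp_pairs)
    if n_tp < 2:
        raise ValueError("need >=2 scoreable TP pairs")
    if len(tn_pairs) < n_tp:
        raise ValueError(
            f"need >= {n_tp} scoreable TN pairs, have {len(tn_pairs)}"
        )
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.ones(n_tp, bool), np.zeros(n_tp, bool)])
    aucs = []
    for _ in range(n_subsamples):
        pick = rng.choice(len(tn_scores), size=n_tp, replace=False)
        aucs.append(roc_auc(np.concatenate([tp_scores, tn_scores[pick]]), labels))
    return AucDistribution(
        matrix_tag=matrix.method_tag,
        auc_values=aucs,
        n_tp_used=n_tp,
        n_subsamples=n_subsamples,
        seed=seed,
    )


def top_fraction_threshold(
    matrix: ScoreMatrix,
    candidates: set[PairKey] | None = None,
    fraction: float = 0.10,
) -> float:
    """Score cutting off the top ``fraction`` of the scoreable candidate universe."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    vals = matrix.pair_values(sorted(candidates) if candidates is not None else None)
    vals = vals.dropna().to_numpy()
    if vals.size == 0:
        raise ValueError("no scoreable candidate pairs")
    return float(np.quantile(vals, 1.0 - fraction))


def top_fraction_accuracy(
    matrix: ScoreMatrix,
    gold: GoldStandard,
    fraction: float = 0.10,
    n_subsamples: int = 200,
    seed: int = 0,
    candidates: set[PairKey] | None = None,
) -> AucDistribution:
    """Balanced classification accuracy using a matrix-wide top-fraction cut.

    The threshold is the (1 - fraction) quantile of the whole scoreable
    candidate universe (all inhibitor x protease pairs by default), fixed
    across subsamples.  Per balanced subsample, pairs at/above the threshold
    are called positive and accuracy is (TP called + TN rejected) / (2 n_tp).
    """
    if candidates is None:
        candidates = gold.all_pairs
    thresh = top_fraction_threshold(matrix, candidates, fraction)
    tp_pairs, tp_scores = _scoreable(matrix, gold.tp)
    tn_pairs, tn_scores = _scoreable(matrix, gold.tn)
    n_tp = len(tp_pairs)
    if n_tp < 2:
        raise ValueError("need >=2 scoreable TP pairs")
    if len(tn_pairs) < n_tp:
        raise ValueError(f"need >= {n_tp} scoreable TN pairs, have {len(tn_pairs)}")
    rng = np.random.default_rng(seed)
    tp_hit = int((tp_scores >= thresh).sum())
    accs = []
    for _ in range(n_subsamples):
        pick = rng.choice(len(tn_scores), size=n_tp, replace=False)
        tn_rej = int((tn_scores[pick] < thresh).sum())
        accs.append((tp_hit + tn_rej) / (2.0 * n_tp))
    return AucDistribution(
        matrix_tag=matrix.method_tag,
        auc_values=accs,
        n_tp_used=n_tp,
        n_subsamples=n_subsamples,
        seed=seed,
    )


def recovery_membership(
    matrices: Sequence[ScoreMatrix],
    pairs: Sequence[PairKey],
    fraction: float = 0.10,
    candidates: set[PairKey] | None = None,
) -> pd.DataFrame:
    """Boolean pair x matrix table: is the pair in each matrix's top fraction?

    A pair missing from a matrix (gene absent or score missing) is never
    recovered there.  ``candidates`` fixes the ranking universe; default is
    each matrix's full off-diagonal pair set.
    """
    cand = sorted(candidates) if candidates is not None else None
    cols = {}
    for m in matrices:
        thresh = top_fraction_threshold(m, set(cand) if cand else None, fraction)
        vals = m.pair_values(list(pairs))
        cols[m.method_tag] = (vals >= thresh).fillna(False).to_numpy()
    return pd.DataFrame(
        cols, index=pd.MultiIndex.from_tuples([tuple(p) for p in pairs])
    )


@dataclass
class ClassifierSpec:
    """Pluggable classifier contract: a factory returning a fit/score object.

    The factory must produce an estimator with sklearn's ``fit(X, y)`` and
    either ``predict_proba`` or ``decision_function``.
    """

    name: str
    factory: Callable[[int], object]


def default_classifier_specs() -> dict[str, ClassifierSpec]:
    """Shipped presets: random forest (max_features 2) and RBF SVM (C 0.1, gamma 0.2)."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.svm import SVC

    return {
        "random_forest": ClassifierSpec(
            "random_forest",
            lambda seed: RandomForestClassifier(
                n_estimators=200, max_features=2, random_state=seed
            ),
        ),
        "svm_radial": ClassifierSpec(
            "svm_radial",
            lambda seed: SVC(kernel="rbf", C=0.1, gamma=0.2, random_state=seed),
        ),
    }


def combine_matrices_classifier(
    matrices: Sequence[ScoreMatrix],
    gold: GoldStandard,
    train_fraction: float = 0.6,
    classifier_spec: str | ClassifierSpec = "random_forest",
    seed: int = 0,
) -> float:
    """Test-set AUC of a classifier on per-matrix score features.

    Each gold pair becomes a feature vector of its scores in every matrix
    (missing scores median-imputed per feature); a stratified
    ``train_fraction`` / rest split is drawn, the classifier fit on the
    training part, and the Mann-Whitney AUC of its test-set scores returned.
    """
    if len(matrices) < 2:
        raise ValueError("need >=2 matrices to combine")
    if isinstance(classifier_spec, str):
        specs = default_classifier_specs()
        if classifier_spec not in specs:
            raise ValueError(
                f"unknown classifier {classifier_spec!r}; choose from {sorted(specs)}"
            )
        spec = specs[classifier_spec]
    else:
        spec = classifier_spec
    pairs = sorted(gold.tp) + sorted(gold.tn)
    y = np.concatenate([np.ones(len(gold.tp), bool), np.zeros(len(gold.tn), bool)])
    X = np.column_stack(
        [m.pair_values(pairs).to_numpy() for m in matrices]
    )
    # median imputation per feature for missing scores
    for j in range(X.shape[1]):
        col = X[:, j]
        med = np.nanmedian(col)
        col[np.isnan(col)] = 0.0 if np.isnan(med) else med
    if y.all() or not y.any():
        raise ValueError("gold standard must contain both classes")

    from sklearn.model_selection import train_test_split

    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=y, random_state=seed
    )
    clf = spec.factory(seed)
    clf.fit(X[train_idx], y[train_idx])
    if hasattr(clf, "predict_proba"):
        s = clf.predict_proba(X[test_idx])[:, 1]
    else:
        s = clf.decision_function(X[test_idx])
    return roc_auc(s, y[test_idx])
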