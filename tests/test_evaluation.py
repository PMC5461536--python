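"""ROC evaluation with balanced subsampling, accuracy, recovery, combination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inhibnet.catalog import GoldStandard, PairKey, build_gold_standard
from inhibnet.coexpression import (
    ScoreMatrix,
    correlation_matrix,
    elementwise_max,
    preprocess_expression,
)
from inhibnet.evaluation import (
    combine_matrices_classifier,
    recovery_membership,
    roc_auc,
    subsampled_auc,
    top_fraction_accuracy,
    top_fraction_threshold,
)
from inhibnet.synth import SynthConfig, generate_world


def brute_force_auc(scores, labels):
    """Independent oracle: count positive/negative comparisons, ties at 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False]) == 1.0

    def test_partial_overlap_counts_three_of_four(self):
        assert roc_auc([0.8, 0.3, 0.5, 0.1], [True, True, False, False]) == 0.75

    def test_all_tied_gives_half(self):
        assert roc_auc([1.0] * 6, [True] * 3 + [False] * 3) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(4, 25))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(23)
        scores = rng.standard_normal(100)
        labels = rng.random(100) < 0.4
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_brute_force_property(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, size=12).astype(float)
        labels = np.array([True] * 5 + [False] * 7)
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


def matrix_from_pair_scores(pair_scores: dict[PairKey, float]) -> ScoreMatrix:
    genes = sorted({g for p in pair_scores for g in p})
    df = pd.DataFrame(np.nan, index=genes, columns=genes)
    for (a, b), s in pair_scores.items():
        df.at[a, b] = df.at[b, a] = s
    return ScoreMatrix(df, method_tag="manual")


def two_class_gold(n_tp: int, n_tn: int) -> GoldStandard:
    tp = {PairKey(f"i{k}", f"pT{k}") for k in range(n_tp)}
    tn = {PairKey(f"i{k % n_tp}", f"pN{k}") for k in range(n_tn)}
    return GoldStandard(tp=tp, tn=tn, unknown=set(), search_space_size=n_tp + n_tn)


class TestSubsampledAuc:
    def test_perfect_matrix_gives_all_ones(self):
        gold = two_class_gold(4, 12)
        scores = {p: 0.9 for p in gold.tp} | {p: 0.1 for p in gold.tn}
        dist = subsampled_auc(matrix_from_pair_scores(scores), gold, 50, seed=0)
        assert dist.auc_values == [1.0] * 50
        assert dist.n_tp_used == 4

    def test_balanced_input_single_subsample_equals_full_auc(self):
        gold = two_class_gold(5, 5)
        rng = np.random.default_rng(2)
        scores = {p: float(rng.random()) for p in gold.tp | gold.tn}
        m = matrix_from_pair_scores(scores)
        dist = subsampled_auc(m, gold, n_subsamples=1, seed=0)
        pairs = sorted(gold.tp) + sorted(gold.tn)
        full = roc_auc(
            [scores[p] for p in pairs],
            [p in gold.tp for p in pairs],
        )
        assert dist.auc_values[0] == pytest.approx(full, abs=1e-12)

    def test_label_independent_scores_near_half(self):
        # averaged over a seed batch the null mean AUC concentrates at 1/2
        means = []
        for seed in range(5):
            gold = two_class_gold(30, 300)
            rng = np.random.default_rng(100 + seed)
            scores = {p: float(rng.random()) for p in gold.tp | gold.tn}
            dist = subsampled_auc(matrix_from_pair_scores(scores), gold, 100, seed=seed)
            means.append(dist.mean)
        assert abs(np.mean(means) - 0.5) < 0.05

    def test_subsample_mean_tracks_full_auc(self, planted_world):
        gold = build_gold_standard(
            planted_world.catalog, planted_world.true_inhibitions, planted_world.rules
        )
        expr = preprocess_expression(planted_world.expression, "log10_floor")
        m = correlation_matrix(expr, "pearson")
        dist = subsampled_auc(m, gold, 200, seed=0)
        tp_scores = m.pair_values(sorted(gold.tp)).dropna()
        tn_scores = m.pair_values(sorted(gold.tn)).dropna()
        full = roc_auc(
            np.concatenate([tp_scores, tn_scores]),
            [True] * len(tp_scores) + [False] * len(tn_scores),
        )
        assert abs(dist.mean - full) < 0.02

    def test_insufficient_tn_rejected(self):
        gold = two_class_gold(5, 3)
        scores = {p: 0.5 for p in gold.tp | gold.tn}
        with pytest.raises(ValueError):
            subsampled_auc(matrix_from_pair_scores(scores), gold, 10, seed=0)

    def test_missing_scores_shrink_n_tp_used(self):
        gold = two_class_gold(4, 12)
        scores = {p: 0.9 for p in list(sorted(gold.tp))[:2]}
        scores |= {p: 0.1 for p in gold.tn}
        dist = subsampled_auc(matrix_from_pair_scores(scores), gold, 10, seed=0)
        assert dist.n_tp_used == 2


class TestTopFractionAccuracy:
    def test_constructed_instance(self):
        # universe scores 1..100 -> top-10% cut at >= 91 (approximately);
        # TP {95,92,50,40,30}, TN {99,20,10,5,2} -> accuracy (2+4)/10
        universe = {}
        genes_scores = list(range(1, 101))
        tp_scores = [95, 92, 50, 40, 30]
        tn_scores = [99, 20, 10, 5, 2]
        tp, tn, others = set(), set(), set()
        k = 0
        for s in genes_scores:
            pair = PairKey(f"i{k}", f"p{k}")
            k += 1
            if s in tp_scores:
                tp.add(pair)
            elif s in tn_scores:
                tn.add(pair)
            else:
                others.add(pair)
            universe[pair] = float(s)
        gold = GoldStandard(tp=tp, tn=tn, unknown=others, search_space_size=100)
        m = matrix_from_pair_scores(universe)
        dist = top_fraction_accuracy(m, gold, fraction=0.10, n_subsamples=5, seed=0)
        assert dist.auc_values == [0.6] * 5

    def test_label_independent_scores_near_half(self):
        means = []
        for seed in range(5):
            gold = two_class_gold(30, 300)
            rng = np.random.default_rng(200 + seed)
            scores = {p: float(rng.random()) for p in gold.tp | gold.tn}
            dist = top_fraction_accuracy(
                matrix_from_pair_scores(scores), gold, 0.10, 100, seed=seed
            )
            means.append(dist.mean)
        # balanced null: (hit rate 0.1 on TPs, rejection 0.9 on TNs) -> 0.5
        assert abs(np.mean(means) - 0.5) < 0.05

    def test_perfect_top_fraction(self):
        gold = two_class_gold(3, 27)
        scores = {p: 1.0 for p in gold.tp} | {
            p: float(i) / 100 for i, p in enumerate(sorted(gold.tn))
        }
        dist = top_fraction_accuracy(
            matrix_from_pair_scores(scores), gold, fraction=0.10, n_subsamples=5, seed=0
        )
        assert dist.auc_values == [1.0] * 5


class TestRecoveryMembership:
    def test_top_ranked_pair_everywhere(self, planted_world):
        expr = preprocess_expression(planted_world.expression, "log10_floor")
        pcc = correlation_matrix(expr, "pearson")
        scc = correlation_matrix(expr, "spearman")
        vals = pcc.pair_values().dropna()
        best = PairKey(*vals.idxmax())
        table = recovery_membership([pcc, scc], [best], fraction=0.10)
        assert table.loc[tuple(best)].all()

    def test_fraction_one_recovers_every_scoreable_pair(self, planted_world):
        expr = preprocess_expression(planted_world.expression, "log10_floor")
        pcc = correlation_matrix(expr, "pearson")
        pairs = sorted(
            build_gold_standard(
                planted_world.catalog,
                planted_world.true_inhibitions,
                planted_world.rules,
            ).tp
        )
        table = recovery_membership([pcc], pairs, fraction=1.0)
        assert table.to_numpy().all()

    def test_max_matrix_recovers_at_least_component_rate(self):
        # componentwise max dominance: a truth in a component's top set stays
        # recoverable in the combined matrix at no lower a rate (20 seeds)
        better, worse = 0, 0
        for seed in range(20):
            world = generate_world(SynthConfig(seed=seed, frac_coexpressed_truth=1.0))
            gold = build_gold_standard(
                world.catalog, world.true_inhibitions, world.rules
            )
            expr = preprocess_expression(world.expression, "log10_floor")
            pcc = correlation_matrix(expr, "pearson")
            scc = correlation_matrix(expr, "spearman")
            mx = elementwise_max(pcc, scc)
            universe = gold.all_pairs
            pairs = sorted(gold.tp)
            tab = recovery_membership([pcc, scc, mx], pairs, candidates=universe)
            n_pcc = tab[pcc.method_tag].sum()
            n_scc = tab[scc.method_tag].sum()
            n_max = tab[mx.method_tag].sum()
            if n_max >= max(n_pcc, n_scc):
                better += 1
            else:
                worse += 1
        assert better >= worse  # dominance holds in the clear majority


class TestCombineMatricesClassifier:
    def _gold_and_features(self, separating: bool, seed=0):
        gold = two_class_gold(40, 80)
        rng = np.random.default_rng(seed)
        pairs = sorted(gold.tp) + sorted(gold.tn)
        f1, f2 = {}, {}
        for p in pairs:
            if separating and p in gold.tp:
                f1[p] = rng.uniform(0.8, 1.0)
            elif separating:
                f1[p] = rng.uniform(0.0, 0.2)
            else:
                f1[p] = rng.uniform(0.0, 1.0)
            f2[p] = rng.uniform(0.0, 1.0)
        return gold, [matrix_from_pair_scores(f1), matrix_from_pair_scores(f2)]

    @pytest.mark.parametrize("spec", ["random_forest", "svm_radial"])
    def test_perfect_feature_yields_auc_one(self, spec):
        gold, mats = self._gold_and_features(separating=True)
        auc = combine_matrices_classifier(mats, gold, classifier_spec=spec, seed=0)
        assert auc == 1.0

    def test_noise_features_near_half(self):
        aucs = []
        for s in range(10):
            gold, mats = self._gold_and_features(separating=False, seed=s)
            aucs.append(combine_matrices_classifier(mats, gold, seed=s))
        assert abs(np.mean(aucs) - 0.5) < 0.12

    def test_unknown_classifier_rejected(self):
        gold, mats = self._gold_and_features(separating=True)
        with pytest.raises(ValueError):
            combine_matrices_classifier(mats, gold, classifier_spec="deep_net")

    def test_combined_not_catastrophically_below_best_single(self, planted_world):
        gold = build_gold_standard(
            planted_world.catalog, planted_world.true_inhibitions, planted_world.rules
        )
        expr = preprocess_expression(planted_world.expression, "log10_floor")
        pcc = correlation_matrix(expr, "pearson")
        scc = correlation_matrix(expr, "spearman")
        best_single = max(
            subsampled_auc(pcc, gold, 50, seed=0).mean,
            subsampled_auc(scc, gold, 50, seed=0).mean,
        )
        combined = combine_matrices_classifier([pcc, scc], gold, seed=0)
        assert combined >= best_single - 0.05


class TestGoldStandardDifficultyOrdering:
    def test_general_ppi_easier_than_inhibition(self):
        """A stronger-signal general-interaction standard must score higher."""
        strong = generate_world(
            SynthConfig(seed=31, frac_coexpressed_truth=1.0, planted_rho=0.95)
        )
        weak = generate_world(
            SynthConfig(seed=31, frac_coexpressed_truth=0.5, planted_rho=0.7)
        )
        aucs = {}
        for name, world in [("ppi", strong), ("inhibition", weak)]:
            gold = build_gold_standard(
                world.catalog, world.true_inhibitions, world.rules
            )
            expr = preprocess_expression(world.expression, "log10_floor")
            m = correlation_matrix(expr, "pearson")
            aucs[name] = subsampled_auc(m, gold, 100, seed=0).mean
        assert aucs["ppi"] > aucs["inhibition"]
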