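import json

import numpy as np
import pytest
from scipy.stats import rankdata

from odfsp.data_model import ExpressionMatrix
from odfsp.ktsp import (
    Barcode,
    KtspModel,
    OdfspEnsemble,
    PairRule,
    barcode_transform,
    load_ensemble,
    pair_score,
    predict_model,
    save_ensemble,
    score_ensemble,
    select_disjoint_pairs,
    stack_training_instances,
    train_ensemble,
    train_ktsp,
    wilcoxon_filter,
)
from odfsp.synthetic import simulate_study
from .test_synthetic import one_cohort_config


def make_expr(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return ExpressionMatrix(gene_ids or [f"g{i:02d}" for i in range(g)],
                            [f"s{j:02d}" for j in range(n)], values)


# --- independent oracles -------------------------------------------------

def oracle_pair_score(values, labels, i, j):
    """Per-sample counting oracle for the pair score."""
    hi = [s for s in range(values.shape[1]) if labels[s] == 1]
    lo = [s for s in range(values.shape[1]) if labels[s] == 0]
    p_hi = sum(values[i, s] < values[j, s] for s in hi) / len(hi)
    p_lo = sum(values[i, s] < values[j, s] for s in lo) / len(lo)
    ranks = np.array([rankdata(values[:, s]) for s in range(values.shape[1])]).T
    gamma = abs((ranks[i, hi].mean() - ranks[j, hi].mean())
                - (ranks[i, lo].mean() - ranks[j, lo].mean()))
    return abs(p_hi - p_lo), p_hi > p_lo, gamma


def oracle_top_pair(expr, labels):
    """Exhaustive enumeration of the best pair under the stated ordering."""
    best = None
    for i in range(expr.n_genes):
        for j in range(i + 1, expr.n_genes):
            delta, ori, gamma = oracle_pair_score(expr.values, labels, i, j)
            gi, gj = expr.gene_ids[i], expr.gene_ids[j]
            if gj < gi:
                gi, gj, ori = gj, gi, not ori
            key = (-delta, -gamma, gi, gj)
            if best is None or key < best[0]:
                best = (key, (gi, gj, delta, ori))
    return best[1]


# --- pair scoring --------------------------------------------------------

class TestPairScore:
    def test_perfect_pair(self):
        values = np.array([[1, 1, 1, 5, 5, 5],
                           [4, 4, 4, 2, 2, 2],
                           [0, 1, 2, 3, 4, 5]], dtype=float)
        labels = np.array([1, 1, 1, 0, 0, 0])
        delta, ori, gamma = pair_score(make_expr(values), labels, "g00", "g01")
        assert delta == 1.0 and ori is True and gamma > 0

    def test_uninformative_pair_scores_zero(self):
        values = np.array([[1, 3, 1, 3], [2, 2, 2, 2]], dtype=float)
        labels = np.array([1, 1, 0, 0])
        delta, _, _ = pair_score(make_expr(values), labels, "g00", "g01")
        assert delta == 0.0

    def test_matches_counting_oracle(self, rng):
        values = rng.normal(size=(6, 20))
        labels = (rng.uniform(size=20) < 0.5).astype(int)
        labels[:2] = [0, 1]  # both classes present
        expr = make_expr(values)
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                got = pair_score(expr, labels, f"g{i:02d}", f"g{j:02d}")
                exp = oracle_pair_score(values, labels, i, j)
                assert got[0] == pytest.approx(exp[0], abs=1e-12)
                assert got[1] == exp[1]
                assert got[2] == pytest.approx(exp[2], abs=1e-9)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            pair_score(make_expr(np.ones((2, 3))), np.array([1, 1, 1]), "g00", "g01")


class TestWilcoxonFilter:
    def test_matches_rank_sum_oracle(self, rng):
        from scipy.stats import mannwhitneyu
        values = rng.normal(size=(10, 30))
        labels = np.array([1] * 12 + [0] * 18)
        expr = make_expr(values)
        got = wilcoxon_filter(expr, labels, 4)
        stats = []
        for g in range(10):
            # oracle: standardized U via the normal approximation
            res = mannwhitneyu(values[g, labels == 1], values[g, labels == 0],
                               alternative="two-sided", method="asymptotic")
            n1, n2 = 12, 18
            z = abs((res.statistic - n1 * n2 / 2)
                    / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12))
            stats.append((-z, expr.gene_ids[g]))
        expected = [g for _, g in sorted(stats)][:4]
        assert got == expected

    def test_constant_gene_ranked_last(self, rng):
        values = rng.normal(size=(5, 20))
        values[2, :] = 7.0
        labels = np.array([1] * 10 + [0] * 10)
        order = wilcoxon_filter(make_expr(values), labels, 5)
        assert order[-1] == "g02"

    def test_separated_gene_ranked_first(self, rng):
        values = rng.normal(size=(5, 20))
        labels = np.array([1] * 10 + [0] * 10)
        values[3, labels == 1] += 100
        order = wilcoxon_filter(make_expr(values), labels, 5)
        assert order[0] == "g03"

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            wilcoxon_filter(make_expr(np.ones((2, 4))), np.array([0, 1, 0, 1]), 0)


# --- training ------------------------------------------------------------

class TestTrainKtsp:
    def test_recovers_planted_perfect_pair(self, rng):
        values = rng.normal(size=(6, 30))
        labels = np.array([1] * 15 + [0] * 15)
        values[0, labels == 1] = -5  # g00 < g01 exactly in class high
        values[0, labels == 0] = 5
        values[1, :] = 0
        model = train_ktsp(make_expr(values), labels, m=6, k_grid=(1,))
        (pair,) = model.pairs
        assert {pair.gene_i, pair.gene_j} == {"g00", "g01"}
        assert pair.orientation is True and pair.score_delta == 1.0

    def test_selection_equals_exhaustive_enumeration(self, rng):
        for trial in range(5):
            values = rng.normal(size=(8, 30))
            labels = (rng.uniform(size=30) < 0.5).astype(int)
            labels[:4] = [0, 0, 1, 1]
            expr = make_expr(values)
            model = train_ktsp(expr, labels, m=8, k_grid=(3,))
            # greedy disjoint oracle over all 28 pairs
            chosen = []
            used = set()
            scored = []
            for i in range(8):
                for j in range(i + 1, 8):
                    delta, ori, gamma = oracle_pair_score(values, labels, i, j)
                    gi, gj = expr.gene_ids[i], expr.gene_ids[j]
                    if gj < gi:
                        gi, gj, ori = gj, gi, not ori
                    scored.append((-delta, -gamma, gi, gj, ori))
            for _, _, gi, gj, ori in sorted(scored):
                if gi in used or gj in used:
                    continue
                used |= {gi, gj}
                chosen.append((gi, gj, ori))
                if len(chosen) == 3:
                    break
            assert [(p.gene_i, p.gene_j, p.orientation) for p in model.pairs] == chosen

    def test_planted_pairs_mostly_selected(self):
        study = simulate_study(one_cohort_config(120, n_genes=60, n_signal_pairs=5,
                                                 effect_delta=0.8, seed=4))
        expr, labels, _ = stack_training_instances(study.training)
        model = train_ktsp(expr, labels, m=50, k_grid=(5, 7, 9), seed=0)
        planted = {tuple(sorted((p["gene_i"], p["gene_j"])))
                   for p in study.truth["pairs"]}
        selected = {tuple(sorted((p.gene_i, p.gene_j))) for p in model.pairs}
        assert len(planted & selected) >= 4

    def test_too_few_disjoint_pairs_errors(self, rng):
        values = rng.normal(size=(4, 20))
        labels = np.array([1] * 10 + [0] * 10)
        with pytest.raises(ValueError, match="disjoint pairs"):
            train_ktsp(make_expr(values), labels, m=4, k_grid=(5,))


# --- barcodes ------------------------------------------------------------

class TestBarcode:
    def test_bit_definition_including_ties(self):
        values = np.array([[1, 2, 2], [2, 1, 2]], dtype=float)
        expr = make_expr(values)
        pairs = [PairRule("g00", "g01", 0.5, True)]
        codes = barcode_transform(expr, pairs)
        assert [c.bits for c in codes] == [(1,), (0,), (0,)]

    def test_monotone_invariance(self, rng):
        values = np.abs(rng.normal(5, 1, size=(6, 10))) + 0.1
        expr = make_expr(values)
        pairs = [PairRule("g00", "g03", 0.5, True), PairRule("g01", "g04", 0.4, False)]
        base = [c.bits for c in barcode_transform(expr, pairs)]
        logx = make_expr(np.log2(values))
        ranked = make_expr(rankdata(values, axis=0))
        assert [c.bits for c in barcode_transform(logx, pairs)] == base
        assert [c.bits for c in barcode_transform(ranked, pairs)] == base

    def test_missing_gene_named(self):
        with pytest.raises(KeyError, match="gX"):
            barcode_transform(make_expr(np.ones((2, 2))),
                              [PairRule("g00", "gX", 0.1, True)])


# --- prediction ----------------------------------------------------------

def test_majority_vote_k3():
    values = np.array([
        [1, 9], [2, 2],  # pair 1: votes high for s0 (1<2), low for s1
        [1, 9], [2, 2],  # pair 2: same
        [9, 9], [2, 2],  # pair 3: votes low for both
    ], dtype=float)
    expr = make_expr(values)
    model = KtspModel(pairs=[
        PairRule("g00", "g01", 0.9, True),
        PairRule("g02", "g03", 0.8, True),
        PairRule("g04", "g05", 0.7, True),
    ], k=3)
    assert predict_model(model, expr).tolist() == [1, 0]


def test_ensemble_score_is_model_fraction():
    values = np.array([[1.0], [2.0], [3.0], [0.5]])
    expr = make_expr(values)
    hi = KtspModel([PairRule("g00", "g01", 0.9, True)], 1)   # 1<2 -> high
    lo = KtspModel([PairRule("g02", "g03", 0.9, True)], 1)   # 3<0.5 false -> low
    ens = OdfspEnsemble([hi, hi, lo, lo])
    assert score_ensemble(ens, expr).tolist() == [0.5]


def test_model_invariants_enforced():
    with pytest.raises(ValueError):
        KtspModel([PairRule("a", "b", 0.5, True), PairRule("b", "c", 0.4, True)], 2)
    with pytest.raises(ValueError):
        KtspModel([PairRule("a", "b", 0.5, True)], 2)


class TestEnsembleTraining:
    def test_b1_full_resample_equals_single_model(self, small_study):
        ens = train_ensemble(small_study.training, B=1, resample_fraction=1.0,
                             m=40, k_grid=(3,), seed=0)
        scores = score_ensemble(ens, small_study.validation[0].expression)
        assert set(np.unique(scores)) <= {0.0, 1.0}
        preds = predict_model(ens.models[0], small_study.validation[0].expression)
        assert np.array_equal(scores, preds.astype(float))

    def test_dual_platform_profiles_score_identically(self, small_study):
        ens = train_ensemble(small_study.training, B=5, m=40, k_grid=(3, 5), seed=0)
        seq, arr = small_study.training
        s1 = score_ensemble(ens, seq.expression)
        s2 = score_ensemble(ens, arr.expression)
        assert np.array_equal(s1, s2)

    def test_prediction_invariance_under_monotone_transforms(self, small_study):
        from odfsp.synthetic import apply_transform
        ens = train_ensemble(small_study.training, B=5, m=40, k_grid=(3, 5), seed=1)
        expr = small_study.validation[0].expression
        base = score_ensemble(ens, expr)
        for transform in ("log2", "affine:3.2:-1.0", "quantile_rankscale"):
            warped = ExpressionMatrix(
                list(expr.gene_ids), list(expr.sample_ids),
                apply_transform(expr.values, transform, batch_shift=0.9))
            assert np.array_equal(score_ensemble(ens, warped), base)

    def test_pair_overlap_across_models(self, small_study):
        ens = train_ensemble(small_study.training, B=20, m=40, k_grid=(5,), seed=2)
        assert len(ens.distinct_genes) < 2 * len(ens.distinct_pairs)

    def test_disjointness_within_every_model(self, small_study):
        ens = train_ensemble(small_study.training, B=10, m=40, k_grid=(3, 5), seed=3)
        for model in ens.models:
            genes = [g for p in model.pairs for g in (p.gene_i, p.gene_j)]
            assert len(set(genes)) == len(genes)

    def test_invalid_b(self, small_study):
        with pytest.raises(ValueError):
            train_ensemble(small_study.training, B=0)


def test_persistence_round_trip(tmp_path, small_study):
    ens = train_ensemble(small_study.training, B=3, m=40, k_grid=(3,), seed=0)
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    save_ensemble(ens, p1, meta={"seed": 0})
    back = load_ensemble(p1)
    save_ensemble(back, p2, meta={"seed": 0})
    assert p1.read_text() == p2.read_text()
    assert back.distinct_pairs == ens.distinct_pairs
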