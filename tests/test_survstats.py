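import numpy as np
import pytest

from odfsp.survstats import (
    KAPPA,
    auroc,
    balanced_accuracy,
    concordance_index,
    d_index,
    km_curve,
    logrank,
    median_split,
    scaled_rankits,
)


# --- independent oracles -------------------------------------------------

def oracle_auroc(scores, labels):
    """O(n^2) pair-counting oracle."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def oracle_cindex(scores, times, events):
    """Hand enumeration of Harrell comparable pairs."""
    n = len(scores)
    conc = comp = 0.0
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            # a must have the event strictly first (or tied time, a only event)
            if not events[a]:
                continue
            if times[a] > times[b]:
                continue
            if times[a] == times[b] and events[b]:
                continue
            comp += 1
            if scores[a] > scores[b]:
                conc += 1
            elif scores[a] == scores[b]:
                conc += 0.5
    return conc / comp if comp else None


# --- AUROC ---------------------------------------------------------------

class TestAuroc:
    def test_perfect_separation(self):
        est = auroc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert est.value == 1.0
        assert est.p_value < 0.05

    def test_all_ties(self):
        est = auroc([5.0] * 8, [0, 1] * 4)
        assert est.value == 0.5
        assert est.p_value == 1.0

    def test_matches_pair_counting_oracle(self, rng):
        scores = np.round(rng.normal(size=60), 1)  # rounding creates ties
        labels = np.array([1] * 30 + [0] * 30)
        est = auroc(scores, labels)
        assert est.value == pytest.approx(oracle_auroc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(size=80)
        labels = (rng.uniform(size=80) < 0.4).astype(int)
        labels[:2] = [0, 1]
        est = auroc(scores, labels)
        assert est.value == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_monotone_invariance(self, rng):
        scores = rng.uniform(0.1, 1, size=50)
        labels = (rng.uniform(size=50) < 0.5).astype(int)
        labels[:2] = [0, 1]
        a = auroc(scores, labels).value
        assert auroc(np.log(scores), labels).value == a
        assert auroc(scores**3, labels).value == a

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])


class TestBalancedAccuracy:
    def test_perfect(self):
        assert balanced_accuracy([1, 0, 1], [1, 0, 1]) == 1.0

    def test_constant_prediction(self):
        assert balanced_accuracy([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5

    def test_confusion_table_arithmetic(self):
        # TP=3, FN=1, TN=2, FP=2 -> (0.75 + 0.5)/2
        pred = [1, 1, 1, 0, 0, 0, 1, 1]
        true = [1, 1, 1, 1, 0, 0, 0, 0]
        assert balanced_accuracy(pred, true) == pytest.approx(0.625)


# --- C-index -------------------------------------------------------------

class TestConcordance:
    def test_perfectly_antiordered_scores(self):
        est = concordance_index([3, 2, 1], [3, 5, 7], [1, 1, 1])
        assert est.value == 1.0

    def test_hand_enumerated_censored_example(self):
        est = concordance_index([1, 3, 2], [5, 3, 7], [0, 1, 1])
        assert est.value == 1.0
        assert est.extras["n_comparable"] == 2

    def test_matches_brute_force_oracle(self, rng):
        n = 200
        times = rng.exponential(365, size=n)
        events = rng.uniform(size=n) < 0.7
        scores = np.round(rng.normal(size=n), 1)
        est = concordance_index(scores, times, events)
        assert est.value == pytest.approx(
            oracle_cindex(scores, times.tolist(), events.tolist()), abs=1e-14)

    def test_matches_scikit_survival(self, rng):
        from sksurv.metrics import concordance_index_censored
        n = 150
        times = rng.exponential(365, size=n)
        events = rng.uniform(size=n) < 0.6
        scores = rng.normal(size=n)
        est = concordance_index(scores, times, events)
        ref = concordance_index_censored(events, times, scores)[0]
        assert est.value == pytest.approx(ref, abs=1e-12)

    def test_equals_auroc_pairs_when_uncensored(self, rng):
        # with all events and distinct times, C equals pairwise ordering of
        # (time, -score) -- checked through the pair-counting oracle
        n = 40
        times = rng.permutation(n).astype(float) + 1
        scores = rng.normal(size=n)
        est = concordance_index(scores, times, np.ones(n, bool))
        total = conc = 0.0
        for a in range(n):
            for b in range(n):
                if times[a] < times[b]:
                    total += 1
                    conc += 1.0 if scores[a] > scores[b] else (0.5 if scores[a] == scores[b] else 0)
        assert est.value == pytest.approx(conc / total, abs=1e-14)

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError):
            concordance_index([1, 2], [5, 5], [1, 1])


# --- D-index -------------------------------------------------------------

class TestDIndex:
    def test_constant_scores_convention(self):
        est = d_index([1.0] * 20, np.arange(1, 21.0), np.ones(20, bool))
        assert est.display_value == 1.0
        assert est.extras.get("se_undefined")

    def test_null_scores_log_d_near_zero(self, rng):
        n = 2000
        times = rng.exponential(1000, size=n)
        scores = rng.normal(size=n)  # independent of survival
        est = d_index(scores, times, np.ones(n, bool))
        assert abs(est.value) < 3 * est.se

    def test_parameter_recovery(self, rng):
        # survival with hazard exp(beta * z) on the scaled rankit covariate
        n = 2000
        scores = rng.normal(size=n)
        z = scaled_rankits(scores)
        beta = 0.5
        times = rng.exponential(1.0 / (0.001 * np.exp(beta * z)))
        est = d_index(scores, times, np.ones(n, bool))
        assert est.display_value == pytest.approx(np.exp(beta), rel=0.10)

    def test_reversed_scores_give_reciprocal(self, rng):
        n = 100
        scores = rng.normal(size=n)
        times = rng.exponential(500 * np.exp(-0.5 * scores))
        events = rng.uniform(size=n) < 0.8
        a = d_index(scores, times, events)
        b = d_index(-scores, times, events)
        assert a.value == pytest.approx(-b.value, abs=1e-8)

    def test_matches_lifelines_cox(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter
        n = 300
        scores = rng.normal(size=n)
        times = rng.exponential(500 * np.exp(-0.4 * scores))
        events = rng.uniform(size=n) < 0.7
        est = d_index(scores, times, events)
        df = pd.DataFrame({"z": scaled_rankits(scores), "t": times, "e": events})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        # continuous times: Efron and Breslow coincide (no ties)
        assert est.value == pytest.approx(cph.params_["z"], abs=1e-5)
        assert est.se == pytest.approx(cph.standard_errors_["z"], abs=1e-5)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            d_index([1, 2, 3], [1, 2, 3], [1, 1, 1])

    def test_kappa_constant(self):
        assert KAPPA == pytest.approx(np.sqrt(8 / np.pi))


# --- KM / log-rank / median split ---------------------------------------

class TestKmLogrank:
    def test_product_limit_arithmetic(self):
        km = km_curve([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert np.allclose(km.survival, [0.8, 0.6, 0.4, 0.2, 0.0])
        assert km.median == 3
        assert km.n_at_risk.tolist() == [5, 4, 3, 2, 1]

    def test_all_censored(self):
        km = km_curve([5, 6, 7], [0, 0, 0])
        assert km.median is None
        assert km.times.size == 0

    def test_km_median_equals_sample_median_without_censoring(self, rng):
        times = rng.exponential(100, size=201)
        km = km_curve(times, np.ones(201, bool))
        assert km.median == pytest.approx(np.sort(times)[100])

    def test_identical_groups_give_null_logrank(self):
        t = [3, 5, 8, 13, 21.0]
        e = [1, 1, 0, 1, 1]
        chi2, p = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        chi2, p = logrank(np.arange(1, 21.0), np.ones(20, bool),
                          np.arange(100, 120.0), np.ones(20, bool))
        assert p < 1e-6


class TestMedianSplit:
    def test_basic(self):
        assert median_split([0.1, 0.2, 0.9, 1.0]).tolist() == [0, 0, 1, 1]

    def test_ties_at_median_go_low(self):
        assert median_split([0, 0.5, 0.5, 1]).tolist() == [0, 0, 0, 1]

    def test_odd_n(self):
        assert median_split([0.1, 0.5, 0.9]).tolist() == [0, 0, 1]

    def test_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split([0.3, 0.3, 0.3])
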