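import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiclass import (
    ScoreTrack,
    compare_methods,
    confusion,
    evaluate_track,
    kappa,
    roc_auc,
    roc_curve,
    select_cutoff,
)
from epiclass.evaluation import rates


def pairwise_ranking_auc(scores, truth):
    """Brute-force AUC: P(score_pos > score_neg), ties counted 1/2."""
    scores = np.asarray(scores)
    truth = np.asarray(truth, dtype=bool)
    pos, neg = scores[truth], scores[~truth]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_track(self):
        truth = [False, True, True, False]
        t = ScoreTrack("a", [0.0, 1.0, 1.0, 0.0])
        for cut in (0.2, 0.5, 1.0):
            tp, fp, tn, fn = confusion(t, truth, cut)
            assert fp == 0 and fn == 0 and tp == 2 and tn == 2

    def test_all_zero_track(self):
        tp, fp, tn, fn = confusion([0.0] * 6, [True] * 3 + [False] * 3, 0.5)
        assert tp == 0 and fp == 0 and fn == 3 and tn == 3

    def test_hand_counted_toy(self):
        # L = 10, truth 3-5, predicted above cutoff at 4-7
        truth = [i in (2, 3, 4) for i in range(10)]
        scores = [0.9 if i in (3, 4, 5, 6) else 0.0 for i in range(10)]
        tp, fp, tn, fn = confusion(scores, truth, 0.5)
        assert (tp, fp, fn, tn) == (2, 2, 1, 5)

    def test_counts_sum_to_length(self, rng):
        scores = rng.random(50)
        truth = rng.random(50) < 0.3
        assert sum(confusion(scores, truth, 0.4)) == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0.1, 0.2], [True], 0.5)


class TestRates:
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    @settings(max_examples=80, deadline=None)
    def test_identities(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        r = rates(tp, fp, tn, fn)
        assert r["specificity"] == pytest.approx(1.0 - r["fpr"], abs=1e-12)
        if tp + fn:
            fnr = fn / (tp + fn)
            assert r["tpr"] == pytest.approx(1.0 - fnr, abs=1e-12)
        for key in ("accuracy", "tpr", "fpr", "precision", "specificity"):
            assert 0.0 <= r[key] <= 1.0


class TestKappa:
    def test_perfect_agreement(self):
        assert kappa(40, 0, 60, 0) == pytest.approx(1.0)

    def test_marginal_independence(self):
        assert kappa(25, 25, 25, 25) == pytest.approx(0.0)

    def test_closed_form(self):
        # p_o = 0.8, p_e = 0.5 -> kappa = 0.6
        assert kappa(40, 10, 40, 10) == pytest.approx(0.6)

    def test_range(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(0, 30, 4)
            if tp + fp + tn + fn == 0:
                continue
            assert -1.0 <= kappa(int(tp), int(fp), int(tn), int(fn)) <= 1.0


class TestRoc:
    def test_perfect_ranking(self):
        truth = [True] * 3 + [False] * 3
        assert roc_auc([0.9, 0.8, 0.7, 0.2, 0.1, 0.0], truth) == pytest.approx(1.0)

    def test_inverted_ranking(self):
        truth = [True] * 3 + [False] * 3
        assert roc_auc([0.0, 0.1, 0.2, 0.7, 0.8, 0.9], truth) == pytest.approx(0.0)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.random(60)
        truth = rng.random(60) < 0.5
        pts = roc_curve(scores, truth)
        assert pts[0][:2] == (0.0, 0.0) and pts[-1][:2] == (1.0, 1.0)
        fprs = [p[0] for p in pts]
        tprs = [p[1] for p in pts]
        assert all(a <= b + 1e-12 for a, b in zip(fprs, fprs[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(tprs, tprs[1:]))

    @given(seed=st.integers(0, 5000), n=st.integers(10, 120))
    @settings(max_examples=40, deadline=None)
    def test_trapezoid_equals_pairwise_ranking(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(n), 2)  # force ties
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            truth[0] = not truth[0]
        assert roc_auc(scores, truth) == pytest.approx(
            pairwise_ranking_auc(scores, truth), abs=1e-12
        )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(200)
        truth = rng.random(200) < 0.4
        assert roc_auc(scores, truth) == pytest.approx(roc_auc_score(truth, scores))

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        aucs = [
            roc_auc(rng.random(1000), np.arange(1000) < 500) for _ in range(10)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])


class TestSelectCutoff:
    def test_separable_all_policies_zero_error(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        truth = [True, True, False, False]
        for policy in ("max_precision", "max_auc_point"):
            cut = select_cutoff(scores, truth, policy)
            tp, fp, tn, fn = confusion(scores, truth, cut)
            assert fp == 0 and fn == 0

    def test_max_precision_exhaustive_sweep(self, rng):
        scores = rng.random(40)
        truth = rng.random(40) < 0.4
        if not truth.any() or truth.all():
            truth[:2] = [True, False]
        cut = select_cutoff(scores, truth, "max_precision")
        best = max(
            rates(*confusion(scores, truth, float(c)))["precision"]
            for c in np.unique(scores)
        )
        assert rates(*confusion(scores, truth, cut))["precision"] == pytest.approx(best)

    def test_youden_exhaustive_sweep(self, rng):
        scores = rng.random(40)
        truth = rng.random(40) < 0.5
        if not truth.any() or truth.all():
            truth[:2] = [True, False]
        cut = select_cutoff(scores, truth, "max_auc_point")
        r = rates(*confusion(scores, truth, cut))
        best = max(
            (lambda q: q["tpr"] - q["fpr"])(rates(*confusion(scores, truth, float(c))))
            for c in np.unique(scores)
        )
        assert r["tpr"] - r["fpr"] == pytest.approx(best)

    def test_default_policy_returns_configured(self):
        assert select_cutoff([0.1, 0.9], [False, True], "default", 0.2) == 0.2

    def test_unknown_policy(self):
        with pytest.raises(ValueError):
            select_cutoff([0.1], [True], "banana")


class TestCompareMethods:
    def _setup(self, rng):
        truths = [rng.random(50) < 0.3 for _ in range(3)]
        oracle = [t.astype(float) for t in truths]
        noise = [rng.random(50) for _ in range(3)]
        return truths, oracle, noise

    def test_method_against_itself_identical(self, rng):
        truths, oracle, _ = self._setup(rng)
        table = compare_methods({"m1": oracle, "m2": oracle}, truths)
        a = table[table.method == "m1"].drop(columns="method").reset_index(drop=True)
        b = table[table.method == "m2"].drop(columns="method").reset_index(drop=True)
        assert a.equals(b)

    def test_rank_invariance_of_auc(self, rng):
        truths, _, noise = self._setup(rng)
        halved = [[s / 2 for s in t] for t in noise]
        t1 = compare_methods({"m": noise}, truths, policies=["max_auc_point"])
        t2 = compare_methods({"m": halved}, truths, policies=["max_auc_point"])
        assert t1["auc"].iloc[0] == pytest.approx(t2["auc"].iloc[0])

    def test_oracle_beats_noise(self, rng):
        truths, oracle, noise = self._setup(rng)
        table = compare_methods(
            {"oracle": oracle, "noise": noise}, truths, policies=["max_auc_point"]
        )
        o = table[table.method == "oracle"].iloc[0]
        n = table[table.method == "noise"].iloc[0]
        assert o["auc"] > n["auc"]
        assert o["accuracy"] >= n["accuracy"]

    def test_pooled_mode_runs(self, rng):
        truths, oracle, _ = self._setup(rng)
        pooled = compare_methods({"m": oracle}, truths, policies=["default"], pool=True)
        assert pooled.shape[0] == 1 and pooled["auc"].iloc[0] == pytest.approx(1.0)

    def test_missing_track_rejected(self, rng):
        truths, oracle, _ = self._setup(rng)
        with pytest.raises(ValueError):
            compare_methods({"m": oracle[:2]}, truths)


def test_evaluate_track_row_is_consistent(rng):
    scores = rng.random(80)
    truth = rng.random(80) < 0.4
    row = evaluate_track(scores, truth, method="m", policy="max_auc_point")
    assert row.specificity == pytest.approx(1 - row.fpr, abs=1e-12)
    assert 0.0 <= row.auc <= 1.0
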