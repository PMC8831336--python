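"""Metrics contracts, checked against independent brute-force oracles
implemented directly from the definitions."""

import numpy as np
import pytest

from phasebmd.errors import StatisticsError, ValidationError
from phasebmd.metrics import agreement_report, classification_report, paired_t

CLASSES = ("NE", "AR", "PV")


# ---------------------------------------------------------------------------
# brute-force oracles (definition-level, independent of sklearn)
# ---------------------------------------------------------------------------

def brute_force_metrics(y_true, y_pred, cls):
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p != cls)
    div = lambda a, b: a / b if b else 0.0
    return {
        "precision": div(tp, tp + fp),
        "sensitivity": div(tp, tp + fn),
        "specificity": div(tn, tn + fp),
        "f1": div(2 * tp, 2 * tp + fp + fn),
    }


def brute_force_auc(y_true, scores, cls):
    pos = [s for t, s in zip(y_true, scores) if t == cls]
    neg = [s for t, s in zip(y_true, scores) if t != cls]
    if not pos or not neg:
        return None
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def random_instance(rng, n):
    y_true = rng.choice(CLASSES, size=n)
    y_pred = rng.choice(CLASSES, size=n)
    probs = rng.dirichlet(np.ones(3), size=n)
    return y_true, y_pred, probs


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassification:
    def test_perfect_predictions_score_one_everywhere(self):
        y = np.array(["NE", "AR", "PV"] * 5)
        probs = np.array([{"NE": 0, "AR": 1, "PV": 2}[c] == np.arange(3) for c in y], dtype=float)
        rep = classification_report(y, y, probs)
        assert rep.accuracy == 1.0
        for c in CLASSES:
            assert rep.precision[c] == rep.sensitivity[c] == rep.f1[c] == 1.0
            assert rep.auc[c] == 1.0
        assert rep.macro_f1 == 1.0 and rep.macro_auc == 1.0

    def test_uninformative_scores_give_auc_half(self):
        y = np.array(["NE", "AR", "PV"] * 4)
        rep = classification_report(y, y, np.full((12, 3), 1 / 3))
        for c in CLASSES:
            assert rep.auc[c] == pytest.approx(0.5)

    def test_hand_confusion_matrix_matches_brute_force(self):
        # confusion ((5,1,0),(0,4,1),(1,0,6)), rows = true NE/AR/PV
        y_true = ["NE"] * 6 + ["AR"] * 5 + ["PV"] * 7
        y_pred = (["NE"] * 5 + ["AR"]) + (["AR"] * 4 + ["PV"]) + (["NE"] + ["PV"] * 6)
        rep = classification_report(y_true, y_pred)
        expected_cm = np.array([[5, 1, 0], [0, 4, 1], [1, 0, 6]])
        assert np.array_equal(rep.confusion, expected_cm)
        for c in CLASSES:
            oracle = brute_force_metrics(y_true, y_pred, c)
            for m in oracle:
                assert getattr(rep, m)[c] == pytest.approx(oracle[m], abs=1e-12)
        assert rep.accuracy == pytest.approx(15 / 18)

    @pytest.mark.parametrize("trial", range(20))
    def test_random_instances_match_brute_force(self, trial):
        rng = np.random.default_rng(1000 + trial)
        y_true, y_pred, probs = random_instance(rng, int(rng.integers(5, 51)))
        rep = classification_report(y_true, y_pred, probs)
        acc = sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)
        assert rep.accuracy == pytest.approx(acc, abs=1e-12)
        for i, c in enumerate(CLASSES):
            oracle = brute_force_metrics(y_true, y_pred, c)
            for m in oracle:
                assert getattr(rep, m)[c] == pytest.approx(oracle[m], abs=1e-12)
            auc = brute_force_auc(y_true, probs[:, i], c)
            if auc is None:
                assert rep.auc[c] is None
            else:
                assert rep.auc[c] == pytest.approx(auc, abs=1e-9)

    def test_class_absent_from_truth_reported_missing(self):
        y_true = ["NE", "NE", "AR", "AR"]
        y_pred = ["NE", "AR", "AR", "NE"]
        probs = np.full((4, 3), 1 / 3)
        rep = classification_report(y_true, y_pred, probs)
        assert rep.auc["PV"] is None
        assert np.isfinite(rep.macro_auc)

    def test_auc_invariant_to_monotone_score_transform(self, rng):
        y_true, y_pred, probs = random_instance(rng, 40)
        a = classification_report(y_true, y_pred, probs)
        b = classification_report(y_true, y_pred, np.exp(3.0 * probs))
        for c in CLASSES:
            assert a.auc[c] == pytest.approx(b.auc[c], abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            classification_report(["NE"], ["NE", "AR"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            classification_report(["XX"], ["NE"])


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

class TestAgreement:
    def test_hand_computed_example(self):
        rep = agreement_report([100.0, 110.0], [110.0, 130.0])
        assert rep.mean_difference == pytest.approx(15.0)
        assert rep.rmse == pytest.approx(np.sqrt(250.0))
        sd = np.std([10.0, 20.0], ddof=1)
        assert rep.sd_difference == pytest.approx(sd)
        assert rep.loa_low == pytest.approx(15.0 - 1.96 * sd)
        assert rep.loa_high == pytest.approx(15.0 + 1.96 * sd)

    def test_identical_vectors_degenerate(self):
        rep = agreement_report([100.0, 120.0, 140.0], [100.0, 120.0, 140.0])
        assert rep.rmse == 0.0 and rep.mean_difference == 0.0
        assert rep.p == 1.0 and rep.degenerate

    def test_constant_shift_property(self, rng):
        x = rng.uniform(80, 200, size=25)
        for c in (-7.3, 0.5, 12.0):
            rep = agreement_report(x, x + c)
            assert rep.mean_difference == pytest.approx(c, abs=1e-9)
            assert rep.rmse == pytest.approx(abs(c), abs=1e-9)
            assert rep.loa_low <= rep.mean_difference <= rep.loa_high

    def test_rmse_bounds_mean_difference(self, rng):
        ref = rng.uniform(80, 200, size=30)
        test = ref + rng.normal(5, 10, size=30)
        rep = agreement_report(ref, test)
        assert rep.rmse >= abs(rep.mean_difference)

    def test_single_pair_rejected(self):
        with pytest.raises(StatisticsError):
            agreement_report([100.0], [110.0])


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------

class TestPairedT:
    def test_hand_computed_t_and_p(self):
        res = paired_t([1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)), abs=1e-9)
        # closed form for df=2: p = 1 - t/sqrt(t^2 + 2)
        t = res.t
        assert res.p == pytest.approx(1.0 - t / np.sqrt(t * t + 2.0), abs=1e-9)

    def test_null_differences_give_large_p(self, rng):
        d = rng.normal(0.0, 1.0, size=400)
        d = d - d.mean()  # exactly zero-mean
        assert paired_t(d).p == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_flagged(self):
        res = paired_t([2.0, 2.0, 2.0])
        assert res.degenerate and res.p == 0.0

    def test_single_observation_rejected(self):
        with pytest.raises(StatisticsError):
            paired_t([1.0])

    def test_matches_scipy_ttest_rel(self, rng):
        from scipy import stats

        a = rng.normal(100, 15, size=20)
        b = a + rng.normal(3, 5, size=20)
        res = paired_t(b - a)
        ref = stats.ttest_rel(b, a)
        assert res.t == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)
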