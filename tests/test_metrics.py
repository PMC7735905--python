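"""Validation-metric suite: formulas, identities, and independent cross-checks."""

import numpy as np
import pytest

from eppheno.metrics import (
    ConfusionMatrix2x2,
    binary_metrics,
    cohens_kappa,
    confusion,
    kappa_from_table,
    management_agreement,
    management_agreement_from_matrix,
    round_half_up,
)


def test_round_half_up_at_the_half():
    assert round_half_up(88.05, 1) == 88.1
    assert round_half_up(82.25, 1) == 82.3
    assert round_half_up(97.64, 1) == 97.6


class TestConfusion:
    def test_identity_labels(self):
        labels = {f"u{i}": i < 7 for i in range(10)}
        cm = confusion(labels, labels)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (7, 0, 0, 3)

    def test_all_false_predictions(self):
        gold = {f"u{i}": i < 7 for i in range(10)}
        pred = {k: False for k in gold}
        cm = confusion(pred, gold)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 0, 7, 3)

    def test_misaligned_ids_error(self):
        with pytest.raises(ValueError):
            confusion({"a": True}, {"b": True})

    def test_matches_sklearn_on_random_labels(self):
        from sklearn.metrics import confusion_matrix

        rng = np.random.default_rng(5)
        pred = rng.random(200) < 0.5
        gold = rng.random(200) < 0.6
        cm = confusion(
            {str(i): bool(p) for i, p in enumerate(pred)},
            {str(i): bool(g) for i, g in enumerate(gold)},
        )
        ref = confusion_matrix(gold, pred, labels=[True, False])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (ref[0, 0], ref[0, 1], ref[1, 0], ref[1, 1])

    def test_order_invariance(self):
        gold = {f"u{i}": i % 3 == 0 for i in range(30)}
        pred = {f"u{i}": i % 2 == 0 for i in range(30)}
        cm1 = confusion(pred, gold)
        cm2 = confusion(dict(reversed(list(pred.items()))), gold)
        assert cm1 == cm2


class TestBinaryMetrics:
    def test_perfect_classifier(self):
        r = binary_metrics(ConfusionMatrix2x2(1, 0, 0, 1))
        assert r.rounded() == {
            "sensitivity": 100.0,
            "specificity": 100.0,
            "ppv": 100.0,
            "npv": 100.0,
            "youden_index": 100.0,
            "f_score": 100.0,
        }

    def test_undefined_metrics_are_none_not_zero(self):
        r = binary_metrics(ConfusionMatrix2x2(tp=0, fp=0, fn=0, tn=5))
        assert r.sensitivity is None and r.ppv is None
        assert r.specificity == 100.0
        assert r.youden_index is None and r.f_score is None

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix2x2(0, 0, 0, 0)

    def test_identities_hold_before_rounding(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 400, size=4))
            if tp + fn == 0 or tn + fp == 0 or tp + fp == 0:
                continue
            r = binary_metrics(ConfusionMatrix2x2(tp, fp, fn, tn))
            assert abs(r.youden_index - (r.sensitivity + r.specificity - 100.0)) < 1e-9
            if r.ppv + r.sensitivity > 0:
                assert (
                    abs(r.f_score - 2 * r.ppv * r.sensitivity / (r.ppv + r.sensitivity)) < 1e-9
                )

    def test_swapping_pred_gold_transposes(self):
        cm = ConfusionMatrix2x2(tp=30, fp=10, fn=5, tn=55)
        swapped = ConfusionMatrix2x2(tp=30, fp=5, fn=10, tn=55)
        a, b = binary_metrics(cm), binary_metrics(swapped)
        assert a.sensitivity == b.ppv and a.ppv == b.sensitivity
        assert a.specificity == b.npv and a.npv == b.specificity


class TestManagementAgreement:
    def test_identical_labels_perfect_accuracy(self):
        labels = {"a": "surgical", "b": "medical", "c": "unclassified"}
        r = management_agreement(labels, labels)
        assert r.overall_accuracy == 100.0

    def test_all_wrong(self):
        pred = {f"u{i}": "unclassified" for i in range(5)}
        gold = {f"u{i}": "surgical" for i in range(5)}
        r = management_agreement(pred, gold)
        assert r.overall_accuracy == 0.0
        assert r.surgical_binary.sensitivity == 0.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            management_agreement({"a": "expectant"}, {"a": "surgical"})

    def test_matrix_and_label_paths_agree(self):
        rng = np.random.default_rng(13)
        lv = ["surgical", "medical", "unclassified"]
        pred = {str(i): lv[int(rng.integers(3))] for i in range(100)}
        gold = {str(i): lv[int(rng.integers(3))] for i in range(100)}
        a = management_agreement(pred, gold)
        b = management_agreement_from_matrix(a.matrix3x3)
        assert a.overall_accuracy == b.overall_accuracy
        assert a.surgical_binary == b.surgical_binary


class TestKappa:
    def test_perfect_agreement_is_one(self):
        labels = [True, False, True, True, False]
        assert cohens_kappa(labels, labels).kappa == 1.0

    def test_chance_level_is_zero(self):
        # po == pe by construction: table (25, 25, 25, 25)
        r = kappa_from_table(25, 25, 25, 25)
        assert r.kappa == pytest.approx(0.0, abs=1e-12)

    def test_formula_vs_brute_force(self):
        a, b, c, d = 40, 10, 10, 40
        n = a + b + c + d
        po = (a + d) / n
        pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
        expected = (po - pe) / (1 - pe)
        assert abs(kappa_from_table(a, b, c, d).kappa - expected) < 1e-12

    def test_symmetry(self):
        rng = np.random.default_rng(21)
        x = [bool(v) for v in rng.random(100) < 0.4]
        y = [bool(v) for v in rng.random(100) < 0.6]
        assert cohens_kappa(x, y).kappa == pytest.approx(cohens_kappa(y, x).kappa, abs=1e-15)

    def test_ci_brackets_kappa_within_bounds(self):
        r = kappa_from_table(40, 10, 10, 40)
        assert -1.0 <= r.ci_low <= r.kappa <= r.ci_high <= 1.0

    def test_constant_identical_raters_undefined(self):
        r = cohens_kappa([True] * 5, [True] * 5)
        assert r.kappa is None and r.note

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        rng = np.random.default_rng(31)
        for _ in range(20):
            t = rng.integers(1, 50, size=4)
            table = np.array([[t[0], t[1]], [t[2], t[3]]])
            ours = kappa_from_table(int(t[0]), int(t[1]), int(t[2]), int(t[3]))
            ref = sm_kappa(table, return_results=True)
            assert ours.kappa == pytest.approx(float(ref.kappa), abs=1e-12)
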