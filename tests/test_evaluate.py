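"""1-NN two-sample behaviour (copy, separation, calibration) and
staging metrics against hand tables and scikit-learn."""

import numpy as np
import pytest
from sklearn.metrics import accuracy_score, cohen_kappa_score, f1_score

from sleepgan.evaluate import (
    classification_metrics,
    format_1nn_table,
    one_nn_two_sample,
    per_stage_1nn_report,
)
from sleepgan.signal import STAGES


def test_exact_copy_gives_zero_accuracy(rng):
    x = rng.standard_normal((30, 16))
    assert one_nn_two_sample(x, x.copy()).accuracy == 0.0


def test_separated_clusters_give_perfect_accuracy(rng):
    real = 100.0 + 0.01 * rng.standard_normal((25, 8))
    fake = -100.0 + 0.01 * rng.standard_normal((25, 8))
    assert one_nn_two_sample(real, fake).accuracy == 1.0


def test_same_distribution_calibrates_to_half():
    rng = np.random.default_rng(0)
    accs = [
        one_nn_two_sample(rng.standard_normal((200, 50)), rng.standard_normal((200, 50))).accuracy
        for _ in range(10)
    ]
    assert abs(np.mean(accs) - 0.5) < 0.05


def test_calibration_deviation_shrinks_with_n():
    rng = np.random.default_rng(1)
    devs = []
    for n in (50, 200, 800):
        accs = [
            one_nn_two_sample(
                rng.standard_normal((n, 20)), rng.standard_normal((n, 20))
            ).accuracy
            for _ in range(6)
        ]
        devs.append(abs(np.mean(accs) - 0.5) + np.std(accs))
    assert devs[2] < devs[0]


def test_accuracy_is_permutation_invariant(rng):
    real = rng.standard_normal((40, 10))
    fake = rng.standard_normal((40, 10)) + 0.5
    base = one_nn_two_sample(real, fake).accuracy
    perm = rng.permutation(40)
    assert one_nn_two_sample(real[perm], fake[perm]).accuracy == base


def test_input_validation(rng):
    with pytest.raises(ValueError, match="non-empty"):
        one_nn_two_sample(np.empty((0, 5)), rng.standard_normal((3, 5)))
    with pytest.raises(ValueError, match="mismatch"):
        one_nn_two_sample(rng.standard_normal((3, 5)), rng.standard_normal((3, 6)))


# ------------------------------------------------------------ per-stage report
def test_identical_data_every_trial_has_zero_variance(rng):
    x = rng.standard_normal((10, 8))
    y = rng.standard_normal((10, 8))
    rep = per_stage_1nn_report({"W": x}, {"W": y}, n_trials=5, n_per_side=10)
    assert rep["W"]["variance"] == 0.0


def test_report_covers_only_populated_stages(rng):
    data = {s: rng.standard_normal((12, 8)) for s in STAGES}
    gen = {s: rng.standard_normal((12, 8)) for s in ("W", "N2")}
    rep = per_stage_1nn_report(data, gen, n_trials=3, n_per_side=12)
    assert set(rep) == {"W", "N2"}


def test_report_table_has_five_stage_columns(rng):
    data = {s: rng.standard_normal((60, 8)) for s in STAGES}
    gen = {s: rng.standard_normal((60, 8)) for s in STAGES}
    rep = per_stage_1nn_report(data, gen, n_trials=4, n_per_side=40, seed=1)
    table = format_1nn_table(rep)
    header = table.splitlines()[0]
    for col in ("W", "N1", "N2", "N3", "R"):
        assert col in header.split()
    for stage in STAGES:  # all-same-distribution fixtures calibrate near 0.5
        assert 0.4 <= rep[stage]["mean"] <= 0.6


# ------------------------------------------------------------ staging metrics
def test_perfect_prediction_is_all_ones():
    y = ["W", "N1", "N2", "N3", "REM"] * 4
    rep = classification_metrics(y, list(y))
    assert rep.acc == rep.mf1 == rep.kappa == 1.0
    assert all(v == 1.0 for v in rep.per_class_f1.values())


def test_hand_contingency_table():
    """40/50 W correct with 10 W->N1 errors, all 200 others correct:
    ACC = 240/250."""
    y_true = ["W"] * 50 + ["N1"] * 50 + ["N2"] * 50 + ["N3"] * 50 + ["REM"] * 50
    y_pred = ["W"] * 40 + ["N1"] * 10 + ["N1"] * 50 + ["N2"] * 50 + ["N3"] * 50 + ["REM"] * 50
    rep = classification_metrics(y_true, y_pred)
    assert rep.acc == pytest.approx(240 / 250)
    # W: precision 1, recall 0.8 -> F1 = 8/9; N1: precision 50/60, recall 1
    assert rep.per_class_f1["W"] == pytest.approx(2 * 0.8 / 1.8)
    assert rep.per_class_f1["N1"] == pytest.approx(2 * (50 / 60) / (50 / 60 + 1))


def test_constant_predictor_on_balanced_labels():
    y_true = ["W", "N1", "N2", "N3", "REM"] * 10
    y_pred = ["N2"] * 50
    rep = classification_metrics(y_true, y_pred)
    assert rep.acc == pytest.approx(0.2)
    assert rep.kappa == pytest.approx(0.0)


def test_stage_absent_from_both_sides_excluded_with_warning():
    y_true = ["W", "N1", "N2", "N3"] * 10
    y_pred = ["W", "N1", "N2", "N3"] * 10
    with pytest.warns(UserWarning, match="REM"):
        rep = classification_metrics(y_true, y_pred)
    assert "REM" not in rep.per_class_f1
    assert rep.mf1 == 1.0


def test_mf1_is_unweighted_mean_of_per_class_f1(rng):
    y_true = [STAGES[i] for i in rng.integers(0, 5, 300)]
    y_pred = [STAGES[i] for i in rng.integers(0, 5, 300)]
    rep = classification_metrics(y_true, y_pred)
    assert rep.mf1 == pytest.approx(np.mean(list(rep.per_class_f1.values())))


def test_metrics_agree_with_sklearn(rng):
    y_true = [STAGES[i] for i in rng.integers(0, 5, 400)]
    noisy = rng.integers(0, 5, 400)
    keep = rng.random(400) < 0.7
    y_pred = [t if k else STAGES[i] for t, k, i in zip(y_true, keep, noisy)]
    rep = classification_metrics(y_true, y_pred)
    assert rep.acc == pytest.approx(accuracy_score(y_true, y_pred))
    assert rep.mf1 == pytest.approx(f1_score(y_true, y_pred, average="macro", labels=list(STAGES)))
    assert rep.kappa == pytest.approx(cohen_kappa_score(y_true, y_pred))


def test_kappa_bounded_by_accuracy_above_chance(rng):
    for seed in range(5):
        r = np.random.default_rng(seed)
        y_true = [STAGES[i] for i in r.integers(0, 5, 200)]
        keep = r.random(200) < 0.6
        y_pred = [t if k else STAGES[r.integers(0, 5)] for t, k in zip(y_true, keep)]
        rep = classification_metrics(y_true, y_pred)
        if rep.acc >= 0.2:
            assert rep.kappa <= rep.acc + 1e-12


def test_label_outside_alphabet_rejected():
    with pytest.raises(ValueError, match="alphabet"):
        classification_metrics(["W", "X"], ["W", "W"])
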