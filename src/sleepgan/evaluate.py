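"""Diagnostics for generated data.

Two families:

* the leave-one-out 1-NN two-sample test — pool real (positive) and
  generated (negative) epochs, classify each by its nearest other sample
  under Euclidean distance, and report the accuracy.  Matched
  distributions give ~50%; an accuracy of 1 means the sets are trivially
  separable, 0 means every sample's nearest neighbour is an
  opposite-class twin (exact copying).
* standard sleep-staging classification metrics: overall accuracy
  ACC = sum_c TP_c / N, one-vs-rest per-class F1, macro F1 (the
  unweighted mean of the five per-class F1 values), and Cohen's kappa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .signal import STAGES


@dataclass(frozen=True)
class TwoSampleResult:
    accuracy: float
    n_real: int
    n_generated: int
    stage: str | None = None


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, (list, tuple)) and x and hasattr(x[0], "samples"):
        x = [e.samples for e in x]
    return np.atleast_2d(np.asarray(x, dtype=np.float64))


def one_nn_two_sample(real, generated, stage: str | None = None) -> TwoSampleResult:
    """Leave-one-out 1-NN accuracy on the pooled real/generated sets.

    Distance ties are broken towards the smaller pooled index, which makes
    the result deterministic across platforms.  Accepts arrays or lists of
    epoch objects (their sample vectors are used).
    """
    xr, xg = _as_matrix(real), _as_matrix(generated)
    if xr.size == 0 or xg.size == 0:
        raise ValueError("both sample sets must be non-empty")
    if xr.shape[1] != xg.shape[1]:
        raise ValueError(f"epoch length mismatch: {xr.shape[1]} vs {xg.shape[1]}")
    pooled = np.vstack([xr, xg])
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 pooled samples")
    labels = np.concatenate([np.ones(len(xr)), np.zeros(len(xg))])
    d = cdist(pooled, pooled)
    np.fill_diagonal(d, np.inf)
    nearest = d.argmin(axis=1)  # argmin takes the first (smallest index) on ties
    acc = float((labels[nearest] == labels).mean())
    return TwoSampleResult(accuracy=acc, n_real=len(xr), n_generated=len(xg), stage=stage)


def per_stage_1nn_report(
    real_by_stage: dict,
    generated_by_stage: dict,
    n_trials: int = 10,
    n_per_side: int = 200,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Mean and variance of the two-sample accuracy per stage.

    Each trial resamples up to ``n_per_side`` epochs per side (without
    replacement when possible) and reruns the test.  Stages missing from
    either dictionary are reported absent (omitted), not as zero.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials to report a variance")
    rng = np.random.default_rng(seed)
    report: dict[str, dict[str, float]] = {}
    for stage in STAGES:
        if stage not in real_by_stage or stage not in generated_by_stage:
            continue
        if len(real_by_stage[stage]) == 0 or len(generated_by_stage[stage]) == 0:
            continue
        xr, xg = _as_matrix(real_by_stage[stage]), _as_matrix(generated_by_stage[stage])
        accs = []
        for _ in range(n_trials):
            ir = rng.choice(len(xr), size=min(n_per_side, len(xr)), replace=False)
            ig = rng.choice(len(xg), size=min(n_per_side, len(xg)), replace=False)
            accs.append(one_nn_two_sample(xr[ir], xg[ig], stage).accuracy)
        report[stage] = {
            "mean": float(np.mean(accs)),
            "variance": float(np.var(accs)),
            "n_trials": n_trials,
        }
    return report


def format_1nn_table(report: dict[str, dict[str, float]]) -> str:
    """Aligned text table, one column per stage (REM shown as R)."""
    cols = [s for s in STAGES if s in report]
    header = "Results   " + "  ".join(f"{('R' if c == 'REM' else c):>9}" for c in cols)
    mean_row = "Average   " + "  ".join(f"{report[c]['mean'] * 100:>8.2f}%" for c in cols)
    var_row = "Variance  " + "  ".join(f"{report[c]['variance']:>9.6f}" for c in cols)
    return "\n".join([header, mean_row, var_row])


# ------------------------------------------------------------ staging metrics
@dataclass(frozen=True)
class MetricReport:
    acc: float
    mf1: float
    kappa: float
    per_class_f1: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "ACC": self.acc,
            "MF1": self.mf1,
            "kappa": self.kappa,
            "F1": dict(self.per_class_f1),
        }


def confusion_matrix(y_true, y_pred) -> np.ndarray:
    """5x5 contingency table in canonical stage order."""
    idx = {s: i for i, s in enumerate(STAGES)}
    cm = np.zeros((5, 5), dtype=int)
    for t, p in zip(y_true, y_pred, strict=True):
        if t not in idx or p not in idx:
            bad = t if t not in idx else p
            raise ValueError(f"label {bad!r} outside the 5-stage alphabet")
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return cm


def classification_metrics(y_true, y_pred) -> MetricReport:
    """ACC, per-class one-vs-rest F1, macro F1 and Cohen's kappa.

    A stage absent from both truth and prediction has an undefined F1; it
    is excluded from the macro average with a warning.
    """
    cm = confusion_matrix(y_true, y_pred)
    n = cm.sum()
    acc = float(np.trace(cm) / n)

    f1: dict[str, float] = {}
    for c, stage in enumerate(STAGES):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        if tp + fp + fn == 0:
            warnings.warn(
                f"stage {stage} absent from both truth and prediction; "
                "excluded from the macro F1 average",
                stacklevel=2,
            )
            continue
        f1[stage] = float(2 * tp / (2 * tp + fp + fn))
    mf1 = float(np.mean(list(f1.values())))

    p_o = acc
    p_e = float((cm.sum(axis=0) / n * cm.sum(axis=1) / n).sum())
    kappa = 1.0 if p_e == 1.0 else float((p_o - p_e) / (1.0 - p_e))
    return MetricReport(acc=acc, mf1=mf1, kappa=kappa, per_class_f1=f1)


def format_metrics_table(report: MetricReport) -> str:
    cols = ["ACC", "MF1", "k"] + list(STAGES)
    vals = [report.acc, report.mf1, report.kappa] + [
        report.per_class_f1.get(s, float("nan")) for s in STAGES
    ]
    return (
        "  ".join(f"{c:>6}" for c in cols)
        + "\n"
        + "  ".join(f"{v:>6.3f}" for v in vals)
    )
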