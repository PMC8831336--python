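"""Evaluation statistics: multi-class classification metrics and BMD agreement.

Classification metrics are one-vs-rest per class (precision, sensitivity,
specificity, F1, rank-based ROC-AUC) with macro averaging by default.
Agreement statistics between paired BMD measurements follow the standard
Bland-Altman convention: mean difference, sample-SD limits of agreement
(mean +/- 1.96 * SD), RMSE, and a two-sided paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix, roc_auc_score

from .anatomy import PHASES
from .errors import StatisticsError, ValidationError


@dataclass
class ClassificationReport:
    """One-vs-rest metrics for a 3-class problem (rows of ``confusion`` = true)."""

    classes: tuple[str, ...]
    confusion: np.ndarray
    precision: dict[str, float]
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    f1: dict[str, float]
    auc: dict[str, float | None]
    accuracy: float
    macro_precision: float = np.nan
    macro_sensitivity: float = np.nan
    macro_specificity: float = np.nan
    macro_f1: float = np.nan
    macro_auc: float = np.nan

    def as_rows(self) -> list[dict]:
        rows = []
        for m in ("precision", "sensitivity", "specificity", "f1", "auc"):
            d = getattr(self, m)
            for c in self.classes:
                v = d[c]
                rows.append({"metric": f"{m}_{c}", "value": np.nan if v is None else v})
            rows.append({"metric": f"macro_{m}", "value": getattr(self, f"macro_{m}")})
        rows.append({"metric": "accuracy", "value": self.accuracy})
        return rows


class PairedT(NamedTuple):
    t: float
    p: float
    degenerate: bool


@dataclass
class AgreementReport:
    """Paired agreement between a test and a reference BMD series."""

    n: int
    rmse: float  # mg/ml
    mean_difference: float  # mg/ml, mean(test - reference)
    sd_difference: float  # sample SD of differences
    loa_low: float
    loa_high: float
    t: float
    p: float
    degenerate: bool = False


def _zero_div(num: float, den: float) -> float:
    return float(num / den) if den > 0 else 0.0


def classification_report(
    y_true, y_pred, y_prob=None, classes: tuple[str, ...] = PHASES
) -> ClassificationReport:
    """One-vs-rest metrics with macro averages over classes present in y_true.

    ``y_prob`` (n, len(classes)) enables per-class ROC-AUC; a class absent
    from ``y_true`` gets AUC None and is skipped by the macro AUC.
    """
    y_true = np.asarray(list(y_true))
    y_pred = np.asarray(list(y_pred))
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    for arr in (y_true, y_pred):
        bad = set(arr.tolist()) - set(classes)
        if bad:
            raise ValidationError(f"labels {bad} outside classes {classes}")
    cm = confusion_matrix(y_true, y_pred, labels=list(classes)).astype(int)
    n = int(cm.sum())
    precision, sensitivity, specificity, f1, auc = {}, {}, {}, {}, {}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        tn = n - tp - fp - fn
        precision[c] = _zero_div(tp, tp + fp)
        sensitivity[c] = _zero_div(tp, tp + fn)
        specificity[c] = _zero_div(tn, tn + fp)
        f1[c] = _zero_div(2 * tp, 2 * tp + fp + fn)
        auc[c] = None
        if y_prob is not None:
            yb = (y_true == c).astype(int)
            if 0 < yb.sum() < len(yb):
                auc[c] = float(roc_auc_score(yb, np.asarray(y_prob)[:, i]))
    present = [c for i, c in enumerate(classes) if cm[i, :].sum() > 0]
    rep = ClassificationReport(
        classes=tuple(classes),
        confusion=cm,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        auc=auc,
        accuracy=_zero_div(np.trace(cm), n),
    )
    rep.macro_precision = float(np.mean([precision[c] for c in present]))
    rep.macro_sensitivity = float(np.mean([sensitivity[c] for c in present]))
    rep.macro_specificity = float(np.mean([specificity[c] for c in present]))
    rep.macro_f1 = float(np.mean([f1[c] for c in present]))
    defined = [auc[c] for c in present if auc[c] is not None]
    rep.macro_auc = float(np.mean(defined)) if defined else np.nan
    return rep


def paired_t(differences) -> PairedT:
    """Two-sided paired t-test on a vector of paired differences.

    t = mean / (SD / sqrt(n)) with sample SD, df = n - 1. Zero-variance
    differences are flagged degenerate (p = 1 when the mean is also zero,
    else p = 0).
    """
    d = np.asarray(list(differences), dtype=float)
    if d.size < 2:
        raise StatisticsError("paired t-test needs at least 2 differences")
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        mean = float(d.mean())
        return PairedT(t=np.nan, p=1.0 if mean == 0.0 else 0.0, degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(d.size)))
    p = float(2.0 * stats.t.sf(abs(t), df=d.size - 1))
    return PairedT(t=t, p=p, degenerate=False)


def agreement_report(reference_bmd, test_bmd) -> AgreementReport:
    """RMSE, Bland-Altman mean difference and limits, and paired t-test.

    Differences are test - reference; limits of agreement use the sample-SD
    (n-1) convention: mean +/- 1.96 * SD.
    """
    ref = np.asarray(list(reference_bmd), dtype=float)
    test = np.asarray(list(test_bmd), dtype=float)
    if ref.shape != test.shape:
        raise StatisticsError("reference and test series must be paired (equal length)")
    if ref.size < 2:
        raise StatisticsError("agreement statistics need >= 2 pairs")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(test))):
        raise StatisticsError("BMD series contain non-finite values")
    diff = test - ref
    rmse = float(np.sqrt(np.mean(diff**2)))
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    tt = paired_t(diff)
    return AgreementReport(
        n=ref.size,
        rmse=rmse,
        mean_difference=md,
        sd_difference=sd,
        loa_low=md - 1.96 * sd,
        loa_high=md + 1.96 * sd,
        t=tt.t,
        p=tt.p,
        degenerate=tt.degenerate,
    )


# ---------------------------------------------------------------------------
# plots (optional outputs; Agg backend, file targets only)
# ---------------------------------------------------------------------------

def roc_plot(y_true, y_prob, path, classes: tuple[str, ...] = PHASES) -> None:
    """One-vs-rest ROC curves for each class, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    y_true = np.asarray(list(y_true))
    y_prob = np.asarray(y_prob)
    fig, ax = plt.subplots(figsize=(5, 5))
    for i, c in enumerate(classes):
        yb = (y_true == c).astype(int)
        if 0 < yb.sum() < len(yb):
            fpr, tpr, _ = roc_curve(yb, y_prob[:, i])
            ax.plot(fpr, tpr, label=f"{c} (AUC {roc_auc_score(yb, y_prob[:, i]):.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bland_altman_plot(reference_bmd, test_bmd, path, title: str = "") -> None:
    """Bland-Altman scatter (mean vs difference) with mean and 1.96-SD lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = agreement_report(reference_bmd, test_bmd)
    ref = np.asarray(list(reference_bmd), dtype=float)
    test = np.asarray(list(test_bmd), dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((ref + test) / 2.0, test - ref, s=14, alpha=0.7)
    ax.axhline(rep.mean_difference, color="k")
    ax.axhline(rep.loa_low, color="k", ls="--")
    ax.axhline(rep.loa_high, color="k", ls="--")
    ax.set_xlabel("mean BMD (mg/ml)")
    ax.set_ylabel("difference (mg/ml)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
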