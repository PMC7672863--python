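"""Diagnostic evaluation of the binary classifier.

Confusion matrix and its derived metrics (accuracy, sensitivity,
specificity, PPV, NPV, misclassification rate), the two-sided Fisher exact
test of association, the ROC curve over all score cut-offs with the
Mann-Whitney AUC (ties count one half), a stratified nonparametric
bootstrap percentile confidence interval for the AUC, and the
Youden-optimal cut-off.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.stats import fisher_exact

from .classify import ClassificationRecord

__all__ = [
    "ConfusionMatrix2x2",
    "MetricsReport",
    "RocResult",
    "confusion_matrix",
    "metrics",
    "roc_curve",
    "bootstrap_auc_ci",
    "write_report",
]


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts by (true, predicted) with a declared positive label."""

    tp: int
    fn: int
    fp: int
    tn: int
    positive_label: str

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    misclassification_rate: float
    fisher_p: float
    positive_label: str


@dataclass(frozen=True)
class RocResult:
    points: list[tuple[float, float, float]]   # (fpr, tpr, threshold)
    auc: float
    auc_ci: tuple[float, float] | None
    best_cutoff: float
    best_sensitivity: float
    best_specificity: float
    cutoff_criterion: str = "youden"


def confusion_matrix(
    records: list[ClassificationRecord], positive_label: str
) -> ConfusionMatrix2x2:
    """Tally (true, predicted) counts; the other observed label is negative."""
    if not records:
        raise ValueError("no classification records")
    labels = sorted({r.true_label for r in records} | {r.predicted_label for r in records})
    if positive_label not in labels:
        raise ValueError(f"positive label {positive_label!r} not among {labels}")
    others = [lab for lab in labels if lab != positive_label]
    if len(others) != 1:
        raise ValueError(f"expected binary labels, got {labels}")
    tp = sum(r.true_label == positive_label and r.predicted_label == positive_label
             for r in records)
    fn = sum(r.true_label == positive_label and r.predicted_label != positive_label
             for r in records)
    fp = sum(r.true_label != positive_label and r.predicted_label == positive_label
             for r in records)
    tn = sum(r.true_label != positive_label and r.predicted_label != positive_label
             for r in records)
    return ConfusionMatrix2x2(tp=tp, fn=fn, fp=fp, tn=tn,
                              positive_label=positive_label)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def metrics(cm: ConfusionMatrix2x2) -> MetricsReport:
    """Diagnostic metrics and two-sided Fisher exact p from a 2x2 table.

    Zero-denominator metrics are reported as NaN (undefined) while the
    others are still computed.  The Fisher p sums the hypergeometric
    probabilities, at fixed margins, of all tables no more probable than
    the observed one (the standard two-sided convention).
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.n
    p = fisher_exact([[cm.tp, cm.fp], [cm.fn, cm.tn]], alternative="two-sided")[1]
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        misclassification_rate=1.0 - accuracy,
        fisher_p=float(p),
        positive_label=cm.positive_label,
    )


def _scores_by_class(records, positive_label):
    pos = np.array([r.score_a for r in records if r.true_label == positive_label])
    neg = np.array([r.score_a for r in records if r.true_label != positive_label])
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present for ROC analysis")
    return pos, neg


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie), computed from all pairs."""
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def roc_curve(
    records: list[ClassificationRecord],
    positive_label: str,
    ci: tuple[float, float] | None = None,
) -> RocResult:
    """ROC over all distinct score cut-offs, AUC, and the Youden cut-off.

    A subject is called positive when its score is >= the threshold, the
    same tie rule the classifier uses.  Thresholds run through every
    distinct score plus sentinels below and above all scores; the best
    cut-off maximizes Youden's J = sensitivity + specificity - 1 and is
    reported as the midpoint between adjacent distinct scores (matching
    common ROC-package conventions).
    """
    pos, neg = _scores_by_class(records, positive_label)
    scores = np.concatenate([pos, neg])
    distinct = np.unique(scores)
    # sentinel thresholds: everything positive / nothing positive
    thresholds = np.concatenate([[-np.inf], distinct, [np.inf]])
    points = []
    best = None
    for i, th in enumerate(thresholds):
        tpr = float((pos >= th).mean())
        fpr = float((neg >= th).mean())
        points.append((fpr, tpr, float(th)))
        j = tpr - fpr
        if best is None or j > best[0] + 1e-12:
            if np.isinf(th):
                cut = float(th)
            elif i >= 2 and not np.isinf(thresholds[i - 1]):
                cut = float((th + thresholds[i - 1]) / 2.0)
            else:
                cut = float(th)
            best = (j, cut, tpr, 1.0 - fpr)
    points.sort(key=lambda p: (p[0], p[1]))
    auc = _auc_mann_whitney(pos, neg)
    return RocResult(
        points=points,
        auc=auc,
        auc_ci=ci,
        best_cutoff=best[1],
        best_sensitivity=best[2],
        best_specificity=best[3],
    )


def bootstrap_auc_ci(
    records: list[ClassificationRecord],
    positive_label: str,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the AUC.

    Subjects are resampled with replacement within each class (class sizes
    preserved), the AUC recomputed per replicate, and the percentile
    interval at ``level`` returned.  Degenerate one-class resamples cannot
    occur under stratification; a resample where one class is all-tied is
    still a valid AUC.
    """
    pos, neg = _scores_by_class(records, positive_label)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs >= 2 members for the bootstrap")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = pos[rng.integers(0, len(pos), len(pos))]
        n = neg[rng.integers(0, len(neg), len(neg))]
        aucs[b] = _auc_mann_whitney(p, n)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(low), float(high)


def write_report(
    report: MetricsReport,
    roc: RocResult,
    outdir,
    cutoff_provenance: str = "default 0.5",
) -> dict[str, Path]:
    """Serialize the evaluation: JSON report, ROC CSV, ROC curve PNG."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": outdir / "report.json",
        "roc_csv": outdir / "roc_points.csv",
        "roc_png": outdir / "roc_curve.png",
    }
    doc = {
        "metrics": asdict(report),
        "roc": {
            "auc": roc.auc,
            "auc_ci": list(roc.auc_ci) if roc.auc_ci else None,
            "best_cutoff": roc.best_cutoff,
            "best_sensitivity": roc.best_sensitivity,
            "best_specificity": roc.best_specificity,
            "cutoff_criterion": roc.cutoff_criterion,
        },
        "cutoff_provenance": cutoff_provenance,
    }
    with open(paths["json"], "w") as fh:
        json.dump(doc, fh, indent=2, allow_nan=True)
    with open(paths["roc_csv"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fpr", "tpr", "threshold"])
        for fpr, tpr, th in roc.points:
            writer.writerow([fpr, tpr, th])
    _plot_roc(roc, paths["roc_png"])
    return paths


def _plot_roc(roc: RocResult, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = [p[0] for p in roc.points]
    tpr = [p[1] for p in roc.points]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, tpr, color="tab:blue", lw=2,
            label=f"AUC = {roc.auc:.3f}")
    if roc.auc_ci:
        ax.fill_between(fpr, 0, tpr, color="tab:blue", alpha=0.12,
                        label=f"95% CI {roc.auc_ci[0]:.3f}-{roc.auc_ci[1]:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.plot(1.0 - roc.best_specificity, roc.best_sensitivity, "+", ms=14,
            color="tab:blue",
            label=f"best cut-off {roc.best_cutoff:.3f}")
    ax.set_xlabel("false positive rate (1 - specificity)")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
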