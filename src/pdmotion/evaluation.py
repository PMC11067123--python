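"""Held-out evaluation: point metrics, ROC, and bootstrap confidence intervals.

The confusion matrix is computed at a fixed operating point of 0.5 on the
positive-class probability.  Confidence intervals come from 100 bootstrap
resamples of the validation set (sampling rows with replacement, each
resample the size of the original set); percentile 2.5/97.5 bounds are
reported, and resamples whose label draw makes a metric undefined are
skipped for that metric with a logged count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

OPERATING_POINT = 0.5


@dataclass
class EvalReport:
    """Point metrics, confusion matrix, ROC and bootstrap CIs for one model."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    auroc: float                      # NaN when labels are single-class
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    n_validation: int
    bootstrap: dict[str, dict[str, float]] = field(default_factory=dict)
    n_boot: int = 0
    n_degenerate_resamples: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roc_fpr"] = np.asarray(self.roc_fpr).tolist()
        d["roc_tpr"] = np.asarray(self.roc_tpr).tolist()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, allow_nan=True)


def _confusion(prob: np.ndarray, labels: np.ndarray) -> tuple[int, int, int, int]:
    pred = prob >= OPERATING_POINT
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return tp, fp, fn, tn


def _prf(tp: int, fp: int, fn: int, warn: bool = False) -> tuple[float, float, float]:
    """Precision, recall, F1 with zero denominators mapped to 0 (logged)."""
    if tp + fp == 0:
        if warn:
            logger.warning("no predicted positives; precision set to 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        if warn:
            logger.warning("no positive labels; recall set to 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def compute_metrics(prob: np.ndarray, labels: np.ndarray) -> EvalReport:
    """Point metrics at the 0.5 operating point plus the ROC curve.

    AUROC uses trapezoidal integration with midrank tie handling; it is
    reported as NaN when only one class is present.
    """
    prob = np.asarray(prob, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    tp, fp, fn, tn = _confusion(prob, labels)
    precision, recall, f1 = _prf(tp, fp, fn, warn=True)
    if len(np.unique(labels)) < 2:
        logger.warning("single-class labels; AUROC undefined")
        auroc = float("nan")
        fpr = tpr = np.array([])
    else:
        auroc = float(roc_auc_score(labels, prob))
        fpr, tpr, _ = roc_curve(labels, prob)
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=precision, recall=recall, f1=f1, auroc=auroc,
        roc_fpr=fpr, roc_tpr=tpr, n_validation=len(labels),
    )


def bootstrap_intervals(
    prob: np.ndarray, labels: np.ndarray, n_boot: int = 100, seed: int = 0
) -> tuple[dict[str, dict[str, float]], int]:
    """Bootstrap mean and percentile 95% CI for precision, recall and F1.

    Returns (intervals, n_degenerate) where ``intervals`` maps metric →
    {mean, ci_lower, ci_upper} and ``n_degenerate`` counts resamples in
    which at least one metric was undefined and skipped.
    """
    prob = np.asarray(prob, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(labels) == 0:
        raise ValueError("empty validation set")
    rng = np.random.default_rng(seed)
    n = len(labels)
    samples = {"precision": [], "recall": [], "f1": []}
    n_degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        tp, fp, fn, _ = _confusion(prob[idx], labels[idx])
        p = tp / (tp + fp) if tp + fp else float("nan")
        r = tp / (tp + fn) if tp + fn else float("nan")
        f = (
            2 * p * r / (p + r)
            if np.isfinite(p) and np.isfinite(r) and (p + r) > 0
            else (0.0 if np.isfinite(p) and np.isfinite(r) else float("nan"))
        )
        if not (np.isfinite(p) and np.isfinite(r) and np.isfinite(f)):
            n_degenerate += 1
        samples["precision"].append(p)
        samples["recall"].append(r)
        samples["f1"].append(f)
    if n_degenerate:
        logger.info("skipped undefined metrics in %d of %d resamples", n_degenerate, n_boot)
    out = {}
    for metric, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        if np.all(np.isnan(arr)):
            out[metric] = {"mean": float("nan"), "ci_lower": float("nan"), "ci_upper": float("nan")}
            continue
        out[metric] = {
            "mean": float(np.nanmean(arr)),
            "ci_lower": float(np.nanpercentile(arr, 2.5)),
            "ci_upper": float(np.nanpercentile(arr, 97.5)),
        }
    return out, n_degenerate


def evaluate_pipeline(pipeline, validation, n_boot: int = 100, seed: int = 0) -> EvalReport:
    """Score a fitted pipeline on a held-out FeatureTable, with bootstrap CIs."""
    prob = pipeline.predict_proba(validation.features)
    labels = validation.labels.to_numpy()
    report = compute_metrics(prob, labels)
    report.bootstrap, report.n_degenerate_resamples = bootstrap_intervals(
        prob, labels, n_boot=n_boot, seed=seed
    )
    report.n_boot = n_boot
    return report


def plot_report(report: EvalReport, path) -> None:
    """ROC curve and confusion matrix, side by side."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_roc, ax_cm) = plt.subplots(1, 2, figsize=(9, 4))
    if len(np.asarray(report.roc_fpr)):
        ax_roc.plot(report.roc_fpr, report.roc_tpr, label=f"AUROC = {report.auroc:.2f}")
    ax_roc.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax_roc.set_xlabel("False positive rate")
    ax_roc.set_ylabel("True positive rate")
    ax_roc.legend(loc="lower right")
    cm = np.array([[report.tn, report.fp], [report.fn, report.tp]])
    ax_cm.imshow(cm, cmap="Blues")
    for (i, j), v in np.ndenumerate(cm):
        ax_cm.text(j, i, str(v), ha="center", va="center")
    ax_cm.set_xticks([0, 1], ["pred 0", "pred 1"])
    ax_cm.set_yticks([0, 1], ["true 0", "true 1"])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
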