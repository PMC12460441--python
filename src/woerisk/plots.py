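"""Optional diagnostic plots (ROC, precision-recall, score box plots,
reliability diagram) written straight to files; nothing here feeds back into
the analysis."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import EvaluationReport


def save_report_plots(report: EvaluationReport, logits, labels, out_dir) -> list:
    """Write roc.png, pr.png, scores.png and calibration.png; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.roc["fpr"], report.roc["tpr"], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set(xlabel="false-positive rate", ylabel="true-positive rate",
           title=f"ROC (AUC = {report.auc:.2f})")
    paths.append(_save(fig, out_dir / "roc.png"))

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.pr["recall"], report.pr["precision"], drawstyle="steps-post")
    ax.set(xlabel="recall", ylabel="precision",
           title=f"Precision-recall (AP = {report.average_precision:.2f})")
    paths.append(_save(fig, out_dir / "pr.png"))

    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=int)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot([logits[labels == 0], logits[labels == 1]],
               tick_labels=["no event", "event"])
    ax.set(ylabel="logit score",
           title=f"Group comparison (p = {report.group_p_value:.3g})")
    paths.append(_save(fig, out_dir / "scores.png"))

    cal = [row for row in report.calibration if row["count"] > 0]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([r["mean_predicted"] for r in cal], [r["observed_rate"] for r in cal],
            "o-")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set(xlabel="mean predicted probability", ylabel="observed event rate",
           title="Reliability")
    paths.append(_save(fig, out_dir / "calibration.png"))
    return paths


def _save(fig, path: Path) -> Path:
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
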