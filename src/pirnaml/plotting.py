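"""Static plots for evaluation reports: ROC/PR curves and accuracy bars.

matplotlib is imported lazily so headless pipeline runs never pay for it.
"""

from __future__ import annotations


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    _, ax = plt.subplots(figsize=(4.5, 4))
    return ax


def plot_roc(report, ax=None, label=None):
    """ROC curve of an :class:`~pirnaml.evaluation.EvaluationReport`."""
    ax = _axes(ax)
    fpr = [p[0] for p in report.roc.points]
    tpr = [p[1] for p in report.roc.points]
    name = label or (report.classifier.name if report.classifier else "model")
    ax.plot(fpr, tpr, label=f"{name} (AUC={report.roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    return ax


def plot_pr(report, ax=None, label=None):
    """Precision-recall curve with its step-interpolated area."""
    ax = _axes(ax)
    recall = [p[0] for p in report.pr.points]
    precision = [p[1] for p in report.pr.points]
    name = label or (report.classifier.name if report.classifier else "model")
    ax.plot(recall, precision, drawstyle="steps-post",
            label=f"{name} (AUPRC={report.pr.auprc:.3f})")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower left")
    return ax


def plot_rates(rates: dict, ax=None, ylabel="accuracy / positive rate"):
    """Bar chart comparing named rates (CV accuracies, positive rates)."""
    ax = _axes(ax)
    names = list(rates)
    ax.bar(names, [rates[n] for n in names], color="#4878a8")
    ax.set_ylim(0, 1.0)
    ax.set_ylabel(ylabel)
    for tick in ax.get_xticklabels():
        tick.set_rotation(30)
        tick.set_ha("right")
    return ax
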