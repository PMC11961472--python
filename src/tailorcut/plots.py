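"""ROC-curve and distribution-with-cutoff plots for a study report."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .pipeline import DecisionReport, _distributions_from_table  # noqa: E402
from .roc_cutoffs import roc_curve  # noqa: E402

__all__ = ["plot_roc", "plot_distributions", "plot_study", "replot_results_dir"]


def plot_roc(report: DecisionReport, h1_label: str, path: Path) -> None:
    """Overlaid ROC curves of all indices for one H0-vs-H1 contrast."""
    cfg = report.config
    dists = _distributions_from_table(report.replicates, h1_label,
                                      cfg.indices, cfg.drop_improper)
    fig, ax = plt.subplots(figsize=(5, 5))
    styles = ["-", "--", "-.", ":"]
    for k, d in enumerate(dists):
        c = roc_curve(d)
        ax.plot(c.points[:, 0], c.points[:, 1], styles[k % len(styles)],
                label=f"{d.index_name} (AUC = {c.auc:.2f})")
    ax.plot([0, 1], [0, 1], color="0.8", lw=0.8)
    ax.set_xlabel("false-positive rate (1 - specificity)")
    ax.set_ylabel("true-positive rate (sensitivity)")
    ax.set_title(f"H0 vs {h1_label}")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_distributions(report: DecisionReport, h1_label: str,
                       outdir: Path) -> None:
    """Per-index overlaid H0/H1 histograms with the tailored cutoff marked."""
    cfg = report.config
    dists = {d.index_name: d for d in _distributions_from_table(
        report.replicates, h1_label, cfg.indices, cfg.drop_improper)}
    for rep in report.cutoff_reports[h1_label]:
        d = dists[rep.index_name]
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.hist(d.h0_values, bins=40, alpha=0.55, color="0.7",
                label="correctly specified (H0)")
        ax.hist(d.h1_values, bins=40, alpha=0.55, color="0.35",
                label=f"misspecified ({h1_label})")
        if not rep.flagged:
            ax.axvline(rep.cutoff, color="black", ls="--", lw=1.2,
                       label=f"cutoff {rep.comparator} {rep.cutoff:.3g}")
        ax.set_xlabel(rep.index_name)
        ax.set_ylabel("replicates")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / f"dist_{rep.index_name}_{h1_label}.png", dpi=150)
        plt.close(fig)


def plot_study(report: DecisionReport, outdir) -> None:
    outdir = Path(outdir)
    for label in report.config.h1_labels:
        plot_roc(report, label, outdir / f"roc_{label}.png")
        plot_distributions(report, label, outdir)


def replot_results_dir(table, cutoffs: dict, outdir) -> None:
    """Rebuild plots from a saved replicates table and cutoffs mapping."""
    from .fit_indices import INDEX_DIRECTIONS
    from .roc_cutoffs import IndexDistributions

    outdir = Path(outdir)
    keep = table["converged"].astype(bool)
    h0 = table[(table["population"] == "H0") & keep]
    for label, reports in cutoffs.items():
        h1 = table[(table["population"] == label) & keep]
        fig, ax = plt.subplots(figsize=(5, 5))
        styles = ["-", "--", "-.", ":"]
        for k, rep in enumerate(reports):
            name = rep["index_name"]
            d = IndexDistributions(h0[name].to_numpy(), h1[name].to_numpy(),
                                   INDEX_DIRECTIONS[name], name)
            c = roc_curve(d)
            ax.plot(c.points[:, 0], c.points[:, 1], styles[k % len(styles)],
                    label=f"{name} (AUC = {c.auc:.2f})")
            figd, axd = plt.subplots(figsize=(5, 3.2))
            axd.hist(d.h0_values, bins=40, alpha=0.55, color="0.7",
                     label="correctly specified (H0)")
            axd.hist(d.h1_values, bins=40, alpha=0.55, color="0.35",
                     label=f"misspecified ({label})")
            if not rep.get("flagged"):
                axd.axvline(rep["cutoff"], color="black", ls="--", lw=1.2,
                            label=f"cutoff {rep['comparator']} {rep['cutoff']:.3g}")
            axd.set_xlabel(name)
            axd.set_ylabel("replicates")
            axd.legend(fontsize=7)
            figd.tight_layout()
            figd.savefig(outdir / f"dist_{name}_{label}.png", dpi=150)
            plt.close(figd)
        ax.plot([0, 1], [0, 1], color="0.8", lw=0.8)
        ax.set_xlabel("false-positive rate (1 - specificity)")
        ax.set_ylabel("true-positive rate (sensitivity)")
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / f"roc_{label}.png", dpi=150)
        plt.close(fig)
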