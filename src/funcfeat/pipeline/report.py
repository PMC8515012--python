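"""Summary tables and figures from completed run artifacts.

Emits four figures (MI-vs-redundancy scatter, re-prediction/SRF
correlation scatter, humanness/veridicality scatter, diagnostic vs
non-diagnostic accuracy bars) and four TSV tables with the same numbers.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["report", "missing_artifacts"]

REQUIRED = [
    "evaluate/info_results.tsv",
    "evaluate/srf_results.tsv",
    "revcor/template_metrics.tsv",
    "generalize/identification.tsv",
]


def missing_artifacts(run_dir) -> list[str]:
    run_dir = Path(run_dir)
    return [r for r in REQUIRED if not (run_dir / r).exists()]


def report(run_dir) -> Path:
    run_dir = Path(run_dir)
    missing = missing_artifacts(run_dir)
    if missing:
        raise FileNotFoundError(f"incomplete run; missing artifacts: {missing}")
    out = run_dir / "report"
    out.mkdir(parents=True, exist_ok=True)

    info = pd.read_csv(run_dir / "evaluate" / "info_results.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(5, 4))
    for space, grp in info.groupby("space"):
        ax.scatter(grp["redundancy_bits"], grp["mi_bits"], s=12, label=space, alpha=0.6)
    ax.set_xlabel("redundancy with shape predictions (bits)")
    ax.set_ylabel("MI with observed ratings (bits)")
    ax.legend(fontsize=7)
    fig.savefig(out / "mi_redundancy.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    summary = info.groupby("space")[["mi_bits", "redundancy_bits", "exceeds"]].mean().reset_index()
    summary.to_csv(out / "mi_redundancy.tsv", sep="\t", index=False)

    srf = pd.read_csv(run_dir / "evaluate" / "srf_results.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(5, 4))
    if len(srf):
        for space, grp in srf.groupby("space"):
            ax.scatter(grp["pred_corr"], grp["srf_corr"], s=12, label=space, alpha=0.6)
        ax.legend(fontsize=7)
    ax.set_xlabel("corr(original, simulated predictions)")
    ax.set_ylabel("corr(shape SRF, simulated SRF)")
    fig.savefig(out / "srf_correlations.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    (srf.groupby("space")[["pred_corr", "srf_corr"]].median().reset_index() if len(srf) else srf).to_csv(
        out / "srf_correlations.tsv", sep="\t", index=False)

    tm = pd.read_csv(run_dir / "revcor" / "template_metrics.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(5, 4))
    for system, grp in tm.groupby("system"):
        ax.scatter(grp["r_humanness"], grp["mae_humanness"], s=12, label=system, alpha=0.6)
    ax.set_xlabel("inward-outward correlation with observer template")
    ax.set_ylabel("template MAE")
    ax.legend(fontsize=7)
    fig.savefig(out / "humanness_veridicality.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    tm.groupby("system")[["mae_humanness", "r_humanness", "mae_veridicality", "r_veridicality"]].median().reset_index().to_csv(
        out / "humanness_veridicality.tsv", sep="\t", index=False)

    ident = pd.read_csv(run_dir / "generalize" / "identification.tsv", sep="\t")
    acc = ident.groupby(["condition", "diagnosticity"])["accuracy"].mean().unstack()
    diff = (acc["D"] - acc["N"]).rename("accuracy_diff").reset_index()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(diff["condition"], diff["accuracy_diff"])
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("accuracy (diagnostic - non-diagnostic)")
    ax.tick_params(axis="x", rotation=45)
    fig.savefig(out / "generalization_accuracy.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    diff.to_csv(out / "generalization_accuracy.tsv", sep="\t", index=False)
    return out
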