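"""Report formatting and figures: prevalence tables, comparison tables, histograms."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import ComparisonReport, TrialEnsemble, scaled_differences


def format_prevalence_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Render a prevalence summary as mean-percent (SD) strings per arm."""

    def cell(mean: float, sd: float) -> str:
        return f"{mean:.1f}% ({sd:.1f}%)"

    out = summary[["variable", "subcategory", "input_count"]].copy()
    out["input_prevalence"] = summary["input_prevalence_pct"].map(lambda v: f"{v:.1f}%")
    out["open_prevalence"] = [
        cell(m, s) for m, s in zip(summary["open_mean_pct"], summary["open_sd_pct"])
    ]
    out["sequestered_prevalence"] = [
        cell(m, s)
        for m, s in zip(summary["sequestered_mean_pct"], summary["sequestered_sd_pct"])
    ]
    return out


def format_p_value(p: float, holm_significant: bool = False, floor: float = 0.01) -> str:
    """Comparison-table p-value style: N/A for untestable, floored below 0.01."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "N/A"
    text = f"p < {floor:.2f}" if p < floor else f"p = {p:.2f}"
    return text + (" **" if holm_significant else "")


def format_comparison_table(report: ComparisonReport) -> pd.DataFrame:
    df = report.table
    out = df[["variable", "subcategory", "input_count"]].copy()
    out["mann_whitney_result"] = [
        format_p_value(p, sig)
        for p, sig in zip(df["p_value"], df["significant_holm"])
    ]
    return out


def write_report_csv(
    df: pd.DataFrame, path: str | Path, master_seed: int, n_trials: int,
    extra: Sequence[str] = (),
) -> None:
    """Write a report CSV with a provenance header comment (seed, trial count)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# master_seed={master_seed} n_trials={n_trials}\n")
        for line in extra:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_report_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def histogram_report(
    ensembles: tuple[TrialEnsemble, TrialEnsemble],
    variable: str,
    out_dir: str | Path,
    arm: str = "open",
    fmt: str = "png",
) -> Path:
    """Overlaid per-subcategory histograms of scaled difference for one variable.

    One figure per variable; within each subcategory panel the two samplers
    share Freedman-Diaconis bins computed on the pooled samples, so a narrower
    histogram directly indicates better balance.  Returns the figure path.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ens_strat, ens_naive = ensembles
    if ens_strat.subcategories != ens_naive.subcategories:
        raise ValueError("ensembles were not computed on the same scheme")
    cols = [
        (j, cat) for j, (var, cat) in enumerate(ens_strat.subcategories)
        if var == variable
    ]
    if not cols:
        raise KeyError(f"no variable {variable!r} in the ensembles")
    d_strat = scaled_differences(ens_strat, arm)
    d_naive = scaled_differences(ens_naive, arm)

    ncols = min(3, len(cols))
    nrows = -(-len(cols) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.2 * ncols, 3.2 * nrows),
                             squeeze=False)
    for ax in axes.flat[len(cols):]:
        ax.set_visible(False)
    for ax, (j, cat) in zip(axes.flat, cols):
        xs = d_strat[:, j]
        xn = d_naive[:, j]
        if np.all(np.isnan(xs)):
            ax.set_title(f"{cat} (N/A)")
            continue
        pooled = np.concatenate([xs, xn])
        if np.ptp(pooled) == 0:
            edges = np.array([pooled[0] - 0.5, pooled[0] + 0.5])
        else:
            edges = np.histogram_bin_edges(pooled, bins="fd")
        ax.hist(xn, bins=edges, alpha=0.55, label="naive", color="tab:blue")
        ax.hist(xs, bins=edges, alpha=0.55, label="stratified", color="tab:orange")
        ax.set_title(cat, fontsize=9)
        ax.set_xlabel("scaled difference from expectation", fontsize=8)
        ax.legend(fontsize=7)
    fig.suptitle(f"{variable} — {arm} arm, {ens_strat.n_trials} trials")
    fig.tight_layout()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"scaled_difference_{variable}.{fmt}"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
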