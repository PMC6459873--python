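"""Figure-style outputs: difference plots, uptake curves, butterfly plots.

Figures are conveniences; every figure has a sibling machine-readable table
with identical numbers, and table-only (headless) operation is the default.
Display rounding is 2 decimals in deuteron units; tables keep full
precision.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import get_logger
from .differential import ComparisonResult

log = get_logger(__name__)


def _agg_backend():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def difference_table(comparison: ComparisonResult) -> pd.DataFrame:
    """The per-peptide x time difference table underlying the figure."""
    return comparison.table()


def render_difference_plot(
    comparison: ComparisonResult,
    table_path: str | Path,
    figure_path: str | Path | None = None,
    ex1_peptides: set[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Write the difference table and, optionally, the difference figure.

    The figure shows per-peptide dD grouped by time point in N- to
    C-terminal order with the +/-CI band as dotted horizontal lines; EX1
    peptides are annotated. An empty comparison yields a header-only table.
    """
    table = difference_table(comparison)
    Path(table_path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(table_path, index=False)

    if figure_path is not None and not table.empty:
        plt = _agg_backend()
        fig, ax = plt.subplots(figsize=(12, 4))
        keys = sorted(comparison.profiles)
        index = {key: i + 1 for i, key in enumerate(keys)}
        times = sorted(table["exposure_min"].unique())
        cmap = plt.get_cmap("viridis", len(times))
        for j, t in enumerate(times):
            sub = table[table["exposure_min"] == t]
            x = [index[(s, e, q)] for s, e, q in zip(sub["start"], sub["end"], sub["sequence"])]
            ax.plot(x, sub["delta_D"], ".", color=cmap(j), label=f"{t:g} min", ms=4)
        ci = comparison.ci.ci
        ax.axhline(ci, ls=":", color="k")
        ax.axhline(-ci, ls=":", color="k")
        ax.axhline(0, lw=0.5, color="k")
        for key, i in index.items():
            if ex1_peptides and (key[0], key[1]) in ex1_peptides:
                ax.annotate("EX1", (i, ax.get_ylim()[1] * 0.9), ha="center", fontsize=7)
        ax.set_xlabel("peptide (N- to C-terminal)")
        ax.set_ylabel(r"$\Delta$D (D)")
        ax.set_title(
            f"{comparison.state_ref} vs {comparison.state_test} "
            f"(CI = {ci:.2f} D)"
        )
        ax.legend(fontsize=7, ncol=len(times))
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return table


def render_uptake_curves(
    summary: pd.DataFrame,
    table_path: str | Path,
    figure_path: str | Path | None = None,
    peptides: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Write the uptake-curve table (mean/SD/n per peptide, state, time) and
    optionally a small grid of uptake-vs-time panels for selected peptides."""
    summary = summary.sort_values(["start", "end", "state", "exposure_min"])
    Path(table_path).parent.mkdir(parents=True, exist_ok=True)
    summary.to_csv(table_path, index=False)

    if figure_path is not None and not summary.empty:
        plt = _agg_backend()
        wanted = peptides or [
            tuple(x) for x in summary[["start", "end"]].drop_duplicates().to_numpy()[:6]
        ]
        ncol = min(3, len(wanted))
        nrow = (len(wanted) + ncol - 1) // ncol
        fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
        for ax, (start, end) in zip(axes.ravel(), wanted):
            sub = summary[(summary["start"] == start) & (summary["end"] == end)]
            for state, s in sub.groupby("state"):
                ax.errorbar(
                    s["exposure_min"], s["mean_D"], yerr=s["sd_D"], marker="o", ms=3, label=state
                )
            ax.set_xscale("log")
            ax.set_title(f"{start}-{end}", fontsize=9)
            ax.set_xlabel("time (min)")
            ax.set_ylabel("uptake (D)")
            ax.legend(fontsize=7)
        for ax in axes.ravel()[len(wanted) :]:
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return summary


def render_butterfly(
    butterfly: pd.DataFrame,
    table_path: str | Path,
    figure_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the butterfly table and optionally the mirrored bar figure."""
    Path(table_path).parent.mkdir(parents=True, exist_ok=True)
    butterfly.to_csv(table_path, index=False)
    if figure_path is not None and not butterfly.empty:
        plt = _agg_backend()
        fig, ax = plt.subplots(figsize=(10, 3.5))
        x = butterfly["peptide_index"]
        ax.bar(x, butterfly["normalized_a"], width=0.8, label="state A")
        ax.bar(x, butterfly["normalized_b_mirrored"], width=0.8, label="state B (mirrored)")
        ax.axhline(0, lw=0.5, color="k")
        ax.set_xlabel("peptide (N- to C-terminal)")
        ax.set_ylabel("normalized uptake")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return butterfly
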