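"""Classify genotype-differential regeneration responses by regression residual.

The core bespoke computation of the workflow: transcripts significant in
both the WT and mutant regeneration contrasts (with a minimum fold-change
in at least one) form a master list; an ordinary least-squares line is fit
through the (WT log2FC, MUT log2FC) points; transcripts whose residual
exceeds +tau are called relatively increased in the mutant, below -tau
relatively decreased, the rest unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MasterList",
    "ResponseFit",
    "ResponseClassification",
    "build_master_list",
    "fit_response_line",
    "classify_residuals",
    "relative_induction_ratio",
    "percent_change",
]

CLASS_INCREASED = "increased_in_mutant"
CLASS_DECREASED = "decreased_in_mutant"
CLASS_UNCHANGED = "unchanged"


@dataclass(frozen=True)
class MasterList:
    """Transcripts eligible for the residual fit.

    ``table`` is indexed by transcript with columns x (WT regeneration
    log2FC), y (MUT regeneration log2FC), p_wt, p_mut. ``n_pass_wt_only``
    etc. count transcripts meeting the per-genotype criteria in one table
    only, for reporting.
    """

    table: pd.DataFrame
    n_pass_wt_only: int
    n_pass_mut_only: int

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class ResponseFit:
    """OLS line y = intercept + slope * x on the master list, with residuals."""

    slope: float
    intercept: float
    residuals: pd.Series  # indexed by transcript
    x: pd.Series
    y: pd.Series


@dataclass(frozen=True)
class ResponseClassification:
    """Three-way residual classification at threshold tau (log2 units)."""

    table: pd.DataFrame  # columns x, y, residual, class
    tau: float

    @property
    def n_increased(self) -> int:
        return int((self.table["class"] == CLASS_INCREASED).sum())

    @property
    def n_decreased(self) -> int:
        return int((self.table["class"] == CLASS_DECREASED).sum())

    @property
    def n_unchanged(self) -> int:
        return int((self.table["class"] == CLASS_UNCHANGED).sum())

    def summary(self) -> dict:
        return {
            "n_master": len(self.table),
            "n_increased": self.n_increased,
            "n_decreased": self.n_decreased,
            "n_unchanged": self.n_unchanged,
            "tau": self.tau,
        }


def build_master_list(
    wt_de: pd.DataFrame,
    mut_de: pd.DataFrame,
    p_cut: float = 0.05,
    lfc_cut: float = 1.0,
    use_adjusted: bool = False,
) -> MasterList:
    """Intersect two DE tables into the master transcript list.

    A transcript qualifies when (1) its p-value is below ``p_cut`` in both
    the WT and mutant regeneration contrasts and (2) |log2FC| exceeds
    ``lfc_cut`` in at least one of the two. Raw p-values are used by
    default; set ``use_adjusted`` to filter on BH-adjusted values instead.

    Transcripts present in only one table are excluded before the
    criteria are applied.
    """
    pcol = "adjusted_p" if use_adjusted else "p_value"
    shared = wt_de.index.intersection(mut_de.index)
    if len(shared) == 0:
        wt_only = list(wt_de.index[:5])
        mut_only = list(mut_de.index[:5])
        raise ValueError(
            "no shared transcript identifiers between the two DE tables "
            f"(WT examples: {wt_only}; MUT examples: {mut_only})"
        )
    wt = wt_de.loc[shared]
    mut = mut_de.loc[shared]
    x = wt["log2FC"].to_numpy(dtype=float)
    y = mut["log2FC"].to_numpy(dtype=float)
    p_wt = wt[pcol].to_numpy(dtype=float)
    p_mut = mut[pcol].to_numpy(dtype=float)

    sig_wt = p_wt < p_cut
    sig_mut = p_mut < p_cut
    big = (np.abs(x) > lfc_cut) | (np.abs(y) > lfc_cut)
    keep = sig_wt & sig_mut & big

    table = pd.DataFrame(
        {"x": x[keep], "y": y[keep], "p_wt": p_wt[keep], "p_mut": p_mut[keep]},
        index=pd.Index(shared[keep], name="transcript"),
    )
    return MasterList(
        table,
        n_pass_wt_only=int(np.sum(sig_wt & big & ~keep)),
        n_pass_mut_only=int(np.sum(sig_mut & big & ~keep)),
    )


def fit_response_line(ml: MasterList) -> ResponseFit:
    """Ordinary least-squares fit of MUT log2FC on WT log2FC.

    Residuals (y minus the fitted line) are attached per transcript; they
    sum to zero and are orthogonal to x, the defining OLS properties.
    """
    if len(ml) < 3:
        raise ValueError("master list needs at least 3 transcripts to fit")
    x = ml.table["x"]
    y = ml.table["y"]
    if np.ptp(x.to_numpy()) == 0.0:
        raise ValueError("x (WT log2FC) is constant; slope undefined")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    return ResponseFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residuals=y - fitted,
        x=x,
        y=y,
    )


def classify_residuals(fit: ResponseFit, tau: float = 1.0) -> ResponseClassification:
    """Call transcripts increased/decreased in the mutant by residual.

    residual > tau -> increased_in_mutant; residual < -tau ->
    decreased_in_mutant; otherwise unchanged. tau is in log2 units.
    """
    r = fit.residuals
    cls = np.where(
        r > tau, CLASS_INCREASED, np.where(r < -tau, CLASS_DECREASED, CLASS_UNCHANGED)
    )
    table = pd.DataFrame(
        {"x": fit.x, "y": fit.y, "residual": r, "class": cls}, index=r.index
    )
    return ResponseClassification(table, tau)


def relative_induction_ratio(fc_mut: float, fc_wt: float) -> float:
    """Ratio of mutant to wild-type fold-changes (how many times more induced)."""
    if fc_wt == 0:
        raise ZeroDivisionError("wild-type fold-change is zero")
    return fc_mut / fc_wt


def percent_change(value_mut: float, value_wt: float) -> float:
    """Percent change of a mutant value relative to wild type, 100*(mut/wt - 1).

    Negative for decreases (e.g. -61.7 for a drop from 81.1 to 31.1).
    """
    if value_wt == 0:
        raise ZeroDivisionError("wild-type value is zero")
    return 100.0 * (value_mut / value_wt - 1.0)


def write_classification(cls: ResponseClassification, path) -> None:
    cls.table.to_csv(path, sep="\t")


def plot_response_scatter(cls: ResponseClassification, fit: ResponseFit, path) -> None:
    """Scatter of WT vs MUT regeneration log2FC with residual coloring.

    Increased-in-mutant transcripts are red, decreased blue, unchanged
    grey; the fitted line and the +-tau residual band are drawn.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = cls.table
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, color in (
        (CLASS_UNCHANGED, "0.6"),
        (CLASS_INCREASED, "crimson"),
        (CLASS_DECREASED, "royalblue"),
    ):
        sub = t[t["class"] == name]
        ax.scatter(sub["x"], sub["y"], s=8, c=color, label=name, alpha=0.7)
    xs = np.linspace(t["x"].min(), t["x"].max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, "k-", lw=1)
    for off in (cls.tau, -cls.tau):
        ax.plot(xs, fit.intercept + fit.slope * xs + off, "k--", lw=0.7)
    ax.set_xlabel("WT regeneration log2FC")
    ax.set_ylabel("mutant regeneration log2FC")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
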