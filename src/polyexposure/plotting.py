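"""Plot exporters for scan results: manhattan-style p-value plot and a
coefficient/effect-size plot with 95% Wald intervals. Both are file
exporters (PNG/SVG) and return the plotted coordinates so tests can assert
on the numbers rather than pixels."""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054


def _as_table(xwas) -> pd.DataFrame:
    return xwas.table if hasattr(xwas, "table") else pd.DataFrame(xwas)


def plot_manhattan(xwas, out: str, threshold: float = 0.05,
                   use_adjusted: bool = True,
                   categories: dict[str, str] | None = None) -> pd.DataFrame:
    """-log10(p) per exposure with a horizontal line at the threshold.

    Zero p-values are floored at the smallest positive float before the
    log so the figure stays finite. Returns the coordinate table.
    """
    table = _as_table(xwas)
    if table.empty:
        raise ValueError("empty scan table")
    col = "p_adjusted" if use_adjusted else "p"
    p = table[col].to_numpy(float)
    if np.nanmin(p[np.isfinite(p)] if np.isfinite(p).any() else [1.0]) <= 0:
        logger.warning("p-values of 0 floored at the machine minimum")
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    coords = pd.DataFrame({"exposure": table["exposure"],
                           "neglog10p": -np.log10(p)})
    coords["category"] = [
        (categories or {}).get(e, "all") for e in coords["exposure"]]
    coords = coords.sort_values(["category", "exposure"], kind="stable").reset_index(drop=True)

    fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(coords)), 4))
    for cat, grp in coords.groupby("category", sort=True):
        ax.scatter(grp.index, grp["neglog10p"], label=cat, s=18)
    ax.axhline(-np.log10(threshold), color="grey", linestyle="--")
    ax.set_xticks(coords.index)
    ax.set_xticklabels(coords["exposure"], rotation=90, fontsize=7)
    ax.set_ylabel(f"-log10({col})")
    if categories:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return coords


def plot_coefficients(source, out: str, exp_scale: bool = False) -> pd.DataFrame:
    """Point estimates with 95% Wald intervals (beta +/- 1.96 se), sorted
    by estimate; with ``exp_scale`` the exponentiated ratios are drawn on a
    log axis (for odds/hazard ratios). Returns the coordinate table."""
    if hasattr(source, "terms"):
        table = source.terms.rename(columns={"term": "label"})
    elif hasattr(source, "summary_frame"):
        table = source.summary_frame().rename(columns={"term": "label"})
    else:
        table = pd.DataFrame(source).rename(columns={"term": "label"})
    table = table.dropna(subset=["beta"])
    if table.empty:
        raise ValueError("no estimates to plot")
    if "se" not in table or table["se"].isna().any():
        raise ValueError("missing standard errors")
    coords = pd.DataFrame({
        "label": table["label"] if "label" in table else table["exposure"],
        "beta": table["beta"].to_numpy(float),
        "lower": table["beta"].to_numpy(float) - _Z95 * table["se"].to_numpy(float),
        "upper": table["beta"].to_numpy(float) + _Z95 * table["se"].to_numpy(float),
    }).sort_values("beta").reset_index(drop=True)

    fig, ax = plt.subplots(figsize=(6, max(3, 0.3 * len(coords))))
    yy = np.arange(len(coords))
    b = coords["beta"].to_numpy()
    lo, hi = coords["lower"].to_numpy(), coords["upper"].to_numpy()
    if exp_scale:
        ax.errorbar(np.exp(b), yy,
                    xerr=[np.exp(b) - np.exp(lo), np.exp(hi) - np.exp(b)],
                    fmt="o", capsize=3)
        ax.set_xscale("log")
        ax.axvline(1.0, color="grey", linestyle="--")
        ax.set_xlabel("ratio (exp scale)")
    else:
        ax.errorbar(b, yy, xerr=[b - lo, hi - b], fmt="o", capsize=3)
        ax.axvline(0.0, color="grey", linestyle="--")
        ax.set_xlabel("effect size")
    ax.set_yticks(yy)
    ax.set_yticklabels(coords["label"], fontsize=7)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return coords
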