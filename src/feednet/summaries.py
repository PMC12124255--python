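"""Reporting surfaces over a simulation results table.

Percentile tables of net-return differences, five-way net-return category
frequencies, grid-number frequencies within categories, per-category
descriptives for any simulated variable, and opportunity-cost descriptives
normalized per 14 added days on feed.  Every summary is a pure function of
the results DataFrame, so re-summarizing saved results reproduces outputs
exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import BASES

__all__ = [
    "REPORT_PERCENTILES",
    "CATEGORY_LABELS",
    "percentile_table",
    "categorize",
    "category_labels",
    "grid_frequency",
    "describe_by_category",
    "opportunity_cost_by_rate",
    "plot_dnr_distributions",
]

REPORT_PERCENTILES = (0.5, 2.5, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 95, 97.5, 99.5)

# right-closed bins: a value exactly on a boundary falls in the lower
# (more negative) category
_CATEGORY_EDGES = (-np.inf, -25.0, -5.0, 5.0, 25.0, np.inf)
CATEGORY_LABELS = (
    "<$-25/animal",
    "$-25 to $-5/animal",
    "$-5 to $5/animal",
    "$5 to $25/animal",
    ">$25/animal",
)


def _dnr_col(basis: str, ep: int) -> str:
    return f"dnr_head_{basis}_ep{ep}"


def percentile_table(results: pd.DataFrame, percentiles=REPORT_PERCENTILES) -> pd.DataFrame:
    """Percentiles of the per-animal net-return difference, basis x endpoint."""
    q = np.asarray(percentiles) / 100.0
    rows = {}
    for basis in BASES:
        for ep in (2, 3, 4):
            rows[(basis, f"EP{ep}")] = results[_dnr_col(basis, ep)].quantile(q).to_numpy()
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(percentiles))
    out.index = pd.MultiIndex.from_tuples(out.index, names=["basis", "endpoint"])
    return out


def category_labels(values: pd.Series) -> pd.Categorical:
    """Assign each net-return difference to one of the five categories."""
    return pd.cut(values, bins=_CATEGORY_EDGES, labels=CATEGORY_LABELS, right=True)


def categorize(results: pd.DataFrame) -> pd.DataFrame:
    """Percent of iterations in each net-return category, basis x endpoint.

    Rows sum to 100 (each basis/endpoint series is fully partitioned).
    """
    rows = {}
    for basis in BASES:
        for ep in (2, 3, 4):
            labels = category_labels(results[_dnr_col(basis, ep)])
            freq = labels.value_counts(sort=False) / len(results) * 100.0
            rows[(basis, f"EP{ep}")] = freq.to_numpy()
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(CATEGORY_LABELS))
    out.index = pd.MultiIndex.from_tuples(out.index, names=["basis", "endpoint"])
    return out


def grid_frequency(results: pd.DataFrame) -> pd.DataFrame:
    """Percent of each QG grid number within each grid-basis net-return
    category and endpoint (each row sums to 100)."""
    rows = {}
    for ep in (2, 3, 4):
        labels = category_labels(results[_dnr_col("grid", ep)])
        for cat in CATEGORY_LABELS:
            sub = results.loc[np.asarray(labels == cat), "grid_id"]
            counts = sub.value_counts().reindex([1.0, 2.0, 3.0], fill_value=0)
            total = counts.sum()
            pct = counts / total * 100.0 if total else counts * np.nan
            rows[(f"EP{ep}", cat)] = pct.to_numpy()
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["grid 1", "grid 2", "grid 3"])
    out.index = pd.MultiIndex.from_tuples(out.index, names=["endpoint", "category"])
    return out


def describe_by_category(results: pd.DataFrame, variable: str, basis: str = "live") -> pd.DataFrame:
    """Median, IQR, and 95% inter-percentile range of ``variable`` within each
    net-return category and endpoint for the given sale basis.

    ``variable`` may be a plain column name or an endpoint template containing
    ``{ep}`` (e.g. ``"live_diff_ep{ep}"``).
    """
    rows = {}
    for ep in (2, 3, 4):
        col = variable.format(ep=ep) if "{ep}" in variable else variable
        labels = category_labels(results[_dnr_col(basis, ep)])
        for cat in CATEGORY_LABELS:
            sub = results.loc[np.asarray(labels == cat), col]
            if len(sub) == 0:
                rows[(f"EP{ep}", cat)] = [np.nan] * 5
                continue
            qs = sub.quantile([0.025, 0.25, 0.5, 0.75, 0.975]).to_numpy()
            rows[(f"EP{ep}", cat)] = [qs[2], qs[1], qs[3], qs[0], qs[4]]
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["median", "q25", "q75", "p2.5", "p97.5"])
    out.index = pd.MultiIndex.from_tuples(out.index, names=["endpoint", "category"])
    return out


def opportunity_cost_by_rate(
    results: pd.DataFrame, basis: str = "live", pen_size: int = 200
) -> pd.DataFrame:
    """Median and 95IPR of opportunity cost per animal per 14 added days.

    Endpoint ``EPi`` opportunity cost is divided by its number of 14-day
    increments (1, 2, 3) and by the nominal pen size, then the three
    endpoints are pooled within each interest rate.
    """
    rows = {}
    for rate in sorted(results["interest_rate"].unique()):
        mask = results["interest_rate"] == rate
        pooled = np.concatenate([
            results.loc[mask, f"oc_{basis}_ep{ep}"].to_numpy() / ((ep - 1) * pen_size)
            for ep in (2, 3, 4)
        ])
        qs = np.quantile(pooled, [0.5, 0.025, 0.975])
        rows[rate] = {"median": qs[0], "p2.5": qs[1], "p97.5": qs[2], "n": mask.sum() * 3}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "interest_rate"
    return out


def plot_dnr_distributions(results: pd.DataFrame, basis: str, path=None,
                           subsample: int = 5000, seed: int = 0):
    """Overlaid density + box/strip plot of net-return differences by endpoint.

    Optional artifact; requires matplotlib/seaborn.  The strip layer uses a
    seeded random subsample for legibility.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    long = pd.concat(
        [pd.DataFrame({"dnr": results[_dnr_col(basis, ep)], "endpoint": f"EP{ep}"})
         for ep in (2, 3, 4)],
        ignore_index=True,
    )
    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    sns.kdeplot(data=long, x="dnr", hue="endpoint", ax=axes[0], common_norm=False)
    axes[0].set_xlabel("net return difference, $/animal")
    sub = long.sample(min(subsample, len(long)), random_state=seed)
    sns.boxplot(data=long, x="endpoint", y="dnr", ax=axes[1], showfliers=False)
    sns.stripplot(data=sub, x="endpoint", y="dnr", ax=axes[1], size=1.5, alpha=0.3,
                  color="0.3")
    axes[1].set_ylabel("net return difference, $/animal")
    fig.suptitle(f"{basis} sale basis")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
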