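"""Cohort-level analysis: Pearson correlation with PFS and group summaries.

The response statistics dV, dD, dS and d(V+D) are correlated against
progression-free survival (months) by Pearson product-moment correlation,
complete-case: patients with missing PFS are excluded, never imputed.
P-values come from the exact t transform with n-2 degrees of freedom,
two-sided; no multiple-testing correction is applied.  Group summaries split
the cohort into progression (PD) versus nonprogression (PR or SD) and report
arithmetic means of the three percent-change statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ContractError, DegenerateDataError
from .io import CohortTable

__all__ = [
    "CorrelationResult",
    "GroupSummary",
    "pearson",
    "group_summaries",
    "correlation_report",
    "plot_scatter",
]

SIGNIFICANCE_LEVEL = 0.05

#: cohort column -> human label of the four response statistics
METRIC_COLUMNS = {
    "combined_pct": "d(V+D)",
    "volume_pct": "dV",
    "density_pct": "dD",
    "size_pct": "dS",
}


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


@dataclass
class GroupSummary:
    group: str  # "progression" | "nonprogression"
    mean_volume_pct: float | None
    mean_density_pct: float | None
    mean_size_pct: float | None
    n: int


def pearson(x, y) -> CorrelationResult:
    """Pearson r with a two-sided t-test p-value (n-2 degrees of freedom)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ContractError("need at least 3 pairs for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance input to Pearson correlation")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=int(x.size))


def group_summaries(cohort: CohortTable) -> dict[str, GroupSummary]:
    """Mean dV, dD, dS within the PD group and the PR∪SD group."""
    import warnings

    rows = cohort.rows
    if rows["recist"].isna().any():
        raise ContractError("every row needs a RECIST category")
    out = {}
    for name, sel in (
        ("progression", rows["recist"] == "PD"),
        ("nonprogression", rows["recist"].isin(("CR", "PR", "SD"))),
    ):
        sub = rows[sel]
        if len(sub) == 0:
            warnings.warn(f"empty {name} group; means absent", stacklevel=2)
            out[name] = GroupSummary(name, None, None, None, 0)
            continue
        out[name] = GroupSummary(
            group=name,
            mean_volume_pct=float(sub["volume_pct"].mean()),
            mean_density_pct=float(sub["density_pct"].mean()),
            mean_size_pct=float(sub["size_pct"].mean()),
            n=len(sub),
        )
    return out


def correlation_report(cohort: CohortTable) -> dict:
    """The four metric-vs-PFS correlations plus scatter data and group means.

    Complete-case: rows without PFS are dropped before correlating.  Returns
    a dict with ``correlations`` (metric -> CorrelationResult), ``scatter``
    (metric -> (x, pfs) arrays) and ``groups``.
    """
    complete = cohort.complete_cases()
    if len(complete) < 3:
        raise ContractError(
            f"need at least 3 rows with PFS, got {len(complete)}"
        )
    pfs = complete["pfs_months"].to_numpy()
    correlations = {}
    scatter = {}
    for col, label in METRIC_COLUMNS.items():
        x = complete[col].to_numpy()
        correlations[label] = pearson(x, pfs)
        scatter[label] = (x, pfs.copy())
    return {
        "correlations": correlations,
        "scatter": scatter,
        "groups": group_summaries(cohort),
        "n_complete": len(complete),
    }


def plot_scatter(report: dict, out_dir: str | Path) -> list[Path]:
    """Write one metric-vs-PFS scatter plot per response statistic."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, (x, pfs) in report["scatter"].items():
        res = report["correlations"][label]
        fig, ax = plt.subplots(figsize=(4, 3.2))
        ax.scatter(x, pfs, s=22, color="tab:blue", edgecolor="k", linewidth=0.4)
        ax.set_xlabel(f"{label} (%)")
        ax.set_ylabel("PFS (months)")
        ax.set_title(f"{label} vs PFS  (r={res.r:.3f}, P={res.p_value:.3f})", fontsize=9)
        fig.tight_layout()
        safe = label.replace("(", "").replace(")", "").replace("+", "plus")
        p = out_dir / f"scatter_{safe}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
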