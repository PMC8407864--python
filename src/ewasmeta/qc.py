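"""Quality checks of cohort-level and meta-analysed EWAS results.

Per cohort x model: the genomic inflation factor lambda, the precision-plot
coordinates (sqrt(n) against 1/median SE), the effect-estimate distribution
summary and a count of extreme estimates. Across models within a cohort:
the Spearman correlation matrix of effect estimates. The same lambda /
correlation checks apply to meta-analysed result tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyAnalysisError
from .meta import genomic_inflation_lambda

__all__ = ["QcReport", "cohort_qc", "qq_coordinates"]


@dataclass
class QcReport:
    """summary: one row per cohort x model; correlations: per-cohort
    cross-model Spearman matrices of effect estimates."""

    summary: pd.DataFrame
    correlations: dict[str, pd.DataFrame]


def _summary_row(table: pd.DataFrame, extreme_threshold: float) -> dict:
    b = table["beta"].to_numpy(dtype=float)
    n = int(table["n"].max()) if "n" in table else len(table)
    med_se = float(np.median(table["se"]))
    return {
        "lambda": genomic_inflation_lambda(table["p"].to_numpy()),
        "n": n,
        "median_se": med_se,
        "precision_x": float(np.sqrt(n)),
        "precision_y": 1.0 / med_se,
        "beta_min": float(b.min()),
        "beta_q1": float(np.percentile(b, 25)),
        "beta_median": float(np.percentile(b, 50)),
        "beta_q3": float(np.percentile(b, 75)),
        "beta_max": float(b.max()),
        "n_extreme": int((np.abs(b) > extreme_threshold).sum()),
    }


def cohort_qc(
    results: dict[tuple[str, str], pd.DataFrame],
    extreme_threshold: float = 10.0,
) -> QcReport:
    """QC a set of result tables keyed by (cohort_id, model_label).

    ``extreme_threshold`` flags effect estimates beyond the given absolute
    size (percentage points per SD); small strata occasionally produce such
    outliers and they should be visible before pooling.
    """
    if not results:
        raise EmptyAnalysisError("no results to QC")
    rows = []
    for (cohort, model), table in results.items():
        row = {"cohort": cohort, "model": model}
        row.update(_summary_row(table, extreme_threshold))
        rows.append(row)
    summary = pd.DataFrame(rows).set_index(["cohort", "model"])

    correlations: dict[str, pd.DataFrame] = {}
    cohorts = sorted({c for c, _ in results})
    for cohort in cohorts:
        models = [m for c, m in results if c == cohort]
        if len(models) < 2:
            continue
        betas = pd.DataFrame({
            m: results[(cohort, m)]["beta"] for m in models}).dropna()
        corr = pd.DataFrame(np.eye(len(models)), index=models, columns=models)
        for i, mi in enumerate(models):
            for j, mj in enumerate(models):
                if i < j:
                    rho, _ = stats.spearmanr(betas[mi], betas[mj])
                    corr.loc[mi, mj] = corr.loc[mj, mi] = rho
        correlations[cohort] = corr
    return QcReport(summary=summary, correlations=correlations)


def qq_coordinates(p_values) -> pd.DataFrame:
    """Plot-ready QQ table: expected vs observed -log10(p)."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(p),
    })
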