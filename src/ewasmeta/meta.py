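"""Inverse-variance fixed-effects meta-analysis and downstream statistics.

Pooling follows the standard fixed-effects convention used by consortium
EWAS tooling: weights w_i = 1/SE_i^2, pooled beta = sum(w b)/sum(w), pooled
SE = sum(w)^-1/2, z = beta/SE with a normal reference, Cochran's
Q = sum w_i (b_i - pooled)^2 on k-1 df and I^2 = max(0, (Q-df)/Q) x 100.
Also implemented here: Benjamini-Hochberg FDR, the genomic inflation factor
lambda, leave-one-out stability screening, inverse-variance-weighted
meta-regression on a cohort-level moderator, sensitivity subset
meta-analyses and the per-cell-type meta-analysis of cell-proportion
regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateModeratorError,
    EmptyAnalysisError,
    InputError,
    InsufficientDataError,
)

__all__ = [
    "fixed_effects_meta",
    "meta_analyse",
    "bh_fdr",
    "genomic_inflation_lambda",
    "LeaveOneOutReport",
    "leave_one_out",
    "meta_regression_age",
    "sensitivity_subset_meta",
    "meta_analyse_cell_associations",
]

CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.4549364...


def fixed_effects_meta(estimates) -> dict:
    """Pool one probe's per-cohort (beta, se) pairs.

    ``estimates`` is a sequence of (beta, se) with se > 0; cohorts with a
    missing probe should be passed as (nan, nan) so the direction string
    keeps one character per cohort ('?' for missing).
    """
    arr = np.asarray([(b, s) for b, s in estimates], dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("no estimates to pool")
    b, s = arr[:, 0], arr[:, 1]
    ok = np.isfinite(b) & np.isfinite(s) & (s > 0)
    if not ok.any():
        raise InsufficientDataError("all cohorts missing at this probe")
    w = 1.0 / s[ok] ** 2
    bw = b[ok]
    sw = w.sum()
    pooled = float((w * bw).sum() / sw)
    pooled_se = float(sw ** -0.5)
    z = pooled / pooled_se
    p = float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))
    k = int(ok.sum())
    q = float((w * (bw - pooled) ** 2).sum())
    q_df = k - 1
    i2 = 0.0 if (k == 1 or q <= q_df or q == 0) else (q - q_df) / q * 100.0
    direction = "".join(
        "?" if not o else ("+" if bi > 0 else ("-" if bi < 0 else "0"))
        for o, bi in zip(ok, b))
    return {"beta": pooled, "se": pooled_se, "z": float(z), "p": p,
            "q": q, "q_df": q_df, "i2": float(i2), "k": k,
            "direction": direction}


def meta_analyse(
    cohort_tables: dict[str, pd.DataFrame],
    cohort_order: list[str] | None = None,
    with_fdr: bool = True,
) -> pd.DataFrame:
    """Vectorized fixed-effects meta-analysis across cohorts.

    ``cohort_tables`` maps cohort id to a per-probe table with columns
    beta/se (probe_id index). Probes absent from a cohort contribute '?'
    to that cohort's position in the direction string; probes absent from
    every cohort are dropped. FDR is computed within this analysis.
    """
    if not cohort_tables:
        raise EmptyAnalysisError("no cohort results supplied")
    order = cohort_order or list(cohort_tables)
    beta = pd.DataFrame({c: cohort_tables[c]["beta"] for c in order})
    se = pd.DataFrame({c: cohort_tables[c]["se"] for c in order})
    b = beta.to_numpy(dtype=float)
    s = se.to_numpy(dtype=float)
    ok = np.isfinite(b) & np.isfinite(s) & (s > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(ok, 1.0 / s**2, 0.0)
    sw = w.sum(axis=1)
    keep = sw > 0
    bw = np.where(ok, b, 0.0)
    pooled = (w * bw).sum(axis=1) / np.where(keep, sw, np.nan)
    pooled_se = np.where(keep, sw, np.nan) ** -0.5
    z = pooled / pooled_se
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
    k = ok.sum(axis=1)
    q = (w * (bw - np.where(keep, pooled, 0.0)[:, None]) ** 2).sum(axis=1)
    q_df = k - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.where((k > 1) & (q > q_df) & (q > 0),
                      (q - q_df) / np.where(q > 0, q, 1.0) * 100.0, 0.0)

    sign = np.where(ok, np.where(b > 0, "+", np.where(b < 0, "-", "0")), "?")
    direction = ["".join(row) for row in sign]

    out = pd.DataFrame({
        "beta": pooled, "se": pooled_se, "z": z, "p": p,
        "q": q, "q_df": q_df, "i2": i2, "k": k, "direction": direction,
    }, index=beta.index)
    out = out[keep]
    if with_fdr:
        out["fdr_p"] = bh_fdr(out["p"].to_numpy())
        out = out[["beta", "se", "z", "p", "fdr_p", "q", "q_df", "i2",
                   "k", "direction"]]
    out.index.name = "probe_id"
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1; ties share the rank
    minimum through the reverse cumulative minimum.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InputError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def genomic_inflation_lambda(p_values) -> float:
    """Genomic inflation factor: median association chi-square (1 df,
    quantile of 1-p) over the null median 0.455."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InputError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


@dataclass
class LeaveOneOutReport:
    """Stability of one probe's pooled estimate under cohort omission."""

    probe_id: str
    table: pd.DataFrame  # per omitted cohort: beta_loo, ci_low, ci_high, reasons
    survived: bool
    failure_reasons: set[str]
    applicable: bool = True


def leave_one_out(
    betas: dict[str, float],
    ses: dict[str, float],
    probe_id: str = "",
    attenuation_threshold: float = 0.20,
    z_crit: float = 1.959963984540054,
) -> LeaveOneOutReport:
    """Re-pool omitting each cohort in turn and apply the three survival
    criteria: same direction as the full pooled estimate, change in
    estimate <= 20% (either direction), and 95% CI excluding the null."""
    cohorts = [c for c in betas if np.isfinite(betas[c]) and
               np.isfinite(ses[c]) and ses[c] > 0]
    if len(cohorts) < 2:
        return LeaveOneOutReport(probe_id, pd.DataFrame(), True, set(),
                                 applicable=False)
    full = fixed_effects_meta([(betas[c], ses[c]) for c in cohorts])
    full_beta = full["beta"]
    rows = []
    reasons: set[str] = set()
    for omit in cohorts:
        rest = [(betas[c], ses[c]) for c in cohorts if c != omit]
        sub = fixed_effects_meta(rest)
        lo = sub["beta"] - z_crit * sub["se"]
        hi = sub["beta"] + z_crit * sub["se"]
        fail = []
        if np.sign(sub["beta"]) != np.sign(full_beta):
            fail.append("direction_flip")
        if full_beta != 0 and \
                abs(sub["beta"] - full_beta) / abs(full_beta) > attenuation_threshold:
            fail.append("attenuation_gt_20pct")
        if lo <= 0.0 <= hi:
            fail.append("ci_crosses_null")
        reasons.update(fail)
        rows.append({"omitted": omit, "beta_loo": sub["beta"],
                     "ci_low": lo, "ci_high": hi,
                     "failures": ";".join(fail)})
    table = pd.DataFrame(rows).set_index("omitted")
    return LeaveOneOutReport(probe_id, table, len(reasons) == 0, reasons)


def meta_regression_age(
    betas,
    ses,
    mean_ages,
) -> tuple[float, float, float]:
    """Inverse-variance weighted least squares of cohort effect estimates
    on cohort mean age at sample collection; returns (slope per year, SE,
    two-sided normal p)."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    a = np.asarray(mean_ages, dtype=float)
    if b.size < 3:
        raise InsufficientDataError("need >= 3 cohorts for meta-regression")
    if np.ptp(a) == 0:
        raise DegenerateModeratorError("cohort mean ages are constant")
    w = 1.0 / s**2
    x = np.column_stack([np.ones_like(a), a])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * b)
    coef = np.linalg.solve(xtwx, xtwy)
    cov = np.linalg.inv(xtwx)
    slope = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    p = float(2.0 * stats.norm.sf(abs(slope / se)))
    return slope, se, p


def sensitivity_subset_meta(
    cohort_tables: dict[str, pd.DataFrame],
    excluded: set[str],
    cohort_order: list[str] | None = None,
) -> pd.DataFrame:
    """Re-run the meta-analysis on the cohorts not in ``excluded``; FDR is
    re-ranked within the subset analysis."""
    remaining = {c: t for c, t in cohort_tables.items() if c not in excluded}
    if not remaining:
        raise EmptyAnalysisError("all cohorts excluded")
    order = [c for c in (cohort_order or list(cohort_tables))
             if c in remaining]
    return meta_analyse(remaining, cohort_order=order)


def meta_analyse_cell_associations(
    per_cohort: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Fixed-effects pooling of per-cohort cell-proportion regressions
    (tables indexed by cell_type with estimate/se columns)."""
    if not per_cohort:
        raise EmptyAnalysisError("no cohort cell regressions supplied")
    cells = sorted({c for t in per_cohort.values() for c in t.index})
    rows = []
    for cell in cells:
        est = [(t.loc[cell, "estimate"], t.loc[cell, "se"])
               for t in per_cohort.values() if cell in t.index]
        res = fixed_effects_meta(est)
        res["cell_type"] = cell
        res["ci_low"] = res["beta"] - 1.959963984540054 * res["se"]
        res["ci_high"] = res["beta"] + 1.959963984540054 * res["se"]
        rows.append(res)
    return pd.DataFrame(rows).set_index("cell_type")
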