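"""Parental effect comparison and candidate-set enrichment statistics.

Covers: per-probe Cochran Q heterogeneity between the paternal and maternal
estimates, Kolmogorov-Smirnov enrichment of a candidate set's p-values
against the uniform null, direction-of-effect concordance with a reference
sign list (with within-set FDR), and whole-genome comparison of two model's
effect estimates (Spearman correlation, median percentage difference, share
with larger absolute estimates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptySetError, InputError
from .meta import bh_fdr
from .probes import map_genes_to_probes, read_gene_intervals

__all__ = [
    "CandidateSet",
    "parental_heterogeneity_q",
    "ks_enrichment",
    "direction_concordance",
    "compare_model_estimates",
]


@dataclass
class CandidateSet:
    """A named set of candidate probes, optionally with expected signs."""

    name: str
    probe_ids: set[str]
    expected_direction: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_probe_file(cls, name: str, path: str | Path) -> "CandidateSet":
        """TSV with a probe_id column and optionally a direction column
        (+1/-1)."""
        df = pd.read_csv(path, sep="\t")
        ids = set(df["probe_id"].astype(str))
        signs = {}
        if "direction" in df.columns:
            signs = {str(r.probe_id): int(np.sign(r.direction))
                     for r in df.itertuples(index=False)}
        return cls(name=name, probe_ids=ids, expected_direction=signs)

    @classmethod
    def from_gene_file(cls, name: str, path: str | Path,
                       annotation: pd.DataFrame) -> "CandidateSet":
        """Gene-interval TSV mapped to probes via the annotation."""
        genes = read_gene_intervals(path)
        mapping = map_genes_to_probes(genes, annotation)
        ids = set().union(*mapping.values()) if mapping else set()
        return cls(name=name, probe_ids=ids)

    def intersect(self, analysed: pd.Index) -> set[str]:
        hit = self.probe_ids & set(analysed)
        if not hit:
            raise EmptySetError(
                f"candidate set {self.name!r} empty after intersection with "
                "analysed probes")
        return hit


def parental_heterogeneity_q(paternal, maternal):
    """Cochran Q (1 df) between a paternal and a maternal estimate.

    Arguments are (beta, se) pairs or aligned arrays thereof. Returns a
    dict (scalar inputs) or DataFrame with q, p (chi-square, 1 df) and the
    two-estimate I^2 = max(0, (Q-1)/Q) x 100.
    """
    bp, sp = np.asarray(paternal[0], float), np.asarray(paternal[1], float)
    bm, sm = np.asarray(maternal[0], float), np.asarray(maternal[1], float)
    if np.any(~np.isfinite(bp)) or np.any(~np.isfinite(bm)) \
            or np.any(~np.isfinite(sp)) or np.any(~np.isfinite(sm)) \
            or np.any(sp <= 0) or np.any(sm <= 0):
        raise InputError("estimates must be finite with positive SEs")
    q = (bp - bm) ** 2 / (sp**2 + sm**2)
    p = stats.chi2.sf(q, df=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.where(q > 1, (q - 1) / np.where(q > 0, q, 1.0) * 100.0, 0.0)
    if np.ndim(q) == 0:
        return {"q": float(q), "df": 1, "p": float(p), "i2": float(i2)}
    return pd.DataFrame({"q": q, "df": 1, "p": p, "i2": i2})


def ks_enrichment(candidate_p, alternative: str = "two-sided"
                  ) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of a candidate set's p-values
    against Uniform(0,1).

    ``alternative='inflation'`` is one-sided for enrichment (p-values
    stochastically smaller than uniform, i.e. ECDF above the diagonal).
    Uses scipy's exact small-n / asymptotic large-n switching.
    """
    p = np.asarray(candidate_p, dtype=float)
    if p.size == 0:
        raise EmptySetError("empty candidate p-value set")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    alt = {"two-sided": "two-sided", "inflation": "greater"}.get(alternative)
    if alt is None:
        raise InputError(f"unknown alternative {alternative!r}")
    res = stats.kstest(p, "uniform", alternative=alt, method="auto")
    return float(res.statistic), float(res.pvalue)


def direction_concordance(
    reference_signs: dict[str, int],
    observed: pd.DataFrame,
) -> dict:
    """Concordance of observed effect directions with a reference sign list.

    ``observed`` is indexed by probe_id with beta and p columns. Ties
    (beta == 0) count as discordant and are reported. Also applies BH-FDR
    within the intersected set (m = set size) and counts survivors at 0.05.
    """
    common = [pid for pid in reference_signs if pid in observed.index]
    if not common:
        raise EmptySetError("no overlap between reference set and results")
    b = observed.loc[common, "beta"].to_numpy(dtype=float)
    p = observed.loc[common, "p"].to_numpy(dtype=float)
    ref = np.array([reference_signs[pid] for pid in common])
    obs_sign = np.sign(b)
    n_ties = int((obs_sign == 0).sum())
    concordant = int(((obs_sign == np.sign(ref)) & (obs_sign != 0)).sum())
    fdr = bh_fdr(p)
    return {
        "n_total": len(common),
        "n_same_direction": concordant,
        "n_ties": n_ties,
        "n_p_below_0.05": int((p < 0.05).sum()),
        "fdr_survivors": int((fdr < 0.05).sum()),
    }


def compare_model_estimates(
    model_a: pd.DataFrame,
    model_b: pd.DataFrame,
) -> dict:
    """Compare two models' effect estimates over their common probes.

    model_b is the baseline (e.g. the not-mutually-adjusted model):
    percentage difference per probe is |b_a - b_b| / |b_b| x 100, probes
    with b_b == 0 excluded and counted. Reports Spearman rho, the median
    and IQR of the percentage differences, and the share of probes where
    |b_a| > |b_b|.
    """
    common = model_a.index.intersection(model_b.index)
    if len(common) == 0:
        raise EmptySetError("models share no probes")
    a = model_a.loc[common, "beta"].to_numpy(dtype=float)
    b = model_b.loc[common, "beta"].to_numpy(dtype=float)
    rho, _ = stats.spearmanr(a, b)
    nonzero = b != 0
    pct = np.abs(a[nonzero] - b[nonzero]) / np.abs(b[nonzero]) * 100.0
    q1, med, q3 = (np.percentile(pct, (25, 50, 75)) if pct.size
                   else (np.nan,) * 3)
    return {
        "n_common": int(len(common)),
        "n_zero_baseline_excluded": int((~nonzero).sum()),
        "spearman_rho": float(rho),
        "median_pct_diff": float(med),
        "iqr_pct_diff": (float(q1), float(q3)),
        "share_larger_abs_a": float((np.abs(a) > np.abs(b)).mean()),
    }
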