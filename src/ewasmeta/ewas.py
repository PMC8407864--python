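"""Cohort-level EWAS, following a shared pre-specified analysis plan.

One cohort's analysis is: standardize the exposure to internal Z-scores,
remove per-probe methylation outliers (Tukey's 3xIQR fences), estimate
cell-type proportions by reference-based constrained projection, estimate
surrogate variables from the residual matrix, then fit a per-CpG ordinary
least squares model of methylation on the exposure plus the fixed covariate
set, estimated cell proportions and surrogate variables. Effect estimates
are reported in percentage-methylation points per 1 SD of exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .errors import (
    DegenerateExposureError,
    InsufficientDataError,
    InvalidConfigError,
    RankDeficiencyError,
    StratumTooSmallError,
    UnidentifiableReferenceError,
)
from .simulate import CellReference, CohortDataset

logger = logging.getLogger(__name__)

__all__ = [
    "EwasModelSpec",
    "CohortEwasResult",
    "standardize_bmi",
    "remove_methylation_outliers",
    "estimate_cell_proportions",
    "estimate_surrogate_variables",
    "run_ewas",
    "regress_cell_on_bmi",
    "parental_bmi_correlation",
]

COVARIATES = ("paternal_age", "maternal_age", "maternal_smoking",
              "paternal_smoking", "paternal_sep", "parity")


@dataclass(frozen=True)
class EwasModelSpec:
    """One model of the analysis plan.

    exposure: which parent's internally standardized BMI is the exposure.
    mutual_adjustment: include the other parent's BMI Z as a covariate.
    sex_stratum: "all" or restrict to one offspring sex.
    n_surrogate_variables: residual-SVD surrogate variables added (default 20).
    """

    exposure: str = "paternal_bmi_z"
    mutual_adjustment: bool = False
    sex_stratum: str = "all"
    n_surrogate_variables: int = 20

    def __post_init__(self) -> None:
        if self.exposure not in ("paternal_bmi_z", "maternal_bmi_z"):
            raise InvalidConfigError(f"unknown exposure {self.exposure!r}")
        if self.sex_stratum not in ("all", "female", "male"):
            raise InvalidConfigError(f"unknown stratum {self.sex_stratum!r}")
        if self.n_surrogate_variables < 0:
            raise InvalidConfigError("n_surrogate_variables must be >= 0")

    @property
    def label(self) -> str:
        parent = "paternal" if self.exposure.startswith("pat") else "maternal"
        adj = "adjusted" if self.mutual_adjustment else "unadjusted"
        return f"{parent}_{adj}_{self.sex_stratum}"


@dataclass
class CohortEwasResult:
    """Per-probe (estimate, se, p, n) for one cohort x model."""

    cohort_id: str
    model: EwasModelSpec
    table: pd.DataFrame  # columns: probe_id (index), beta, se, p, n
    n_samples: int = 0

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.10g")


def standardize_bmi(values) -> np.ndarray:
    """Internal Z-scores: (x - mean)/SD with the n-1 denominator, computed
    over non-missing entries; missing values propagate as NaN."""
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise DegenerateExposureError("need >= 2 non-missing BMI values")
    sd = np.std(x[ok], ddof=1)
    if sd == 0:
        raise DegenerateExposureError("BMI has zero variance")
    z = np.full_like(x, np.nan)
    z[ok] = (x[ok] - x[ok].mean()) / sd
    return z


def remove_methylation_outliers(
    betas: pd.DataFrame,
    multiplier: float = 3.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Set per-probe Tukey outliers to missing.

    Values outside [Q1 - multiplier*IQR, Q3 + multiplier*IQR] (quartiles by
    linear interpolation over non-missing values) become NaN. Probes with
    fewer than 4 non-missing values are skipped. Returns the cleaned matrix
    and the per-probe removal counts.
    """
    mat = betas.to_numpy(dtype=float, copy=True)
    n_ok = np.isfinite(mat).sum(axis=1)
    enough = n_ok >= 4
    n_skipped = int((~enough).sum())
    if n_skipped:
        logger.warning(
            "outlier removal skipped for %d probes with <4 non-missing values",
            n_skipped)
    removed = np.zeros(mat.shape[0], dtype=int)
    if enough.any():
        sub = mat[enough]
        with np.errstate(invalid="ignore"):
            q1 = np.nanpercentile(sub, 25, axis=1)
            q3 = np.nanpercentile(sub, 75, axis=1)
        iqr = q3 - q1
        lo = (q1 - multiplier * iqr)[:, None]
        hi = (q3 + multiplier * iqr)[:, None]
        with np.errstate(invalid="ignore"):
            out = (sub < lo) | (sub > hi)
        removed[enough] = out.sum(axis=1)
        sub[out] = np.nan
        mat[enough] = sub
    cleaned = pd.DataFrame(mat, index=betas.index, columns=betas.columns)
    counts = pd.Series(removed, index=betas.index, name="n_removed")
    return cleaned, counts


def estimate_cell_proportions(
    betas: pd.DataFrame,
    reference: CellReference,
    sum_to_one: bool = True,
) -> pd.DataFrame:
    """Reference-based cell deconvolution by constrained projection.

    Per sample, solves nonnegative least squares of the beta vector
    (restricted to the reference's deconvolution panel, complete cases per
    sample) on the reference profiles, then renormalizes to sum 1
    (``sum_to_one=True``, the default) or leaves the raw nonnegative
    solution (row sums <= ~1).
    """
    shared = betas.index.intersection(reference.deconvolution_probes)
    k = reference.profiles.shape[1]
    if len(shared) < k:
        raise UnidentifiableReferenceError(
            f"only {len(shared)} reference probes shared; need >= {k}")
    ref = reference.profiles.loc[shared].to_numpy()
    if np.linalg.matrix_rank(ref) < k:
        raise UnidentifiableReferenceError(
            "reference panel rank deficient on shared probes")
    y = betas.loc[shared].to_numpy()
    out = np.zeros((betas.shape[1], k))
    for j in range(betas.shape[1]):
        ok = np.isfinite(y[:, j])
        if ok.sum() < k:
            out[j] = np.nan
            continue
        sol, _ = nnls(ref[ok], y[ok, j])
        if sum_to_one:
            s = sol.sum()
            sol = sol / s if s > 0 else np.full(k, 1.0 / k)
        out[j] = sol
    return pd.DataFrame(out, index=betas.columns,
                        columns=reference.cell_labels)


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residual of each row of y on the column space of x (samples axis)."""
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    return y - (x @ beta).T


def estimate_surrogate_variables(
    betas: pd.DataFrame,
    design: np.ndarray,
    k: int,
) -> np.ndarray:
    """Surrogate variables from the residual matrix.

    Probes are mean-imputed (estimation only), residualized on ``design``
    (which must exclude the exposure), and the top-k right singular vectors
    of the residual matrix are returned as a samples x k matrix. SVs are
    orthogonal to the design column space by construction; signs are fixed
    so each SV's first nonzero entry is positive.
    """
    n = betas.shape[1]
    rank = np.linalg.matrix_rank(design)
    if k >= n - rank:
        raise InvalidConfigError(
            f"k={k} surrogate variables infeasible with n={n} samples and "
            f"design rank {rank}")
    if k == 0:
        return np.zeros((n, 0))
    mat = betas.to_numpy(dtype=float, copy=True)
    bad = ~np.isfinite(mat)
    if bad.any():
        row_mean = np.where(
            np.isfinite(mat).any(axis=1),
            np.nanmean(np.where(bad, np.nan, mat), axis=1), 0.0)
        mat[bad] = np.broadcast_to(row_mean[:, None], mat.shape)[bad]
    resid = _residualize(mat, design)
    # Right singular vectors via the (small) sample-space Gram matrix.
    gram = resid.T @ resid
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1][:k]
    svs = vecs[:, order]
    for j in range(svs.shape[1]):
        col = svs[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            svs[:, j] = -col
    return svs


def _design_rank_check(x: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr
        _, r, piv = qr(x, mode="economic", pivoting=True)
        tol = np.abs(r[0, 0]) * max(x.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(x.shape[1])
               if abs(r[i, i]) < tol]
        raise RankDeficiencyError(
            f"design matrix rank deficient; collinear columns: {bad}")


def _ols_probe_block(x: np.ndarray, y: np.ndarray, j_exposure: int
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorized OLS of many probes (rows of y) on a common design.

    Returns (beta_exposure, se, p, df) with t-based two-sided p-values.
    """
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = xtx_inv @ x.T @ y.T          # p x probes
    resid = y.T - x @ coef              # n x probes
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    var = sigma2 * xtx_inv[j_exposure, j_exposure]
    se = np.sqrt(var)
    b = coef[j_exposure]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, np.nan)
    pval = np.maximum(2.0 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny)
    return b, se, pval, df


def run_ewas(
    dataset: CohortDataset,
    model: EwasModelSpec,
    reference: CellReference,
    min_stratum_size: int = 30,
    remove_outliers: bool = True,
    cell_proportions: pd.DataFrame | None = None,
) -> CohortEwasResult:
    """Run one cohort x model EWAS.

    Per probe, fits OLS of beta on exposure Z + fixed covariates + estimated
    cell proportions (one column dropped against the sum constraint) + k
    surrogate variables (+ the other parent's BMI Z under mutual
    adjustment), complete-case per probe. The exposure coefficient and SE
    are scaled x100 to percentage points; p-values use the t distribution
    with the residual degrees of freedom.
    """
    pheno = dataset.phenotypes
    missing = [c for c in COVARIATES + ("paternal_bmi", "maternal_bmi", "child_sex")
               if c not in pheno.columns]
    if missing:
        raise InvalidConfigError(f"phenotype columns missing: {missing}")

    # complete-case on phenotypes
    needed = list(COVARIATES) + ["paternal_bmi", "maternal_bmi", "child_sex"]
    keep = pheno[needed].notna().all(axis=1)
    if model.sex_stratum != "all":
        keep &= pheno["child_sex"] == model.sex_stratum
    samples = pheno.index[keep]
    if model.sex_stratum != "all" and len(samples) < min_stratum_size:
        raise StratumTooSmallError(
            f"{dataset.cohort_id}: {model.sex_stratum} stratum has "
            f"{len(samples)} samples (< {min_stratum_size})")
    if len(samples) < 10:
        raise InsufficientDataError(
            f"{dataset.cohort_id}: only {len(samples)} analysable samples")

    betas = dataset.betas[samples]
    if remove_outliers:
        betas, _ = remove_methylation_outliers(betas)

    sub = pheno.loc[samples]
    exposure_parent = ("paternal_bmi" if model.exposure == "paternal_bmi_z"
                       else "maternal_bmi")
    other_parent = ("maternal_bmi" if exposure_parent == "paternal_bmi"
                    else "paternal_bmi")
    z_exp = standardize_bmi(sub[exposure_parent])

    if cell_proportions is None:
        cells = estimate_cell_proportions(betas, reference)
    else:
        cells = cell_proportions.loc[samples]
    cell_cols = cells.to_numpy()[:, :-1]  # drop last column (sum constraint)
    cell_names = list(cells.columns[:-1])

    cov = sub[list(COVARIATES)].to_numpy(dtype=float)
    n = len(samples)
    base_cols = [np.ones(n)] + [cov[:, i] for i in range(cov.shape[1])] \
        + [cell_cols[:, i] for i in range(cell_cols.shape[1])]
    base_names = ["intercept", *COVARIATES, *cell_names]

    # SVs are estimated from residuals on the covariates-plus-cells design;
    # the exposure is left out of the residualizing design. Leaving it out
    # lets the SVs retain any batch variation that happens to correlate
    # with the exposure in-sample (which the per-probe model then adjusts
    # away); with realistically many probes the SVs' incidental overlap
    # with true exposure signal is negligible.
    sv_design = np.column_stack(base_cols)
    svs = estimate_surrogate_variables(
        betas, sv_design, model.n_surrogate_variables)

    cols = [np.ones(n), z_exp]
    names = ["intercept", model.exposure]
    if model.mutual_adjustment:
        cols.append(standardize_bmi(sub[other_parent]))
        names.append(f"{other_parent}_z")
    cols += base_cols[1:]
    names += base_names[1:]
    for j in range(svs.shape[1]):
        cols.append(svs[:, j])
        names.append(f"sv{j + 1}")
    x = np.column_stack(cols)
    _design_rank_check(x, names)
    j_exp = 1

    y = betas.to_numpy(dtype=float)
    complete = np.isfinite(y).all(axis=1)
    nb = y.shape[0]
    est = np.full(nb, np.nan)
    se = np.full(nb, np.nan)
    pv = np.full(nb, np.nan)
    nn = np.zeros(nb, dtype=int)

    if complete.any():
        b, s, p, _ = _ols_probe_block(x, y[complete], j_exp)
        est[complete], se[complete], pv[complete] = b, s, p
        nn[complete] = n
    for i in np.nonzero(~complete)[0]:
        ok = np.isfinite(y[i])
        if ok.sum() <= x.shape[1]:
            continue  # probe unanalysable in this cohort
        xs = x[ok]
        if np.linalg.matrix_rank(xs) < xs.shape[1]:
            continue
        b, s, p, _ = _ols_probe_block(xs, y[i, ok][None, :], j_exp)
        est[i], se[i], pv[i] = b[0], s[0], p[0]
        nn[i] = int(ok.sum())

    table = pd.DataFrame({
        "beta": est * 100.0,
        "se": se * 100.0,
        "p": pv,
        "n": nn,
    }, index=betas.index)
    table = table[np.isfinite(table["se"]) & (table["se"] > 0)]
    return CohortEwasResult(cohort_id=dataset.cohort_id, model=model,
                            table=table, n_samples=n)


def regress_cell_on_bmi(
    dataset: CohortDataset,
    estimates: pd.DataFrame,
) -> pd.DataFrame:
    """Simple linear regression of each estimated cell proportion on the
    cohort's paternal BMI Z-score; returns per-cell-type slope, SE and
    two-sided t-based p for downstream meta-analysis."""
    if dataset.n_samples < 3:
        raise InsufficientDataError("need >= 3 samples")
    z = standardize_bmi(dataset.phenotypes["paternal_bmi"])
    x = np.column_stack([np.ones(len(z)), z])
    rows = []
    for cell in estimates.columns:
        y = estimates[cell].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(z)
        b, s, p, _ = _ols_probe_block(x[ok], y[ok][None, :], 1)
        if s[0] == 0:
            logger.warning("cell type %s has (near-)constant proportions", cell)
        rows.append({"cell_type": cell, "estimate": b[0], "se": s[0],
                     "p": p[0], "n": int(ok.sum())})
    return pd.DataFrame(rows).set_index("cell_type")


def parental_bmi_correlation(dataset: CohortDataset) -> tuple[float, float]:
    """Spearman correlation between paternal and maternal BMI with its
    two-sided p-value (assortative-mating check)."""
    pat = dataset.phenotypes["paternal_bmi"].to_numpy(dtype=float)
    mat = dataset.phenotypes["maternal_bmi"].to_numpy(dtype=float)
    ok = np.isfinite(pat) & np.isfinite(mat)
    if ok.sum() < 4:
        raise InsufficientDataError("need >= 4 complete parental BMI pairs")
    rho, p = stats.spearmanr(pat[ok], mat[ok])
    return float(rho), float(p)
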