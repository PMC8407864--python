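"""Synthetic multi-cohort methylation consortium with known ground truth.

The generator emulates the statistical structure of a coordinated
birth-cohort consortium: per-cohort beta-value matrices (CpG x sample,
bounded [0,1]), phenotype tables with correlated parental BMIs and the
standard adjustment covariates, reference-driven cell-mixture structure,
latent technical (batch) factors, and injectable CpG effects with optional
sex restriction. Every downstream stage of the pipeline can therefore be
tested against a known truth without any external data.

Generative model, per probe i and sample j::

    s_ij = logit(m_ij) + (L F')_ij + sum_e  a_e(i) * z_e(j) + eps_ij
    beta_ij = expit(s_ij)

where ``m = R W'`` is the linear cell-mixture expectation (reference
profiles R times Dirichlet mixing weights W), L/F are sparse batch
loadings and standard-normal factors, ``z_e`` is the within-cohort
standardized parental BMI of an injected effect (times a sex indicator
when restricted) and eps is Gaussian noise. The logistic squash keeps
betas bounded while the effect amplitude ``a_e`` is calibrated
numerically so that the *linear-scale* slope equals the requested
percentage-methylation points per 1 SD of BMI.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import InvalidConfigError, UnknownProbeError

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "CellReference",
    "CohortDataset",
    "generate_cell_reference",
    "select_effect_probes",
    "generate_annotation",
    "generate_cohort",
    "generate_consortium",
    "write_cohort",
    "read_cohort",
    "birth_consortium_config",
]

# Default cord-blood style cell panel; nRBC is the cord-specific type.
CORD_CELL_LABELS = ("CD4T", "CD8T", "Bcell", "NK", "Gran", "Mono", "nRBC")
CORD_CELL_MEANS = (0.16, 0.10, 0.07, 0.04, 0.45, 0.08, 0.10)

# Study conditions of the birth-timepoint consortium: 13 cohorts,
# (n, paternal BMI mean/SD, maternal BMI mean/SD); pooled n = 4894.
BIRTH_COHORT_TABLE = (
    (531, 25.0, 3.0, 22.6, 3.3),
    (70, 26.6, 5.3, 26.2, 5.8),
    (115, 27.5, 4.7, 26.7, 6.1),
    (158, 28.0, 4.2, 26.5, 4.5),
    (947, 25.2, 3.2, 23.2, 3.9),
    (390, 25.1, 3.1, 23.4, 3.7),
    (352, 25.8, 3.5, 23.8, 4.5),
    (982, 25.6, 3.1, 24.0, 4.1),
    (621, 25.7, 3.1, 24.3, 4.6),
    (212, 26.0, 3.1, 24.0, 3.9),
    (98, 24.9, 3.0, 22.6, 3.9),
    (324, 26.3, 3.6, 24.3, 4.9),
    (94, 27.2, 4.0, 25.1, 5.5),
)

BMI_BOUNDS = (15.0, 60.0)


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth injected effect at one CpG.

    ``effect_size`` is in percentage-methylation points per 1 SD of the
    parent's BMI on the linear (beta*100) scale; ``parent`` selects which
    standardized exposure drives it ("both" adds the effect for each
    parent); ``sex_restriction`` limits the effect to one offspring sex.
    """

    probe_id: str
    parent: str = "paternal"
    effect_size: float = 1.0
    sex_restriction: str = "none"

    def __post_init__(self) -> None:
        if self.parent not in ("paternal", "maternal", "both"):
            raise InvalidConfigError(f"unknown parent {self.parent!r}")
        if self.sex_restriction not in ("none", "female", "male"):
            raise InvalidConfigError(
                f"unknown sex_restriction {self.sex_restriction!r}")
        if not np.isfinite(self.effect_size):
            raise InvalidConfigError("effect_size must be finite")


@dataclass
class SimulationConfig:
    """Consortium-level simulation parameters.

    ``parent_bmi_correlation`` is the latent bivariate-Gaussian correlation
    between the two parents' BMIs (the consortium reports ~0.2 on the
    Spearman scale); ``bmi_means_sds`` gives per-cohort
    ((paternal mean, SD), (maternal mean, SD)) in kg/m^2; ``noise_sd`` is
    the residual SD on the beta scale; ``n_batch_factors`` latent technical
    factors load sparsely on probes.
    """

    n_cohorts: int = 5
    cohort_sizes: Sequence[int] = (500, 500, 500, 500, 500)
    n_probes: int = 2000
    n_cell_types: int = 7
    n_batch_factors: int = 20
    parent_bmi_correlation: float = 0.2
    bmi_means_sds: Sequence[tuple[tuple[float, float], tuple[float, float]]] | None = None
    noise_sd: float = 0.015
    effect_specs: Sequence[EffectSpec] = ()
    missing_rate: float = 0.0
    seed: int = 0
    cohort_ids: Sequence[str] | None = None
    batch_loading_sd: float = 0.15
    batch_probe_fraction: float = 0.3
    dirichlet_concentration: float = 60.0

    def __post_init__(self) -> None:
        self.cohort_sizes = tuple(int(n) for n in self.cohort_sizes)
        if len(self.cohort_sizes) != self.n_cohorts:
            raise InvalidConfigError(
                f"cohort_sizes has {len(self.cohort_sizes)} entries for "
                f"{self.n_cohorts} cohorts")
        if any(n < 2 for n in self.cohort_sizes):
            raise InvalidConfigError("every cohort needs at least 2 samples")
        if not -1.0 < self.parent_bmi_correlation < 1.0:
            raise InvalidConfigError(
                "parent_bmi_correlation must lie in (-1, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidConfigError("missing_rate must lie in [0, 1)")
        if self.n_probes < len({e.probe_id for e in self.effect_specs}):
            raise InvalidConfigError(
                "n_probes smaller than the number of probes named in "
                "effect_specs")
        if self.bmi_means_sds is None:
            self.bmi_means_sds = tuple(
                ((27.0, 3.2), (23.7, 4.1)) for _ in range(self.n_cohorts))
        if len(self.bmi_means_sds) != self.n_cohorts:
            raise InvalidConfigError("bmi_means_sds length != n_cohorts")
        if self.cohort_ids is None:
            self.cohort_ids = tuple(
                f"cohort_{i + 1:02d}" for i in range(self.n_cohorts))
        elif len(self.cohort_ids) != self.n_cohorts:
            raise InvalidConfigError("cohort_ids length != n_cohorts")


@dataclass
class CellReference:
    """Mean methylation profile per cell type (probes x cell types).

    ``discriminating`` marks the cell-type-discriminating probes that
    deconvolution should use (the DMR panel in reference-based methods);
    when None, all probes are used.
    """

    profiles: pd.DataFrame
    discriminating: pd.Index | None = None

    @property
    def cell_labels(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.profiles.index

    @property
    def deconvolution_probes(self) -> pd.Index:
        return self.probe_ids if self.discriminating is None \
            else self.discriminating


@dataclass
class CohortDataset:
    """One cohort: betas (probes x samples), phenotypes, simulation truth."""

    cohort_id: str
    betas: pd.DataFrame
    phenotypes: pd.DataFrame
    true_cell_proportions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.betas.columns) != list(self.phenotypes.index):
            raise InvalidConfigError(
                "phenotype rows must match beta columns one-to-one")

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]


PHENOTYPE_COLUMNS = (
    "paternal_bmi", "maternal_bmi", "paternal_age", "maternal_age",
    "maternal_smoking", "paternal_smoking", "parity", "paternal_sep",
    "child_sex",
)


def _probe_ids(n_probes: int) -> pd.Index:
    return pd.Index([f"cg{i:08d}" for i in range(n_probes)], name="probe_id")


def generate_cell_reference(
    n_probes: int,
    n_cell_types: int,
    seed: int,
    discriminating_fraction: float = 0.2,
    exclude_discriminating: Sequence[str] = (),
) -> CellReference:
    """Build a synthetic cell-type reference panel.

    Baseline probe means follow the bimodal distribution typical of array
    methylation; a ``discriminating_fraction`` subset of probes (at least
    ``n_cell_types`` of them) gets independent per-cell-type means so that
    the panel has full column rank and deconvolution is identifiable.
    Probes in ``exclude_discriminating`` (e.g. probes carrying injected
    exposure effects) are kept out of the discriminating panel, as real
    candidate CpGs are not part of a deconvolution DMR set.
    """
    if n_cell_types < 2:
        raise InvalidConfigError("need at least 2 cell types")
    if n_probes < n_cell_types:
        raise InvalidConfigError("need n_probes >= n_cell_types")
    rng = np.random.default_rng(seed)
    ids = _probe_ids(n_probes)

    # Bimodal baseline: mostly un/fully methylated with an intermediate arm.
    arm = rng.choice(3, size=n_probes, p=(0.4, 0.4, 0.2))
    baseline = np.where(
        arm == 0, rng.beta(2, 10, n_probes),
        np.where(arm == 1, rng.beta(10, 2, n_probes), rng.beta(5, 5, n_probes)))

    n_disc = min(n_probes, max(n_cell_types, int(round(discriminating_fraction * n_probes))))
    eligible = np.array([i for i, pid in enumerate(ids)
                         if pid not in set(exclude_discriminating)])
    if len(eligible) < n_disc:
        raise InvalidConfigError("too few probes eligible for the "
                                 "discriminating panel")
    disc = rng.choice(eligible, size=n_disc, replace=False)
    profiles = np.tile(baseline[:, None], (1, n_cell_types))
    profiles[disc, :] = rng.uniform(0.05, 0.95, size=(n_disc, n_cell_types))

    if n_cell_types == len(CORD_CELL_LABELS):
        labels = list(CORD_CELL_LABELS)
    else:
        labels = [f"cell_{k + 1}" for k in range(n_cell_types)]
    return CellReference(pd.DataFrame(profiles, index=ids, columns=labels),
                         discriminating=ids[np.sort(disc)])


def generate_annotation(
    probe_ids: Sequence[str],
    seed: int = 0,
    frac_450k_only: float = 0.0,
    frac_epic_only: float = 0.0,
    frac_control: float = 0.0,
    frac_snp: float = 0.0,
    frac_cross_hybridizing: float = 0.0,
    frac_sex_chromosome: float = 0.0,
) -> pd.DataFrame:
    """Random probe annotation table for the generated probes.

    Flags are drawn independently at the given fractions; by default every
    probe is clean, autosomal and common to both arrays. Positions are
    1-based and unique within chromosome.
    """
    rng = np.random.default_rng(seed)
    n = len(probe_ids)
    autosomes = [str(c) for c in range(1, 23)]
    chrom = rng.choice(autosomes, size=n)
    sex = rng.random(n) < frac_sex_chromosome
    chrom[sex] = rng.choice(["X", "Y"], size=int(sex.sum()))
    ann = pd.DataFrame({
        "probe_id": list(probe_ids),
        "chr": chrom,
        "pos": rng.integers(1, 200_000_000, size=n),
        "on_450k": ~(rng.random(n) < frac_epic_only),
        "on_epic": ~(rng.random(n) < frac_450k_only),
        "is_control": rng.random(n) < frac_control,
        "on_snp": rng.random(n) < frac_snp,
        "cross_hybridizing": rng.random(n) < frac_cross_hybridizing,
    })
    return ann


_GH_NODES, _GH_WEIGHTS = None, None


def _gh_mean_expit_deriv(l0: float, tau: float) -> float:
    """E[expit'(l0 + tau*U)] for U ~ N(0,1), by Gauss-Hermite quadrature."""
    global _GH_NODES, _GH_WEIGHTS
    if _GH_NODES is None:
        from scipy.special import roots_hermitenorm
        x, w = roots_hermitenorm(41)
        _GH_NODES, _GH_WEIGHTS = x, w / np.sqrt(2.0 * np.pi)
    p = expit(l0 + tau * _GH_NODES)
    return float((_GH_WEIGHTS * p * (1.0 - p)).sum())


def _calibrate_logit_amplitude(l0: float, linear_delta: float,
                               sigma: float = 0.0) -> float:
    """Logit-scale amplitude whose *linear-scale* regression slope on a
    standard-Gaussian exposure equals ``linear_delta``.

    With beta = expit(l0 + sigma*U + a*Z) and independent standard
    Gaussians U (all non-exposure variation) and Z, Stein's lemma gives the
    population OLS slope on Z as a * E[expit'(l0 + sqrt(sigma^2+a^2) V)];
    we solve that for ``a`` numerically.
    """
    if linear_delta == 0.0:
        return 0.0
    d = abs(linear_delta)

    def slope(a: float) -> float:
        tau = np.hypot(sigma, a)
        return a * _gh_mean_expit_deriv(l0, tau)

    # slope(a) rises from 0, saturates, then decays; bracket the first
    # crossing of d on an increasing grid.
    grid = np.linspace(0.0, 60.0, 601)
    lo = 0.0
    for a in grid[1:]:
        if slope(a) >= d:
            hi = a
            break
        lo = a
    else:
        raise InvalidConfigError(
            f"effect of {linear_delta:+.4f} (beta scale) cannot fit a probe "
            f"with baseline logit {l0:.3f}")
    a = brentq(lambda t: slope(t) - d, lo, hi, xtol=1e-12)
    if a > 1.0:
        # More than one logit unit per SD means the requested linear slope
        # only arises through saturation of the squash - an unrealistic,
        # highly non-linear dose-response. Ask for an intermediate-baseline
        # probe instead (see select_effect_probes).
        raise InvalidConfigError(
            f"effect of {linear_delta:+.4f} (beta scale) is too large for a "
            f"probe with baseline logit {l0:.3f}; choose a probe with an "
            "intermediate methylation baseline")
    return float(np.copysign(a, linear_delta))


def select_effect_probes(
    reference: CellReference,
    n: int,
    seed: int = 0,
    baseline_range: tuple[float, float] = (0.2, 0.8),
) -> list[str]:
    """Choose ``n`` probes suitable for effect injection: intermediate
    population-baseline methylation (linear effects have headroom there)
    and outside the deconvolution panel."""
    if len(CORD_CELL_MEANS) == reference.profiles.shape[1]:
        wbase = np.asarray(CORD_CELL_MEANS)
    else:
        wbase = np.full(reference.profiles.shape[1],
                        1.0 / reference.profiles.shape[1])
    m0 = reference.profiles.to_numpy() @ wbase
    disc = set(reference.deconvolution_probes) \
        if reference.discriminating is not None else set()
    ok = [(pid, m) for pid, m in zip(reference.probe_ids, m0)
          if baseline_range[0] <= m <= baseline_range[1] and pid not in disc]
    if len(ok) < n:
        raise InvalidConfigError(
            f"only {len(ok)} probes have baseline in {baseline_range} and "
            "sit outside the deconvolution panel")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(ok), size=n, replace=False)
    return [ok[i][0] for i in np.sort(pick)]


def _cohort_rng(seed: int, cohort_index: int) -> np.random.Generator:
    # Deterministic child stream per (master seed, cohort index).
    return np.random.default_rng(np.random.SeedSequence((seed, cohort_index)))


def generate_cohort(
    config: SimulationConfig,
    cohort_index: int,
    reference: CellReference,
) -> CohortDataset:
    """Generate one cohort's betas, phenotypes and ground-truth mixing.

    Parental BMIs come from a bivariate Gaussian with the configured
    correlation, truncated to plausible bounds (15-60 kg/m^2); cell
    proportions from a Dirichlet centred on typical cord-blood fractions;
    the methylation signal from the logistic-scale model in the module
    docstring; missingness is completely at random.
    """
    if cohort_index >= config.n_cohorts:
        raise InvalidConfigError(
            f"cohort_index {cohort_index} out of range (K={config.n_cohorts})")
    n = config.cohort_sizes[cohort_index]
    if n < 2:
        raise InvalidConfigError("cohort size must be >= 2")
    if reference.profiles.shape[0] != config.n_probes:
        raise InvalidConfigError("reference panel does not match n_probes")
    probe_index = reference.probe_ids
    for spec in config.effect_specs:
        if spec.probe_id not in probe_index:
            raise UnknownProbeError(
                f"effect probe {spec.probe_id!r} absent from annotation")

    rng = _cohort_rng(config.seed, cohort_index)
    cohort_id = config.cohort_ids[cohort_index]
    sample_ids = pd.Index(
        [f"{cohort_id}_s{j:05d}" for j in range(n)], name="sample_id")

    # --- phenotypes -------------------------------------------------------
    (pat_mean, pat_sd), (mat_mean, mat_sd) = config.bmi_means_sds[cohort_index]
    rho = config.parent_bmi_correlation
    cov = np.array([[pat_sd**2, rho * pat_sd * mat_sd],
                    [rho * pat_sd * mat_sd, mat_sd**2]])
    bmi = rng.multivariate_normal([pat_mean, mat_mean], cov, size=n,
                                  method="cholesky")
    bmi = np.clip(bmi, *BMI_BOUNDS)
    child_sex = np.where(rng.random(n) < 0.48, "female", "male")
    pheno = pd.DataFrame({
        "paternal_bmi": bmi[:, 0],
        "maternal_bmi": bmi[:, 1],
        "paternal_age": np.clip(rng.normal(31.0, 5.0, n), 16, 70),
        "maternal_age": np.clip(rng.normal(29.0, 4.5, n), 16, 55),
        "maternal_smoking": (rng.random(n) < 0.15).astype(int),
        "paternal_smoking": (rng.random(n) < 0.25).astype(int),
        "parity": (rng.random(n) < 0.45).astype(int),
        "paternal_sep": (rng.random(n) < 0.30).astype(int),
        "child_sex": child_sex,
    }, index=sample_ids)

    # --- cell mixture -----------------------------------------------------
    k = config.n_cell_types
    if k == len(CORD_CELL_MEANS):
        base = np.asarray(CORD_CELL_MEANS)
    else:
        base = np.full(k, 1.0 / k)
    w = rng.dirichlet(base * config.dirichlet_concentration, size=n)  # n x k
    cells = pd.DataFrame(w, index=sample_ids,
                         columns=reference.cell_labels)
    mixture = reference.profiles.to_numpy() @ w.T  # probes x n

    # --- logistic-scale signal -------------------------------------------
    eps = 1e-6
    signal = logit(np.clip(mixture, eps, 1 - eps))

    if config.n_batch_factors > 0:
        b = config.n_batch_factors
        loadings = rng.normal(0.0, config.batch_loading_sd,
                              size=(config.n_probes, b))
        loadings *= rng.random((config.n_probes, b)) < config.batch_probe_fraction
        factors = rng.normal(size=(n, b))
        signal += loadings @ factors.T

    if config.effect_specs:
        zs = {}
        for parent in ("paternal", "maternal"):
            x = pheno[f"{parent}_bmi"].to_numpy()
            zs[parent] = (x - x.mean()) / x.std(ddof=1)
        probe_pos = {p: i for i, p in enumerate(probe_index)}
        # Calibration must see every non-exposure source of logit-scale
        # variation (mixture, batch, noise) so the squash's smoothing of
        # the slope is compensated exactly.
        m0c = np.clip(mixture.mean(axis=1), 0.05, 0.95)
        noise_logit_sd = (config.noise_sd / (m0c * (1.0 - m0c))
                          if config.noise_sd > 0 else np.zeros_like(m0c))
        base_sd = signal.std(axis=1)
        total_sd = np.hypot(base_sd, noise_logit_sd)
        base_mean = signal.mean(axis=1)
        for spec in config.effect_specs:
            i = probe_pos[spec.probe_id]
            amp = _calibrate_logit_amplitude(
                base_mean[i], spec.effect_size / 100.0, sigma=total_sd[i])
            parents = (("paternal", "maternal") if spec.parent == "both"
                       else (spec.parent,))
            mask = np.ones(n)
            if spec.sex_restriction != "none":
                mask = (child_sex == spec.sex_restriction).astype(float)
            for parent in parents:
                signal[i, :] += amp * zs[parent] * mask

    if config.noise_sd > 0:
        m0c = np.clip(mixture.mean(axis=1), 0.05, 0.95)
        logit_sd = config.noise_sd / (m0c * (1.0 - m0c))
        signal += rng.normal(size=(config.n_probes, n)) * logit_sd[:, None]

    betas = expit(signal)
    if config.missing_rate > 0:
        betas[rng.random(betas.shape) < config.missing_rate] = np.nan

    return CohortDataset(
        cohort_id=cohort_id,
        betas=pd.DataFrame(betas, index=probe_index, columns=sample_ids),
        phenotypes=pheno,
        true_cell_proportions=cells,
    )


def generate_consortium(
    config: SimulationConfig,
    reference: CellReference | None = None,
) -> tuple[list[CohortDataset], CellReference]:
    """Generate all cohorts of a consortium (shared reference panel)."""
    if reference is None:
        reference = generate_cell_reference(
            config.n_probes, config.n_cell_types, seed=config.seed,
            exclude_discriminating=[e.probe_id for e in config.effect_specs])
    datasets = [generate_cohort(config, i, reference)
                for i in range(config.n_cohorts)]
    return datasets, reference


def birth_consortium_config(
    n_probes: int = 2000,
    seed: int = 0,
    effect_specs: Sequence[EffectSpec] = (),
    **overrides,
) -> SimulationConfig:
    """The 13-cohort birth-timepoint study conditions (pooled n = 4894,
    parental-BMI correlation 0.2, per-cohort BMI means/SDs)."""
    sizes = tuple(row[0] for row in BIRTH_COHORT_TABLE)
    means = tuple(((row[1], row[2]), (row[3], row[4]))
                  for row in BIRTH_COHORT_TABLE)
    kwargs = dict(
        n_cohorts=len(sizes),
        cohort_sizes=sizes,
        n_probes=n_probes,
        parent_bmi_correlation=0.2,
        bmi_means_sds=means,
        effect_specs=tuple(effect_specs),
        seed=seed,
        cohort_ids=tuple(f"birth_{i + 1:02d}" for i in range(len(sizes))),
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


# --- serialization --------------------------------------------------------

_FLOAT_FMT = "%.17g"  # full round-trip precision, deterministic


def write_cohort(dataset: CohortDataset, directory: str | Path,
                 effect_specs: Sequence[EffectSpec] = ()) -> dict[str, Path]:
    """Write one cohort to ``directory``.

    Emits ``betas.tsv`` (TSV, first column probe id, missing as "NA"),
    ``phenotypes.csv`` and a ground-truth sidecar (``truth_cells.tsv`` +
    ``truth_effects.tsv``). Writes are byte-deterministic.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "betas": directory / "betas.tsv",
        "phenotypes": directory / "phenotypes.csv",
        "truth_cells": directory / "truth_cells.tsv",
        "truth_effects": directory / "truth_effects.tsv",
    }
    dataset.betas.to_csv(paths["betas"], sep="\t", na_rep="NA",
                         float_format=_FLOAT_FMT)
    dataset.phenotypes.to_csv(paths["phenotypes"], float_format=_FLOAT_FMT)
    if dataset.true_cell_proportions is not None:
        dataset.true_cell_proportions.to_csv(
            paths["truth_cells"], sep="\t", float_format=_FLOAT_FMT)
    effects = pd.DataFrame(
        [dataclasses.asdict(e) for e in effect_specs],
        columns=["probe_id", "parent", "effect_size", "sex_restriction"])
    effects.to_csv(paths["truth_effects"], sep="\t", index=False,
                   float_format=_FLOAT_FMT)
    return paths


def read_cohort(directory: str | Path, cohort_id: str | None = None) -> CohortDataset:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    betas = pd.read_csv(directory / "betas.tsv", sep="\t",
                        index_col="probe_id", na_values=["NA"])
    pheno = pd.read_csv(directory / "phenotypes.csv", index_col="sample_id")
    cells_path = directory / "truth_cells.tsv"
    cells = (pd.read_csv(cells_path, sep="\t", index_col="sample_id")
             if cells_path.exists() and cells_path.stat().st_size > 0 else None)
    return CohortDataset(
        cohort_id=cohort_id or directory.name,
        betas=betas, phenotypes=pheno, true_cell_proportions=cells)
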