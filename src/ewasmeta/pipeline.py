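"""End-to-end orchestration of the consortium analysis.

Composes the stages in the pre-specified order: probe filtering ->
cohort-level EWAS over the model grid -> cohort QC -> fixed-effects
meta-analysis per model -> FDR -> meta QC -> leave-one-out at top probes ->
meta-regression on cohort mean age -> sensitivity subset meta-analyses ->
model comparison and candidate-set enrichment. Every artefact is written
as a TSV plus a manifest recording the configuration hash and seed, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import compare as cmp_mod
from . import ewas as ewas_mod
from . import meta as meta_mod
from . import probes as probes_mod
from . import qc as qc_mod
from . import simulate as sim_mod
from .errors import EwasMetaError, StratumTooSmallError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_full_pipeline",
            "default_model_grid"]

_FLOAT_FMT = "%.10g"


def default_model_grid(n_surrogate_variables: int = 20
                       ) -> list[ewas_mod.EwasModelSpec]:
    """The analysis plan's model grid: each parent's BMI, with and without
    mutual adjustment, for all offspring and each sex stratum."""
    grid = []
    for exposure in ("paternal_bmi_z", "maternal_bmi_z"):
        for mutual in (False, True):
            for stratum in ("all", "female", "male"):
                grid.append(ewas_mod.EwasModelSpec(
                    exposure=exposure, mutual_adjustment=mutual,
                    sex_stratum=stratum,
                    n_surrogate_variables=n_surrogate_variables))
    return grid


@dataclass
class RunConfig:
    """Machine form of the shared analysis plan.

    Either ``cohort_dirs`` (written cohorts) or ``simulation`` (a
    SimulationConfig) supplies the data. Thresholds: FDR 0.05, leave-one-out
    attenuation 0.20, minimum sex-stratum size 30, relaxed top-probe
    threshold 1e-5.
    """

    output_dir: str = "ewasmeta_out"
    seed: int = 0
    simulation: sim_mod.SimulationConfig | None = None
    cohort_dirs: list[str] = field(default_factory=list)
    annotation_path: str | None = None
    candidate_set_paths: dict[str, str] = field(default_factory=dict)
    models: list[ewas_mod.EwasModelSpec] = field(default_factory=default_model_grid)
    fdr_threshold: float = 0.05
    attenuation_threshold: float = 0.20
    min_stratum_size: int = 30
    relaxed_p_threshold: float = 1e-5
    exclusion_sets: dict[str, list[str]] = field(default_factory=dict)
    cohort_mean_ages: dict[str, float] = field(default_factory=dict)
    extreme_estimate_threshold: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise EwasMetaError("fdr_threshold must lie in (0,1)")
        if not 0 < self.attenuation_threshold:
            raise EwasMetaError("attenuation_threshold must be positive")
        if self.min_stratum_size < 2:
            raise EwasMetaError("min_stratum_size must be >= 2")

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj
        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            effects = [sim_mod.EffectSpec(**e)
                       for e in sim.pop("effect_specs", [])]
            raw["simulation"] = sim_mod.SimulationConfig(
                effect_specs=tuple(effects), **sim)
        if "models" in raw:
            raw["models"] = [ewas_mod.EwasModelSpec(**m)
                             for m in raw["models"]]
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory view of the pipeline outputs (all are also written)."""

    cohort_results: dict  # (cohort_id, model_label) -> result table
    meta_results: dict    # model_label -> meta table
    qc: qc_mod.QcReport
    loo: dict             # model_label -> {probe_id -> LeaveOneOutReport}
    sensitivity: dict     # (set name, model_label) -> meta table
    comparison: dict      # model pair label -> comparison dict
    enrichment: pd.DataFrame
    meta_regression: dict  # model_label -> (slope, se, p) or None
    manifest: dict
    filter_counts: dict
    output_dir: Path


def _stratum_tag(model: ewas_mod.EwasModelSpec) -> str:
    return model.label


def run_full_pipeline(
    config: RunConfig,
    datasets: list[sim_mod.CohortDataset] | None = None,
    reference: sim_mod.CellReference | None = None,
    annotation: pd.DataFrame | None = None,
) -> PipelineResult:
    """Execute the full analysis plan and write all artefacts.

    Data can be passed in-memory (``datasets``/``reference``) or loaded
    from ``config.cohort_dirs``; with neither, ``config.simulation``
    generates a synthetic consortium. Stage failures propagate with the
    stage name in the message; partial outputs remain on disk next to a
    ``FAILED`` marker.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        result = _run(config, datasets, reference, annotation, out)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return result


def _run(config, datasets, reference, annotation, out: Path) -> PipelineResult:
    # --- stage: inputs ----------------------------------------------------
    if datasets is None:
        if config.cohort_dirs:
            datasets = [sim_mod.read_cohort(d) for d in config.cohort_dirs]
        elif config.simulation is not None:
            datasets, reference = sim_mod.generate_consortium(config.simulation)
        else:
            raise EwasMetaError("inputs stage: no datasets, cohort_dirs or "
                                "simulation config supplied")
    if reference is None:
        raise EwasMetaError("inputs stage: a cell-type reference is required")
    cohort_order = [d.cohort_id for d in datasets]

    # --- stage 1: probe filtering ----------------------------------------
    if annotation is None:
        if config.annotation_path:
            annotation = probes_mod.read_annotation(config.annotation_path)
        else:
            annotation = sim_mod.generate_annotation(
                datasets[0].betas.index, seed=config.seed)
    retained, filter_counts = probes_mod.filter_probes(annotation)
    logger.info("probe filtering: %d retained, exclusions %s",
                len(retained), dict(filter_counts))

    # --- stage: cohort EWAS over the model grid ---------------------------
    ewas_dir = out / "cohort_results"
    ewas_dir.mkdir(exist_ok=True)
    cohort_results: dict[tuple[str, str], pd.DataFrame] = {}
    for ds in datasets:
        keep = ds.betas.index.intersection(retained)
        ds_f = sim_mod.CohortDataset(
            cohort_id=ds.cohort_id, betas=ds.betas.loc[keep],
            phenotypes=ds.phenotypes,
            true_cell_proportions=ds.true_cell_proportions)
        for model in config.models:
            try:
                res = ewas_mod.run_ewas(
                    ds_f, model, reference,
                    min_stratum_size=config.min_stratum_size)
            except StratumTooSmallError as exc:
                logger.warning("cohort EWAS: %s", exc)
                continue
            cohort_results[(ds.cohort_id, model.label)] = res.table
            res.write(ewas_dir / f"{ds.cohort_id}_{model.label}.tsv")
    if not cohort_results:
        raise EwasMetaError("cohort EWAS stage produced no results")

    # --- stage 2: cohort QC ----------------------------------------------
    qc_report = qc_mod.cohort_qc(
        cohort_results, extreme_threshold=config.extreme_estimate_threshold)
    qc_report.summary.to_csv(out / "cohort_qc.tsv", sep="\t",
                             float_format=_FLOAT_FMT)

    # --- stages 3-5: meta-analysis, FDR, meta QC --------------------------
    model_labels = sorted({m for _, m in cohort_results})
    meta_results: dict[str, pd.DataFrame] = {}
    meta_qc_rows = []
    for label in model_labels:
        tables = {c: t for (c, m), t in cohort_results.items() if m == label}
        meta_tab = meta_mod.meta_analyse(
            tables, cohort_order=[c for c in cohort_order if c in tables])
        meta_results[label] = meta_tab
        meta_tab.to_csv(out / f"meta_{label}.tsv", sep="\t",
                        float_format=_FLOAT_FMT)
        meta_qc_rows.append({
            "model": label,
            "lambda": meta_mod.genomic_inflation_lambda(meta_tab["p"]),
            "n_probes": len(meta_tab),
            "n_fdr_significant": int((meta_tab["fdr_p"]
                                      < config.fdr_threshold).sum()),
        })
    pd.DataFrame(meta_qc_rows).set_index("model").to_csv(
        out / "meta_qc.tsv", sep="\t", float_format=_FLOAT_FMT)

    # --- stage 6: leave-one-out at top probes -----------------------------
    loo: dict[str, dict] = {}
    loo_rows = []
    for label, meta_tab in meta_results.items():
        tables = {c: t for (c, m), t in cohort_results.items() if m == label}
        top = meta_tab.index[
            (meta_tab["fdr_p"] < config.fdr_threshold)
            | (meta_tab["p"] < config.relaxed_p_threshold)]
        loo[label] = {}
        for pid in top:
            betas = {c: t.loc[pid, "beta"] for c, t in tables.items()
                     if pid in t.index}
            ses = {c: t.loc[pid, "se"] for c, t in tables.items()
                   if pid in t.index}
            rep = meta_mod.leave_one_out(
                betas, ses, probe_id=pid,
                attenuation_threshold=config.attenuation_threshold)
            loo[label][pid] = rep
            loo_rows.append({"model": label, "probe_id": pid,
                             "survived": rep.survived,
                             "failure_reasons": ";".join(sorted(rep.failure_reasons))})
    pd.DataFrame(loo_rows, columns=["model", "probe_id", "survived",
                                    "failure_reasons"]).to_csv(
        out / "leave_one_out.tsv", sep="\t", index=False)

    # --- stage 7: meta-regression on cohort mean age ----------------------
    # Applied at the same top-probe tier as leave-one-out: for each probe,
    # IVW regression of the cohort estimates on cohort mean age at sample
    # collection. Skipped (with a log note) when no ages are configured,
    # e.g. for birth cohorts where collection age is ~0 for everyone.
    meta_regression: dict[str, pd.DataFrame | None] = {}
    if config.cohort_mean_ages:
        mr_rows = []
        for label, meta_tab in meta_results.items():
            tables = {c: t for (c, m), t in cohort_results.items()
                      if m == label and c in config.cohort_mean_ages}
            probes = list(loo[label])
            for pid in probes:
                cs = [c for c, t in tables.items() if pid in t.index]
                if len(cs) < 3:
                    continue
                try:
                    slope, se, p = meta_mod.meta_regression_age(
                        [tables[c].loc[pid, "beta"] for c in cs],
                        [tables[c].loc[pid, "se"] for c in cs],
                        [config.cohort_mean_ages[c] for c in cs])
                except EwasMetaError as exc:
                    logger.warning("meta-regression: %s", exc)
                    continue
                mr_rows.append({"model": label, "probe_id": pid,
                                "slope_per_year": slope, "se": se, "p": p})
        mr_table = pd.DataFrame(
            mr_rows, columns=["model", "probe_id", "slope_per_year", "se", "p"])
        mr_table.to_csv(out / "meta_regression.tsv", sep="\t", index=False,
                        float_format=_FLOAT_FMT)
        for label in model_labels:
            sub = mr_table[mr_table["model"] == label]
            meta_regression[label] = sub if len(sub) else None
    else:
        logger.info("meta-regression skipped: no cohort mean ages supplied")

    # --- stages 8-9: sensitivity subset meta-analyses ---------------------
    sensitivity: dict[tuple[str, str], pd.DataFrame] = {}
    for set_name, excluded in config.exclusion_sets.items():
        for label in model_labels:
            tables = {c: t for (c, m), t in cohort_results.items()
                      if m == label and c not in set(excluded)}
            if not tables:
                continue
            sens = meta_mod.meta_analyse(
                tables, cohort_order=[c for c in cohort_order if c in tables])
            sensitivity[(set_name, label)] = sens
            sens.to_csv(out / f"sensitivity_{set_name}_{label}.tsv",
                        sep="\t", float_format=_FLOAT_FMT)

    # --- comparison of adjusted vs unadjusted models ----------------------
    comparison: dict[str, dict] = {}
    for parent in ("paternal", "maternal"):
        la, lb = f"{parent}_adjusted_all", f"{parent}_unadjusted_all"
        if la in meta_results and lb in meta_results:
            comparison[f"{parent}_adjusted_vs_unadjusted"] = \
                cmp_mod.compare_model_estimates(meta_results[la],
                                                meta_results[lb])
    if comparison:
        pd.DataFrame(comparison).T.to_csv(out / "model_comparison.tsv",
                                          sep="\t")

    # --- candidate-set enrichment ----------------------------------------
    enr_rows = []
    for set_name, path in config.candidate_set_paths.items():
        cand = cmp_mod.CandidateSet.from_probe_file(set_name, path)
        for label, meta_tab in meta_results.items():
            try:
                hit = cand.intersect(meta_tab.index)
            except EwasMetaError as exc:
                logger.warning("enrichment: %s", exc)
                continue
            d, ks_p = cmp_mod.ks_enrichment(
                meta_tab.loc[sorted(hit), "p"].to_numpy())
            row = {"set": set_name, "model": label, "n_overlap": len(hit),
                   "D": d, "ks_p": ks_p}
            if cand.expected_direction:
                conc = cmp_mod.direction_concordance(
                    {p: s for p, s in cand.expected_direction.items()
                     if p in hit}, meta_tab)
                row.update({"n_concordant": conc["n_same_direction"],
                            "n_total": conc["n_total"]})
            enr_rows.append(row)
    enrichment = pd.DataFrame(enr_rows)
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_cohorts": len(datasets),
        "n_probes_retained": int(len(retained)),
        "filter_counts": dict(filter_counts),
        "models": model_labels,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        cohort_results=cohort_results, meta_results=meta_results,
        qc=qc_report, loo=loo, sensitivity=sensitivity,
        comparison=comparison, enrichment=enrichment,
        meta_regression=meta_regression, manifest=manifest,
        filter_counts=dict(filter_counts), output_dir=out)
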