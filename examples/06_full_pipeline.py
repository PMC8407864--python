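"""End-to-end pipeline run from a single configuration object.

Simulates a consortium with four female-restricted CpG effects, runs the
whole analysis plan (filtering, cohort EWAS over a model grid, QC,
meta-analysis, FDR, leave-one-out) and prints where the injected signal
surfaced. All artefacts land in scratch/pipeline_demo as TSVs plus a
manifest that makes the run reproducible.
"""

import ewasmeta as em

reference = em.generate_cell_reference(2000, 7, seed=21)
probes = em.select_effect_probes(reference, 4, seed=21)
sim = em.SimulationConfig(
    n_cohorts=4, cohort_sizes=(350,) * 4, n_probes=2000, seed=21,
    effect_specs=tuple(
        em.EffectSpec(p, "paternal", 2.0, sex_restriction="female")
        for p in probes),
)
models = [em.EwasModelSpec(sex_stratum=s, n_surrogate_variables=10)
          for s in ("all", "female", "male")]
config = em.RunConfig(output_dir="scratch/pipeline_demo", seed=21,
                      simulation=sim, models=models)

datasets, _ = em.generate_consortium(sim, reference=reference)
result = em.run_full_pipeline(config, datasets=datasets,
                              reference=reference)

print(f"artefacts in {result.output_dir} "
      f"(config hash {result.manifest['config_hash'][:12]}...)")
for label, meta in sorted(result.meta_results.items()):
    n_sig = int((meta["fdr_p"] < 0.05).sum())
    lam = em.genomic_inflation_lambda(meta["p"])
    print(f"  {label}: lambda={lam:.3f}, FDR<0.05 hits={n_sig}")

female = result.meta_results["paternal_unadjusted_female"]
print("\ninjected female-restricted probes in the female stratum:")
print(female.loc[probes, ["beta", "se", "fdr_p"]]
      .to_string(float_format=lambda v: f"{v:.3g}"))
survived = [pid for pid in probes
            if result.loo["paternal_unadjusted_female"][pid].survived]
print(f"leave-one-out survivors: {len(survived)}/{len(probes)}")

# The effects appear at FDR<0.05 only in the female stratum and survive
# leave-one-out, the signature of a robust sex-specific association.
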