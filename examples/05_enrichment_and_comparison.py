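"""Candidate-set enrichment and maternal-vs-paternal comparison.

Runs paternal and maternal EWAS meta-analyses on a consortium where only
the paternal exposure has effects, then (1) tests KS enrichment of the
candidate set in each parent's p-values, (2) contrasts the two parents'
estimates at the top probes with the Cochran Q heterogeneity statistic.
"""

import ewasmeta as em

reference = em.generate_cell_reference(2000, 7, seed=12)
candidates = em.select_effect_probes(reference, 15, seed=12)
cfg = em.SimulationConfig(
    n_cohorts=4, cohort_sizes=(400,) * 4, n_probes=2000, seed=12,
    effect_specs=tuple(em.EffectSpec(p, "paternal", 1.2)
                       for p in candidates),
)
datasets, _ = em.generate_consortium(cfg, reference=reference)

metas = {}
for exposure in ("paternal_bmi_z", "maternal_bmi_z"):
    model = em.EwasModelSpec(exposure=exposure, mutual_adjustment=True)
    tabs = {d.cohort_id: em.run_ewas(d, model, reference).table
            for d in datasets}
    metas[exposure] = em.meta_analyse(tabs)

for exposure, meta in metas.items():
    d, p = em.ks_enrichment(meta.loc[candidates, "p"].to_numpy())
    print(f"KS enrichment of the candidate set in the {exposure} "
          f"meta-analysis: D={d:.3f}, p={p:.3g}")

top = metas["paternal_bmi_z"].nsmallest(3, "p").index
print("\nparental heterogeneity at the top paternal probes:")
for pid in top:
    pat = metas["paternal_bmi_z"].loc[pid]
    mat = metas["maternal_bmi_z"].loc[pid]
    het = em.parental_heterogeneity_q((pat["beta"], pat["se"]),
                                      (mat["beta"], mat["se"]))
    print(f"  {pid}: paternal {pat['beta']:+.2f}, maternal "
          f"{mat['beta']:+.2f}, Q={het['q']:.1f} (p={het['p']:.2g}, "
          f"I2={het['i2']:.0f}%)")

# The candidate set is strongly enriched only for the parent whose
# exposure carries the injected effects, and the per-probe Q confirms the
# paternal and maternal estimates differ beyond chance at those sites.
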