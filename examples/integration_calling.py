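"""The two methylation-expression integration procedures.

First, a demethylation-treatment experiment: genes with a significant
promoter DMR (demethylation delta > 0.2, p < 0.05) AND significant
upregulation (fold change > 2, p < 0.05) are called reactivated.  Second,
the tumor-cohort procedure: genes whose expression falls with the CIMP score
and that carry a hypermethylated promoter/body probe in hCIMP vs lCIMP are
called repressed.  The intersection of the two lists mirrors the search for
genes silenced in high-CIMP tumors and rescuable by a demethylating agent.
"""

from cimpkit import (
    CimpSignature, CohortConfig, DemethylationConfig, build_promoter_windows,
    call_reactivated_genes, call_repressed_genes, compute_cimp_score,
    intersect_calls, simulate_cohort, simulate_demethylation_experiment,
)

experiment = simulate_demethylation_experiment(
    DemethylationConfig(seed=7, n_genes=50, n_planted=5))
promoters = build_promoter_windows(experiment.gene_models)
reactivated = call_reactivated_genes(experiment.dmrs, experiment.de, promoters)
print("reactivated genes:", [c.gene_id for c in reactivated])
print("planted truth:    ", list(experiment.reactivated_genes))

cohort = simulate_cohort(CohortConfig(seed=42))
score = compute_cimp_score(
    cohort.beta, CimpSignature(cohort.ground_truth.signature_probes))
repressed = call_repressed_genes(
    cohort.beta, cohort.annotation, cohort.expression, score,
    cohort.metadata, cohort.gene_models)
wired = set(cohort.ground_truth.immune_marker_genes)
called = {c.gene_id for c in repressed}
print(f"repressed genes called: {len(called)} "
      f"({len(called & wired)}/{len(wired)} wired immune markers, "
      f"{len(called - wired)} others)")

both = intersect_calls(repressed, list(called))
print(f"repressed-and-reactivatable intersection size: {len(both)}")
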