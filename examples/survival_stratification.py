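"""Overall survival stratified by DNMT1 expression tertiles.

Samples are split into low/medium/high thirds of DNMT1 expression;
Kaplan-Meier curves are estimated per stratum and compared with the k-group
log-rank test, Bonferroni-adjusted for the two DNMT genes examined.  In the
synthetic cohort the death hazard rises with DNMT expression, so the high
tertile should die sooner.
"""

from cimpkit import CohortConfig, simulate_cohort, survival_by_expression

cohort = simulate_cohort(CohortConfig(seed=42, n_samples=120))

for gene in ("DNMT1", "DNMT3A"):
    result = survival_by_expression(cohort.expression, gene, cohort.metadata,
                                    n_genes_tested=2)
    print(f"{gene}: log-rank chi2 = {result.logrank_statistic:.1f}, "
          f"p = {result.logrank_p:.2e}, "
          f"Bonferroni-adjusted p = {result.adjusted_p:.2e}")
    for stratum in ("low", "medium", "high"):
        print(f"  {stratum:6s} median survival = "
              f"{result.median_survival[stratum]:7.0f} days")
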