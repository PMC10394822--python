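# cimpkit

Analysis toolkit for the CpG island methylator phenotype (CIMP) in tumor
cohorts: signature scoring from methylation β-values, partial-correlation
modelling of what drives the phenotype, and the downstream consequences —
enrichment, immune-cell depletion, methylation-repressed gene calling and
survival stratification.

## The scientific problem

In several cancers — adrenocortical carcinoma being a striking example — a
subgroup of tumors coordinately hypermethylates hundreds of promoter CpG
islands (graded lCIMP / iCIMP / hCIMP) and carries a markedly worse
prognosis. Two questions drive the analyses implemented here:

1. **What establishes the phenotype?** The working model is a causal chain:
   copy-number gains and cell hyperproliferation raise expression of the DNA
   methyltransferases *DNMT1* and *DNMT3A*, and the excess methyltransferase
   writes the promoter hypermethylation. With a proliferation score $P$,
   methyltransferase expression $D_k$ and a CIMP score $C$, the chain
   $P \to D \to C$ predicts
   $r(P, C) \gg 0$, $r(D_k, C \mid P) \gg 0$ and $r(P, C \mid D_1, D_2)
   \approx 0$, whereas a common cause ($D \leftarrow P \to C$) predicts
   $r(D_k, C \mid P) \approx 0$. `mediation_report` computes exactly these
   residual-based Pearson partial correlations and issues a verdict.
2. **What does the phenotype do?** CIMP scoring
   ($C = \sum_{j \in \text{signature}} \beta_j$ over promoter probes whose
   methylation rises monotonically across the groups), GSEA with
   signal-to-noise ranking $(\mu_a - \mu_b)/(\sigma_a + \sigma_b)$, marker-set
   immune deconvolution (mean $\log_2(x+1)$ of population markers, compared
   with Kruskal–Wallis + Dunn + Benjamini–Hochberg), promoter-window
   DMR/expression integration (TSS − 1000 bp .. TSS + 200 bp), and
   Kaplan–Meier curves by expression tertile with log-rank tests.

Because the cohorts such analyses run on are large external data sets, the
package ships a **synthetic cohort generator** (`simulate_cohort`) that
encodes the causal chain above with known ground truth — planted signature
probes, latent proliferation and CIMP values, wired immune marker genes, a
DNMT-dependent death hazard — so every stage is testable for *recovery*, not
just for running.

## Worked example

`examples/mediation_analysis.py` simulates an 80-tumor cohort, scores CIMP
from the planted signature, adjusts for tumor purity, builds a proliferation
module-activity score and runs the mediation report:

```
r(proliferation, CIMP)             = +0.68  (p = 3.3e-12)
r(DNMT1, CIMP | proliferation)  = +0.50  (p = 3e-06)
r(DNMT3A, CIMP | proliferation)  = +0.57  (p = 5.5e-08)
r(proliferation, CIMP | DNMTs)     = -0.02  (p = 0.89)
verdict: mediation_consistent
```

Proliferation and the CIMP score are strongly associated, each
methyltransferase remains associated with CIMP after removing the
proliferation effect, and the proliferation–CIMP association vanishes once
both methyltransferases are controlled for — the mediation pattern. The other
scripts in `examples/` (one per capability: simulation, CIMP scoring,
enrichment, immune deconvolution, integration calling, survival
stratification) are equally short and print what they compute.

## Layout

```
src/cimpkit/
  io.py          typed containers + TSV/GMT readers and writers
  simulate.py    synthetic cohort and demethylation-experiment generators
  cimp.py        signature selection, CIMP score
  association.py correlations, partial correlations, mediation report,
                 stemness and module-activity scores
  enrichment.py  signal-to-noise GSEA, over-representation tests
  immune.py      marker-set abundance, Kruskal-Wallis + Dunn + BH
  integrate.py   promoter windows, reactivated/repressed gene calling
  survival.py    Kaplan-Meier, log-rank, expression-tertile stratification
examples/        one narrative script per capability
docs/methods.md  models, assumptions, parameter choices, limitations
```
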