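"""Synthetic tumor cohorts with a known causal structure.

The generator emits a cohort in which a latent proliferation drive ``P`` and
per-locus copy-number gains jointly raise the expression of two DNA
methyltransferases (DNMT1, DNMT3A); DNMT expression in turn raises a latent
methylator-phenotype variable ``C`` (CIMP); ``C`` hypermethylates a planted
set of promoter probes and represses immune marker genes; DNMT expression
raises the death hazard.  Tumor purity dilutes the observed methylation
signal.  All coefficients sit in :class:`CohortConfig`, so downstream
analyses (signature selection, mediation modelling, deconvolution, survival)
can be tested against known ground truth, including null and common-cause
variants obtained by zeroing individual edges.

Causal graph (defaults)::

    gain_k --a_k-->  DNMT_k --g_k--> C --> beta(signature probes)
    P ------b_k-/        \\            \\--> immune marker expression (down)
     \\__________ d ______/ \\--> survival hazard
    (d = coef_prolif_to_cimp, 0 by default; set >0 with g_k = 0 for the
     common-cause structure D <- P -> C)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    BetaMatrix,
    DETable,
    DMRTable,
    ExpressionMatrix,
    GeneModelTable,
    GeneSetCollection,
    ProbeAnnotation,
    SampleMetadata,
    write_beta_matrix,
    write_de_table,
    write_dmr_table,
    write_expression_matrix,
    write_gene_models,
    write_gmt,
    write_metadata,
    write_probe_annotation,
)

DNMT_LOCI = ("DNMT1", "DNMT3A")

#: Populations whose marker genes respond (negatively) to the CIMP latent.
IMMUNE_POPULATIONS = (
    "T cells",
    "CD8 T cells",
    "Cytotoxic lymphocytes",
    "NK cells",
    "B lineage",
    "Monocytic lineage",
    "Myeloid dendritic cells",
    "Neutrophils",
)
#: Stromal populations left independent of CIMP.
STROMAL_POPULATIONS = ("Endothelial cells", "Fibroblasts")


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CohortConfig:
    """All knobs of the cohort generator.

    Coefficients are on standardized scales: proliferation ``P`` has standard
    deviation ``prolif_sd``; DNMT and CIMP latents are built from it as
    described in the module docstring and standardized before entering the
    methylation / expression / survival layers.
    """

    seed: int  # mandatory; every draw flows from it
    n_samples: int = 80
    n_probes: int = 2000
    n_signature_probes: int = 50
    n_genes: int = 500
    n_markers_per_population: int = 3
    n_prolif_marker_genes: int = 20

    # causal coefficients
    coef_cnv_to_dnmt: tuple[float, float] = (1.0, 1.0)
    coef_prolif_to_dnmt: tuple[float, float] = (1.0, 1.0)
    coef_dnmt_to_cimp: tuple[float, float] = (0.7, 0.7)
    coef_prolif_to_cimp: float = 0.0  # direct P->C edge; 0 under mediation
    coef_cimp_to_immune: float = -0.8  # log2 units per CIMP SD
    coef_prolif_to_prolif_markers: float = 0.8

    # noise scales
    prolif_sd: float = 1.0
    dnmt_noise_sd: float = 0.5
    cimp_noise_sd: float = 0.5
    beta_logit_noise_sd: float = 0.25
    expr_noise_sd: float = 0.8

    # methylation layer
    signature_slope: float = 2.2  # logit units per CIMP SD
    signature_intercept_range: tuple[float, float] = (-0.4, 0.4)
    normal_background_beta: float = 0.05
    null_probe_concentration: float = 30.0

    # copy number
    gain_probability: float = 0.3
    loss_probability: float = 0.05

    # purity (tumor cell fraction) ~ Beta(a, b)
    purity_alpha: float = 27.0
    purity_beta: float = 3.0

    # survival
    survival_baseline_hazard: float = 1e-3  # events per day
    survival_log_hazard_per_dnmt_sd: float = 0.9
    censoring_rate: float = 0.3

    def validate(self) -> None:
        counts = (self.n_samples, self.n_probes, self.n_signature_probes,
                  self.n_genes, self.n_markers_per_population)
        if any(c < 1 for c in counts):
            raise ConfigError("all counts must be >= 1")
        if self.n_signature_probes > self.n_probes:
            raise ConfigError("n_signature_probes > n_probes")
        for p in (self.gain_probability, self.loss_probability, self.censoring_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0,1]")
        if self.gain_probability + self.loss_probability > 1.0:
            raise ConfigError("gain_probability + loss_probability > 1")
        if self.seed is None:
            raise ConfigError("seed is mandatory")


@dataclass
class GroundTruth:
    """Latent quantities the generator knows and analyses must recover."""

    proliferation: pd.Series  # latent P per sample
    cimp_latent: pd.Series  # latent C per sample (unstandardized)
    dnmt_latent: pd.DataFrame  # latent D per sample x locus (pre-measurement)
    signature_probes: tuple[str, ...]
    marker_sets: dict[str, tuple[str, ...]]  # population -> marker genes
    immune_populations: tuple[str, ...]
    prolif_marker_genes: tuple[str, ...]
    dnmt_genes: tuple[str, ...] = DNMT_LOCI

    @property
    def immune_marker_genes(self) -> tuple[str, ...]:
        out: list[str] = []
        for pop in self.immune_populations:
            out.extend(self.marker_sets[pop])
        return tuple(out)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    beta: BetaMatrix
    annotation: ProbeAnnotation
    expression: ExpressionMatrix
    metadata: SampleMetadata
    gene_models: GeneModelTable
    cnv_status: pd.DataFrame  # samples × loci, values in {loss, neutral, gain}
    ground_truth: GroundTruth


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort from the generative model.

    Deterministic given ``config`` (including its seed): two calls with an
    equal config produce identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i + 1:03d}" for i in range(n)]

    # --- latent causal chain -------------------------------------------------
    P = rng.normal(0.0, config.prolif_sd, size=n)

    u = rng.random(size=(n, 2))
    gain = u < config.gain_probability
    loss = u > 1.0 - config.loss_probability
    G = gain.astype(float) - loss.astype(float)
    cnv_status = pd.DataFrame(
        np.where(gain, "gain", np.where(loss, "loss", "neutral")),
        index=samples, columns=list(DNMT_LOCI),
    )

    D = np.empty((n, 2))
    for k in range(2):
        D[:, k] = (config.coef_cnv_to_dnmt[k] * G[:, k]
                   + config.coef_prolif_to_dnmt[k] * P
                   + rng.normal(0.0, config.dnmt_noise_sd, size=n))

    C = (config.coef_dnmt_to_cimp[0] * D[:, 0]
         + config.coef_dnmt_to_cimp[1] * D[:, 1]
         + config.coef_prolif_to_cimp * P
         + rng.normal(0.0, config.cimp_noise_sd, size=n))
    C_std = _standardize(C)

    # CIMP group labels by tertiles of the latent C
    order = np.argsort(C, kind="stable")
    groups = np.empty(n, dtype=object)
    cuts = [n // 3, 2 * n // 3]
    groups[order[: cuts[0]]] = "lCIMP"
    groups[order[cuts[0]: cuts[1]]] = "iCIMP"
    groups[order[cuts[1]:]] = "hCIMP"

    purity = rng.beta(config.purity_alpha, config.purity_beta, size=n)

    # --- methylation layer ---------------------------------------------------
    probes = [f"cg{i + 1:06d}" for i in range(config.n_probes)]
    sig_idx = rng.choice(config.n_probes, size=config.n_signature_probes, replace=False)
    sig_idx.sort()
    sig_mask = np.zeros(config.n_probes, dtype=bool)
    sig_mask[sig_idx] = True
    sig_probes = tuple(probes[i] for i in sig_idx)

    beta = np.empty((config.n_probes, n))
    lo, hi = config.signature_intercept_range
    a_sig = rng.uniform(lo, hi, size=config.n_signature_probes)
    logit = (a_sig[:, None]
             + config.signature_slope * C_std[None, :]
             + rng.normal(0.0, config.beta_logit_noise_sd,
                          size=(config.n_signature_probes, n)))
    tumor_beta = _invlogit(logit)
    # bulk signal = purity-weighted mix of tumor and unmethylated normal tissue
    beta[sig_mask] = (purity[None, :] * tumor_beta
                      + (1 - purity[None, :]) * config.normal_background_beta)

    n_null = config.n_probes - config.n_signature_probes
    m_null = rng.uniform(0.05, 0.95, size=n_null)
    kappa = config.null_probe_concentration
    beta[~sig_mask] = rng.beta(m_null[:, None] * kappa,
                               (1 - m_null[:, None]) * kappa,
                               size=(n_null, n))
    beta_df = pd.DataFrame(beta, index=probes, columns=samples)

    # --- gene universe and expression layer ----------------------------------
    marker_sets: dict[str, tuple[str, ...]] = {}
    gene_names: list[str] = list(DNMT_LOCI)
    codes = {
        "T cells": "TCELL", "CD8 T cells": "CD8T", "Cytotoxic lymphocytes": "CTL",
        "NK cells": "NK", "B lineage": "BLIN", "Monocytic lineage": "MONO",
        "Myeloid dendritic cells": "MDC", "Neutrophils": "NEUT",
        "Endothelial cells": "ENDO", "Fibroblasts": "FIB",
    }
    for pop in IMMUNE_POPULATIONS + STROMAL_POPULATIONS:
        genes = tuple(f"{codes[pop]}_M{i + 1}" for i in range(config.n_markers_per_population))
        marker_sets[pop] = genes
        gene_names.extend(genes)
    prolif_markers = tuple(f"PROLIF_M{i + 1}" for i in range(config.n_prolif_marker_genes))
    gene_names.extend(prolif_markers)
    n_special = len(gene_names)
    if config.n_genes < n_special:
        raise ConfigError(f"n_genes must be >= {n_special} (special genes)")
    gene_names.extend(f"G{i + 1:04d}" for i in range(config.n_genes - n_special))

    P_std = _standardize(P)
    base = rng.uniform(3.0, 8.0, size=config.n_genes)
    log2expr = (base[:, None]
                + rng.normal(0.0, config.expr_noise_sd, size=(config.n_genes, n)))
    name_to_row = {g: i for i, g in enumerate(gene_names)}
    D_std = np.column_stack([_standardize(D[:, k]) for k in range(2)])
    for k, locus in enumerate(DNMT_LOCI):
        log2expr[name_to_row[locus]] = base[name_to_row[locus]] + 1.5 * D_std[:, k] \
            + rng.normal(0.0, 0.2, size=n)
    immune_genes = [g for pop in IMMUNE_POPULATIONS for g in marker_sets[pop]]
    for g in immune_genes:
        log2expr[name_to_row[g]] += config.coef_cimp_to_immune * C_std
    for g in prolif_markers:
        log2expr[name_to_row[g]] += config.coef_prolif_to_prolif_markers * P_std
    expr_df = pd.DataFrame(np.maximum(2.0 ** log2expr - 1.0, 0.0),
                           index=gene_names, columns=samples)

    # --- probe annotation and gene models ------------------------------------
    # toy genome: genes every 10 kb on chr1, TSS mid-gene-start, body 4 kb
    tss = 5000 + 10_000 * np.arange(config.n_genes)
    strand = np.where(np.arange(config.n_genes) % 2 == 0, "+", "-")
    body_start = np.where(strand == "+", tss, tss - 4000)
    body_end = body_start + 4000
    gene_models = GeneModelTable(pd.DataFrame({
        "chrom": "chr1", "tss": tss, "strand": strand,
        "body_start": body_start, "body_end": body_end,
    }, index=pd.Index(gene_names, name="gene_id")))

    # signature probes sit in promoters (TSS200): the first ones on immune
    # marker genes (wiring methylation and repression to the same genes),
    # the rest on otherwise-null genes
    tss_rel = np.empty(config.n_probes, dtype=object)
    gene_of_probe = np.empty(config.n_probes, dtype=object)
    pos = np.zeros(config.n_probes, dtype=int)
    null_gene_pool = [g for g in gene_names
                      if g not in set(immune_genes) | set(DNMT_LOCI) | set(prolif_markers)]
    sig_genes = list(immune_genes[: config.n_signature_probes])
    extra = config.n_signature_probes - len(sig_genes)
    if extra > 0:
        sig_genes += null_gene_pool[:extra]
    for j, i in enumerate(sig_idx):
        g = sig_genes[j]
        tss_rel[i] = "TSS200"
        gene_of_probe[i] = g
        pos[i] = int(gene_models.table.loc[g, "tss"]) + (100 if gene_models.table.loc[g, "strand"] == "+" else -100)
    null_idx = np.flatnonzero(~sig_mask)
    rel_choices = rng.choice(["TSS200", "TSS1500", "Body", "other"],
                             size=null_idx.size, p=[0.3, 0.2, 0.4, 0.1])
    null_assign_pool = [g for g in null_gene_pool if g not in set(sig_genes)]
    assigned = rng.choice(len(null_assign_pool), size=null_idx.size, replace=True)
    for j, i in enumerate(null_idx):
        g = null_assign_pool[assigned[j]]
        rel = rel_choices[j]
        tss_rel[i] = rel
        gene_of_probe[i] = g
        gt = gene_models.table.loc[g]
        sgn = 1 if gt["strand"] == "+" else -1
        offset = {"TSS200": 100, "TSS1500": 800, "Body": -2000, "other": -6000}[rel]
        pos[i] = int(gt["tss"]) + sgn * offset
    annotation = ProbeAnnotation(pd.DataFrame({
        "gene_symbol": gene_of_probe, "tss_relation": tss_rel,
        "chrom": "chr1", "pos": pos,
        "strand": [str(gene_models.table.loc[g, "strand"]) for g in gene_of_probe],
    }, index=pd.Index(probes, name="probe_id")))

    # --- clinical layer -------------------------------------------------------
    mitotic = rng.poisson(np.exp(2.5 + 0.6 * P_std))
    Dbar = D_std.mean(axis=1)
    lam = config.survival_baseline_hazard * np.exp(
        config.survival_log_hazard_per_dnmt_sd * Dbar)
    T = rng.exponential(1.0 / lam)
    if config.censoring_rate > 0:
        horizon = 1.0 / (config.survival_baseline_hazard * config.censoring_rate)
        Cens = rng.uniform(0.0, horizon, size=n)
    else:
        Cens = np.full(n, np.inf)
    time = np.minimum(T, Cens)
    event = (T <= Cens).astype(int)
    time = np.maximum(time, 1.0)  # days, floored at 1 to keep times positive

    metadata = SampleMetadata(pd.DataFrame({
        "cimp_group": groups, "purity": purity, "mitotic_rate": mitotic.astype(float),
        "survival_time": time, "event": event,
    }, index=pd.Index(samples, name="sample_id")))

    gt = GroundTruth(
        proliferation=pd.Series(P, index=samples, name="proliferation"),
        cimp_latent=pd.Series(C, index=samples, name="cimp_latent"),
        dnmt_latent=pd.DataFrame(D, index=samples, columns=list(DNMT_LOCI)),
        signature_probes=sig_probes,
        marker_sets=marker_sets,
        immune_populations=IMMUNE_POPULATIONS,
        prolif_marker_genes=prolif_markers,
    )
    return SyntheticCohort(
        config=config, beta=BetaMatrix(beta_df), annotation=annotation,
        expression=ExpressionMatrix(expr_df, scale="rpkm"),
        metadata=metadata, gene_models=gene_models,
        cnv_status=cnv_status, ground_truth=gt,
    )


def marker_collection(cohort: SyntheticCohort) -> GeneSetCollection:
    """The cohort's marker sets as a GeneSetCollection (for deconvolution)."""
    return GeneSetCollection.from_dict(cohort.ground_truth.marker_sets)


# ---------------------------------------------------------------------------
# demethylation-treatment experiment
# ---------------------------------------------------------------------------

@dataclass
class DemethylationConfig:
    """Planted-truth design for a demethylating-agent experiment.

    ``n_planted`` genes receive both a promoter DMR (demethylation delta
    strictly above ``delta_min``, p strictly below ``dmr_alpha``) and
    upregulation (fold change strictly above ``fc_min``, p strictly below
    ``de_alpha``).  Decoy genes each fail exactly one criterion; remaining
    genes are null.
    """

    seed: int
    n_genes: int = 50
    n_planted: int = 5
    dmr_alpha: float = 0.05
    delta_min: float = 0.2
    de_alpha: float = 0.05
    fc_min: float = 2.0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_planted < 0 or self.n_planted > self.n_genes:
            raise ConfigError("n_planted must lie in [0, n_genes]")


@dataclass
class DemethylationExperiment:
    dmrs: DMRTable
    de: DETable
    gene_models: GeneModelTable
    reactivated_genes: tuple[str, ...]  # ground truth
    decoy_classes: dict[str, str] = field(default_factory=dict)


_DECOY_CLASSES = ("weak_delta", "weak_dmr_p", "dmr_outside_promoter",
                  "weak_fc", "weak_de_p", "null")


def simulate_demethylation_experiment(config: DemethylationConfig) -> DemethylationExperiment:
    """Emit DMR and DE tables with planted reactivated genes and decoys.

    DMR ``delta_beta`` follows the control − treated convention, so
    demethylation under treatment is positive.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"GENE{i + 1:03d}" for i in range(config.n_genes)]
    tss = 5000 + 10_000 * np.arange(config.n_genes)
    strand = np.where(np.arange(config.n_genes) % 2 == 0, "+", "-")
    body_start = np.where(strand == "+", tss, tss - 4000)
    gene_models = GeneModelTable(pd.DataFrame({
        "chrom": "chr1", "tss": tss, "strand": strand,
        "body_start": body_start, "body_end": body_start + 4000,
    }, index=pd.Index(genes, name="gene_id")))

    planted = tuple(genes[: config.n_planted])
    classes: dict[str, str] = {g: "planted" for g in planted}
    for j, g in enumerate(genes[config.n_planted:]):
        classes[g] = _DECOY_CLASSES[j % len(_DECOY_CLASSES)]

    dmr_rows = []
    de_rows = []

    def strong_dmr(delta=None, p=None):
        return (delta if delta is not None else rng.uniform(config.delta_min + 0.1,
                                                            config.delta_min + 0.3),
                p if p is not None else rng.uniform(1e-4, config.dmr_alpha / 2))

    def strong_de():
        return rng.uniform(np.log2(config.fc_min) + 0.5, np.log2(config.fc_min) + 2.0), \
            rng.uniform(1e-4, config.de_alpha / 2)

    for i, g in enumerate(genes):
        cls = classes[g]
        t = int(tss[i])
        # promoter midpoint works for both strands with the default window
        in_prom = (t - 500, t - 300) if strand[i] == "+" else (t + 300, t + 500)
        out_prom = (t + 3000, t + 3200)
        dmr_iv, dmr_delta, dmr_p = None, None, None
        lfc, de_p = rng.normal(0.0, 0.2), rng.uniform(0.3, 0.95)  # null defaults
        if cls == "planted":
            dmr_iv, (dmr_delta, dmr_p) = in_prom, strong_dmr()
            lfc, de_p = strong_de()
        elif cls == "weak_delta":
            dmr_iv, (dmr_delta, dmr_p) = in_prom, strong_dmr(
                delta=rng.uniform(0.02, config.delta_min - 0.05))
            lfc, de_p = strong_de()
        elif cls == "weak_dmr_p":
            dmr_iv, (dmr_delta, dmr_p) = in_prom, strong_dmr(
                p=rng.uniform(config.dmr_alpha * 2, 0.9))
            lfc, de_p = strong_de()
        elif cls == "dmr_outside_promoter":
            dmr_iv, (dmr_delta, dmr_p) = out_prom, strong_dmr()
            lfc, de_p = strong_de()
        elif cls == "weak_fc":
            dmr_iv, (dmr_delta, dmr_p) = in_prom, strong_dmr()
            lfc = rng.uniform(0.05, np.log2(config.fc_min) - 0.3)
            de_p = rng.uniform(1e-4, config.de_alpha / 2)
        elif cls == "weak_de_p":
            dmr_iv, (dmr_delta, dmr_p) = in_prom, strong_dmr()
            lfc = rng.uniform(np.log2(config.fc_min) + 0.5, np.log2(config.fc_min) + 2.0)
            de_p = rng.uniform(config.de_alpha * 2, 0.9)
        if dmr_iv is not None:
            dmr_rows.append(("chr1", dmr_iv[0], dmr_iv[1], dmr_delta, dmr_p))
        de_rows.append((g, lfc, de_p, min(1.0, de_p * 1.5)))

    dmrs = DMRTable(pd.DataFrame(dmr_rows, columns=["chrom", "start", "end",
                                                    "delta_beta", "p_value"]))
    de = DETable(pd.DataFrame(
        [(r[1], r[2], r[3]) for r in de_rows],
        columns=["log2_fold_change", "p_value", "fdr"],
        index=pd.Index([r[0] for r in de_rows], name="gene_id"),
    ))
    return DemethylationExperiment(dmrs=dmrs, de=de, gene_models=gene_models,
                                   reactivated_genes=planted, decoy_classes=classes)


# ---------------------------------------------------------------------------
# on-disk emission (the file set every reader in io.py can load back)
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the full cohort file set plus a ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "annotation": outdir / "probe_annotation.tsv",
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "gene_models": outdir / "gene_models.tsv",
        "marker_sets": outdir / "marker_sets.gmt",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_beta_matrix(cohort.beta, paths["beta"])
    write_probe_annotation(cohort.annotation, paths["annotation"])
    write_expression_matrix(cohort.expression, paths["expression"])
    write_metadata(cohort.metadata, paths["metadata"])
    write_gene_models(cohort.gene_models, paths["gene_models"])
    write_gmt(marker_collection(cohort), paths["marker_sets"])
    gt = cohort.ground_truth
    sidecar = {
        "config": asdict(cohort.config),
        "proliferation": gt.proliferation.round(6).to_dict(),
        "cimp_latent": gt.cimp_latent.round(6).to_dict(),
        "signature_probes": list(gt.signature_probes),
        "marker_sets": {k: list(v) for k, v in gt.marker_sets.items()},
        "immune_populations": list(gt.immune_populations),
        "prolif_marker_genes": list(gt.prolif_marker_genes),
        "cnv_status": {loc: cohort.cnv_status[loc].to_dict() for loc in cohort.cnv_status},
    }
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)
    return paths
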