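"""Methylation-expression integration: promoter windows and gene calling.

Two calling procedures share the promoter-window machinery:

* **demethylation-reactivated genes** (treatment experiment): a gene is
  called when a significant promoter DMR shows demethylation beyond a delta
  threshold AND the gene is significantly upregulated beyond a fold-change
  threshold;
* **methylation-repressed genes** (tumor cohort): a gene is called when its
  expression correlates negatively with the CIMP score (BH-significant,
  Spearman) AND at least one promoter/body probe is hypermethylated in
  hCIMP versus lCIMP tumors.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import (
    BetaMatrix, DETable, DMRTable, ExpressionMatrix, GeneModelTable,
    ProbeAnnotation, SampleMetadata,
)

logger = logging.getLogger("cimpkit")


def build_promoter_windows(
    genes: GeneModelTable,
    upstream: int = 1000,
    downstream: int = 200,
) -> pd.DataFrame:
    """Strand-aware promoter windows around each TSS (0-based half-open).

    Plus strand: ``[tss − upstream, tss + downstream)``; minus strand
    mirrored.  Windows reaching below coordinate 0 are clipped at 0 with a
    warning.  Returns a frame indexed by gene_id with chrom/start/end.
    """
    t = genes.table
    plus = t["strand"].to_numpy() == "+"
    start = np.where(plus, t["tss"] - upstream, t["tss"] - downstream)
    end = np.where(plus, t["tss"] + downstream, t["tss"] + upstream)
    clipped = start < 0
    if clipped.any():
        logger.warning("build_promoter_windows: %d windows clipped at coordinate 0",
                       int(clipped.sum()))
        start = np.maximum(start, 0)
    return pd.DataFrame({"chrom": t["chrom"].to_numpy(),
                         "start": start.astype(int), "end": end.astype(int)},
                        index=t.index.copy())


@dataclass
class GeneCallResult:
    gene_id: str
    call_type: str  # repressed_in_hcimp | reactivated_by_demethylation
    methylation_evidence: dict = field(default_factory=dict)
    expression_evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.methylation_evidence or not self.expression_evidence:
            raise ValidationError("a gene call needs both evidence arms")


def call_reactivated_genes(
    dmrs: DMRTable,
    de: DETable,
    promoters: pd.DataFrame,
    *,
    dmr_alpha: float = 0.05,
    delta_min: float = 0.2,
    de_alpha: float = 0.05,
    fc_min: float = 2.0,
    invert_delta: bool = False,
) -> list[GeneCallResult]:
    """Genes demethylated at the promoter and upregulated under treatment.

    A gene is called iff at least one DMR overlaps its promoter window (any
    shared base, half-open semantics) with ``p < dmr_alpha`` and
    demethylation delta ``> delta_min`` (``delta_beta`` stored as
    control − treated; set ``invert_delta=True`` for tables with the
    opposite sign convention), AND its DE record has ``p < de_alpha`` with
    fold change ``> fc_min`` in the up direction (log2 fold change
    ``> log2(fc_min)``).  Genes present in the promoter table but absent
    from the DE table are logged and left uncalled.
    """
    d = dmrs.table.copy()
    delta = -d["delta_beta"] if invert_delta else d["delta_beta"]
    d = d[(delta > delta_min) & (d["p_value"] < dmr_alpha)]

    calls: list[GeneCallResult] = []
    log2fc_min = np.log2(fc_min)
    missing_de = 0
    for gene_id, win in promoters.iterrows():
        hits = d[(d["chrom"] == win["chrom"])
                 & (d["start"] < win["end"]) & (d["end"] > win["start"])]
        if hits.empty:
            continue
        if gene_id not in de.table.index:
            missing_de += 1
            continue
        rec = de.table.loc[gene_id]
        if rec["p_value"] < de_alpha and rec["log2_fold_change"] > log2fc_min:
            calls.append(GeneCallResult(
                gene_id, "reactivated_by_demethylation",
                methylation_evidence={"dmrs": hits[["chrom", "start", "end",
                                                    "delta_beta", "p_value"]]
                                      .to_dict("records")},
                expression_evidence={"log2_fold_change": float(rec["log2_fold_change"]),
                                     "p_value": float(rec["p_value"])},
            ))
    if missing_de:
        logger.info("call_reactivated_genes: %d genes with qualifying DMRs "
                    "lacked DE records", missing_de)
    calls.sort(key=lambda c: c.gene_id)
    return calls


def call_repressed_genes(
    beta: BetaMatrix,
    annotation: ProbeAnnotation,
    expr: ExpressionMatrix,
    cimp_scores: pd.Series,
    groups: SampleMetadata,
    gene_bodies: GeneModelTable | None = None,
    *,
    alpha: float = 0.05,
    dmc_alpha: float = 0.05,
    dmc_delta: float = 0.1,
    promoter_categories: tuple[str, ...] = ("TSS200", "TSS1500"),
    body_categories: tuple[str, ...] = ("Body",),
) -> list[GeneCallResult]:
    """Genes repressed by methylation in high-CIMP tumors.

    Arm (a): Spearman correlation of the gene's log2 expression with the
    continuous CIMP score, BH-corrected at ``alpha`` across tested genes,
    required negative.  Arm (b): at least one probe assigned to the gene's
    promoter (``promoter_categories``) or body (``body_categories``, or
    body-interval overlap when ``gene_bodies`` is given) with a
    hypermethylation delta ``> dmc_delta`` (hCIMP mean − lCIMP mean) and a
    two-sided Wilcoxon rank-sum p ``< dmc_alpha``.  Constant-expression
    genes are excluded from arm (a).
    """
    samples = [s for s in expr.sample_ids
               if s in cimp_scores.index and not np.isnan(cimp_scores.get(s, np.nan))]
    if set(samples) - set(beta.sample_ids):
        raise ValidationError("expression/CIMP samples missing from beta matrix")
    if len(samples) < 5:
        raise ValidationError("need >= 5 aligned samples")

    log2 = expr.to_log2()[samples]
    score = cimp_scores[samples].to_numpy(dtype=float)

    # arm (a): expression ~ CIMP score, Spearman with BH
    values = log2.to_numpy()
    variable = np.ptp(values, axis=1) > 0
    tested = log2.index[variable]
    rho, pval = stats.spearmanr(score, values[variable].T)
    if np.ndim(rho) > 0:  # spearmanr returns a matrix when >1 gene
        rho = np.asarray(rho)[0, 1:]
        pval = np.asarray(pval)[0, 1:]
    else:
        rho, pval = np.array([rho]), np.array([pval])
    reject, _, _, _ = multipletests(pval, alpha=alpha, method="fdr_bh")
    corr_genes = {
        g: {"spearman_rho": float(r), "p_value": float(p)}
        for g, r, p, rej in zip(tested, rho, pval, reject)
        if rej and r < 0
    }
    if not corr_genes:
        return []

    # arm (b): differentially methylated probes, hCIMP vs lCIMP
    h = [s for s in groups.samples_in_group("hCIMP") if s in beta.values.columns]
    l = [s for s in groups.samples_in_group("lCIMP") if s in beta.values.columns]
    if len(h) < 2 or len(l) < 2:
        raise ValidationError("need >= 2 hCIMP and >= 2 lCIMP samples")

    ann = annotation.table
    categories = set(promoter_categories) | set(body_categories)
    cand = ann[ann["gene_symbol"].isin(corr_genes)
               & (ann["tss_relation"].isin(categories))]
    if gene_bodies is not None:
        # probes inside the gene body interval count even if labelled otherwise
        bodies = gene_bodies.table
        extra = ann[ann["gene_symbol"].isin(corr_genes)]
        in_body = []
        for pid, row in extra.iterrows():
            g = row["gene_symbol"]
            if g in bodies.index:
                b = bodies.loc[g]
                if b["chrom"] == row["chrom"] and b["body_start"] <= row["pos"] < b["body_end"]:
                    in_body.append(pid)
        cand = ann.loc[sorted(set(cand.index) | set(in_body))]

    calls: list[GeneCallResult] = []
    bh_arr = beta.values
    for gene_id in sorted(corr_genes):
        probes = cand.index[cand["gene_symbol"] == gene_id]
        probes = [p for p in probes if p in bh_arr.index]
        evidence = []
        for p in probes:
            vh = bh_arr.loc[p, h].dropna().to_numpy()
            vl = bh_arr.loc[p, l].dropna().to_numpy()
            if len(vh) < 2 or len(vl) < 2:
                continue
            delta = float(vh.mean() - vl.mean())
            if delta <= dmc_delta:
                continue
            if np.ptp(np.concatenate([vh, vl])) == 0:
                continue
            _, pv = stats.mannwhitneyu(vh, vl, alternative="two-sided")
            if pv < dmc_alpha:
                evidence.append({"probe_id": p, "delta_beta": delta, "p_value": float(pv)})
        if evidence:
            calls.append(GeneCallResult(
                gene_id, "repressed_in_hcimp",
                methylation_evidence={"probes": evidence},
                expression_evidence=corr_genes[gene_id],
            ))
    return calls


def intersect_calls(list_a, list_b) -> list[str]:
    """Deterministic (lexicographic) intersection of two call lists.

    Accepts lists of :class:`GeneCallResult` or of gene ids; duplicates are
    removed before intersecting.
    """
    def ids(lst):
        return {c.gene_id if isinstance(c, GeneCallResult) else c for c in lst}

    return sorted(ids(list_a) & ids(list_b))
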