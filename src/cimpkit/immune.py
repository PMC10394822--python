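"""Marker-set abundance scoring of immune/stromal populations.

Each population's abundance in a bulk sample is summarized as the mean
log2(x+1) expression of its marker genes — a relative score, comparable
across samples within a population but not across populations.  Group
differences are assessed per population with a Kruskal-Wallis test followed
by Dunn's tie-corrected pairwise z-tests and Benjamini-Hochberg correction
within the pairwise family of each population.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import ExpressionMatrix, GeneSetCollection, SampleMetadata

logger = logging.getLogger("cimpkit")

#: Small illustrative marker collection (human bulk transcriptome symbols).
#: Real analyses should supply their own marker GMT.
DEFAULT_MARKER_SETS = GeneSetCollection.from_dict({
    "T cells": ["CD3D", "CD3E", "CD2"],
    "CD8 T cells": ["CD8A", "CD8B"],
    "Cytotoxic lymphocytes": ["GZMB", "PRF1", "KLRK1"],
    "NK cells": ["NCR1", "KLRD1", "NKG7"],
    "B lineage": ["CD19", "MS4A1", "CD79A"],
    "Monocytic lineage": ["CD14", "CD163", "CSF1R"],
    "Myeloid dendritic cells": ["CD1C", "FLT3", "CLEC10A"],
    "Neutrophils": ["FCGR3B", "CSF3R", "CEACAM8"],
    "Endothelial cells": ["PECAM1", "VWF", "CDH5"],
    "Fibroblasts": ["COL1A1", "COL3A1", "PDGFRB"],
})


def marker_abundance(
    expr: ExpressionMatrix,
    markers: GeneSetCollection,
) -> pd.DataFrame:
    """Population × sample abundance scores (mean log2(x+1) of markers).

    Populations with no marker present in the matrix are omitted with a
    warning; if no population has any present marker, raises.
    """
    log2 = expr.to_log2()
    rows = {}
    for pop, genes in markers.items():
        present = [g for g in genes if g in log2.index]
        if not present:
            logger.warning("marker_abundance: population %r has no marker in matrix", pop)
            continue
        rows[pop] = log2.loc[present].mean(axis=0)
    if not rows:
        raise ValidationError("no population has any marker present in the matrix")
    return pd.DataFrame(rows).T


@dataclass
class GroupComparisonResult:
    population: str
    kruskal_wallis_p: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_value, bh_adjusted_p


def dunn_pairwise(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Dunn's post-hoc z-tests on pooled ranks, with tie correction.

    For groups i, j with pooled mean ranks R̄_i, R̄_j and pooled size N::

        z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)),
        T = Σ(t³ − t) / (12(N − 1))   over tie groups of size t.

    Two-sided p from the standard normal.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    N = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    T = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (N - 1))
    groups = sorted(set(labels), key=str)
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    n = {g: int((labels == g).sum()) for g in groups}
    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        denom = np.sqrt((N * (N + 1) / 12.0 - T) * (1.0 / n[ga] + 1.0 / n[gb]))
        z = (mean_rank[ga] - mean_rank[gb]) / denom if denom > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z)) if denom > 0 else 1.0
        rows.append((ga, gb, z, min(1.0, p)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_value"])


def compare_abundance_across_groups(
    abundance: pd.DataFrame,
    groups: SampleMetadata,
    *,
    group_column: str = "cimp_group",
    exclude_groups: tuple[str, ...] = ("unknown",),
) -> list[GroupComparisonResult]:
    """Kruskal-Wallis + Dunn + BH per population, across sample groups.

    The BH family is the set of pairwise comparisons within each population
    (matching per-population figure annotation), not the global family.
    """
    labels_all = groups.table[group_column].reindex(abundance.columns)
    keep = labels_all.notna() & ~labels_all.isin(exclude_groups)
    labels = labels_all[keep].to_numpy()
    data = abundance.loc[:, keep.index[keep]]
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need >= 2 groups")
    small = [g for g, c in zip(uniq, counts) if c < 2]
    if small:
        raise ValidationError(f"groups with < 2 samples: {small}")

    results = []
    for pop in data.index:
        v = data.loc[pop].to_numpy(dtype=float)
        by_group = [v[labels == g] for g in uniq]
        if all(np.ptp(g) == 0 for g in by_group) and len({g[0] for g in by_group}) == 1:
            kw_p = 1.0
        else:
            try:
                _, kw_p = stats.kruskal(*by_group)
            except ValueError:
                kw_p = 1.0
        pw = dunn_pairwise(v, labels)
        pw["bh_adjusted_p"] = multipletests(pw["p_value"], method="fdr_bh")[1]
        results.append(GroupComparisonResult(pop, float(kw_p), pw))
    return results
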