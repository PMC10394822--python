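"""Ranked gene-set enrichment (GSEA-style) and over-representation testing.

The ranked analysis follows the classic weighted Kolmogorov-Smirnov scheme:
genes are ranked by the signal-to-noise ratio between two phenotype groups,
a running sum increments by |s|^p (normalized) at in-set genes and decrements
by 1/(N − |set|) elsewhere, the enrichment score (ES) is the signed maximum
deviation, and significance comes from phenotype-label (or gene-set)
permutations with sign-matched normalization (NES), nominal p-values and the
positive/negative-pool FDR procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, ValidationError
from .io import ExpressionMatrix, GeneSetCollection


@dataclass
class RankedList:
    """Genes ordered by a ranking statistic, descending.

    Ties in the statistic are broken by gene identifier (ascending), so the
    order is strict and platform-independent.
    """

    gene_ids: np.ndarray
    statistics: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.statistics):
            raise ValidationError("gene_ids and statistics differ in length")
        if np.any(np.diff(self.statistics) > 0):
            raise ValidationError("statistics must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    set_name: str
    size: int  # genes of the set present in the ranked list
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    leading_edge: tuple[str, ...]
    inconclusive: bool = False  # no same-sign null ES; NES/p/q not defined

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.es <= 1.0 + 1e-9:
            raise ValidationError(f"ES out of [-1,1]: {self.es}")


def signal_to_noise_ranking(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    *,
    min_sd: float = 1e-8,
    sd_floor_fraction: float = 0.2,
) -> RankedList:
    """Rank genes by the signal-to-noise ratio (μ_a − μ_b)/(σ_a + σ_b).

    Each group's standard deviation is floored at
    ``max(σ, sd_floor_fraction·|μ|, min_sd)`` (the classical convention).
    Expression is moved to the log2(x+1) scale first unless already log2.
    """
    a, b = list(group_a), list(group_b)
    if set(a) & set(b):
        raise ValidationError(f"groups overlap: {sorted(set(a) & set(b))}")
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 samples")
    log2 = expr.to_log2()
    missing = [s for s in a + b if s not in log2.columns]
    if missing:
        raise ValidationError(f"samples not in matrix: {missing}")
    s = _s2n(log2[a].to_numpy(), log2[b].to_numpy(), sd_floor_fraction, min_sd)
    genes = np.asarray(log2.index, dtype=object)
    order = np.lexsort((genes, -s))
    return RankedList(genes[order], s[order])


def _s2n(xa: np.ndarray, xb: np.ndarray, floor_frac: float, min_sd: float) -> np.ndarray:
    mu_a, mu_b = xa.mean(axis=1), xb.mean(axis=1)
    sd_a = np.maximum.reduce([xa.std(axis=1, ddof=1), floor_frac * np.abs(mu_a),
                              np.full_like(mu_a, min_sd)])
    sd_b = np.maximum.reduce([xb.std(axis=1, ddof=1), floor_frac * np.abs(mu_b),
                              np.full_like(mu_b, min_sd)])
    return (mu_a - mu_b) / (sd_a + sd_b)


@dataclass
class EnrichmentScore:
    es: float
    running_sum: np.ndarray  # deviation after each rank position; starts/ends near 0
    leading_edge: tuple[str, ...]


def enrichment_score(
    ranked: RankedList,
    gene_set: Sequence[str],
    weight_p: float = 1.0,
) -> EnrichmentScore:
    """Weighted running-sum enrichment score of one gene set.

    The running sum increments by |s_i|^weight_p (normalized over in-set
    genes) at set members and decrements by 1/(N − |set|) at non-members;
    the ES is the deviation of largest magnitude (first occurrence on ties).
    The leading edge is the in-set genes up to (positive ES) or from
    (negative ES) the peak.
    """
    members = set(gene_set)
    mask = np.fromiter((g in members for g in ranked.gene_ids), dtype=bool,
                       count=len(ranked))
    k = int(mask.sum())
    if k == 0:
        raise ValidationError("gene set does not intersect the ranked list")
    if k == len(ranked):
        raise ValidationError("gene set covers the entire ranked list")
    running = _running_sum(ranked.statistics, mask, weight_p)
    idx = _peak_index(running)
    es = float(running[idx])
    if es >= 0:
        leading = tuple(ranked.gene_ids[: idx + 1][mask[: idx + 1]])
    else:
        leading = tuple(ranked.gene_ids[idx:][mask[idx:]])
    return EnrichmentScore(es, running, leading)


#: Absolute tolerance for declaring two running-sum deviations tied; ties go
#: to the earliest rank so the ES does not depend on float summation order.
_PEAK_TOL = 1e-12


def _peak_index(dev: np.ndarray) -> int:
    absd = np.abs(dev)
    return int(np.argmax(absd >= absd.max() - _PEAK_TOL))


def _running_sum(statistics: np.ndarray, mask: np.ndarray, weight_p: float) -> np.ndarray:
    k = int(mask.sum())
    w = np.where(mask, np.abs(statistics) ** weight_p, 0.0)
    total = w.sum()
    if total == 0:  # all in-set statistics are exactly zero: fall back to equal steps
        w = mask.astype(float)
        total = float(k)
    hit = np.cumsum(w) / total
    miss = np.cumsum(~mask) / (len(mask) - k)
    return hit - miss


def _es_batch(stats_sorted: np.ndarray, mask_sorted: np.ndarray, weight_p: float) -> np.ndarray:
    """Vectorized ES over permutations: rows are permutations, columns ranks."""
    P, N = mask_sorted.shape
    k = mask_sorted.sum(axis=1)
    w = np.where(mask_sorted, np.abs(stats_sorted) ** weight_p, 0.0)
    tot = w.sum(axis=1, keepdims=True)
    zero = tot[:, 0] == 0
    if np.any(zero):
        w[zero] = mask_sorted[zero].astype(float)
        tot = w.sum(axis=1, keepdims=True)
    hit = np.cumsum(w, axis=1) / tot
    miss = np.cumsum(~mask_sorted, axis=1) / (N - k)[:, None]
    dev = hit - miss
    absd = np.abs(dev)
    idx = np.argmax(absd >= absd.max(axis=1, keepdims=True) - _PEAK_TOL, axis=1)
    return dev[np.arange(P), idx]


def gsea(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    gene_sets: GeneSetCollection,
    *,
    n_permutations: int = 1000,
    permutation_type: str = "auto",
    weight_p: float = 1.0,
    seed: int = 0,
    min_size: int = 2,
) -> list[EnrichmentResult]:
    """Two-group GSEA over a gene-set collection.

    ``permutation_type`` is ``phenotype`` (relabel samples), ``gene_set``
    (random same-size sets from the ranked universe) or ``auto``, which
    uses phenotype permutation when both groups have >= 7 samples and
    gene-set permutation otherwise.  NES is the ES divided by the mean of
    same-sign permutation ES; nominal p is the same-sign permutation tail;
    FDR q follows the pooled positive/negative null-NES procedure.  Results
    are deterministic for a fixed seed.
    """
    if n_permutations < 100:
        raise ValidationError("need >= 100 permutations")
    if permutation_type not in ("auto", "phenotype", "gene_set"):
        raise ValidationError(f"unknown permutation_type {permutation_type!r}")
    if permutation_type == "auto":
        permutation_type = "phenotype" if min(len(group_a), len(group_b)) >= 7 \
            else "gene_set"
    rng = np.random.default_rng(seed)

    ranked = signal_to_noise_ranking(expr, group_a, group_b)
    universe = set(ranked.gene_ids)
    usable = [(name, [g for g in genes if g in universe])
              for name, genes in gene_sets.items()]
    usable = [(name, genes) for name, genes in usable
              if min_size <= len(genes) < len(ranked)]
    if not usable:
        raise ValidationError("no gene set overlaps the expression matrix")

    observed = {name: enrichment_score(ranked, genes, weight_p)
                for name, genes in usable}

    # --- null ES matrix (n_permutations × sets) ------------------------------
    if permutation_type == "phenotype":
        log2 = expr.to_log2()
        cols = list(group_a) + list(group_b)
        X = log2[cols].to_numpy()
        na = len(group_a)
        genes_arr = np.asarray(log2.index, dtype=object)
        id_rank = np.argsort(np.argsort(genes_arr, kind="stable"), kind="stable")
        null_stats = np.empty((n_permutations, X.shape[0]))
        for p in range(n_permutations):
            perm = rng.permutation(X.shape[1])
            null_stats[p] = _s2n(X[:, perm[:na]], X[:, perm[na:]], 0.2, 1e-8)
        # per permutation: descending stat, gene-id tie-break (matches observed rule)
        order = np.lexsort((np.broadcast_to(id_rank, null_stats.shape), -null_stats),
                           axis=1)
        rows = np.arange(n_permutations)[:, None]
        stats_sorted = null_stats[rows, order]
        null_es = np.empty((n_permutations, len(usable)))
        for j, (name, genes) in enumerate(usable):
            set_mask = np.isin(genes_arr, genes)
            null_es[:, j] = _es_batch(stats_sorted, set_mask[order], weight_p)
    else:  # gene-set permutation: observed ranking fixed, random sets
        stats_sorted = np.broadcast_to(ranked.statistics, (n_permutations, len(ranked)))
        null_es = np.empty((n_permutations, len(usable)))
        for j, (name, genes) in enumerate(usable):
            k = len(genes)
            mask = np.zeros((n_permutations, len(ranked)), dtype=bool)
            for p in range(n_permutations):
                mask[p, rng.choice(len(ranked), size=k, replace=False)] = True
            null_es[:, j] = _es_batch(stats_sorted, mask, weight_p)

    # --- NES, nominal p, FDR --------------------------------------------------
    results: list[EnrichmentResult] = []
    nes_obs = np.full(len(usable), np.nan)
    null_nes_cols = []
    inconclusive = np.zeros(len(usable), dtype=bool)
    for j, (name, genes) in enumerate(usable):
        es = observed[name].es
        null = null_es[:, j]
        pos, neg = null[null > 0], null[null < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = neg.mean() if neg.size else np.nan
        same = pos if es >= 0 else neg
        if same.size == 0:
            inconclusive[j] = True
            null_nes_cols.append(np.full_like(null, np.nan))
            continue
        denom = mean_pos if es >= 0 else abs(mean_neg)
        nes_obs[j] = es / denom
        nominal = (np.sum(same >= es) / same.size if es >= 0
                   else np.sum(same <= es) / same.size)
        observed[name] = (observed[name], float(nominal))
        col = np.where(null >= 0,
                       null / mean_pos if pos.size else np.nan,
                       null / abs(mean_neg) if neg.size else np.nan)
        null_nes_cols.append(col)
    null_nes = np.column_stack(null_nes_cols)
    pooled = null_nes[~np.isnan(null_nes)]
    obs_valid = nes_obs[~np.isnan(nes_obs)]

    def fdr_q(nes: float) -> float:
        if np.isnan(nes):
            return np.nan
        if nes >= 0:
            n_null_tail, n_null_side = np.sum(pooled >= nes), np.sum(pooled >= 0)
            n_obs_tail, n_obs_side = np.sum(obs_valid >= nes), np.sum(obs_valid >= 0)
        else:
            n_null_tail, n_null_side = np.sum(pooled <= nes), np.sum(pooled < 0)
            n_obs_tail, n_obs_side = np.sum(obs_valid <= nes), np.sum(obs_valid < 0)
        if n_null_side == 0 or n_obs_side == 0 or n_obs_tail == 0:
            return 1.0
        num = n_null_tail / n_null_side
        den = n_obs_tail / n_obs_side
        return float(min(1.0, num / den)) if den > 0 else 1.0

    qs = np.array([fdr_q(v) for v in nes_obs])
    # enforce monotonicity: a more extreme NES never gets a larger q, so take
    # the running minimum from the least extreme set toward the most extreme
    for sign in (1, -1):
        side = np.where((np.sign(nes_obs) == sign) | ((nes_obs == 0) & (sign == 1)))[0]
        if side.size:
            order = side[np.argsort(-sign * nes_obs[side])]  # most extreme first
            qs[order] = np.minimum.accumulate(qs[order][::-1])[::-1]

    for j, (name, genes) in enumerate(usable):
        if inconclusive[j]:
            esr = observed[name]
            results.append(EnrichmentResult(name, len(genes), esr.es, np.nan,
                                            np.nan, np.nan, esr.leading_edge,
                                            inconclusive=True))
        else:
            esr, nominal = observed[name]
            results.append(EnrichmentResult(name, len(genes), esr.es,
                                            float(nes_obs[j]), nominal,
                                            float(qs[j]), esr.leading_edge))
    results.sort(key=lambda r: (-(r.nes if np.isfinite(r.nes) else -np.inf), r.set_name))
    return results


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Results as a table with the conventional report columns."""
    return pd.DataFrame(
        [(r.set_name, r.size, r.es, r.nes, r.nominal_p, r.fdr_q) for r in results],
        columns=["NAME", "SIZE", "ES", "NES", "NOM p-val", "FDR q-val"],
    )


def overrepresentation_test(
    query_genes: Sequence[str],
    universe_genes: Sequence[str],
    gene_sets: GeneSetCollection,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    For each set, tests whether the query contains at least the observed
    number of set members given the universe; BH correction across sets.
    Set membership is intersected with the universe first.
    """
    query = set(query_genes)
    if not query:
        raise ValidationError("empty query")
    universe = set(universe_genes)
    stray = sorted(query - universe)
    if stray:
        raise ValidationError(f"query genes outside universe: {stray[:10]}")
    N, n = len(universe), len(query)
    rows = []
    for name, genes in gene_sets.items():
        m = len(set(genes) & universe)
        k = len(set(genes) & query)
        p = float(stats.hypergeom.sf(k - 1, N, m, n)) if m else 1.0
        rows.append((name, m, k, min(1.0, p)))
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p_value"])
    df["bh_q"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_value", "set_name"]).reset_index(drop=True)
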