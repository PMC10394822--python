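"""CIMP signature selection and per-sample CIMP scoring.

A CIMP signature is the set of promoter probes whose methylation differs
across the three methylator-phenotype groups and rises monotonically from
lCIMP through iCIMP to hCIMP by more than a β-difference threshold at each
step.  The per-sample CIMP score is the plain sum of β-values over the
signature probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptySignatureError, ValidationError
from .io import BetaMatrix, ProbeAnnotation, SampleMetadata

logger = logging.getLogger("cimpkit")

_GROUP_ORDER = ("lCIMP", "iCIMP", "hCIMP")


@dataclass
class CimpSignature:
    """Selected signature probes plus the parameters that produced them."""

    probe_ids: tuple[str, ...]
    selection_params: dict = field(default_factory=dict)
    group_means: pd.DataFrame | None = None  # probes × (lCIMP, iCIMP, hCIMP)

    def __post_init__(self) -> None:
        if len(self.probe_ids) == 0:
            raise EmptySignatureError("signature has no probes")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probes in signature")

    def __len__(self) -> int:
        return len(self.probe_ids)


def select_signature_probes(
    beta: BetaMatrix,
    annotation: ProbeAnnotation,
    groups: SampleMetadata,
    *,
    delta_threshold: float = 0.2,
    alpha: float = 0.05,
    test: str = "kruskal",
    promoter_categories: tuple[str, ...] = ("TSS200",),
    max_probe_missing: float = 0.2,
) -> CimpSignature:
    """Select signature probes from a labeled cohort.

    A promoter probe (``tss_relation`` in ``promoter_categories``) is
    selected iff the across-group test (Kruskal-Wallis by default, one-way
    ANOVA with ``test="anova"``) is significant after Benjamini-Hochberg
    correction at ``alpha`` AND group mean β rises by more than
    ``delta_threshold`` from lCIMP to iCIMP and again from iCIMP to hCIMP.
    Probes missing in more than ``max_probe_missing`` of samples are
    excluded before testing; group means use available samples.

    Raises
    ------
    ValidationError
        if any CIMP group has fewer than 2 labeled samples.
    EmptySignatureError
        if no probe passes the filters.
    """
    group_samples = {}
    for g in _GROUP_ORDER:
        members = [s for s in groups.samples_in_group(g) if s in beta.values.columns]
        if len(members) < 2:
            raise ValidationError(f"group {g} has < 2 samples with beta values")
        group_samples[g] = members

    candidates = annotation.probes_in_categories(promoter_categories)
    candidates = candidates.intersection(beta.values.index)
    sub = beta.values.loc[candidates]
    keep = sub.isna().mean(axis=1) <= max_probe_missing
    sub = sub.loc[keep]
    logger.info("select_signature_probes: %d promoter probes tested "
                "(%d dropped for missingness)", len(sub), int((~keep).sum()))
    if len(sub) == 0:
        raise EmptySignatureError("no promoter probes available for testing")

    arrs = {g: sub[group_samples[g]].to_numpy() for g in _GROUP_ORDER}
    means = pd.DataFrame(
        {g: np.nanmean(arrs[g], axis=1) for g in _GROUP_ORDER}, index=sub.index
    )

    pvals = np.ones(len(sub))
    for i in range(len(sub)):
        samples = [arrs[g][i][~np.isnan(arrs[g][i])] for g in _GROUP_ORDER]
        if any(len(s) < 2 for s in samples):
            continue
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            continue  # identical constant in all groups: no signal, p stays 1
        try:
            if test == "kruskal":
                _, pvals[i] = stats.kruskal(*samples)
            elif test == "anova":
                _, pvals[i] = stats.f_oneway(*samples)
            else:
                raise ValidationError(f"unknown test {test!r}")
        except ValueError:
            pvals[i] = 1.0  # all identical within the test's tolerance

    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    delta1 = means["iCIMP"] - means["lCIMP"]
    delta2 = means["hCIMP"] - means["iCIMP"]
    selected = sub.index[reject
                         & (delta1.to_numpy() > delta_threshold)
                         & (delta2.to_numpy() > delta_threshold)]
    if len(selected) == 0:
        raise EmptySignatureError(
            f"no probe passed BH alpha={alpha} with both deltas > {delta_threshold}"
        )
    params = {
        "delta_threshold": delta_threshold, "significance_alpha": alpha,
        "test_name": test, "promoter_categories": tuple(promoter_categories),
        "max_probe_missing": max_probe_missing,
    }
    return CimpSignature(tuple(sorted(selected)), params, means.loc[selected])


def compute_cimp_score(
    beta: BetaMatrix,
    signature: CimpSignature,
    max_missing: float = 0.1,
) -> pd.Series:
    """Per-sample CIMP score: sum of β over available signature probes.

    Samples whose fraction of missing signature probes (absent from the
    matrix or NaN) exceeds ``max_missing`` get a missing (NaN) score.
    """
    if len(signature) == 0:  # CimpSignature construction already forbids this
        raise EmptySignatureError("signature has no probes")
    present = [p for p in signature.probe_ids if p in beta.values.index]
    sub = beta.values.reindex(list(signature.probe_ids))
    missing_frac = sub.isna().mean(axis=0)
    score = sub.sum(axis=0, skipna=True)
    score[missing_frac > max_missing] = np.nan
    score.name = "cimp_score"
    if len(present) < len(signature):
        logger.info("compute_cimp_score: %d/%d signature probes absent from matrix",
                    len(signature) - len(present), len(signature))
    return score
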