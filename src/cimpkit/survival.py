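"""Kaplan-Meier estimation, log-rank testing and expression stratification.

Thin, typed wrappers over lifelines: the product-limit estimator and the
k-group log-rank chi-square are standard machinery; what this module adds is
the expression-tertile stratification design (split samples by a gene's
expression quantiles, estimate survival per stratum, test with log-rank,
Bonferroni-adjust across the genes examined in a session).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import DegenerateInputError, ValidationError
from .io import ExpressionMatrix, SampleMetadata

logger = logging.getLogger("cimpkit")


@dataclass
class SurvivalCurve:
    """A product-limit curve: survival after each distinct event time."""

    event_times: np.ndarray  # distinct times with >= 1 event, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # subjects at risk just before each event time
    censor_times: np.ndarray  # times of censored observations

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValidationError("survival probabilities must be non-increasing")

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate; ties handled simultaneously."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValidationError("no subjects")
    if np.any(times <= 0):
        raise ValidationError("times must be positive")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValidationError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    has_event = table["observed"] > 0
    event_times = table.index[has_event].to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"]
    survival = np.array([float(surv.loc[t]) for t in event_times])
    at_risk = table.loc[has_event, "at_risk"].to_numpy(dtype=float)
    return SurvivalCurve(event_times, survival, at_risk,
                         np.sort(times[events == 0]))


def logrank_test(groups) -> tuple[float, float]:
    """k-group log-rank test; ``groups`` is a sequence of (times, events).

    Returns the chi-square statistic (k − 1 degrees of freedom) and p-value.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if np.any(t <= 0):
            raise ValidationError("times must be positive")
        times.append(t)
        events.append(e)
        labels.append(np.full(len(t), i))
    times = np.concatenate(times)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    if events.sum() == 0:
        raise DegenerateInputError("no events in any group")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class StratifiedSurvivalResult:
    curves: dict[str, SurvivalCurve]  # stratum label -> curve
    strata: pd.Series  # sample -> stratum label
    logrank_statistic: float
    logrank_p: float
    adjusted_p: float
    adjust_method: str
    median_survival: dict[str, float]


_TERTILE_LABELS = {2: ("low", "high"), 3: ("low", "medium", "high")}


def survival_by_expression(
    expr: ExpressionMatrix,
    gene_id: str,
    metadata: SampleMetadata,
    n_strata: int = 3,
    adjust: str = "bonferroni",
    n_genes_tested: int = 1,
) -> StratifiedSurvivalResult:
    """Survival stratified by a gene's expression quantiles.

    Samples are split into ``n_strata`` equal-size strata by expression rank
    (ties broken deterministically by sample id), Kaplan-Meier curves are
    estimated per stratum and compared with the k-group log-rank test.  With
    ``adjust="bonferroni"`` the p-value is multiplied by ``n_genes_tested``
    (the family being the genes examined in one session).
    """
    if gene_id not in expr.values.index:
        raise ValidationError(f"gene {gene_id!r} not in expression matrix")
    md = metadata.table
    usable = [s for s in expr.sample_ids
              if s in md.index
              and not np.isnan(md.loc[s, "survival_time"])
              and not np.isnan(md.loc[s, "event"])]
    dropped = len(expr.sample_ids) - len(usable)
    if dropped:
        logger.info("survival_by_expression: dropped %d samples without survival data",
                    dropped)
    if len(usable) < n_strata * 2:
        raise ValidationError("too few samples with survival data")

    values = expr.to_log2().loc[gene_id, usable]
    if values.nunique() < n_strata:
        raise DegenerateInputError(
            f"expression ties leave < {n_strata} distinct values; use fewer strata"
        )
    order = np.lexsort((np.asarray(usable, dtype=object), values.to_numpy()))
    labels_for_n = _TERTILE_LABELS.get(n_strata,
                                       tuple(f"stratum_{i + 1}" for i in range(n_strata)))
    strata = pd.Series(index=pd.Index(usable, name="sample_id"), dtype=object)
    bounds = np.linspace(0, len(usable), n_strata + 1).round().astype(int)
    for i in range(n_strata):
        strata.iloc[order[bounds[i]: bounds[i + 1]]] = labels_for_n[i]

    curves, med = {}, {}
    group_data = []
    for lab in labels_for_n:
        members = strata.index[strata == lab]
        t = md.loc[members, "survival_time"].to_numpy(dtype=float)
        e = md.loc[members, "event"].to_numpy(dtype=int)
        curves[lab] = km_estimate(t, e)
        group_data.append((t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        med[lab] = float(kmf.median_survival_time_)

    stat, p = logrank_test(group_data)
    if adjust == "bonferroni":
        adj = min(1.0, p * n_genes_tested)
    elif adjust == "none":
        adj = p
    else:
        raise ValidationError(f"unknown adjust method {adjust!r}")
    return StratifiedSurvivalResult(curves, strata, stat, p, adj, adjust, med)
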