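"""Correlation, partial correlation and the mediation / common-cause report.

The causal question addressed here: does cell proliferation drive the
methylator phenotype directly, or only through raising DNA-methyltransferase
expression?  With proliferation P, DNMT expression D_k and CIMP score C, the
mediation-consistent pattern is

* r(P, C) marginal: significant,
* r(D_k, C | P): significant and positive for every DNMT, and
* r(P, C | D_1, D_2): vanishing (the whole P effect routes through the Ds),

whereas a common cause P of both D and C leaves r(D_k, C | P) at zero.
Partial correlations are residual-based: each variable is regressed on the
controls (with intercept) by least squares and the Pearson correlation of
the residuals is taken, with a t-test on n − 2 − #controls degrees of
freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .io import ExpressionMatrix

__all__ = [
    "AssociationResult", "CausalModelReport", "MediationThresholds",
    "correlate", "partial_correlation", "purity_adjust", "mediation_report",
    "derive_verdict", "stemness_score", "module_activity_score",
    "STEMNESS_MARKERS", "GENE_ALIASES",
]

#: Stemness marker panel (HGNC symbols).
STEMNESS_MARKERS = ("POU5F1", "SOX2", "KLF4", "MYC", "NANOG", "SALL4")

#: Common aliases mapped to the HGNC symbols used above.
GENE_ALIASES = {"OCT4": "POU5F1", "OCT-4": "POU5F1", "C-MYC": "MYC", "CMYC": "MYC"}


@dataclass
class AssociationResult:
    r: float
    p_value: float
    n_effective: int
    method: str  # pearson | spearman | partial_pearson
    controlled_variables: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValidationError(f"correlation out of [-1,1]: {self.r}")


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def correlate(x, y, method: str = "pearson") -> AssociationResult:
    """Pearson or Spearman correlation with pairwise deletion of missing values."""
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in x or y")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return AssociationResult(float(r), float(p), n, method)


def _control_matrix(controls) -> np.ndarray:
    """Stack controls into an (n, k) array from a vector, sequence, or 2-D array."""
    arr = np.asarray(controls, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    elif arr.ndim == 2 and arr.shape[0] < arr.shape[1]:
        # sequence-of-vectors orientation: each row one control
        arr = arr.T
    return arr


def _residuals(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(v)), Z])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ coef


def partial_correlation(x, y, controls, control_names: Sequence[str] = ()) -> AssociationResult:
    """Pearson partial correlation of x and y given one or more controls.

    Residual-based: correlation of least-squares residuals of x and y on the
    controls (with intercept); two-sided p from the t distribution with
    n − 2 − #controls degrees of freedom.  Missing values are removed
    listwise across x, y and all controls.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = _control_matrix(controls)
    if not (len(x) == len(y) == Z.shape[0]):
        raise ValidationError("x, y and controls must share sample dimension")
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(Z).any(axis=1))
    x, y, Z = x[keep], y[keep], Z[keep]
    n, k = len(x), Z.shape[1]
    if n < 3 + k:
        raise ValidationError(f"need >= {3 + k} complete cases, got {n}")
    rx = _residuals(x, Z)
    ry = _residuals(y, Z)
    if np.std(rx) < 1e-12 * max(1.0, np.std(x)) or np.std(ry) < 1e-12 * max(1.0, np.std(y)):
        raise DegenerateInputError("a control is collinear with x or y (zero residual variance)")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = min(1.0, max(-1.0, r))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    names = tuple(control_names) if control_names else tuple(f"z{i + 1}" for i in range(k))
    return AssociationResult(r, p, n, "partial_pearson", names)


def purity_adjust(score: pd.Series, purity: pd.Series) -> pd.Series:
    """Residualize a per-sample score on tumor purity.

    Returns the residuals of ``score ~ 1 + purity``; samples with missing
    purity (or score) get a missing adjusted score.  Constant purity cannot
    be adjusted for: the centered score is returned with a warning.
    """
    score = pd.Series(score, dtype=float)
    purity = pd.Series(purity, dtype=float).reindex(score.index)
    keep = score.notna() & purity.notna()
    if int(keep.sum()) < 3:
        raise ValidationError(f"need >= 3 paired values, got {int(keep.sum())}")
    out = pd.Series(np.nan, index=score.index, name=score.name)
    s, p = score[keep].to_numpy(), purity[keep].to_numpy()
    if np.ptp(p) == 0:
        warnings.warn("purity is constant; returning centered scores", stacklevel=2)
        out[keep] = s - s.mean()
        return out
    out[keep] = _residuals(s, p[:, None])
    return out


@dataclass
class MediationThresholds:
    alpha: float = 0.05
    min_direct: float = 0.2  # minimum r(DNMT, CIMP | proliferation)
    max_residual: float = 0.15  # maximum |r(proliferation, CIMP | DNMTs)|


@dataclass
class CausalModelReport:
    """All statistics entering the verdict, plus the verdict itself.

    The verdict is a pure function of the stored statistics and thresholds:
    :func:`derive_verdict` recomputes it from this report alone.
    """

    r_prolif_cimp_marginal: AssociationResult
    r_dnmt_cimp_given_prolif: dict[str, AssociationResult]
    r_prolif_cimp_given_dnmt: AssociationResult
    thresholds: MediationThresholds
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        self.verdict = derive_verdict(self)


def derive_verdict(report: CausalModelReport) -> str:
    """Re-derive the verdict from a report's stored statistics."""
    th = report.thresholds
    a = report.r_prolif_cimp_marginal
    bs = report.r_dnmt_cimp_given_prolif.values()
    c = report.r_prolif_cimp_given_dnmt
    if a.p_value >= th.alpha:
        return "no_association"
    direct_ok = all(b.p_value < th.alpha and b.r > th.min_direct for b in bs)
    residual_ok = c.p_value >= th.alpha and abs(c.r) < th.max_residual
    if direct_ok and residual_ok:
        return "mediation_consistent"
    if all(b.p_value >= th.alpha for b in bs):
        return "common_cause_consistent"
    return "inconclusive"


def mediation_report(
    prolif: pd.Series,
    dnmt_expr: Mapping[str, pd.Series],
    cimp: pd.Series,
    thresholds: MediationThresholds | None = None,
) -> CausalModelReport:
    """Discriminate mediation (P → D → C) from a common cause (D ← P → C).

    Inputs are per-sample vectors aligned by index (pandas Series sharing a
    sample index, or equal-length arrays).  Computes the marginal
    correlation of proliferation with the CIMP score, the partial
    correlation of each DNMT's expression with the CIMP score controlling
    for proliferation, and the partial correlation of proliferation with the
    CIMP score controlling for all DNMTs jointly; the verdict rule is in
    :func:`derive_verdict`.
    """
    thresholds = thresholds or MediationThresholds()
    prolif = pd.Series(prolif, dtype=float)
    cimp = pd.Series(cimp, dtype=float)
    frame = {"prolif": prolif, "cimp": cimp}
    for name, v in dnmt_expr.items():
        frame[name] = pd.Series(v, dtype=float)
    try:
        df = pd.DataFrame(frame)
    except ValueError as exc:
        raise ValidationError(f"misaligned sample vectors: {exc}") from exc
    if df.isna().all(axis=0).any() or len(df.dropna()) < 10:
        raise ValidationError("need >= 10 aligned complete samples")
    df = df.dropna()
    dnmt_names = [c for c in df.columns if c not in ("prolif", "cimp")]

    a = correlate(df["prolif"], df["cimp"], method="pearson")
    bs = {
        name: partial_correlation(df[name], df["cimp"], df["prolif"].to_numpy(),
                                  control_names=("prolif",))
        for name in dnmt_names
    }
    c = partial_correlation(df["prolif"], df["cimp"],
                            df[dnmt_names].to_numpy(),
                            control_names=tuple(dnmt_names))
    return CausalModelReport(a, bs, c, thresholds)


# ---------------------------------------------------------------------------
# composite expression scores
# ---------------------------------------------------------------------------

def stemness_score(
    expr: ExpressionMatrix,
    marker_genes: Sequence[str] = STEMNESS_MARKERS,
) -> tuple[pd.Series, list[str]]:
    """Mean log2 expression over stemness markers, per sample.

    Marker aliases (OCT4, C-MYC, ...) are mapped to HGNC symbols.  Returns
    the score and the list of markers not found in the matrix.
    """
    mapped = [GENE_ALIASES.get(g.upper(), g) for g in marker_genes]
    log2 = expr.to_log2()
    present = [g for g in mapped if g in log2.index]
    missing = [g for g in mapped if g not in log2.index]
    if not present:
        raise ValidationError("no stemness marker present in expression matrix")
    score = log2.loc[present].mean(axis=0)
    score.name = "stemness_score"
    return score, missing


def module_activity_score(expr: ExpressionMatrix, gene_set: Sequence[str]) -> pd.Series:
    """First-principal-component activity of a gene module, per sample.

    The log2 submatrix of the module's genes is z-scored gene-wise, its
    first principal component over samples is taken, and the sign is
    oriented so the score correlates positively with the module's mean
    expression.  This is a deliberate simplification of module-activity
    tools that additionally test overdispersion: only the activity score is
    consumed downstream.
    """
    log2 = expr.to_log2()
    present = [g for g in dict.fromkeys(gene_set) if g in log2.index]
    if len(present) < 2:
        raise ValidationError(f"need >= 2 module genes in matrix, got {len(present)}")
    if log2.shape[1] < 3:
        raise ValidationError("need >= 3 samples")
    sub = log2.loc[present].to_numpy()
    sd = sub.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    # PC1 over samples: leading right singular vector of the gene x sample z-matrix
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    pc1 = vt[0] * s[0]
    mean_expr = log2.loc[present].mean(axis=0).to_numpy()
    if np.std(mean_expr) > 0 and np.corrcoef(pc1, mean_expr)[0, 1] < 0:
        pc1 = -pc1
    return pd.Series(pc1, index=log2.columns, name="module_activity")
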