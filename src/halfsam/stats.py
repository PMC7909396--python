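"""Per-gene two-sample scores and the CV-minimizing fudge factor.

Four statistics for a case/control comparison of gene ``g``:

* Student's t:  ``ts = (m1 - m0) / (sp * sqrt(1/n1 + 1/n0))``, df ``n1+n0-2``
* half Student's t:  ``th = (m1 - m0) / (s0 * sqrt(1/n1 + 1/n0))``, df ``n0-1``
* SAM:  ``d = (m1 - m0) / (sp * sqrt(1/n1 + 1/n0) + c0)``
* half SAM:  ``dh = (m1 - m0) / (s0 * sqrt(1/n1 + 1/n0) + c0)``

where ``sp`` is the pooled standard deviation and ``s0`` the control-group
standard deviation.  The half variants ignore the case-group variance, the
working model for heterogeneous diseases where the case group mixes
etiological subtypes and is over-dispersed relative to the controls.

The fudge factor ``c0`` is an additive denominator constant chosen so that
the coefficient of variation of the score's spread is minimized across
genes of comparable scatter, preventing genes with tiny variance from
dominating the ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

STATISTICS = ("student_t", "half_t", "sam", "half_sam")
#: statistics whose denominator includes the fudge factor
SCORE_STATISTICS = ("sam", "half_sam")

__all__ = [
    "STATISTICS",
    "SCORE_STATISTICS",
    "GroupSummary",
    "ScoreVector",
    "FudgeFactor",
    "summarize_groups",
    "student_t_scores",
    "half_t_scores",
    "sam_scores",
    "half_sam_scores",
    "estimate_fudge_factor",
    "fudge_factor_for",
    "scatter_for",
]


@dataclass
class GroupSummary:
    """Per-gene group sizes, means, SDs and the pooled SD."""

    n1: int
    n0: int
    mean1: np.ndarray
    mean0: np.ndarray
    sd1: np.ndarray
    sd0: np.ndarray
    sp: np.ndarray
    gene_ids: list

    @property
    def n_genes(self) -> int:
        return self.mean1.size

    @property
    def se_factor(self) -> float:
        """sqrt(1/n1 + 1/n0), the scatter scale shared by all statistics."""
        return float(np.sqrt(1.0 / self.n1 + 1.0 / self.n0))


@dataclass
class ScoreVector:
    """Per-gene values of one statistic.

    ``df`` is set for the t statistics, ``c0`` for the SAM-type scores; the
    two are mutually exclusive.  Genes whose denominator is exactly zero
    are NaN in ``scores`` and flagged in ``undefined``.
    """

    method: str
    scores: np.ndarray
    undefined: np.ndarray
    gene_ids: list
    df: Optional[int] = None
    c0: Optional[float] = None

    def __post_init__(self):
        if (self.df is None) == (self.c0 is None):
            raise ValueError("exactly one of df/c0 must be set")


@dataclass
class FudgeFactor:
    """A chosen fudge factor with its selection audit trail.

    ``c0`` equals the ``percentile``-th percentile of the per-gene scatter;
    ``cv_profile`` holds the minimized criterion at every candidate grid
    point.
    """

    c0: float
    percentile: float
    cv_profile: np.ndarray
    percentiles: np.ndarray
    candidates: np.ndarray


def summarize_groups(matrix) -> GroupSummary:
    """Per-gene sample means, SDs (n-1 denominator) and pooled SD."""
    case = matrix.case_values
    ctrl = matrix.control_values
    n1, n0 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n0 < 2:  # LabeledExpressionMatrix already enforces this
        from .data import InvalidDesignError

        raise InvalidDesignError("each group needs at least 2 samples")
    mean1 = case.mean(axis=1)
    mean0 = ctrl.mean(axis=1)
    var1 = case.var(axis=1, ddof=1)
    var0 = ctrl.var(axis=1, ddof=1)
    sp = np.sqrt(((n1 - 1) * var1 + (n0 - 1) * var0) / (n1 + n0 - 2))
    return GroupSummary(n1=n1, n0=n0, mean1=mean1, mean0=mean0,
                        sd1=np.sqrt(var1), sd0=np.sqrt(var0), sp=sp,
                        gene_ids=list(matrix.gene_ids))


def _ratio_scores(numerator, denominator, method):
    undefined = denominator == 0
    if undefined.any():
        logger.warning("%s: %d gene(s) with zero denominator flagged undefined",
                       method, int(undefined.sum()))
    scores = np.full(numerator.shape, np.nan)
    np.divide(numerator, denominator, out=scores, where=~undefined)
    return scores, undefined


def student_t_scores(summary: GroupSummary) -> ScoreVector:
    """Pooled-SD two-sample t, df = n1 + n0 - 2."""
    scores, undef = _ratio_scores(summary.mean1 - summary.mean0,
                                  summary.sp * summary.se_factor, "student_t")
    return ScoreVector("student_t", scores, undef, summary.gene_ids,
                       df=summary.n1 + summary.n0 - 2)


def half_t_scores(summary: GroupSummary) -> ScoreVector:
    """Control-SD-only two-sample t, df = n0 - 1."""
    scores, undef = _ratio_scores(summary.mean1 - summary.mean0,
                                  summary.sd0 * summary.se_factor, "half_t")
    return ScoreVector("half_t", scores, undef, summary.gene_ids,
                       df=summary.n0 - 1)


def _as_c0(c0) -> float:
    value = float(c0.c0 if isinstance(c0, FudgeFactor) else c0)
    if value < 0:
        raise ValueError(f"fudge factor must be non-negative, got {value}")
    return value


def sam_scores(summary: GroupSummary, c0) -> ScoreVector:
    """SAM score: pooled scatter plus fudge factor in the denominator."""
    c0v = _as_c0(c0)
    scores, undef = _ratio_scores(summary.mean1 - summary.mean0,
                                  summary.sp * summary.se_factor + c0v, "sam")
    return ScoreVector("sam", scores, undef, summary.gene_ids, c0=c0v)


def half_sam_scores(summary: GroupSummary, c0) -> ScoreVector:
    """Half SAM score: control-only scatter plus fudge factor."""
    c0v = _as_c0(c0)
    scores, undef = _ratio_scores(summary.mean1 - summary.mean0,
                                  summary.sd0 * summary.se_factor + c0v,
                                  "half_sam")
    return ScoreVector("half_sam", scores, undef, summary.gene_ids, c0=c0v)


def scatter_for(summary: GroupSummary, method: str) -> np.ndarray:
    """Per-gene denominator scatter of a SAM-type score (without c0).

    For ``half_sam`` this is the control-only scatter s0*sqrt(1/n1+1/n0),
    mirroring the dh denominator; for ``sam`` the pooled equivalent.
    """
    if method == "sam":
        return summary.sp * summary.se_factor
    if method == "half_sam":
        return summary.sd0 * summary.se_factor
    raise ValueError(f"no scatter defined for method {method!r}")


def estimate_fudge_factor(numerators, scatters,
                          percentiles=None, n_windows: int = 100) -> FudgeFactor:
    """Choose c0 on a percentile grid of the scatter distribution.

    Candidates are the percentiles 0, 5, ..., 100 of the per-gene scatter.
    For each candidate the genes are partitioned into ``n_windows``
    scatter-quantile windows; the criterion is the coefficient of
    variation, across windows, of the within-window median absolute
    deviation of the resulting scores.  The candidate minimizing the
    criterion wins; ties break toward the lowest percentile.
    """
    numerators = np.asarray(numerators, dtype=float)
    scatters = np.asarray(scatters, dtype=float)
    if numerators.shape != scatters.shape or numerators.ndim != 1:
        raise ValueError("numerators and scatters must be equal-length vectors")
    n_genes = numerators.size
    if n_genes < 20:
        raise ValueError(f"need at least 20 genes to estimate c0, got {n_genes}")
    if (scatters < 0).any():
        raise ValueError("scatters must be non-negative")
    if not scatters.any():
        raise ValueError("all scatters are zero; c0 is unidentifiable")

    if percentiles is None:
        percentiles = np.arange(0, 101, 5)
    percentiles = np.asarray(percentiles, dtype=float)
    candidates = np.percentile(scatters, percentiles)

    n_windows = max(1, min(int(n_windows), n_genes // 2))
    order = np.argsort(scatters, kind="stable")
    windows = np.array_split(order, n_windows)

    cv_profile = np.empty(percentiles.size)
    for k, cand in enumerate(candidates):
        denom = scatters + cand
        with np.errstate(divide="ignore", invalid="ignore"):
            d = numerators / denom
        mads = np.array([_mad(d[w]) for w in windows])
        if not np.isfinite(mads).all():
            cv_profile[k] = np.inf
            continue
        mean = mads.mean()
        if mean > 0:
            cv_profile[k] = mads.std(ddof=1) / mean if mads.size > 1 else 0.0
        else:
            cv_profile[k] = 0.0 if np.all(mads == 0) else np.inf
    best = int(np.argmin(cv_profile))  # argmin takes the first = lowest percentile
    return FudgeFactor(c0=float(candidates[best]),
                       percentile=float(percentiles[best]),
                       cv_profile=cv_profile, percentiles=percentiles,
                       candidates=candidates)


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def fudge_factor_for(summary: GroupSummary, method: str, **kwargs) -> FudgeFactor:
    """Estimate c0 for ``sam`` or ``half_sam`` from a group summary."""
    return estimate_fudge_factor(summary.mean1 - summary.mean0,
                                 scatter_for(summary, method), **kwargs)
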