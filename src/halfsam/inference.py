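"""Resampling-based significance for the two-sample scores.

The null distribution of the SAM-type scores is not a t distribution, so
p-values come from relabeling the samples: for each of B random
relabelings that preserve the group sizes, every statistic is recomputed
in full -- including the control-group SD taken from the permuted
"control" samples -- while the fudge factor c0 stays frozen at its
observed-data estimate (the score is a fixed functional of the data; only
the labels are random under the null).

Two p-value conventions are offered:

* ``per_gene`` (default) -- each gene is compared against its own B
  permuted scores, p = (1 + #{|d*_b| >= |d|}) / (B + 1).
* ``pooled`` -- the SAM convention: one null distribution pooled across
  all genes and permutations, p = (1 + #{|d*| >= |d|}) / (1 + B*G),
  giving much finer resolution at small B.

When B is at least the number of distinct label assignments the engine
switches to exhaustive enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import LabeledExpressionMatrix
from .stats import (SCORE_STATISTICS, STATISTICS, ScoreVector,
                    estimate_fudge_factor, fudge_factor_for, scatter_for,
                    summarize_groups)

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "permutation_null",
    "permutation_pvalues",
    "bh_fdr",
    "detect_degs",
    "compute_scores",
]


def compute_scores(matrix: LabeledExpressionMatrix, method: str,
                   c0=None) -> ScoreVector:
    """Score every gene with one statistic, estimating c0 if needed."""
    from . import stats as _s

    if method not in STATISTICS:
        raise ValueError(f"unknown statistic {method!r}; choose from {STATISTICS}")
    summary = summarize_groups(matrix)
    if method == "student_t":
        return _s.student_t_scores(summary)
    if method == "half_t":
        return _s.half_t_scores(summary)
    if c0 is None:
        c0 = fudge_factor_for(summary, method)
    if method == "sam":
        return _s.sam_scores(summary, c0)
    return _s.half_sam_scores(summary, c0)


# ---------------------------------------------------------------------------
# vectorized statistics over many relabelings
# ---------------------------------------------------------------------------

def _stats_for_weight_matrices(X, Wc, Wn, n1, n0):
    """Group means/SDs for many (re)labelings at once.

    ``Wc``/``Wn`` are (n_samples, B) column-weight matrices whose columns
    sum to n1 and n0 (multiplicities; 0/1 for plain permutations).
    Returns (m1, m0, s1, s0, sp), each (n_genes, B).
    """
    X2 = X * X
    m1 = (X @ Wc) / n1
    m0 = (X @ Wn) / n0
    e1 = (X2 @ Wc) / n1
    e0 = (X2 @ Wn) / n0
    v1 = np.clip(e1 - m1 * m1, 0.0, None) * (n1 / (n1 - 1))
    v0 = np.clip(e0 - m0 * m0, 0.0, None) * (n0 / (n0 - 1))
    s1 = np.sqrt(v1)
    s0 = np.sqrt(v0)
    sp = np.sqrt(((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2))
    return m1, m0, s1, s0, sp


def _score_matrix(X, Wc, Wn, n1, n0, method, c0):
    """(n_genes, B) matrix of scores for the given labelings."""
    m1, m0, s1, s0, sp = _stats_for_weight_matrices(X, Wc, Wn, n1, n0)
    se = np.sqrt(1.0 / n1 + 1.0 / n0)
    num = m1 - m0
    if method == "student_t":
        den = sp * se
    elif method == "half_t":
        den = s0 * se
    elif method == "sam":
        den = sp * se + c0
    elif method == "half_sam":
        den = s0 * se + c0
    else:
        raise ValueError(f"unknown statistic {method!r}")
    out = np.full(num.shape, np.nan)
    np.divide(num, den, out=out, where=den != 0)
    return out


@dataclass
class PermutationResult:
    """Observed scores plus their resampled null scores."""

    method: str
    observed: ScoreVector
    null_scores: np.ndarray  # (B, n_genes)
    B: int
    seed: int
    exhaustive: bool = False
    resampling: str = "permutation"
    # observed scores recomputed through the permutation engine's exact
    # arithmetic, so ties with null scores are counted reliably
    observed_engine: np.ndarray = None

    def __post_init__(self):
        if self.observed_engine is None:
            self.observed_engine = self.observed.scores

    @property
    def pvalues(self) -> np.ndarray:
        return permutation_pvalues(self)


def _assignment_weights(matrix, B, rng, exhaustive_limit=True):
    """Case/control 0-1 weight matrices for B relabelings (or all of them)."""
    n = matrix.n_samples
    n1 = matrix.n_case
    total = comb(n, n1)
    if exhaustive_limit and B >= total:
        logger.info("B=%d >= %d distinct assignments; enumerating exhaustively",
                    B, total)
        sets = list(combinations(range(n), n1))
        B = total
        exhaustive = True
    else:
        sets = [tuple(rng.permutation(n)[:n1]) for _ in range(B)]
        exhaustive = False
    Wc = np.zeros((n, B))
    for b, cols in enumerate(sets):
        Wc[list(cols), b] = 1.0
    return Wc, 1.0 - Wc, B, exhaustive


def _bootstrap_weights(matrix, B, rng):
    """Within-group multinomial resampling weights, groups mean-centered.

    Each replicate redraws n1 case columns (from the case group) and n0
    control columns (from the control group) with replacement.  The
    caller must centre each group at its per-gene mean first so that the
    resampling distribution obeys the null of equal means.
    """
    n = matrix.n_samples
    case_idx = np.flatnonzero(matrix.labels == 1)
    ctrl_idx = np.flatnonzero(matrix.labels == 0)
    Wc = np.zeros((n, B))
    Wn = np.zeros((n, B))
    for b in range(B):
        for src, W in ((case_idx, Wc), (ctrl_idx, Wn)):
            draws = rng.choice(src, size=src.size, replace=True)
            np.add.at(W[:, b], draws, 1.0)
    return Wc, Wn


def permutation_null(matrix: LabeledExpressionMatrix, method: str, B: int,
                     seed: int = 0, resampling: str = "permutation",
                     recompute_c0: bool = False, c0=None) -> PermutationResult:
    """Null scores from B relabelings (or within-group bootstrap draws).

    For SAM-type statistics the fudge factor is estimated once from the
    observed labeling and held fixed across resamples unless
    ``recompute_c0`` is set.
    """
    if method not in STATISTICS:
        raise ValueError(f"unknown statistic {method!r}")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    observed = compute_scores(matrix, method, c0=c0)
    c0_val = observed.c0 if method in SCORE_STATISTICS else None

    X = matrix.values
    n1, n0 = matrix.n_case, matrix.n_control
    exhaustive = False
    if resampling == "permutation":
        Wc, Wn, B, exhaustive = _assignment_weights(matrix, B, rng)
    elif resampling == "bootstrap":
        X = X.copy()
        X[:, matrix.labels == 1] -= X[:, matrix.labels == 1].mean(1, keepdims=True)
        X[:, matrix.labels == 0] -= X[:, matrix.labels == 0].mean(1, keepdims=True)
        Wc, Wn = _bootstrap_weights(matrix, B, rng)
    else:
        raise ValueError(f"unknown resampling mode {resampling!r}")

    obs_w = (matrix.labels == 1).astype(float)[:, None]
    if recompute_c0 and method in SCORE_STATISTICS:
        null = np.empty((B, matrix.n_genes))
        se = np.sqrt(1.0 / n1 + 1.0 / n0)
        for b in range(B):
            m1, m0, s1, s0, sp = _stats_for_weight_matrices(
                X, Wc[:, [b]], Wn[:, [b]], n1, n0)
            num = (m1 - m0).ravel()
            scat = (sp if method == "sam" else s0).ravel() * se
            cb = estimate_fudge_factor(num, scat).c0
            null[b] = _score_matrix(X, Wc[:, [b]], Wn[:, [b]], n1, n0,
                                    method, cb).ravel()
        obs_engine = _score_matrix(matrix.values, obs_w, 1.0 - obs_w, n1, n0,
                                   method, c0_val).ravel()
    elif resampling == "permutation":
        # the observed labeling rides along as the last column so that it
        # shares the exact BLAS arithmetic of the null columns (tie counting)
        all_scores = _score_matrix(np.ascontiguousarray(matrix.values),
                                   np.hstack([Wc, obs_w]),
                                   np.hstack([Wn, 1.0 - obs_w]),
                                   n1, n0, method, c0_val).T
        null, obs_engine = all_scores[:B], all_scores[B]
    else:
        null = _score_matrix(X, Wc, Wn, n1, n0, method, c0_val).T
        obs_engine = _score_matrix(matrix.values, obs_w, 1.0 - obs_w, n1, n0,
                                   method, c0_val).ravel()
    return PermutationResult(method=method, observed=observed,
                             null_scores=null, B=B, seed=seed,
                             exhaustive=exhaustive, resampling=resampling,
                             observed_engine=obs_engine)


def permutation_pvalues(result: PermutationResult,
                        mode: str = "per_gene") -> np.ndarray:
    """Two-sided add-one p-values; NaN for genes with undefined scores."""
    obs = np.abs(result.observed_engine)
    null = np.abs(result.null_scores)
    B = result.B
    if mode == "per_gene":
        counts = np.nansum(null >= obs[None, :], axis=0)
        p = (1.0 + counts) / (B + 1.0)
    elif mode == "pooled":
        flat = np.sort(null[np.isfinite(null)], axis=None)
        counts = flat.size - np.searchsorted(flat, obs, side="left")
        p = (1.0 + counts) / (1.0 + flat.size)
    else:
        raise ValueError(f"unknown p-value mode {mode!r}")
    p = np.minimum(p, 1.0)
    p[result.observed.undefined] = np.nan
    return p


def bh_fdr(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up; returns (adjusted p, significant flags).

    NaN p-values (undefined genes) are excluded from the procedure and
    come back NaN/False.
    """
    p = np.asarray(pvalues, dtype=float)
    padj = np.full(p.shape, np.nan)
    signif = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        rej, adj, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        padj[ok] = adj
        signif[ok] = rej
    return padj, signif


def detect_degs(matrix: LabeledExpressionMatrix, method: str,
                threshold_type: str = "fdr", level: float = 0.05,
                B: int = 1000, seed: int = 0, null_mode: str = "per_gene",
                resampling: str = "permutation",
                recompute_c0: bool = False) -> pd.DataFrame:
    """End-to-end DEG calling: score, permute, threshold.

    Returns the full audit table (one row per gene): gene_id, method,
    score, pvalue, padj, significant, threshold_type, level.  Undefined
    genes (zero denominator with c0 = 0) are never called significant.
    """
    if threshold_type not in ("alpha", "fdr"):
        raise ValueError("threshold_type must be 'alpha' or 'fdr'")
    result = permutation_null(matrix, method, B=B, seed=seed,
                              resampling=resampling, recompute_c0=recompute_c0)
    pvals = permutation_pvalues(result, mode=null_mode)
    if threshold_type == "fdr":
        padj, signif = bh_fdr(pvals, q=level)
    else:
        padj, _ = bh_fdr(pvals, q=level)
        signif = np.where(np.isnan(pvals), False, pvals <= level)
    return pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "method": method,
        "score": result.observed.scores,
        "pvalue": pvals,
        "padj": padj,
        "significant": signif,
        "threshold_type": threshold_type,
        "level": level,
    })
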