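"""Model/Results front-end for differential-expression testing.

    >>> model = DifferentialExpressionModel(matrix, method="half_sam")
    >>> res = model.fit(threshold_type="fdr", level=0.05, B=1000, seed=7)
    >>> print(res.summary())
    >>> res.to_tsv("half_sam_degs.tsv")

The model wraps a :class:`~halfsam.data.LabeledExpressionMatrix` and a
choice of statistic; fitting runs the full pipeline (group summary, fudge
factor for the SAM-type scores, permutation null, p-values, threshold)
and returns a results object carrying the per-gene estimates and the run
metadata needed to replay it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LabeledExpressionMatrix, write_results
from .inference import bh_fdr, permutation_null, permutation_pvalues
from .stats import SCORE_STATISTICS, STATISTICS

__all__ = ["DifferentialExpressionModel", "DifferentialExpressionResults"]


class DifferentialExpressionModel:
    """A two-group differential-expression test bound to one dataset.

    Parameters
    ----------
    matrix : LabeledExpressionMatrix
        Genes x samples expression values with case/control labels.
    method : str
        One of ``student_t``, ``half_t``, ``sam``, ``half_sam``.
    """

    def __init__(self, matrix: LabeledExpressionMatrix,
                 method: str = "half_sam"):
        if method not in STATISTICS:
            raise ValueError(
                f"unknown statistic {method!r}; choose from {STATISTICS}")
        self.matrix = matrix
        self.method = method

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, labels,
                       method: str = "half_sam") -> "DifferentialExpressionModel":
        return cls(LabeledExpressionMatrix.from_dataframe(df, labels),
                   method=method)

    def fit(self, threshold_type: str = "fdr", level: float = 0.05,
            B: int = 1000, seed: int = 0, null_mode: str = "per_gene",
            resampling: str = "permutation",
            recompute_c0: bool = False) -> "DifferentialExpressionResults":
        """Run the permutation pipeline and return a results object."""
        if threshold_type not in ("alpha", "fdr"):
            raise ValueError("threshold_type must be 'alpha' or 'fdr'")
        perm = permutation_null(self.matrix, self.method, B=B, seed=seed,
                                resampling=resampling,
                                recompute_c0=recompute_c0)
        pvalues = permutation_pvalues(perm, mode=null_mode)
        padj, fdr_signif = bh_fdr(pvalues, q=level)
        if threshold_type == "fdr":
            significant = fdr_signif
        else:
            significant = np.where(np.isnan(pvalues), False, pvalues <= level)
        return DifferentialExpressionResults(
            model=self, permutation=perm, pvalues=pvalues, padj=padj,
            significant=significant, threshold_type=threshold_type,
            level=level, null_mode=null_mode, seed=seed)


@dataclass
class DifferentialExpressionResults:
    """Per-gene scores, p-values and DEG calls from one fitted model."""

    model: DifferentialExpressionModel
    permutation: object = field(repr=False)
    pvalues: np.ndarray = field(repr=False)
    padj: np.ndarray = field(repr=False)
    significant: np.ndarray = field(repr=False)
    threshold_type: str
    level: float
    null_mode: str
    seed: int

    @property
    def method(self) -> str:
        return self.model.method

    @property
    def scores(self) -> np.ndarray:
        return self.permutation.observed.scores

    @property
    def c0(self):
        return self.permutation.observed.c0

    @property
    def df(self):
        return self.permutation.observed.df

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.model.matrix.gene_ids,
            "method": self.method,
            "score": self.scores,
            "pvalue": self.pvalues,
            "padj": self.padj,
            "significant": self.significant,
            "threshold_type": self.threshold_type,
            "level": self.level,
        })

    def to_tsv(self, path) -> None:
        write_results(self.to_frame(), path)

    def summary(self) -> str:
        """Plain-text summary table of the fit and the top genes."""
        m = self.model.matrix
        lines = [
            "Differential Expression Results",
            "=" * 46,
            f"statistic:            {self.method}",
            f"genes:                {m.n_genes}",
            f"samples:              {m.n_samples} "
            f"({m.n_case} case / {m.n_control} control)",
            f"permutations (B):     {self.permutation.B}"
            f"{' (exhaustive)' if self.permutation.exhaustive else ''}",
            f"p-value null:         {self.null_mode}",
            f"threshold:            {self.threshold_type} <= {self.level:g}",
            f"seed:                 {self.seed}",
        ]
        if self.c0 is not None:
            lines.append(f"fudge factor c0:      {self.c0:.6g}")
        if self.df is not None:
            lines.append(f"degrees of freedom:   {self.df}")
        undef = int(self.permutation.observed.undefined.sum())
        if undef:
            lines.append(f"undefined genes:      {undef}")
        lines.append(f"significant genes:    {self.n_significant} "
                     f"({100.0 * self.n_significant / m.n_genes:.2f}%)")
        top = (self.to_frame().dropna(subset=["pvalue"])
               .sort_values(["pvalue", "gene_id"],
                            key=lambda s: s if s.name == "pvalue"
                            else s.astype(str))
               .head(10))
        if len(top):
            lines += ["-" * 46,
                      f"{'gene':<14}{'score':>10}{'pvalue':>11}{'padj':>11}"]
            for _, row in top.iterrows():
                lines.append(f"{str(row.gene_id):<14}{row.score:>10.3f}"
                             f"{row.pvalue:>11.4g}{row.padj:>11.4g}")
        return "\n".join(lines)
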