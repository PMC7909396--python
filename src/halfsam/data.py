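"""Expression-matrix containers, file I/O and preprocessing filters.

The on-disk convention is tab-separated genes x samples matrices (first
column gene identifier, first row sample identifiers) with a separate
plain-text label file, one entry per sample.  Two label dialects are
understood:

* ``alon`` -- signed sample identifiers as distributed with the Alon et
  al. colon-cancer dataset: a positive number marks a tumor (case)
  sample, a negative number a normal (control) sample.
* ``generic`` -- explicit ``case``/``control`` tokens (``1``/``0``,
  ``tumor``/``normal`` are accepted as synonyms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LabeledExpressionMatrix",
    "RawCountMatrix",
    "InvalidDesignError",
    "FormatError",
    "read_expression_matrix",
    "read_labels",
    "filter_positive_total_counts",
    "log_transform",
    "write_results",
    "read_results",
]


class InvalidDesignError(ValueError):
    """Raised when a study design cannot support a two-sample comparison."""


class FormatError(ValueError):
    """Raised when an input file does not parse as the documented format."""


@dataclass
class LabeledExpressionMatrix:
    """Gene x sample expression values with binary case/control labels.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_samples)
        Expression intensities or counts, original or log scale.
    gene_ids : sequence of str
        One identifier per row.
    labels : ndarray of {0, 1}
        Per-sample group membership, 1 = case, 0 = control.
    log_transformed : bool
        Set by :func:`log_transform`; guards against double transforms.
    """

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    labels: np.ndarray = None
    log_transformed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidDesignError("expression values must be a 2-D matrix")
        if self.labels is None:
            raise InvalidDesignError("sample labels are required")
        self.labels = np.asarray(self.labels).astype(int)
        if not self.gene_ids:
            self.gene_ids = [f"g{i}" for i in range(self.values.shape[0])]
        self.gene_ids = list(self.gene_ids)
        if len(self.gene_ids) != self.values.shape[0]:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if self.labels.shape != (self.values.shape[1],):
            raise FormatError(
                f"{self.labels.size} labels for {self.values.shape[1]} sample columns"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise FormatError("labels must be binary (1 = case, 0 = control)")
        if not np.isfinite(self.values).all():
            raise FormatError("expression matrix contains missing/non-finite values")
        if self.n_case < 2 or self.n_control < 2:
            raise InvalidDesignError(
                "each group needs at least 2 samples "
                f"(got {self.n_case} case, {self.n_control} control)"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_case(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_control(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def case_values(self) -> np.ndarray:
        return self.values[:, self.labels == 1]

    @property
    def control_values(self) -> np.ndarray:
        return self.values[:, self.labels == 0]

    # -- constructors / converters --------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, labels) -> "LabeledExpressionMatrix":
        """Build from a genes-as-rows DataFrame and a label sequence."""
        return cls(values=df.to_numpy(dtype=float), gene_ids=list(df.index),
                   labels=np.asarray(labels))

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{'case' if l else 'ctrl'}_{i}" for i, l in enumerate(self.labels)]
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)


@dataclass
class RawCountMatrix:
    """Non-negative integer RNA-seq count matrix (genes x samples)."""

    counts: np.ndarray
    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("count matrix must be 2-D")
        if self.counts.size and (
            (self.counts < 0).any() or not np.equal(np.mod(self.counts, 1), 0).all()
        ):
            raise FormatError("counts must be non-negative integers")
        if not self.gene_ids:
            self.gene_ids = [f"g{i}" for i in range(self.counts.shape[0])]
        if not self.sample_ids:
            self.sample_ids = [f"s{j}" for j in range(self.counts.shape[1])]
        if len(self.gene_ids) != self.counts.shape[0]:
            raise FormatError("gene id count does not match row count")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise FormatError("sample id count does not match column count")


_CASE_TOKENS = {"case", "tumor", "tumour", "treated", "1"}
_CONTROL_TOKENS = {"control", "ctrl", "normal", "healthy", "0"}


def read_labels(labels_path, dialect: str = "auto") -> np.ndarray:
    """Parse a plain-text label file into a binary 0/1 vector.

    ``alon`` dialect: signed numeric sample identifiers, positive = case.
    ``generic`` dialect: case/control tokens.  ``auto`` picks ``alon`` when
    every token parses as a number, otherwise ``generic``.
    """
    with open(labels_path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise FormatError(f"empty label file: {labels_path}")
    if dialect == "auto":
        try:
            [float(t) for t in tokens]
            dialect = "alon"
        except ValueError:
            dialect = "generic"
        if dialect == "alon" and all(
            t.strip().lstrip("+-") in ("0", "1") for t in tokens
        ):
            # bare 0/1 vectors are group indicators, not signed sample ids
            dialect = "generic"
    if dialect == "alon":
        return (np.array([float(t) for t in tokens]) > 0).astype(int)
    if dialect == "generic":
        labels = []
        for t in tokens:
            tl = t.lower()
            if tl in _CASE_TOKENS:
                labels.append(1)
            elif tl in _CONTROL_TOKENS:
                labels.append(0)
            else:
                raise FormatError(f"unrecognized group label {t!r}")
        return np.array(labels)
    raise FormatError(f"unknown label dialect {dialect!r}")


def read_expression_matrix(matrix_path, labels_path,
                           dialect: str = "auto") -> LabeledExpressionMatrix:
    """Read a tab-separated genes x samples matrix plus its label file."""
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"non-numeric value in column {col!r}, gene {gene!r}"
            )
        if converted.isna().any():
            gene = raw.index[converted.isna().to_numpy().argmax()]
            raise FormatError(f"missing value in column {col!r}, gene {gene!r}")
        values[:, j] = converted.to_numpy()
    labels = read_labels(labels_path, dialect=dialect)
    if labels.size != values.shape[1]:
        raise FormatError(
            f"label file has {labels.size} entries for {values.shape[1]} "
            "sample columns"
        )
    return LabeledExpressionMatrix(values=values, gene_ids=list(raw.index),
                                   labels=labels)


def filter_positive_total_counts(counts: RawCountMatrix) -> RawCountMatrix:
    """Keep genes whose total count across samples is > 0, order preserved."""
    keep = np.asarray(counts.counts).sum(axis=1) > 0
    return RawCountMatrix(
        counts=counts.counts[keep],
        gene_ids=[g for g, k in zip(counts.gene_ids, keep) if k],
        sample_ids=list(counts.sample_ids),
    )


def log_transform(matrix: LabeledExpressionMatrix,
                  pseudocount: float = 0.0) -> LabeledExpressionMatrix:
    """Elementwise log2(x + pseudocount); refuses to transform twice."""
    if matrix.log_transformed:
        raise ValueError("matrix is already log-transformed")
    shifted = matrix.values + pseudocount
    if (shifted <= 0).any():
        i, j = np.argwhere(shifted <= 0)[0]
        raise ValueError(
            f"log2 undefined for gene {matrix.gene_ids[i]!r}, sample column {j} "
            f"(value {matrix.values[i, j]} + pseudocount {pseudocount})"
        )
    return replace(matrix, values=np.log2(shifted), log_transformed=True)


_RESULT_COLUMNS = ["gene_id", "score", "pvalue", "padj", "significant"]


def write_results(table: pd.DataFrame, path) -> None:
    """Serialize a DEG table as TSV with the stable public column order."""
    out = table.loc[:, _RESULT_COLUMNS].copy()
    out["significant"] = out["significant"].astype(bool)
    out.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"results file missing columns {missing}")
    return df[_RESULT_COLUMNS]
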