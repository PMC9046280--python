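"""Expression matrices: median-of-ratios normalization, log and z transforms.

The matrix is a genes x samples table with an explicit unit (counts, fpkm,
tpm, log2, zscore). Normalization follows the median-of-ratios scheme: each
all-positive gene row contributes a per-sample ratio to its geometric mean,
and a sample's size factor is the median of those ratios. Z-transformation is
per gene with the population (n-denominator) standard deviation — the
transform serves visualization and signature scoring, not inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataFormatError, UsageError

__all__ = [
    "ExpressionMatrix",
    "SizeFactors",
    "median_of_ratios",
    "normalize",
    "log_transform",
    "zscore_per_gene",
    "log2_fold_change",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_log2fc_tsv",
    "write_log2fc_tsv",
]

logger = logging.getLogger(__name__)

UNITS = ("counts", "fpkm", "tpm", "log2", "zscore")
_LINEAR_UNITS = ("counts", "fpkm", "tpm")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric table with a stated unit."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise UsageError(f"unknown unit {self.unit!r}; one of {UNITS}")
        if self.values.index.has_duplicates:
            raise DataFormatError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise DataFormatError("duplicate sample ids in expression matrix")
        if self.unit in _LINEAR_UNITS and (self.values.values < 0).any():
            raise DataFormatError(
                f"negative values not allowed for unit {self.unit!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SizeFactors:
    """Per-sample positive scale factors from median-of-ratios."""

    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise DataFormatError("size factors must all be positive")


def median_of_ratios(m: ExpressionMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    Each gene with an all-positive row defines a reference value (geometric
    mean across samples); a sample's factor is the median over such genes of
    value / reference. Genes with any zero are excluded from the reference
    set. Factors are centered to geometric mean 1, which fixes the arbitrary
    overall scale and makes normalization idempotent.
    """
    if m.unit not in _LINEAR_UNITS:
        raise UsageError(f"cannot estimate size factors on unit {m.unit!r}")
    vals = m.values.to_numpy(dtype=float)
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise DataFormatError(
            "no gene with all-positive values; size factors undefined"
        )
    logs = np.log(vals[positive])
    log_ref = logs.mean(axis=1, keepdims=True)  # log geometric mean
    log_factors = np.median(logs - log_ref, axis=0)
    factors = np.exp(log_factors - log_factors.mean())
    return SizeFactors(pd.Series(factors, index=m.values.columns))


def normalize(m: ExpressionMatrix, factors: SizeFactors | None = None) -> ExpressionMatrix:
    """Divide each sample column by its size factor."""
    if factors is None:
        factors = median_of_ratios(m)
    scaled = m.values.div(factors.factors, axis="columns")
    return ExpressionMatrix(scaled, unit=m.unit)


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount), unit becomes log2."""
    if m.unit not in _LINEAR_UNITS:
        raise UsageError(f"matrix already transformed (unit {m.unit!r})")
    shifted = m.values + pseudocount
    if (shifted.values <= 0).any():
        raise UsageError(
            "log transform undefined: value + pseudocount <= 0 encountered"
        )
    return ExpressionMatrix(np.log2(shifted), unit="log2")


def zscore_per_gene(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-transform with population (n-denominator) sd.

    Zero-variance genes map to all-zero rows (with a logged warning) so that
    downstream sums remain defined.
    """
    if m.values.shape[1] < 2:
        raise UsageError("z-transform requires at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning(
            "%d zero-variance gene rows set to all-zero z-scores", flat.sum()
        )
    sd[sd == 0] = 1.0
    z = (vals - mean) / sd
    return ExpressionMatrix(
        pd.DataFrame(z, index=m.values.index, columns=m.values.columns),
        unit="zscore",
    )


def log2_fold_change(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean_B + pc) / (mean_A + pc)) — B relative to A."""
    if not group_a or not group_b:
        raise UsageError("both sample groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise UsageError(f"sample groups overlap: {sorted(overlap)}")
    missing = (set(group_a) | set(group_b)) - set(m.sample_ids)
    if missing:
        raise UsageError(f"samples absent from matrix: {sorted(missing)}")
    if m.unit not in _LINEAR_UNITS:
        raise UsageError(f"fold change needs linear-scale values, not {m.unit!r}")
    mean_a = m.values[group_a].mean(axis=1)
    mean_b = m.values[group_b].mean(axis=1)
    fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    fc.name = "log2fc"
    return fc


# ---------------------------------------------------------------------------
# TSV I/O: first column gene id, header row of sample ids
# ---------------------------------------------------------------------------

def read_matrix_tsv(path, unit: str = "counts") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise DataFormatError(f"expression matrix {path} has no sample columns")
    return ExpressionMatrix(df, unit=unit)


def write_matrix_tsv(path, m: ExpressionMatrix) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


def read_log2fc_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise DataFormatError(
            f"log2FC table {path} must have exactly two columns (gene, log2fc)"
        )
    s = df.iloc[:, 0].astype(float)
    s.name = "log2fc"
    return s


def write_log2fc_tsv(path, fc: pd.Series) -> None:
    fc.rename("log2fc").to_csv(path, sep="\t", index_label="gene_id")
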