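"""Expression filters and transforms applied before modeling.

RNA-seq samples with fewer than ``min_read_counts`` total counts are
removed, and count data are Box-Cox transformed per gene to approximate
normality.  Microarray matrices are taken as already normalized and pass
through untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

#: Offset added to zero-containing count vectors before Box-Cox.
ZERO_OFFSET = 0.5


@dataclass(frozen=True)
class FilterConfig:
    min_read_counts: int = 100_000
    data_type: str = "rnaseq"

    def __post_init__(self) -> None:
        if self.min_read_counts < 0:
            raise ValueError("min_read_counts must be >= 0")
        if self.data_type not in ("microarray", "rnaseq"):
            raise ValueError(f"unknown data_type {self.data_type!r}")


def filter_low_count_samples(matrix: pd.DataFrame,
                             config: FilterConfig = FilterConfig()) -> pd.DataFrame:
    """Drop samples whose total count is below ``min_read_counts``.

    Samples exactly at the threshold are kept (removal applies to strictly
    fewer counts).  For microarray input the filter is a no-op with a
    warning.  Idempotent.
    """
    if config.data_type == "microarray":
        warnings.warn("count filter skipped for microarray data", stacklevel=2)
        return matrix
    if (matrix.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")
    totals = matrix.sum(axis=1)
    return matrix.loc[totals >= config.min_read_counts]


def boxcox_transform(values: np.ndarray | pd.Series) -> tuple[np.ndarray, float]:
    """Box-Cox transform one nonnegative vector; returns (transformed, lambda).

    lambda is the maximum-likelihood estimate; a constant vector is returned
    unchanged with lambda = NaN (there is no normality to improve).  Vectors
    containing zeros are offset by ``ZERO_OFFSET`` first.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    if np.any(x < 0):
        raise ValueError("Box-Cox requires nonnegative input")
    if np.all(x == x[0]):
        return x.copy(), float("nan")
    if np.any(x == 0):
        x = x + ZERO_OFFSET
    transformed, lam = stats.boxcox(x)
    return np.asarray(transformed), float(lam)


def boxcox_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Apply :func:`boxcox_transform` per gene (column-wise).

    Returns the transformed matrix and a per-gene lambda table (NaN marks
    constant genes left untouched).
    """
    out = {}
    lams = {}
    for gene in matrix.columns:
        out[gene], lams[gene] = boxcox_transform(matrix[gene].to_numpy())
    transformed = pd.DataFrame(out, index=matrix.index)
    transformed.index.name = matrix.index.name
    return transformed, pd.Series(lams, name="lambda")


def preprocess(matrix: pd.DataFrame, config: FilterConfig) -> tuple[pd.DataFrame, pd.Series | None]:
    """Full preprocessing for one matrix: filter, then transform counts."""
    if config.data_type == "microarray":
        return matrix, None
    filtered = filter_low_count_samples(matrix, config)
    return boxcox_matrix(filtered)


def run(expr_path: str | Path, out_path: str | Path,
        config: FilterConfig = FilterConfig()) -> Path:
    """CLI entry: read expression TSV, write filtered/transformed TSV.

    For RNA-seq a sidecar ``<out>.lambda.tsv`` holds per-gene lambdas.
    """
    from .synthgen import read_expression

    matrix = read_expression(expr_path)
    transformed, lams = preprocess(matrix, config)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    transformed.to_csv(out_path, sep="\t", float_format="%.6f")
    if lams is not None:
        lams.rename_axis("gene_id").to_csv(
            out_path.with_suffix(out_path.suffix + ".lambda.tsv"), sep="\t")
    return out_path
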