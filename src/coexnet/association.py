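"""Spearman rank-correlation association matrix over filtered genes.

Spearman is used because RNA-seq count data are not normally distributed;
rank correlation is also invariant to any strictly monotone per-gene
transform, so correlating raw cpm or log cpm gives the same matrix.
Ties receive mid-ranks (average rank), and the correlation is the Pearson
correlation of the rank-transformed expression vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import NormalizedMatrix

__all__ = ["AssociationMatrix", "spearman_matrix"]


@dataclass(frozen=True)
class AssociationMatrix:
    """Symmetric gene × gene Spearman correlation matrix with unit diagonal."""

    gene_ids: tuple[str, ...]
    rho: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.rho.shape != (n, n):
            raise ValueError("rho shape mismatch")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12):
            raise ValueError("rho must be symmetric")
        if np.any(np.abs(self.rho) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.gene_ids, columns=self.gene_ids)


def spearman_matrix(
    nm: NormalizedMatrix | pd.DataFrame,
    log_transform: bool = False,
) -> AssociationMatrix:
    """Spearman correlation of every gene pair across samples.

    Genes with constant expression across all samples have undefined rank
    correlation; they are dropped with a warning before computing the matrix.
    ``log_transform`` applies log2(cpm + 1) first — a no-op for the result on
    strictly positive data (ranks are transform-invariant) kept for parity
    with pipelines that correlate on the log scale.
    """
    values = nm.cpm if isinstance(nm, NormalizedMatrix) else nm
    X = values.to_numpy(dtype=float)
    gene_ids = [str(g) for g in values.index]
    if X.shape[1] < 3:
        raise ValueError("Spearman association needs at least 3 samples")
    if log_transform:
        X = np.log2(X + 1.0)
    variable = X.std(axis=1) > 0
    if not variable.all():
        dropped = [g for g, v in zip(gene_ids, variable) if not v]
        warnings.warn(
            f"dropping {len(dropped)} constant-expression gene(s) before "
            f"correlation: {', '.join(dropped[:5])}"
            + ("..." if len(dropped) > 5 else ""),
            stacklevel=2,
        )
        X = X[variable]
        gene_ids = [g for g, v in zip(gene_ids, variable) if v]
    if len(gene_ids) < 2:
        raise ValueError("fewer than 2 variable genes; association undefined")
    ranks = rankdata(X, axis=1)  # mid-ranks for ties
    rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2.0
    return AssociationMatrix(tuple(gene_ids), rho)
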