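"""Count-matrix containers, I/O, counts-per-million normalisation and expression filtering.

The pipeline starts from a genes × samples matrix of raw RNA-seq read counts
with a group label (e.g. ``"shoot"`` / ``"inflorescence"``) per sample.  Counts
are library-size normalised to counts per million (cpm)::

    cpm[g, s] = counts[g, s] / library_size[s] * 1e6

and lowly expressed genes are removed by requiring cpm strictly above a floor
(default 5) in *every* sample.  Library size is the plain column sum of the
input matrix; no compositional scaling factors (TMM etc.) are applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "CountMatrixError",
    "read_counts",
    "read_group_map",
    "write_counts",
    "write_cpm",
    "write_group_map",
    "cpm_normalize",
    "filter_low_expression",
]


class CountMatrixError(ValueError):
    """Raised when a count matrix or its annotation violates the contract."""


def _check_ids(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dups = sorted(set(index[index.duplicated()].astype(str)))
        raise CountMatrixError(f"duplicate {what} ID(s): {', '.join(dups)}")


@dataclass(frozen=True)
class CountMatrix:
    """Raw integer counts, genes × samples, with a group label per sample.

    Parameters
    ----------
    counts
        DataFrame with gene IDs as index and sample IDs as columns.  Entries
        must be non-negative integers; every column sum must be positive
        (a zero-library sample is an error, not a warning).
    groups
        Mapping ``sample_id -> group label``; every sample must be present.
    """

    counts: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        _check_ids(self.counts.index, "gene")
        _check_ids(self.counts.columns, "sample")
        values = self.counts.to_numpy()
        if values.size == 0:
            raise CountMatrixError("empty count matrix")
        if not np.issubdtype(values.dtype, np.number):
            raise CountMatrixError("count matrix contains non-numeric entries")
        if np.any(~np.isfinite(values)):
            raise CountMatrixError("count matrix contains non-finite entries")
        if np.any(values < 0):
            gene, sample = self._first_offender(values < 0)
            raise CountMatrixError(
                f"negative count at gene {gene!r}, sample {sample!r}"
            )
        if np.any(values != np.round(values)):
            gene, sample = self._first_offender(values != np.round(values))
            raise CountMatrixError(
                f"non-integer count at gene {gene!r}, sample {sample!r}"
            )
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise CountMatrixError(
                f"sample(s) without group label: {', '.join(map(str, missing))}"
            )
        colsums = values.sum(axis=0)
        if np.any(colsums <= 0):
            bad = [str(s) for s, c in zip(self.counts.columns, colsums) if c <= 0]
            raise CountMatrixError(
                f"zero-library sample(s): {', '.join(bad)}"
            )

    def _first_offender(self, mask: np.ndarray) -> tuple[str, str]:
        i, j = np.argwhere(mask)[0]
        return str(self.counts.index[i]), str(self.counts.columns[j])

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.counts.columns]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def drop_samples(self, samples: Iterable[str]) -> "CountMatrix":
        """Return a new matrix without the given samples (groups pruned too)."""
        drop = set(samples)
        keep = [s for s in self.counts.columns if s not in drop]
        if not keep:
            raise CountMatrixError("dropping all samples leaves an empty matrix")
        groups = {s: self.groups[s] for s in keep}
        return CountMatrix(self.counts[keep], groups)


@dataclass(frozen=True)
class NormalizedMatrix:
    """Counts-per-million values, genes × samples, with sample group labels."""

    cpm: pd.DataFrame
    groups: Mapping[str, str]

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.cpm.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.cpm.columns]

    def subset_genes(self, genes: Sequence[str]) -> "NormalizedMatrix":
        return NormalizedMatrix(self.cpm.loc[list(genes)], self.groups)

    def subset_samples(self, samples: Sequence[str]) -> "NormalizedMatrix":
        groups = {s: self.groups[s] for s in samples}
        return NormalizedMatrix(self.cpm[list(samples)], groups)


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) TSV/CSV into a dict."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                     comment="#")
    if df.shape[1] < 2:
        raise CountMatrixError(f"group map {path}: expected two columns")
    # tolerate a header line such as "sample\tgroup"
    first = df.iloc[0]
    if str(first[0]).lower() in {"sample", "sample_id"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_counts(path: str | Path, groups: Mapping[str, str] | str | Path) -> CountMatrix:
    """Read a delimited genes × samples count file.

    First column holds gene IDs, header row holds sample IDs; the delimiter
    (tab or comma) is sniffed.  ``groups`` may be a mapping or a path to a
    two-column sample→group file.  Duplicate IDs, negative, non-integer or
    non-numeric entries and zero-library samples are rejected with an error
    naming the offender.
    """
    if not isinstance(groups, Mapping):
        groups = read_group_map(groups)
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            gene = df.index[numeric.isna().to_numpy()][0]
            raise CountMatrixError(
                f"{path}: non-numeric entry at gene {gene!r}, sample {col!r}"
            )
        df[col] = numeric
    return CountMatrix(df, dict(groups))


def write_counts(cm: CountMatrix, path: str | Path, sep: str = "\t") -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.astype(np.int64).to_csv(path, sep=sep)


def write_group_map(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def write_cpm(nm: NormalizedMatrix, path: str | Path, sep: str = "\t") -> None:
    out = nm.cpm.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=sep, float_format="%.6g")


def cpm_normalize(cm: CountMatrix) -> NormalizedMatrix:
    """Normalise raw counts to counts per million.

    Each column is divided by its library size (column sum) and scaled by
    1e6, so every column of the result sums to exactly one million before
    any gene filtering.
    """
    counts = cm.counts.astype(float)
    cpm = counts.div(counts.sum(axis=0), axis=1) * 1e6
    return NormalizedMatrix(cpm, dict(cm.groups))


def filter_low_expression(
    nm: NormalizedMatrix,
    min_cpm: float = 5.0,
    strict: bool = True,
) -> tuple[list[str], NormalizedMatrix]:
    """Keep genes expressed above ``min_cpm`` in every sample.

    A gene is retained iff its cpm exceeds ``min_cpm`` in *all* samples;
    the comparison is strict (``>``) by default, so a gene sitting exactly
    on the floor is removed.  Gene order is preserved.

    Returns the retained gene IDs and the reduced matrix.
    """
    if min_cpm < 0:
        raise ValueError("min_cpm must be >= 0")
    values = nm.cpm.to_numpy()
    if strict:
        keep = (values > min_cpm).all(axis=1)
    else:
        keep = (values >= min_cpm).all(axis=1)
    retained = [g for g, k in zip(nm.gene_ids, keep) if k]
    if not retained:
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return retained, NormalizedMatrix(nm.cpm.loc[keep], dict(nm.groups))
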