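"""Expression containers and FPKM normalisation.

The screening pipeline works in FPKM units (fragments per kilobase of
exon per million mapped reads).  :class:`CountMatrix` holds raw gene-level
read counts together with the gene lengths and per-sample library sizes
needed to convert them; :class:`ExpressionMatrix` holds the resulting
FPKM values.  Both are thin, validated wrappers around pandas objects so
they interoperate with the rest of the scientific Python stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "compute_fpkm",
    "group_summary",
]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class CountMatrix:
    """Gene-level read counts (genes x samples) with gene lengths.

    Parameters
    ----------
    counts
        Non-negative integer counts, indexed by gene id with sample ids
        as columns.
    gene_lengths
        Effective gene (exon) length in base pairs, one entry per gene.
    library_sizes
        Mapped reads per sample.  Defaults to the column sums of
        ``counts``, which makes the container self-contained; pass the
        externally determined totals to override.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    library_sizes: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = pd.DataFrame(self.counts)
        self.counts.index.name = "gene_id"
        _check_unique(self.counts.index, "gene ids")
        _check_unique(self.counts.columns, "sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_lengths = pd.Series(self.gene_lengths).reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()][:5].tolist()
            raise ValueError(f"gene lengths missing for: {missing}")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = pd.Series(self.library_sizes).reindex(
                self.counts.columns
            )
            if self.library_sizes.isna().any():
                raise ValueError("library size missing for some samples")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class ExpressionMatrix:
    """FPKM expression values (genes x samples)."""

    fpkm: pd.DataFrame

    def __post_init__(self) -> None:
        self.fpkm = pd.DataFrame(self.fpkm).astype(float)
        self.fpkm.index.name = "gene_id"
        _check_unique(self.fpkm.index, "gene ids")
        _check_unique(self.fpkm.columns, "sample ids")
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fpkm.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.fpkm.shape


def compute_fpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Convert read counts to FPKM.

    FPKM[g, s] = counts[g, s] * 1e9 / (library_size[s] * length[g]);
    the 1e9 factor is the product of the per-kilobase (1e3) and the
    per-million-reads (1e6) scalings.  No pseudocount is added here --
    zero counts map to zero FPKM; pseudocounts appear only where
    logarithms are taken (see :mod:`prefexpr.de`).
    """
    c = counts.counts.to_numpy(dtype=float)
    lengths = counts.gene_lengths.to_numpy(dtype=float)[:, None]
    libs = counts.library_sizes.to_numpy(dtype=float)[None, :]
    fpkm = c * 1e9 / (libs * lengths)
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.counts.index, columns=counts.counts.columns)
    )


def group_summary(expr: ExpressionMatrix, design: dict[str, str]) -> pd.DataFrame:
    """Per-gene, per-group mean/min/max of FPKM.

    ``design`` maps every sample id to a group label.  Singleton groups
    yield mean == min == max.  Raises on samples missing from the design
    or groups with no samples in the matrix.
    """
    unmapped = [s for s in expr.sample_ids if s not in design]
    if unmapped:
        raise ValueError(f"samples not mapped to a group: {unmapped[:5]}")
    absent = [s for s in design if s not in expr.fpkm.columns]
    if absent:
        raise ValueError(f"design references absent samples: {absent[:5]}")
    groups = pd.Series({s: design[s] for s in expr.sample_ids})
    agg = expr.fpkm.T.groupby(groups).agg(["mean", "min", "max"])
    # columns: (gene, stat) after transpose-groupby; reshape to long table
    agg = agg.T.unstack(level=1)
    agg.columns = [f"{grp}_{stat}" for grp, stat in agg.columns]
    agg.index.name = "gene_id"
    return agg
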