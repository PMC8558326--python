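"""Readers and writers for the pipeline's plain-text formats.

All tabular files are tab-separated UTF-8 with a header row and no
quoting; gene ids are opaque strings.  Term sets use the standard GMT
layout (term, description, then member gene ids, tab-separated); gene
lists are one id per line; alignments are FASTA (via Biopython).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import AlignIO

from .expression import CountMatrix, ExpressionMatrix
from .qpcr import CtTable

__all__ = [
    "read_counts",
    "write_counts",
    "read_lengths",
    "write_lengths",
    "read_library_sizes",
    "read_design",
    "write_design",
    "read_expression",
    "write_expression",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_de_table",
    "write_de_table",
    "read_ct_table",
    "read_distance_matrix",
    "read_alignment",
]


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def _write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_counts(
    counts_path: str | Path,
    lengths_path: str | Path,
    libsizes_path: str | Path | None = None,
) -> CountMatrix:
    counts = _read_tsv(counts_path, index_col="gene_id")
    lengths = read_lengths(lengths_path)
    libs = read_library_sizes(libsizes_path) if libsizes_path else None
    return CountMatrix(counts=counts, gene_lengths=lengths, library_sizes=libs)


def write_counts(cm: CountMatrix, counts_path: str | Path, lengths_path: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    _write_tsv(out, counts_path)
    write_lengths(cm.gene_lengths, lengths_path)


def read_lengths(path: str | Path) -> pd.Series:
    df = _read_tsv(path)
    return df.set_index(df.columns[0])[df.columns[1]]


def write_lengths(lengths: pd.Series, path: str | Path) -> None:
    df = lengths.rename("length").to_frame()
    df.index.name = "gene_id"
    _write_tsv(df, path)


def read_library_sizes(path: str | Path) -> pd.Series:
    df = _read_tsv(path)
    return df.set_index(df.columns[0])[df.columns[1]].astype(float)


def read_design(path: str | Path) -> dict[str, str]:
    """Sample→group map from a two-column (sample, group) TSV."""
    df = _read_tsv(path)
    return dict(zip(df[df.columns[0]].astype(str), df[df.columns[1]].astype(str)))


def write_design(design: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(design.keys()), "group": list(design.values())}
    ).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> ExpressionMatrix:
    return ExpressionMatrix(_read_tsv(path, index_col="gene_id"))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.fpkm.copy()
    out.index.name = "gene_id"
    _write_tsv(out, path)


def read_gene_list(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    terms: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = {g for g in parts[2:] if g}
    return terms


def write_gmt(
    terms: Mapping[str, Iterable[str]], path: str | Path, description: str = "na"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, genes in terms.items():
            members = "\t".join(sorted(genes))
            fh.write(f"{term}\t{description}\t{members}\n")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, index_col="gene_id")


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(table, path)


def read_ct_table(
    path: str | Path,
    reference_gene: str | None = None,
    calibrator_sample: str | None = None,
) -> CtTable:
    kw = {}
    if reference_gene is not None:
        kw["reference_gene"] = reference_gene
    return CtTable(_read_tsv(path), calibrator_sample=calibrator_sample, **kw)


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, index_col=0)


def read_alignment(path: str | Path) -> dict[str, str]:
    aln = AlignIO.read(str(path), "fasta")
    return {rec.id: str(rec.seq) for rec in aln}
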