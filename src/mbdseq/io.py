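"""Readers and writers for the plain-text genomics formats the pipeline uses.

BED (3/6 column and narrowPeak), chrom.sizes, bedGraph, and simple TSV
tables.  GTF/GFF3 handling lives in :mod:`mbdseq.annotation` next to the gene
models it produces.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomeLayout, GenomicInterval


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Two-column (name, length) TSV -> :class:`GenomeLayout`."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'name<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return GenomeLayout(sizes)


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chrom_lengths.items():
            fh.write(f"{name}\t{length}\n")


_BED_STRANDS = {"+", "-", ".", ""}


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED6/narrowPeak; strand taken from column 6 when present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            strand = parts[5] if len(parts) >= 6 and parts[5] in _BED_STRANDS else "."
            out.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand or ".")
            )
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """BED6 when names/scores/strand carry information, else BED3."""
    six = names is not None or scores is not None or any(
        iv.strand != "." for iv in intervals
    )
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if six:
                name = names[i] if names is not None else "."
                score = scores[i] if scores is not None else 0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_bedgraph(
    intervals: Sequence[GenomicInterval],
    values: Iterable[float],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        for iv, v in zip(intervals, values):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.6g}\n")


def read_bedgraph(path: str | Path) -> tuple[list[GenomicInterval], np.ndarray]:
    intervals: list[GenomicInterval] = []
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            intervals.append(GenomicInterval(chrom, int(start), int(end)))
            values.append(float(value))
    return intervals, np.asarray(values, dtype=float)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """(gene_id, count) table; header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0] == "gene_id":
        df = df.iloc[1:]
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "count"]
    df["count"] = df["count"].astype(int)
    return df.reset_index(drop=True)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def atomic_write_text(text: str, path: str | Path) -> None:
    tmp = str(path) + ".tmp"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)
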