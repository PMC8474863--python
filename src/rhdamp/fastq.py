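"""Thin FASTQ I/O helpers (plain or gzip, Phred+33)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .preprocess import MergedRead, ReadPair

__all__ = ["open_maybe_gzip", "iter_read_pairs", "write_read_pairs", "write_merged_reads"]


def open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_read_pairs(fastq1: str | Path, fastq2: str | Path) -> Iterator[ReadPair]:
    """Stream synchronized read pairs from two FASTQ files.

    Read ids are taken from read 1 (first whitespace-delimited token);
    the files must be in the same order and of equal length.
    """
    with open_maybe_gzip(fastq1) as fh1, open_maybe_gzip(fastq2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2):
            yield ReadPair(
                id=t1.split()[0],
                read1_seq=s1.upper(),
                read1_quals=q1,
                read2_seq=s2.upper(),
                read2_quals=q2,
            )
        # detect ragged files
        for leftover in (it1, it2):
            try:
                next(leftover)
            except StopIteration:
                continue
            raise ValueError("FASTQ files have unequal numbers of reads")


def write_read_pairs(
    pairs: Iterable[ReadPair], fastq1: str | Path, fastq2: str | Path
) -> int:
    n = 0
    with open_maybe_gzip(fastq1, "wt") as fh1, open_maybe_gzip(fastq2, "wt") as fh2:
        for p in pairs:
            fh1.write(f"@{p.id}\n{p.read1_seq}\n+\n{p.read1_quals}\n")
            fh2.write(f"@{p.id}\n{p.read2_seq}\n+\n{p.read2_quals}\n")
            n += 1
    return n


def write_merged_reads(reads: Iterable[MergedRead], path: str | Path) -> int:
    n = 0
    with open_maybe_gzip(path, "wt") as fh:
        for r in reads:
            umi = f" UMI:{r.umi}" if r.umi else ""
            fh.write(f"@{r.id}{umi}\n{r.sequence}\n+\n{r.quals}\n")
            n += 1
    return n
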