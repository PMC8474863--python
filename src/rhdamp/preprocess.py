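"""Read preprocessing: adaptor trimming, pair merging, filters, UMI handling.

Amplicons (105/148 bp) are shorter than the 151-bp reads, so read 1 and
read 2 overlap across the whole insert and a merged consensus can demand
a perfect overlap (zero mismatch density): any pair whose two reads
disagree anywhere in the overlap is rejected rather than reconciled.
Merged reads are then size-filtered to the exact amplicon lengths and
mean-quality filtered. In UMI mode the 12-base molecular tag at the
start of read 1 is split off before size filtering, and PCR duplicates
are collapsed per UMI by plurality consensus.

All operations are deterministic and treat rejections as data (ledger
entries), not exceptions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ReadPair",
    "MergedRead",
    "Rejection",
    "FilterParams",
    "DedupStats",
    "DEFAULT_ADAPTOR_R1",
    "DEFAULT_ADAPTOR_R2",
    "reverse_complement",
    "trim_adaptors",
    "merge_pair",
    "size_filter",
    "quality_filter",
    "extract_umi",
    "dedup_umi",
]

#: Illumina TruSeq read-through adaptor as seen at the 3' end of read 1 / read 2.
DEFAULT_ADAPTOR_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
DEFAULT_ADAPTOR_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read (Phred+33 qualities)."""

    id: str
    read1_seq: str
    read1_quals: str
    read2_seq: str
    read2_quals: str

    def __post_init__(self) -> None:
        if len(self.read1_seq) != len(self.read1_quals):
            raise ValueError(f"{self.id}: read 1 sequence/quality length mismatch")
        if len(self.read2_seq) != len(self.read2_quals):
            raise ValueError(f"{self.id}: read 2 sequence/quality length mismatch")


@dataclass(frozen=True)
class MergedRead:
    """A merged, adaptor-trimmed read, optionally with its UMI split off."""

    id: str
    sequence: str
    quals: str
    umi: str | None = None
    source: str = "merged"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quals):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")
        if self.umi is not None:
            if len(self.umi) != 12 or set(self.umi) - set("ACGTN"):
                raise ValueError(f"{self.id}: UMI must be 12 bases of A/C/G/T/N")


@dataclass(frozen=True)
class Rejection:
    """A read removed at a pipeline stage, with the stage and reason."""

    id: str
    stage: str
    reason: str


@dataclass(frozen=True)
class FilterParams:
    """Preprocessing thresholds.

    ``base_quality_cutoff`` is the minimum mean Phred over the merged
    read (boundary inclusive); ``max_mismatch_density`` is the tolerated
    mismatch fraction in the pair overlap (0 = perfect overlap only);
    ``expected_sizes`` are the amplicon lengths that pass the size
    filter.
    """

    base_quality_cutoff: float = 25.0
    max_mismatch_density: float = 0.0
    min_overlap: int = 10
    expected_sizes: tuple[int, ...] = (105, 148)
    umi_length: int = 12
    umi_mode: bool = False

    def __post_init__(self) -> None:
        if self.base_quality_cutoff < 0:
            raise ValueError("base_quality_cutoff must be non-negative")
        if not 0 <= self.max_mismatch_density <= 1:
            raise ValueError("max_mismatch_density must lie in [0, 1]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be positive")
        if self.umi_length < 1:
            raise ValueError("umi_length must be positive")


def _mismatches_within(a: str, b: str, allowed: int) -> int:
    """Mismatch count of equal-length strings, early-exiting past ``allowed``."""
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > allowed:
                return m
    return m


@lru_cache(maxsize=1 << 17)
def _adaptor_cut(seq: str, adaptor: str, min_overlap: int) -> int:
    """Earliest 0-based position from which ``seq`` reads into the adaptor.

    A match anchors at position i and must cover min(len(adaptor),
    len(seq)-i) bases with at most 1 mismatch per 10 matched bases.
    Returns len(seq) when no adaptor is found.
    """
    n, la = len(seq), len(adaptor)
    # Fast path: exact full-adaptor occurrence.
    exact = seq.find(adaptor)
    scan_end = exact if exact != -1 else n - min_overlap + 1
    for i in range(0, scan_end):
        overlap = min(la, n - i)
        if overlap < min_overlap:
            break
        allowed = overlap // 10
        if allowed == 0:
            if seq.startswith(adaptor[:overlap], i):
                return i
        elif _mismatches_within(seq[i : i + overlap], adaptor[:overlap], allowed) <= allowed:
            return i
    if exact != -1:
        return exact
    return n


def trim_adaptors(
    pair: ReadPair,
    adaptor_r1: str = DEFAULT_ADAPTOR_R1,
    adaptor_r2: str = DEFAULT_ADAPTOR_R2,
    min_overlap: int = 3,
) -> ReadPair:
    """Remove 3' read-through adaptor sequence from both reads.

    Matching is exact-prefix with up to 1 mismatch per 10 matched bases;
    qualities are trimmed in lockstep. Reads without an adaptor match are
    returned unchanged; a read that is all adaptor becomes empty (and is
    rejected later by the size filter).
    """
    c1 = _adaptor_cut(pair.read1_seq, adaptor_r1, min_overlap)
    c2 = _adaptor_cut(pair.read2_seq, adaptor_r2, min_overlap)
    if c1 == len(pair.read1_seq) and c2 == len(pair.read2_seq):
        return pair
    return ReadPair(
        id=pair.id,
        read1_seq=pair.read1_seq[:c1],
        read1_quals=pair.read1_quals[:c1],
        read2_seq=pair.read2_seq[:c2],
        read2_quals=pair.read2_quals[:c2],
    )


@lru_cache(maxsize=1 << 17)
def _best_overlap(seq1: str, rc2: str, min_overlap: int, density: float) -> int:
    """Largest overlap length L such that seq1's suffix of L matches rc2's
    prefix of L with at most floor(density*L) mismatches; 0 if none."""
    l1 = len(seq1)
    for L in range(min(l1, len(rc2)), min_overlap - 1, -1):
        allowed = int(density * L)
        if allowed == 0:
            if seq1[l1 - L :] == rc2[:L]:
                return L
        elif _mismatches_within(seq1[l1 - L :], rc2[:L], allowed) <= allowed:
            return L
    return 0


def merge_pair(pair: ReadPair, params: FilterParams) -> MergedRead | Rejection:
    """Merge read 1 with the reverse complement of read 2.

    Scans for the maximal overlap of at least ``min_overlap`` bases
    whose mismatch fraction does not exceed ``max_mismatch_density``
    (zero density = perfect overlap). In the overlap, the merged quality
    is the per-position maximum of the two reads. Failure to find an
    overlap yields a :class:`Rejection`, not an exception.
    """
    if not pair.read1_seq or not pair.read2_seq:
        return Rejection(pair.id, "merge", "empty_read")
    rc2 = reverse_complement(pair.read2_seq)
    L = _best_overlap(pair.read1_seq, rc2, params.min_overlap, params.max_mismatch_density)
    if L == 0:
        return Rejection(pair.id, "merge", "no_acceptable_overlap")
    l1 = len(pair.read1_seq)
    rq2 = pair.read2_quals[::-1]
    q1 = np.frombuffer(pair.read1_quals.encode(), dtype=np.uint8)
    q2 = np.frombuffer(rq2.encode(), dtype=np.uint8)
    over_q = np.maximum(q1[l1 - L :], q2[:L])
    merged_quals = pair.read1_quals[: l1 - L] + over_q.tobytes().decode() + rq2[L:]
    merged_seq = pair.read1_seq + rc2[L:]
    return MergedRead(id=pair.id, sequence=merged_seq, quals=merged_quals)


def size_filter(
    read: MergedRead, expected_sizes: Sequence[int] = (105, 148)
) -> MergedRead | Rejection:
    """Keep only merged reads of an exact expected amplicon length."""
    if len(read.sequence) in expected_sizes:
        return read
    return Rejection(
        read.id, "size_filter", f"unexpected_size_{len(read.sequence)}"
    )


def quality_filter(read: MergedRead, params: FilterParams) -> MergedRead | Rejection:
    """Keep reads whose mean Phred quality meets the cutoff (inclusive)."""
    if not read.quals:
        return Rejection(read.id, "quality_filter", "empty_read")
    mean_q = float(
        np.frombuffer(read.quals.encode(), dtype=np.uint8).mean()
    ) - 33.0
    if mean_q >= params.base_quality_cutoff:
        return read
    return Rejection(read.id, "quality_filter", f"mean_quality_{mean_q:.2f}")


def extract_umi(read: MergedRead, params: FilterParams) -> MergedRead | Rejection:
    """Split the leading 12-base UMI off a merged read (UMI mode only)."""
    if not params.umi_mode:
        return read
    k = params.umi_length
    if len(read.sequence) < k:
        return Rejection(read.id, "extract_umi", "read_shorter_than_umi")
    return MergedRead(
        id=read.id,
        sequence=read.sequence[k:],
        quals=read.quals[k:],
        umi=read.sequence[:k],
    )


@dataclass(frozen=True)
class DedupStats:
    """Accounting of UMI-based PCR-duplicate removal."""

    input_reads: int
    unique_molecules: int
    unique_umis: int
    duplicates_removed: int
    reads_per_molecule: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "input_reads": self.input_reads,
            "unique_molecules": self.unique_molecules,
            "unique_umis": self.unique_umis,
            "duplicates_removed": self.duplicates_removed,
            "reads_per_molecule": {str(k): v for k, v in sorted(self.reads_per_molecule.items())},
        }


def dedup_umi(reads: Iterable[MergedRead]) -> tuple[list[MergedRead], DedupStats]:
    """Collapse PCR duplicates sharing a UMI to one read per molecule.

    Reads are grouped by exact (UMI, amplicon-length-class); within a
    group the plurality sequence wins, ties broken by lexicographically
    smallest sequence. The emitted read is the first input read carrying
    the winning sequence, preserving input order of first appearance.
    """
    groups: dict[tuple[str, int], Counter] = {}
    first_read: dict[tuple[str, int, str], MergedRead] = {}
    order: list[tuple[str, int]] = []
    n_in = 0
    for read in reads:
        if read.umi is None:
            raise ValueError(f"{read.id}: dedup_umi requires reads with a UMI")
        n_in += 1
        key = (read.umi, len(read.sequence))
        if key not in groups:
            groups[key] = Counter()
            order.append(key)
        groups[key][read.sequence] += 1
        first_read.setdefault((*key, read.sequence), read)

    out: list[MergedRead] = []
    hist: Counter = Counter()
    for key in order:
        counts = groups[key]
        hist[sum(counts.values())] += 1
        best = min(counts, key=lambda s: (-counts[s], s))
        out.append(first_read[(*key, best)])
    stats = DedupStats(
        input_reads=n_in,
        unique_molecules=len(out),
        unique_umis=len({k[0] for k in groups}),
        duplicates_removed=n_in - len(out),
        reads_per_molecule=dict(hist),
    )
    return out, stats
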