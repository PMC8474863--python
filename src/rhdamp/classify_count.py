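"""Read-to-amplicon assignment and per-position base counting.

After size filtering every read is a full-length, ungapped amplicon, so
alignment reduces to Hamming distance against the two co-amplified
references of the read's length class. A read is assigned only when one
reference is strictly closest (uniqueness margin >= 1) and within a
mismatch budget; ties are "ambiguous", distant reads "unassigned". The
c.1227 allele class (RHD wild-type vs c.1227A) is not a separate
reference: it is resolved from the base observed at the variant offset
when diagnostic counts are extracted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .reference_model import AmpliconRef, infer_roles

__all__ = [
    "Assignment",
    "BaseCountMatrix",
    "DiagnosticCounts",
    "BASE_COLUMNS",
    "classify_read",
    "count_bases",
    "extract_diagnostics",
    "write_wig",
    "read_wig",
]

#: Column order of the base-count matrix; non-ACGT symbols fall into "other".
BASE_COLUMNS = ("A", "C", "G", "T", "other")

_BASE_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_LUT[ord(_b)] = _i


@lru_cache(maxsize=4096)
def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class Assignment:
    """Outcome of classifying one read against its length class."""

    read_id: str
    region: str  # reference name, or "ambiguous" / "unassigned"
    mismatches: int
    margin: int

    @property
    def assigned(self) -> bool:
        return self.region not in ("ambiguous", "unassigned")


def classify_read(
    read_seq_or_read, refs: Sequence[AmpliconRef], max_mismatch: int = 3
) -> Assignment:
    """Assign a merged read to the unique closest reference of its length.

    Accepts a :class:`~rhdamp.preprocess.MergedRead` or a plain sequence
    string (id then defaults to ""). Raises if no reference matches the
    read length — the size filter guarantees that never happens in the
    pipeline.
    """
    if isinstance(read_seq_or_read, str):
        read_id, seq = "", read_seq_or_read
    else:
        read_id, seq = read_seq_or_read.id, read_seq_or_read.sequence
    cands = [r for r in refs if r.length == len(seq)]
    if not cands:
        raise ValueError(
            f"{read_id}: no reference with length {len(seq)} (size filter violated?)"
        )
    arr = None
    dists: list[tuple[int, str]] = []
    for ref in cands:
        if seq == ref.sequence:
            dists.append((0, ref.name))
            continue
        if arr is None:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        dists.append(
            (int(np.count_nonzero(arr != _seq_array(ref.sequence))), ref.name)
        )
    dists.sort()
    best, best_name = dists[0]
    margin = (dists[1][0] - best) if len(dists) > 1 else len(seq)
    if best > max_mismatch:
        return Assignment(read_id, "unassigned", best, margin)
    if margin == 0:
        return Assignment(read_id, "ambiguous", best, margin)
    return Assignment(read_id, best_name, best, margin)


class BaseCountMatrix:
    """Per-position read counts over {A, C, G, T, other} for one region."""

    def __init__(self, region: str, length: int, counts: np.ndarray | None = None):
        self.region = region
        self.length = length
        if counts is None:
            counts = np.zeros((length, 5), dtype=np.int64)
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (length, 5):
            raise ValueError(f"counts must have shape ({length}, 5)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts

    def add_sequence(self, seq: str, n: int = 1) -> None:
        if len(seq) != self.length:
            raise ValueError(
                f"sequence length {len(seq)} != matrix length {self.length}"
            )
        cols = _BASE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
        np.add.at(self.counts, (np.arange(self.length), cols), n)

    def count_at(self, offset: int, base: str) -> int:
        """Count of ``base`` at a 1-based amplicon offset."""
        col = 4 if base not in "ACGT" else "ACGT".index(base)
        return int(self.counts[offset - 1, col])

    def total_at(self, offset: int) -> int:
        return int(self.counts[offset - 1].sum())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BaseCountMatrix)
            and self.region == other.region
            and self.length == other.length
            and bool(np.array_equal(self.counts, other.counts))
        )


@dataclass(frozen=True)
class DiagnosticCounts:
    """Read counts of the five diagnostic classes."""

    upstream_box: int
    downstream_box: int
    RHD_wt: int
    RHD_var: int
    RHCE: int

    def to_dict(self) -> dict[str, int]:
        return {
            "upstream_box": self.upstream_box,
            "downstream_box": self.downstream_box,
            "RHD_wt": self.RHD_wt,
            "RHD_var": self.RHD_var,
            "RHCE": self.RHCE,
        }


def count_bases(
    assigned: Iterable[tuple[Assignment, "object"]],
    refs: Sequence[AmpliconRef],
) -> dict[str, BaseCountMatrix]:
    """Build per-region base-count matrices from classified reads.

    ``assigned`` yields (Assignment, read) pairs where the read exposes
    ``sequence``; ambiguous and unassigned reads are skipped. Matrices
    exist (all-zero if empty) for every reference.
    """
    matrices = {r.name: BaseCountMatrix(r.name, r.length) for r in refs}
    bulk: Counter[tuple[str, str]] = Counter()
    for assignment, read in assigned:
        if not assignment.assigned:
            continue
        seq = read if isinstance(read, str) else read.sequence
        bulk[(assignment.region, seq)] += 1
    for (region, seq), n in bulk.items():
        matrices[region].add_sequence(seq, n)
    return matrices


def extract_diagnostics(
    matrices: Mapping[str, BaseCountMatrix], refs: Sequence[AmpliconRef]
) -> DiagnosticCounts:
    """Pull the five diagnostic read counts out of the count matrices.

    Upstream/downstream counts are the counts of each box's own
    diagnostic base at the box-discriminating offset; RHD_wt and RHD_var
    are the wild-type and c.1227A base counts at the variant offset in
    the RHD exon-9 matrix; RHCE is the count of its expected base at the
    same declared offset in the RHCE matrix.
    """
    roles = infer_roles(refs)
    for role, ref in roles.items():
        if ref.name not in matrices:
            raise ValueError(f"missing count matrix for region {ref.name} ({role})")

    def site_with(ref: AmpliconRef, key: str):
        for site in ref.diagnostic_sites:
            if key in site.expected_base_by_source:
                return site
        raise ValueError(f"{ref.name}: no diagnostic site declares source {key!r}")

    up_ref = roles["upstream_box"]
    down_ref = roles["downstream_box"]
    up_site = site_with(up_ref, "upstream_box")
    down_site = site_with(down_ref, "downstream_box")
    rhd_ref = roles["RHD_exon9"]
    rhce_ref = roles["RHCE_exon9"]
    c1227 = next(s for s in rhd_ref.diagnostic_sites if s.is_c1227)

    return DiagnosticCounts(
        upstream_box=matrices[up_ref.name].count_at(
            up_site.amplicon_offset, up_site.expected_base_by_source["upstream_box"]
        ),
        downstream_box=matrices[down_ref.name].count_at(
            down_site.amplicon_offset,
            down_site.expected_base_by_source["downstream_box"],
        ),
        RHD_wt=matrices[rhd_ref.name].count_at(
            c1227.amplicon_offset, c1227.expected_base_by_source["RHD_wt"]
        ),
        RHD_var=matrices[rhd_ref.name].count_at(
            c1227.amplicon_offset, c1227.expected_base_by_source["RHD_var"]
        ),
        RHCE=matrices[rhce_ref.name].count_at(
            c1227.amplicon_offset, c1227.expected_base_by_source["RHCE"]
        ),
    )


def write_wig(
    matrices: Mapping[str, BaseCountMatrix],
    refs: Sequence[AmpliconRef],
    path: str | Path,
) -> None:
    """Write per-position per-base counts as a wiggle-style text file.

    One fixedStep track per region in reference order, five
    tab-separated count columns (A, C, G, T, other) per position, with a
    comment line carrying the genomic anchor. Output is byte-stable for
    identical input.
    """
    lines: list[str] = []
    for ref in refs:
        m = matrices[ref.name]
        lines.append(f'track type=wiggle_0 name="{ref.name}"')
        lines.append(
            f"# region={ref.name} group={ref.group} "
            f"genomic_start={ref.genomic_start} strand={ref.strand}"
        )
        lines.append("# columns: A C G T other")
        lines.append(f"fixedStep chrom={ref.name} start=1 step=1")
        for row in m.counts:
            lines.append("\t".join(str(int(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_wig(path: str | Path) -> dict[str, BaseCountMatrix]:
    """Parse a file written by :func:`write_wig` back into matrices."""
    matrices: dict[str, BaseCountMatrix] = {}
    region = None
    rows: list[list[int]] = []

    def flush():
        if region is not None:
            matrices[region] = BaseCountMatrix(
                region, len(rows), np.array(rows, dtype=np.int64)
            )

    for line in Path(path).read_text().splitlines():
        if line.startswith("track"):
            flush()
            region = line.split('name="', 1)[1].rstrip('"')
            rows = []
        elif line.startswith("#") or line.startswith("fixedStep"):
            continue
        elif line.strip():
            rows.append([int(v) for v in line.split("\t")])
    flush()
    return matrices
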