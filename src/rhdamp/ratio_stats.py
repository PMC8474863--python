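"""Allele ratios and the pooled per-position error-ratio statistic.

Allele ratios are kept as exact rationals and rendered Table-style at
two decimals; within each group the majority fraction is rendered as
100 minus the rendered minor fractions, so a rendered tuple always sums
to 100%. A minor fraction that is positive but would render as 0.00 is
shown with enough extra decimals to be nonzero (e.g. a single read among
~60,000 renders as 0.002).

The error ratio at a position pools the two co-amplified regions of a
group: it is the fraction of reads carrying a base other than the
region's own reference base, computed over positionally identical bases.
Each region's own base is the reference at that region, so the
paralog-diagnostic positions contribute correctly. PCR-primer footprints
and (for exon 9) the c.1227 variant offset are excluded from summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from statistics import median
from typing import Mapping, Sequence

from .classify_count import BaseCountMatrix, DiagnosticCounts
from .preprocess import DedupStats
from .reference_model import AmpliconRef, infer_roles

__all__ = [
    "AlleleRatios",
    "ErrorRatioProfile",
    "allele_ratios",
    "error_ratio_profile",
    "summarize_run",
    "validate_report",
    "render_percent",
]


def render_percent(value: Fraction) -> str:
    """Render an exact fraction (of 1) as a percent string, Table style."""
    pct = float(value * 100)
    for nd in range(2, 8):
        s = f"{pct:.{nd}f}"
        if float(s) != 0.0 or value == 0:
            return f"{pct:.2f}" if nd == 2 else s
    return s


def _render_group(counts: Sequence[int]) -> tuple[str, ...] | None:
    """Render a count tuple as percentages; the last entry is the complement."""
    total = sum(counts)
    if total == 0:
        return None
    out: list[str] = []
    for c in counts[:-1]:
        out.append("0" if c == 0 else render_percent(Fraction(c, total)))
    if counts[-1] == 0:
        out.append("0")
    else:
        complement = 100.0 - sum(float(s) for s in out)
        out.append(f"{complement:.2f}")
    return tuple(out)


@dataclass(frozen=True)
class AlleleRatios:
    """Observed allele ratios with raw counts carried alongside.

    ``box`` orders (upstream, downstream); ``exon9`` orders
    (RHD_wt, RHD_var, RHCE). ``*_fracs`` are exact fractions of 1 (None
    when the group has no reads); ``*_percent`` are the rendered strings.
    """

    box_counts: tuple[int, int]
    exon9_counts: tuple[int, int, int]

    @property
    def box_fracs(self) -> tuple[Fraction, Fraction] | None:
        total = sum(self.box_counts)
        if total == 0:
            return None
        return tuple(Fraction(c, total) for c in self.box_counts)

    @property
    def exon9_fracs(self) -> tuple[Fraction, Fraction, Fraction] | None:
        total = sum(self.exon9_counts)
        if total == 0:
            return None
        return tuple(Fraction(c, total) for c in self.exon9_counts)

    @property
    def box_percent(self) -> tuple[str, str] | None:
        return _render_group(self.box_counts)

    @property
    def exon9_percent(self) -> tuple[str, str, str] | None:
        return _render_group(self.exon9_counts)

    @property
    def upstream_frac(self) -> Fraction | None:
        fr = self.box_fracs
        return None if fr is None else fr[0]

    @property
    def RHD_wt_frac(self) -> Fraction | None:
        fr = self.exon9_fracs
        return None if fr is None else fr[0]

    @property
    def RHD_var_frac(self) -> Fraction | None:
        fr = self.exon9_fracs
        return None if fr is None else fr[1]

    def to_dict(self) -> dict:
        return {
            "box": {
                "classes": ["upstream_box", "downstream_box"],
                "counts": list(self.box_counts),
                "percent": list(self.box_percent) if self.box_percent else None,
            },
            "exon9": {
                "classes": ["RHD_wt", "RHD_var", "RHCE"],
                "counts": list(self.exon9_counts),
                "percent": list(self.exon9_percent) if self.exon9_percent else None,
            },
        }


def allele_ratios(d: DiagnosticCounts) -> AlleleRatios:
    """Observed ratios from diagnostic read counts.

    A group with zero total reads yields a "no data" (None) rendering,
    not an exception.
    """
    return AlleleRatios(
        box_counts=(d.upstream_box, d.downstream_box),
        exon9_counts=(d.RHD_wt, d.RHD_var, d.RHCE),
    )


@dataclass(frozen=True)
class ErrorRatioProfile:
    """Pooled per-position error ratios for one amplicon group.

    ``ratios`` maps 1-based positions to exact error ratios (None where
    no reads cover the position); ``excluded`` maps excluded positions
    to reasons (primer footprint, c.1227 variant offset).
    ``analyzable_range`` is the non-primer interior over which the
    summary ``max_ratio`` / ``median_ratio`` are taken.
    """

    group: str
    ratios: Mapping[int, Fraction | None]
    excluded: Mapping[int, str]
    analyzable_range: tuple[int, int]
    max_ratio: Fraction | None
    median_ratio: Fraction | None

    @property
    def analyzable_size(self) -> int:
        return self.analyzable_range[1] - self.analyzable_range[0] + 1

    def to_dict(self) -> dict:
        mx = None if self.max_ratio is None else float(self.max_ratio)
        md = None if self.median_ratio is None else float(self.median_ratio)
        return {
            "group": self.group,
            "analyzable_range": list(self.analyzable_range),
            "analyzable_size": self.analyzable_size,
            "n_excluded": len(self.excluded),
            "max_ratio": mx,
            "median_ratio": md,
        }


def error_ratio_profile(
    matrices: Mapping[str, BaseCountMatrix],
    refs: Sequence[AmpliconRef],
    group: str,
) -> ErrorRatioProfile:
    """Compute the pooled error-ratio profile for one group.

    error(p) = sum over the group's two regions of non-own-reference
    base counts at p, divided by the pooled total at p. Positions with
    zero pooled total are reported as None and excluded from summaries.
    """
    members = [r for r in refs if r.group == group]
    if len(members) != 2:
        raise ValueError(f"group {group!r} must have exactly 2 references")
    a, b = members
    length = a.length

    excluded: dict[int, str] = {}
    for ref_span, label in ((a.primer_spans, "primer"),):
        for lo, hi in ref_span:
            for p in range(lo, hi + 1):
                excluded[p] = "primer"
    if group == "exon9":
        for site in a.diagnostic_sites:
            if site.is_c1227:
                excluded[site.amplicon_offset] = "c1227_variant"

    ratios: dict[int, Fraction | None] = {}
    for p in range(1, length + 1):
        if excluded.get(p) == "c1227_variant":
            continue
        err = 0
        total = 0
        for ref in (a, b):
            m = matrices[ref.name]
            t = m.total_at(p)
            total += t
            err += t - m.count_at(p, ref.base_at(p))
        ratios[p] = Fraction(err, total) if total > 0 else None

    lo, hi = a.interior_range()
    interior = [
        ratios[p]
        for p in range(lo, hi + 1)
        if p in ratios and ratios[p] is not None
    ]
    return ErrorRatioProfile(
        group=group,
        ratios=ratios,
        excluded=excluded,
        analyzable_range=(lo, hi),
        max_ratio=max(interior) if interior else None,
        median_ratio=median(interior) if interior else None,
    )


def _contamination_flags(
    ratios: AlleleRatios,
    profiles: Mapping[str, ErrorRatioProfile],
    minor_signal_ceiling: float = 0.005,
) -> list[dict]:
    """Flag diagnostic-class signals above the run's own background.

    A class fraction that exceeds the group's interior maximum error
    ratio yet stays below the positive-signal ceiling looks like
    carry-over contamination rather than a genuine minor allele.
    """
    flags: list[dict] = []
    groups = (
        ("rhesus_box", ("upstream_box", "downstream_box"), ratios.box_fracs),
        ("exon9", ("RHD_wt", "RHD_var", "RHCE"), ratios.exon9_fracs),
    )
    for group, classes, fracs in groups:
        if fracs is None or group not in profiles:
            continue
        background = profiles[group].max_ratio
        if background is None:
            continue
        for cls, frac in zip(classes, fracs):
            if background < frac < Fraction(minor_signal_ceiling):
                flags.append(
                    {
                        "flag": "possible_contamination",
                        "group": group,
                        "class": cls,
                        "ratio": float(frac),
                        "background_max": float(background),
                    }
                )
    return flags


def summarize_run(
    ratios: AlleleRatios,
    profiles: Mapping[str, ErrorRatioProfile],
    dedup_stats: DedupStats | None = None,
    ledger: Mapping[str, int] | None = None,
    minor_signal_ceiling: float = 0.005,
) -> dict:
    """Bundle counts, ratios, error summaries and QC flags into a report.

    The returned dict is JSON-serializable and validates against the
    schema shipped with the package (``data/run_report.schema.json``).
    """
    report = {
        "schema_version": 1,
        "ratios": ratios.to_dict(),
        "error_ratios": {g: p.to_dict() for g, p in sorted(profiles.items())},
        "dedup": dedup_stats.to_dict() if dedup_stats else None,
        "ledger": dict(ledger) if ledger else None,
        "qc_flags": _contamination_flags(ratios, profiles, minor_signal_ceiling),
    }
    return report


def _check(value, schema, path: str) -> list[str]:
    problems: list[str] = []
    types = schema.get("type")
    if types is not None:
        if isinstance(types, str):
            types = [types]
        type_map = {
            "object": dict,
            "array": list,
            "string": str,
            "integer": int,
            "number": (int, float),
            "boolean": bool,
            "null": type(None),
        }
        if not any(
            isinstance(value, type_map[t])
            and not (t in ("integer", "number") and isinstance(value, bool))
            for t in types
        ):
            problems.append(f"{path}: expected {types}, got {type(value).__name__}")
            return problems
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                problems.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                problems.extend(_check(value[key], sub, f"{path}.{key}"))
    if isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            problems.extend(_check(item, schema["items"], f"{path}[{i}]"))
    return problems


def validate_report(report: dict) -> None:
    """Validate a run report against the shipped schema; raise on failure."""
    with resources.files("rhdamp.data").joinpath("run_report.schema.json").open() as fh:
        schema = json.load(fh)
    problems = _check(report, schema, "report")
    if problems:
        raise ValueError("run report fails schema validation:\n" + "\n".join(problems))
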