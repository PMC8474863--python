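"""End-to-end orchestration: preprocess -> (dedup) -> classify/count ->
ratios/error profiles -> genotype call.

The pipeline is deterministic given input order; every stage records an
exact ledger (counts in = counts kept + counts rejected) and rejections
are carried as data. All stochastic behavior lives in the simulator.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .classify_count import (
    Assignment,
    BaseCountMatrix,
    DiagnosticCounts,
    classify_read,
    count_bases,
    extract_diagnostics,
    write_wig,
)
from .genotype_caller import (
    CallThresholds,
    GenotypeCall,
    MaternalPatternError,
    call_fetal,
    call_maternal,
)
from .preprocess import (
    DedupStats,
    FilterParams,
    MergedRead,
    ReadPair,
    Rejection,
    dedup_umi,
    extract_umi,
    merge_pair,
    quality_filter,
    size_filter,
    trim_adaptors,
)
from .ratio_stats import (
    AlleleRatios,
    ErrorRatioProfile,
    allele_ratios,
    error_ratio_profile,
    summarize_run,
)
from .reference_model import AlleleModel, AmpliconRef

__all__ = ["PipelineResult", "EmptyRunError", "preprocess_pairs", "classify_and_count", "run_pipeline"]


class EmptyRunError(RuntimeError):
    """No reads survived preprocessing; nothing to analyze."""


@dataclass
class PipelineResult:
    """Everything one run produces."""

    ledger: dict[str, int]
    rejections: list[Rejection]
    dedup_stats: DedupStats | None
    assignments: list[Assignment]
    matrices: dict[str, BaseCountMatrix]
    diagnostics: DiagnosticCounts
    ratios: AlleleRatios
    profiles: dict[str, ErrorRatioProfile]
    report: dict
    call: GenotypeCall | None
    maternal_error: str | None = None


def preprocess_pairs(
    pairs: Iterable[ReadPair], params: FilterParams
) -> tuple[list[MergedRead], dict[str, int], list[Rejection]]:
    """Trim, merge, (UMI-extract,) size-filter and quality-filter pairs.

    Returns the surviving merged reads, an exact stage ledger, and the
    rejection records.
    """
    ledger = {
        "input_pairs": 0,
        "merged": 0,
        "merge_rejected": 0,
        "umi_rejected": 0,
        "size_passed": 0,
        "size_rejected": 0,
        "quality_passed": 0,
        "quality_rejected": 0,
    }
    rejections: list[Rejection] = []
    out: list[MergedRead] = []
    for pair in pairs:
        ledger["input_pairs"] += 1
        merged = merge_pair(trim_adaptors(pair), params)
        if isinstance(merged, Rejection):
            ledger["merge_rejected"] += 1
            rejections.append(merged)
            continue
        ledger["merged"] += 1
        if params.umi_mode:
            merged = extract_umi(merged, params)
            if isinstance(merged, Rejection):
                ledger["umi_rejected"] += 1
                rejections.append(merged)
                continue
        sized = size_filter(merged, params.expected_sizes)
        if isinstance(sized, Rejection):
            ledger["size_rejected"] += 1
            rejections.append(sized)
            continue
        ledger["size_passed"] += 1
        kept = quality_filter(sized, params)
        if isinstance(kept, Rejection):
            ledger["quality_rejected"] += 1
            rejections.append(kept)
            continue
        ledger["quality_passed"] += 1
        out.append(kept)
    return out, ledger, rejections


def classify_and_count(
    reads: Sequence[MergedRead],
    refs: Sequence[AmpliconRef],
    max_mismatch: int = 3,
) -> tuple[list[Assignment], dict[str, BaseCountMatrix], dict[str, int]]:
    """Classify reads against their length class and build count matrices."""
    cache: dict[str, Assignment] = {}
    assignments: list[Assignment] = []
    counted: list[tuple[Assignment, MergedRead]] = []
    ledger = {"assigned": 0, "ambiguous": 0, "unassigned": 0}
    for read in reads:
        proto = cache.get(read.sequence)
        if proto is None:
            proto = classify_read(read, refs, max_mismatch)
            cache[read.sequence] = proto
        a = Assignment(read.id, proto.region, proto.mismatches, proto.margin)
        assignments.append(a)
        if a.assigned:
            ledger["assigned"] += 1
            counted.append((a, read))
        elif a.region == "ambiguous":
            ledger["ambiguous"] += 1
        else:
            ledger["unassigned"] += 1
    matrices = count_bases(counted, refs)
    return assignments, matrices, ledger


def run_pipeline(
    pairs: Iterable[ReadPair],
    refs: Sequence[AmpliconRef],
    params: FilterParams | None = None,
    thresholds: CallThresholds | None = None,
    model: AlleleModel | None = None,
    max_mismatch: int = 3,
    maternal_candidates: Sequence[Sequence[str]] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on an iterable of read pairs.

    Raises :class:`EmptyRunError` when no reads survive preprocessing.
    When ``out_dir`` is given, writes report.json, genotype_call.json,
    counts.wig, assignments.tsv, rejections.tsv and error_ratios.tsv.
    """
    expected_sizes = tuple(sorted({r.length for r in refs}))
    params = params or FilterParams()
    if tuple(sorted(params.expected_sizes)) != expected_sizes:
        params = FilterParams(
            base_quality_cutoff=params.base_quality_cutoff,
            max_mismatch_density=params.max_mismatch_density,
            min_overlap=params.min_overlap,
            expected_sizes=expected_sizes,
            umi_length=params.umi_length,
            umi_mode=params.umi_mode,
        )
    thresholds = thresholds or CallThresholds()
    model = model or AlleleModel.default()

    reads, ledger, rejections = preprocess_pairs(pairs, params)
    if ledger["input_pairs"] == 0:
        raise EmptyRunError("no reads in input")

    dedup_stats = None
    if params.umi_mode:
        ledger["dedup_input"] = len(reads)
        reads, dedup_stats = dedup_umi(reads)
        ledger["unique_molecules"] = len(reads)
    if not reads:
        raise EmptyRunError("no reads survived preprocessing")

    assignments, matrices, cls_ledger = classify_and_count(reads, refs, max_mismatch)
    ledger.update(cls_ledger)

    diagnostics = extract_diagnostics(matrices, refs)
    ratios = allele_ratios(diagnostics)
    profiles = {
        group: error_ratio_profile(matrices, refs, group)
        for group in sorted({r.group for r in refs})
    }
    report = summarize_run(ratios, profiles, dedup_stats, ledger)
    report["diagnostic_counts"] = diagnostics.to_dict()

    call: GenotypeCall | None = None
    maternal_error: str | None = None
    try:
        maternal, _dist = call_maternal(
            ratios,
            candidates=maternal_candidates,
            model=model,
            tolerance=thresholds.maternal_match_tolerance,
        )
        call = call_fetal(ratios, maternal, thresholds, dedup_stats, model)
    except MaternalPatternError as exc:
        maternal_error = str(exc)

    result = PipelineResult(
        ledger=ledger,
        rejections=rejections,
        dedup_stats=dedup_stats,
        assignments=assignments,
        matrices=matrices,
        diagnostics=diagnostics,
        ratios=ratios,
        profiles=profiles,
        report=report,
        call=call,
        maternal_error=maternal_error,
    )
    if out_dir is not None:
        _write_artifacts(result, refs, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, refs: Sequence[AmpliconRef], out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(result.report, indent=2) + "\n")
    if result.call is not None:
        (out / "genotype_call.json").write_text(
            json.dumps(result.call.to_dict(), indent=2) + "\n"
        )
    else:
        (out / "genotype_call.json").write_text(
            json.dumps({"error": result.maternal_error}, indent=2) + "\n"
        )
    write_wig(result.matrices, refs, out / "counts.wig")

    with open(out / "assignments.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["read_id", "region", "mismatches", "margin"])
        for a in result.assignments:
            w.writerow([a.read_id, a.region, a.mismatches, a.margin])

    with open(out / "rejections.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["read_id", "stage", "reason"])
        for r in result.rejections:
            w.writerow([r.id, r.stage, r.reason])

    by_group = {}
    for ref in refs:
        by_group.setdefault(ref.group, []).append(ref)
    with open(out / "error_ratios.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["group", "position", "total", "errors", "ratio", "excluded_reason"])
        for group, profile in sorted(result.profiles.items()):
            a, b = by_group[group]
            for p in range(1, a.length + 1):
                total = sum(result.matrices[r.name].total_at(p) for r in (a, b))
                errors = sum(
                    result.matrices[r.name].total_at(p)
                    - result.matrices[r.name].count_at(p, r.base_at(p))
                    for r in (a, b)
                )
                ratio = profile.ratios.get(p)
                w.writerow(
                    [
                        group,
                        p,
                        total,
                        errors,
                        "" if ratio is None else f"{float(ratio):.6g}",
                        profile.excluded.get(p, ""),
                    ]
                )
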