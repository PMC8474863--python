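"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own optimized code paths: the
classifier oracle scores every reference by direct position-wise
comparison, and the error-ratio oracle recounts errors read by read.
"""

from fractions import Fraction


def brute_force_classify(seq, refs, max_mismatch):
    """Score all references of matching length by direct comparison."""
    scores = {
        r.name: sum(1 for a, b in zip(seq, r.sequence) if a != b)
        for r in refs
        if len(r.sequence) == len(seq)
    }
    ordered = sorted(scores.values())
    best = ordered[0]
    winners = [n for n, s in scores.items() if s == best]
    margin = (ordered[1] - best) if len(ordered) > 1 else len(seq)
    if best > max_mismatch:
        return "unassigned", best, margin
    if len(winners) > 1:
        return "ambiguous", best, margin
    return winners[0], best, margin


def recount_error_ratios(counted, refs, group):
    """Per-position pooled error ratios recounted read by read.

    ``counted`` holds (Assignment, read) pairs; only reads assigned to
    the group's two regions contribute. Returns {position: Fraction or
    None}, skipping the c.1227 variant offset for the exon-9 group.
    """
    members = [r for r in refs if r.group == group]
    a, _b = members
    by_name = {r.name: r for r in members}
    reads = [
        (by_name[asg.region], rd if isinstance(rd, str) else rd.sequence)
        for asg, rd in counted
        if asg.region in by_name
    ]
    skip = set()
    if group == "exon9":
        skip = {s.amplicon_offset for s in a.diagnostic_sites if s.is_c1227}
    out = {}
    for p in range(1, a.length + 1):
        if p in skip:
            continue
        total = len(reads)
        errs = sum(1 for ref, seq in reads if seq[p - 1] != ref.base_at(p))
        out[p] = Fraction(errs, total) if total else None
    return out
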