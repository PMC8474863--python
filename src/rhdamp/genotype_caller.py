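"""Maternal genotype matching and fetal RhD status calling.

Detection of the *RHD\\*01* wild-type allele in maternal plasma cfDNA
demonstrates an RhD-positive fetus. Absence of that signal leaves two
possibilities — a fetus homozygous for the deletion allele, or a fetal
fraction too low to detect — so the caller returns an explicit
"inconclusive" outcome whenever the evidence is compatible with low
fetal fraction, and reports a mixture-fraction estimate from the
upstream-box ratio when the maternal genotype permits that inversion.

The assay cannot phase fetal alleles: a positive call reports the RhD
status plus the compatible allele, never a full fetal genotype. No
numeric decision thresholds are published for this assay; the defaults
here anchor the negative ceiling to the observed background error level
(~0.1%) and the positive floor well below genuine fetal signals at
plausible fetal fractions (>= 0.5% plus a molecule-count floor), and
every threshold is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

from .preprocess import DedupStats
from .ratio_stats import AlleleRatios
from .reference_model import (
    AlleleModel,
    MixtureSpec,
    RHD_NEGATIVE_MATERNAL_GENOTYPES,
    UnsupportedMixtureError,
    expected_ratios,
    fetal_fraction_from_upstream,
    format_genotype,
)

__all__ = [
    "CallThresholds",
    "GenotypeCall",
    "MaternalPatternError",
    "call_maternal",
    "call_fetal",
    "estimate_mixture_fraction",
]

FETAL_POSITIVE = "RhD-positive"
FETAL_NEGATIVE = "RhD-negative (del/del)"
FETAL_INCONCLUSIVE = "inconclusive"


class MaternalPatternError(ValueError):
    """Observed ratios match no candidate maternal genotype."""


@dataclass(frozen=True)
class CallThresholds:
    """Decision cutoffs for the fetal call.

    ``min_positive_frac``/``max_negative_frac`` are percentages of group
    reads; ``min_positive_count`` is a raw read (or unique-molecule)
    floor; ``maternal_match_tolerance`` is an absolute L1 distance on
    fractions of 1.
    """

    min_positive_frac: float = 0.5
    min_positive_count: int = 50
    max_negative_frac: float = 0.1
    maternal_match_tolerance: float = 0.15

    def __post_init__(self) -> None:
        if not self.max_negative_frac < self.min_positive_frac:
            raise ValueError("max_negative_frac must be below min_positive_frac")
        if self.min_positive_count < 0:
            raise ValueError("min_positive_count must be non-negative")


@dataclass(frozen=True)
class GenotypeCall:
    """The assay's verdict for one run."""

    maternal_genotype: tuple[str, str]
    maternal_distance: float
    fetal_status: str
    compatible_fetal_allele: str | None
    evidence: dict
    mixture_fraction_estimate: float | None
    thresholds: CallThresholds
    qc_notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "maternal_genotype": format_genotype(self.maternal_genotype),
            "maternal_distance": self.maternal_distance,
            "fetal_status": self.fetal_status,
            "compatible_fetal_allele": self.compatible_fetal_allele,
            "evidence": self.evidence,
            "mixture_fraction_estimate": self.mixture_fraction_estimate,
            "thresholds": {
                "min_positive_frac": self.thresholds.min_positive_frac,
                "min_positive_count": self.thresholds.min_positive_count,
                "max_negative_frac": self.thresholds.max_negative_frac,
                "maternal_match_tolerance": self.thresholds.maternal_match_tolerance,
            },
            "qc_notes": list(self.qc_notes),
        }

    def summary(self) -> str:
        lines = [
            f"Maternal genotype : {format_genotype(self.maternal_genotype)} "
            f"(L1 distance {self.maternal_distance:.4f})",
            f"Fetal RhD status  : {self.fetal_status}",
        ]
        if self.compatible_fetal_allele:
            lines.append(f"Compatible allele : {self.compatible_fetal_allele}")
        if self.mixture_fraction_estimate is not None:
            lines.append(
                f"Mixture fraction  : {self.mixture_fraction_estimate:.4f} "
                "(proxy from upstream-box ratio, not a true fetal fraction)"
            )
        for note in self.qc_notes:
            lines.append(f"QC note           : {note}")
        return "\n".join(lines)


def _observed_vector(ratios: AlleleRatios) -> tuple[Fraction, Fraction, Fraction]:
    """(upstream, RHD_wt, RHD_var) observed fractions of 1."""
    if ratios.box_fracs is None or ratios.exon9_fracs is None:
        raise MaternalPatternError("a group has no reads; cannot match a pattern")
    return ratios.upstream_frac, ratios.RHD_wt_frac, ratios.RHD_var_frac


def _maternal_vector(
    genotype: Sequence[str], model: AlleleModel
) -> tuple[Fraction, Fraction, Fraction]:
    """(upstream, RHD_wt, RHD_var) expected fractions at fetal fraction 0."""
    mix = MixtureSpec(
        maternal_genotype=tuple(genotype),
        fetal_genotype=tuple(genotype),
        maternal_weight=Fraction(1),
        fetal_weight=Fraction(0),
    )
    exp = expected_ratios(mix, model)
    return exp["upstream_frac"], exp["RHD_wt_frac"], exp["RHD_var_frac"]


def call_maternal(
    ratios: AlleleRatios,
    candidates: Sequence[Sequence[str]] | None = None,
    model: AlleleModel | None = None,
    tolerance: float = 0.15,
) -> tuple[tuple[str, str], float]:
    """Match observed ratios to a maternal genotype at fetal fraction 0.

    Picks the candidate minimizing the L1 distance between the observed
    (upstream, RHD_wt, RHD_var) fractions and the candidate's expected
    pattern; raises :class:`MaternalPatternError` when the best distance
    exceeds ``tolerance`` — e.g. for an RhD-positive (high wild-type)
    pattern, which no RhD-negative maternal genotype can produce.
    """
    model = model or AlleleModel.default()
    if candidates is None:
        candidates = RHD_NEGATIVE_MATERNAL_GENOTYPES
    if not candidates:
        raise ValueError("candidate genotype list is empty")
    obs = _observed_vector(ratios)
    best: tuple[float, tuple[str, str]] | None = None
    for cand in candidates:
        exp = _maternal_vector(cand, model)
        dist = float(sum(abs(o - e) for o, e in zip(obs, exp)))
        if best is None or dist < best[0]:
            best = (dist, tuple(cand))
    dist, genotype = best
    if dist > tolerance:
        raise MaternalPatternError(
            f"no candidate maternal genotype within tolerance {tolerance} "
            f"(best: {format_genotype(genotype)} at distance {dist:.4f})"
        )
    return genotype, dist


def call_fetal(
    ratios: AlleleRatios,
    maternal_genotype: Sequence[str],
    thresholds: CallThresholds | None = None,
    dedup_stats: DedupStats | None = None,
    model: AlleleModel | None = None,
) -> GenotypeCall:
    """Decide the fetal RhD status given the maternal genotype.

    RhD-positive requires the wild-type exon-9 signal to clear both the
    fraction and count floors and — for mothers without an upstream box
    — a corroborating upstream-box signal; discordance between the two
    independent amplicon groups yields "inconclusive" with a QC note.
    RhD-negative requires the wild-type signal at or below the
    background ceiling and an upstream ratio matching the maternal-only
    expectation. Everything in between is "inconclusive" (compatible
    with a low fetal fraction). When dedup statistics are present the
    counts are unique-molecule counts, which is what makes the count
    floor meaningful.
    """
    thresholds = thresholds or CallThresholds()
    model = model or AlleleModel.default()
    maternal_genotype = tuple(maternal_genotype)
    obs_up, obs_wt, obs_var = _observed_vector(ratios)
    wt_count = ratios.exon9_counts[0]
    exp_up, _, _ = _maternal_vector(maternal_genotype, model)
    maternal_has_upstream = model.unit_vector(maternal_genotype)["upstream_box"] > 0

    pos_frac = Fraction(thresholds.min_positive_frac) / 100
    neg_frac = Fraction(thresholds.max_negative_frac) / 100
    qc: list[str] = []

    wt_signal = obs_wt >= pos_frac
    count_ok = wt_count >= thresholds.min_positive_count
    if maternal_has_upstream:
        up_matches_maternal = abs(obs_up - exp_up) <= Fraction(
            thresholds.maternal_match_tolerance
        )
        if wt_signal and count_ok:
            status = FETAL_POSITIVE
        elif obs_wt <= neg_frac and up_matches_maternal:
            status = FETAL_NEGATIVE
        else:
            status = FETAL_INCONCLUSIVE
            if wt_signal and not count_ok:
                qc.append(
                    f"wild-type signal present but only {wt_count} supporting "
                    f"reads (floor {thresholds.min_positive_count})"
                )
    else:
        up_signal = obs_up >= pos_frac
        if wt_signal and up_signal and count_ok:
            status = FETAL_POSITIVE
        elif wt_signal != up_signal:
            status = FETAL_INCONCLUSIVE
            qc.append(
                "discordant amplicon groups: wild-type exon-9 and upstream-box "
                "signals disagree (possible non-deletion fetal allele or artefact)"
            )
        elif wt_signal and up_signal:
            status = FETAL_INCONCLUSIVE
            qc.append(
                f"wild-type signal present but only {wt_count} supporting "
                f"reads (floor {thresholds.min_positive_count})"
            )
        elif obs_wt <= neg_frac and obs_up <= neg_frac:
            status = FETAL_NEGATIVE
        else:
            status = FETAL_INCONCLUSIVE

    f_est: float | None = None
    if not maternal_has_upstream:
        try:
            f_est = float(
                fetal_fraction_from_upstream(
                    obs_up, maternal_genotype, ("RHD*01", "RHD*01N.01"), model
                )
            )
        except (UnsupportedMixtureError, ValueError):
            f_est = None

    evidence = {
        "upstream_frac": float(obs_up),
        "RHD_wt_frac": float(obs_wt),
        "RHD_var_frac": float(obs_var),
        "RHD_wt_count": wt_count,
        "counts_are_unique_molecules": dedup_stats is not None,
    }
    return GenotypeCall(
        maternal_genotype=maternal_genotype,
        maternal_distance=float(
            sum(
                abs(o - e)
                for o, e in zip(
                    (obs_up, obs_wt, obs_var), _maternal_vector(maternal_genotype, model)
                )
            )
        ),
        fetal_status=status,
        compatible_fetal_allele="RHD*01" if status == FETAL_POSITIVE else None,
        evidence=evidence,
        mixture_fraction_estimate=f_est,
        thresholds=thresholds,
        qc_notes=tuple(qc),
    )


def estimate_mixture_fraction(
    ratios: AlleleRatios,
    maternal_genotype: Sequence[str],
    assumed_fetal_genotype: Sequence[str] = ("RHD*01", "RHD*01N.01"),
    model: AlleleModel | None = None,
) -> Fraction:
    """Mixture-fraction proxy from the observed upstream-box ratio.

    Delegates to the closed-form inversion; only supported when the
    maternal genotype contributes no upstream-box reads. The result is a
    proxy under the assumed fetal genotype, not a measured fetal
    fraction — the assay by itself cannot determine the fetal fraction.
    """
    if ratios.box_fracs is None:
        raise ValueError("no box reads; cannot estimate a mixture fraction")
    return fetal_fraction_from_upstream(
        ratios.upstream_frac, maternal_genotype, assumed_fetal_genotype, model
    )
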