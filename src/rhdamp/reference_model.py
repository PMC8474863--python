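"""Reference amplicons, allele models, and closed-form mixture ratios.

The assay amplifies four near-identical genomic regions with two primer
pairs: the upstream and downstream *Rhesus boxes* (105-bp amplicons that
differ at a single base) and the exon 9 regions of *RHD* and *RHCE*
(148-bp amplicons that differ at two paralog-diagnostic bases and
additionally carry the intra-allelic c.1227G>A variant site on *RHD*).
Each *RHD* allele contributes a fixed integer number of copies of each
amplicon unit, so for any maternal/fetal genotype mixture the expected
read fractions have a closed form in exact rational arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from numbers import Real
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "DiagnosticSite",
    "AmpliconRef",
    "AlleleModel",
    "MixtureSpec",
    "ReferenceValidationError",
    "UnknownAlleleError",
    "UnsupportedMixtureError",
    "GROUP_LENGTHS",
    "PRIMER_SPANS",
    "UNIT_KEYS",
    "RHD_NEGATIVE_MATERNAL_GENOTYPES",
    "load_reference_spec",
    "validate_references",
    "infer_roles",
    "expected_ratios",
    "fetal_fraction_from_upstream",
    "parse_genotype",
    "format_genotype",
]

#: Canonical amplicon group lengths in bases.
GROUP_LENGTHS = {"rhesus_box": 105, "exon9": 148}

#: PCR-primer footprints per group, 1-based closed intervals in amplicon coordinates.
PRIMER_SPANS = {
    "rhesus_box": ((1, 20), (81, 105)),
    "exon9": ((1, 22), (120, 148)),
}

#: Amplicon-unit labels of the per-allele contribution vector.
UNIT_KEYS = ("upstream_box", "downstream_box", "RHD_wt", "RHD_var", "RHCE")

#: Canonical region (reference) role names, one per amplicon.
REGION_ROLES = ("upstream_box", "downstream_box", "RHD_exon9", "RHCE_exon9")

#: The three common RhD-negative maternal genotypes in East Asian populations.
RHD_NEGATIVE_MATERNAL_GENOTYPES = (
    ("RHD*01N.01", "RHD*01N.01"),
    ("RHD*01N.01", "RHD*01EL.01"),
    ("RHD*01N.01", "RHD*01N.04"),
)

_VALID_BASES = frozenset("ACGT")


class ReferenceValidationError(ValueError):
    """A reference record violates a structural invariant."""


class UnknownAlleleError(KeyError):
    """An allele name is absent from the allele-unit table."""


class UnsupportedMixtureError(ValueError):
    """A mixture configuration does not admit the requested inversion."""


@dataclass(frozen=True)
class DiagnosticSite:
    """A single base that discriminates co-amplified sequences.

    ``expected_base_by_source`` maps source labels to bases; for the
    box-discriminating site the sources are ``upstream_box`` /
    ``downstream_box``, for the two exon-9 paralog sites ``RHD`` /
    ``RHCE``, and for the c.1227 variant site ``RHD_wt`` / ``RHD_var`` /
    ``RHCE``.
    """

    amplicon_offset: int
    genomic_pos: int
    expected_base_by_source: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.amplicon_offset < 1:
            raise ReferenceValidationError(
                f"diagnostic site offset must be >= 1, got {self.amplicon_offset}"
            )
        bases = list(self.expected_base_by_source.values())
        if len(bases) < 2:
            raise ReferenceValidationError(
                "a diagnostic site needs expected bases for at least two sources"
            )
        for b in bases:
            if b not in _VALID_BASES:
                raise ReferenceValidationError(f"invalid diagnostic base {b!r}")
        if len(set(bases)) < 2:
            raise ReferenceValidationError(
                "diagnostic bases must differ between at least two sources"
            )

    @property
    def is_c1227(self) -> bool:
        """True for the intra-allelic RHD_wt/RHD_var variant site."""
        keys = set(self.expected_base_by_source)
        return "RHD_wt" in keys and "RHD_var" in keys


@dataclass(frozen=True)
class AmpliconRef:
    """One reference amplicon with its metadata.

    ``primer_spans`` are 1-based closed intervals; ``genomic_start`` is
    the hg19 coordinate of amplicon position 1 (on the ``strand`` given,
    so on '-' the genomic coordinate decreases along the amplicon).
    """

    name: str
    group: str
    sequence: str
    primer_spans: tuple[tuple[int, int], tuple[int, int]]
    genomic_start: int
    strand: str
    diagnostic_sites: tuple[DiagnosticSite, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUP_LENGTHS:
            raise ReferenceValidationError(
                f"{self.name}: unknown group {self.group!r}"
            )
        expected_len = GROUP_LENGTHS[self.group]
        if len(self.sequence) != expected_len:
            raise ReferenceValidationError(
                f"{self.name}: {self.group} amplicons are {expected_len} bases, "
                f"got {len(self.sequence)}"
            )
        if set(self.sequence) - _VALID_BASES:
            raise ReferenceValidationError(
                f"{self.name}: sequence contains non-ACGT characters"
            )
        if self.strand not in {"+", "-"}:
            raise ReferenceValidationError(f"{self.name}: strand must be '+' or '-'")
        if tuple(tuple(s) for s in self.primer_spans) != PRIMER_SPANS[self.group]:
            raise ReferenceValidationError(
                f"{self.name}: primer spans {self.primer_spans} do not match the "
                f"{self.group} layout {PRIMER_SPANS[self.group]}"
            )
        for site in self.diagnostic_sites:
            if site.amplicon_offset > expected_len:
                raise ReferenceValidationError(
                    f"{self.name}: diagnostic offset {site.amplicon_offset} outside amplicon"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, offset: int) -> str:
        """Base at a 1-based amplicon offset."""
        return self.sequence[offset - 1]

    def genomic_position(self, offset: int) -> int:
        """hg19 coordinate of a 1-based amplicon offset."""
        if self.strand == "+":
            return self.genomic_start + offset - 1
        return self.genomic_start - offset + 1

    def interior_range(self) -> tuple[int, int]:
        """The non-primer interval (1-based, closed) of this amplicon."""
        (a1, a2), (b1, b2) = self.primer_spans
        return a2 + 1, b1 - 1


def _role_base(ref_role: str, site: DiagnosticSite) -> str | None:
    """The base a reference with the given role should carry at a site.

    The RHD exon-9 reference is the wild-type sequence, so at the c.1227
    site it carries the RHD_wt base.
    """
    by = site.expected_base_by_source
    if ref_role in by:
        return by[ref_role]
    if ref_role == "upstream_box" or ref_role == "downstream_box":
        return None
    if ref_role == "RHD_exon9":
        return by.get("RHD_wt", by.get("RHD"))
    if ref_role == "RHCE_exon9":
        return by.get("RHCE")
    return None


def infer_roles(refs: Sequence[AmpliconRef]) -> dict[str, AmpliconRef]:
    """Assign each reference its canonical role from its diagnostic bases.

    Returns a map with keys ``upstream_box``, ``downstream_box``,
    ``RHD_exon9``, ``RHCE_exon9``. Raises if any role is missing or
    duplicated.
    """
    roles: dict[str, AmpliconRef] = {}
    for ref in refs:
        candidates = []
        group_roles = (
            ("upstream_box", "downstream_box")
            if ref.group == "rhesus_box"
            else ("RHD_exon9", "RHCE_exon9")
        )
        for role in group_roles:
            ok = True
            for site in ref.diagnostic_sites:
                want = _role_base(role, site)
                if want is not None and ref.base_at(site.amplicon_offset) != want:
                    ok = False
                    break
            if ok:
                candidates.append(role)
        if len(candidates) != 1:
            raise ReferenceValidationError(
                f"{ref.name}: cannot assign a unique role from diagnostic bases "
                f"(candidates: {candidates})"
            )
        role = candidates[0]
        if role in roles:
            raise ReferenceValidationError(
                f"role {role} claimed by both {roles[role].name} and {ref.name}"
            )
        roles[role] = ref
    missing = [r for r in REGION_ROLES if r not in roles]
    if missing:
        raise ReferenceValidationError(f"missing reference roles: {missing}")
    return roles


def validate_references(refs: Sequence[AmpliconRef]) -> dict[str, AmpliconRef]:
    """Enforce all cross-record invariants; return the role map.

    Checks: unique names, both groups present with two references each,
    equal lengths within a group, diagnostic bases consistent with the
    sequences, and that the two references of a group differ at exactly
    the diagnostic offsets declared for that group.
    """
    names = [r.name for r in refs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ReferenceValidationError(f"duplicate reference names: {sorted(dupes)}")

    by_group: dict[str, list[AmpliconRef]] = {}
    for r in refs:
        by_group.setdefault(r.group, []).append(r)
    for group, members in by_group.items():
        if len(members) != 2:
            raise ReferenceValidationError(
                f"group {group} must contain exactly 2 references, got {len(members)}"
            )
        a, b = members
        if a.length != b.length:
            raise ReferenceValidationError(
                f"group {group}: lengths differ ({a.name}={a.length}, {b.name}={b.length})"
            )
        diag_offsets = {s.amplicon_offset for s in a.diagnostic_sites}
        if diag_offsets != {s.amplicon_offset for s in b.diagnostic_sites}:
            raise ReferenceValidationError(
                f"group {group}: diagnostic sites differ between {a.name} and {b.name}"
            )
        diff = {
            i + 1 for i, (x, y) in enumerate(zip(a.sequence, b.sequence)) if x != y
        }
        if diff != diag_offsets:
            raise ReferenceValidationError(
                f"group {group}: references differ at offsets {sorted(diff)} "
                f"but diagnostic offsets are {sorted(diag_offsets)}"
            )

    roles = infer_roles(refs)

    # Every declared diagnostic base for a reference's own role must match its sequence.
    for role, ref in roles.items():
        for site in ref.diagnostic_sites:
            want = _role_base(role, site)
            if want is not None and ref.base_at(site.amplicon_offset) != want:
                raise ReferenceValidationError(
                    f"{ref.name}: base {ref.base_at(site.amplicon_offset)} at offset "
                    f"{site.amplicon_offset} contradicts declared {role} base {want}"
                )
    return roles


def load_reference_spec(
    fasta_path: str | Path, meta_path: str | Path
) -> list[AmpliconRef]:
    """Load and validate amplicon references from FASTA + JSON metadata.

    The JSON file holds a list of records ``{name, group, primer_spans,
    genomic_start, strand, diagnostic_sites: [{amplicon_offset,
    genomic_pos, expected_base_by_source}]}`` whose names must match the
    FASTA record ids exactly.
    """
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    with open(meta_path) as fh:
        meta = json.load(fh)

    refs: list[AmpliconRef] = []
    seen: set[str] = set()
    for entry in meta:
        name = entry["name"]
        if name in seen:
            raise ReferenceValidationError(f"duplicate reference name: {name}")
        seen.add(name)
        if name not in seqs:
            raise ReferenceValidationError(f"{name}: no FASTA record with this id")
        sites = tuple(
            DiagnosticSite(
                amplicon_offset=s["amplicon_offset"],
                genomic_pos=s["genomic_pos"],
                expected_base_by_source=dict(s["expected_base_by_source"]),
            )
            for s in entry["diagnostic_sites"]
        )
        refs.append(
            AmpliconRef(
                name=name,
                group=entry["group"],
                sequence=seqs[name],
                primer_spans=tuple(tuple(span) for span in entry["primer_spans"]),
                genomic_start=entry["genomic_start"],
                strand=entry["strand"],
                diagnostic_sites=sites,
            )
        )
    extra = set(seqs) - seen
    if extra:
        raise ReferenceValidationError(
            f"FASTA records without metadata: {sorted(extra)}"
        )
    validate_references(refs)
    return refs


class AlleleModel:
    """Per-allele amplicon-unit contribution table.

    Each allele maps to a vector of non-negative integer copies of the
    five amplicon units (two *Rhesus boxes*, wild-type *RHD* exon 9,
    c.1227A *RHD* exon 9, *RHCE* exon 9) contributed per allele copy.
    The default table covers *RHD\\*01* and the three common D-negative
    alleles and ships as package data so further alleles can be added
    without code changes.
    """

    def __init__(self, units: Mapping[str, Mapping[str, int]]):
        table: dict[str, dict[str, int]] = {}
        for allele, vec in units.items():
            if set(vec) != set(UNIT_KEYS):
                raise ReferenceValidationError(
                    f"allele {allele}: unit vector must have keys {UNIT_KEYS}"
                )
            if any(v < 0 or int(v) != v for v in vec.values()):
                raise ReferenceValidationError(
                    f"allele {allele}: unit counts must be non-negative integers"
                )
            table[allele] = {k: int(vec[k]) for k in UNIT_KEYS}
        self._units = table

    @classmethod
    def default(cls) -> "AlleleModel":
        with resources.files("rhdamp.data").joinpath("allele_units.json").open() as fh:
            return cls(json.load(fh))

    @classmethod
    def from_json(cls, path: str | Path) -> "AlleleModel":
        with open(path) as fh:
            return cls(json.load(fh))

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(self._units)

    def units_for(self, allele: str) -> dict[str, int]:
        try:
            return dict(self._units[allele])
        except KeyError:
            raise UnknownAlleleError(allele) from None

    def unit_vector(self, genotype: Sequence[str]) -> dict[str, int]:
        """Total unit counts contributed by one genome copy of a genotype."""
        total = dict.fromkeys(UNIT_KEYS, 0)
        for allele in genotype:
            for k, v in self.units_for(allele).items():
                total[k] += v
        return total


def parse_genotype(text: str) -> tuple[str, str]:
    """Parse ``"RHD*01/RHD*01N.01"`` into an allele-name pair."""
    parts = text.split("/")
    if len(parts) != 2:
        raise ValueError(f"genotype must be two '/'-separated alleles: {text!r}")
    return parts[0], parts[1]


def format_genotype(genotype: Sequence[str]) -> str:
    return "/".join(genotype)


@dataclass(frozen=True)
class MixtureSpec:
    """A maternal/fetal genotype mixture with relative genome weights.

    Weights are per genome equivalent: a 10:1 genomic DNA mixture of two
    diploid individuals corresponds to ``maternal_weight=10,
    fetal_weight=1``, i.e. fetal fraction f = 1/11.
    """

    maternal_genotype: tuple[str, str]
    fetal_genotype: tuple[str, str]
    maternal_weight: Fraction = Fraction(10)
    fetal_weight: Fraction = Fraction(1)

    def __post_init__(self) -> None:
        for w, label in (
            (self.maternal_weight, "maternal_weight"),
            (self.fetal_weight, "fetal_weight"),
        ):
            if not isinstance(w, (int, Fraction)) and not isinstance(w, Real):
                raise ValueError(f"{label} must be a number")
            if w < 0:
                raise ValueError(f"{label} must be non-negative")
        if self.maternal_weight + self.fetal_weight <= 0:
            raise ValueError("total mixture weight must be positive")

    @property
    def fetal_fraction(self) -> Fraction:
        return Fraction(self.fetal_weight) / (
            Fraction(self.maternal_weight) + Fraction(self.fetal_weight)
        )

    @classmethod
    def from_fetal_fraction(
        cls,
        maternal_genotype: Sequence[str],
        fetal_genotype: Sequence[str],
        f: Fraction | float,
    ) -> "MixtureSpec":
        f = Fraction(f)
        if not 0 <= f <= 1:
            raise ValueError("fetal fraction must lie in [0, 1]")
        return cls(
            maternal_genotype=tuple(maternal_genotype),
            fetal_genotype=tuple(fetal_genotype),
            maternal_weight=1 - f,
            fetal_weight=f,
        )


def expected_ratios(
    mix: MixtureSpec, model: AlleleModel | None = None
) -> dict[str, Fraction]:
    """Closed-form expected read fractions for a genotype mixture.

    Sums the per-allele unit vectors weighted by genotype copy number and
    mixture weight, then normalizes within each co-amplified group.
    Returns exact fractions ``upstream_frac``/``downstream_frac`` (among
    box reads) and ``RHD_wt_frac``/``RHD_var_frac``/``RHCE_frac`` (among
    exon-9 reads).
    """
    model = model or AlleleModel.default()
    mw = Fraction(mix.maternal_weight)
    fw = Fraction(mix.fetal_weight)
    m_units = model.unit_vector(mix.maternal_genotype)
    f_units = model.unit_vector(mix.fetal_genotype)
    total = {k: mw * m_units[k] + fw * f_units[k] for k in UNIT_KEYS}

    box = total["upstream_box"] + total["downstream_box"]
    ex9 = total["RHD_wt"] + total["RHD_var"] + total["RHCE"]
    if box == 0 or ex9 == 0:
        raise UnsupportedMixtureError(
            "mixture contributes no amplicons to one of the groups"
        )
    return {
        "upstream_frac": total["upstream_box"] / box,
        "downstream_frac": total["downstream_box"] / box,
        "RHD_wt_frac": total["RHD_wt"] / ex9,
        "RHD_var_frac": total["RHD_var"] / ex9,
        "RHCE_frac": total["RHCE"] / ex9,
    }


def fetal_fraction_from_upstream(
    u: Fraction | float,
    maternal_genotype: Sequence[str],
    fetal_genotype: Sequence[str],
    model: AlleleModel | None = None,
) -> Fraction:
    """Invert the expected upstream-box fraction to a fetal fraction.

    Only identifiable when the maternal genotype contributes zero
    upstream-box units (e.g. an *RHD\\*01N.01* homozygote): then the
    upstream signal is purely fetal and

        u = f*Uf / ((1-f)*Dm + f*(Uf+Df))

    inverts to f = u*Dm / (Uf + u*(Dm - Uf - Df)), where Uf/Df are the
    fetal genotype's upstream/downstream units per genome and Dm the
    maternal downstream units. For mother del/del and fetus
    *RHD\\*01*/del this reduces to f = 2u/(1-u).
    """
    model = model or AlleleModel.default()
    u = Fraction(u)
    if not 0 <= u < 1:
        raise ValueError("observed upstream fraction must lie in [0, 1)")
    m_units = model.unit_vector(maternal_genotype)
    if m_units["upstream_box"] != 0:
        raise UnsupportedMixtureError(
            "maternal genotype contributes upstream-box reads; the fetal "
            "fraction is not identifiable from the upstream ratio"
        )
    dm = m_units["downstream_box"]
    f_units = model.unit_vector(fetal_genotype)
    uf, df = f_units["upstream_box"], f_units["downstream_box"]
    if uf == 0:
        if u == 0:
            return Fraction(0)
        raise UnsupportedMixtureError(
            "fetal genotype contributes no upstream-box reads but the "
            "observed upstream fraction is positive"
        )
    f = u * dm / (uf + u * (dm - uf - df))
    if not 0 <= f <= 1:
        raise ValueError(
            f"upstream fraction {float(u):.4f} is inconsistent with the "
            f"assumed genotypes (implied f = {float(f):.4f})"
        )
    return f
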