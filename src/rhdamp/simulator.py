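"""Synthetic reference and read simulator with ground truth.

The simulator replaces wet-lab inputs: it builds four synthetic
reference amplicons that satisfy every structural invariant of the
assay (105/148-bp lengths, a single box-discriminating base, two
exon-9 paralog bases plus the c.1227 variant offset, fixed primer
footprints, the published hg19 diagnostic coordinates as anchors) and
emits paired-end 151-bp reads from a maternal/fetal genotype mixture
with per-molecule UMIs, geometric PCR duplication, template-level PCR
substitution errors (shared by both reads of a duplicate) and per-read
sequencing substitution errors (independent between mates, hence
removable by perfect-overlap merging).

The reference sequences are synthetic: the genomic sequences of the
amplified intervals are not reproduced here, only their discriminating
structure. All randomness flows from a single seed; identical
configurations produce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import fastq
from .preprocess import (
    DEFAULT_ADAPTOR_R1,
    DEFAULT_ADAPTOR_R2,
    ReadPair,
    reverse_complement,
)
from .reference_model import (
    AlleleModel,
    AmpliconRef,
    DiagnosticSite,
    MixtureSpec,
    RHD_NEGATIVE_MATERNAL_GENOTYPES,
    expected_ratios,
    format_genotype,
    infer_roles,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ReadProvenance",
    "make_synthetic_references",
    "simulate_reads",
    "simulate_twelve_panel",
    "write_run",
    "write_reference_spec",
    "TWELVE_PANEL_FETAL_GENOTYPES",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Amplicon classes per group, in fixed simulation order.
GROUP_CLASSES = {
    "rhesus_box": ("upstream_box", "downstream_box"),
    "exon9": ("RHD_wt", "RHD_var", "RHCE"),
}

#: The "B" (fetus-analog) genotypes of the 3 x 4 mixture panel.
TWELVE_PANEL_FETAL_GENOTYPES = (
    ("RHD*01", "RHD*01N.01"),
) + RHD_NEGATIVE_MATERNAL_GENOTYPES


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated run.

    Defaults mirror the assay's validation design: a 10:1 genomic DNA
    mixture of two diploid individuals (fetal fraction 1/11), 20,000
    template molecules per amplicon group, geometric PCR duplication
    with mean 3, a per-base per-read substitution sequencing error of
    1e-3 and a per-base per-duplication PCR error of 1e-4.
    ``amplification_bias`` maps class names to multipliers on the
    expected class probabilities (e.g. to emulate bias towards the
    *RHCE* exon-9 amplicon).
    """

    seed: int
    mixture: MixtureSpec = field(
        default_factory=lambda: MixtureSpec(
            maternal_genotype=("RHD*01N.01", "RHD*01N.01"),
            fetal_genotype=("RHD*01", "RHD*01N.01"),
        )
    )
    molecules_per_group: int = 20_000
    duplication_mean: float = 3.0
    substitution_error_rate: float = 0.001
    pcr_error_rate: float = 0.0001
    umi_mode: bool = False
    read_length: int = 151
    amplification_bias: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.molecules_per_group <= 0:
            raise ValueError("molecules_per_group must be positive")
        if self.duplication_mean < 1:
            raise ValueError("duplication_mean must be >= 1")
        for rate, label in (
            (self.substitution_error_rate, "substitution_error_rate"),
            (self.pcr_error_rate, "pcr_error_rate"),
        ):
            if not 0 <= rate <= 1:
                raise ValueError(f"{label} must lie in [0, 1]")
        if self.read_length < 20:
            raise ValueError("read_length must be a plausible Illumina length")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "mixture": {
                "maternal_genotype": format_genotype(self.mixture.maternal_genotype),
                "fetal_genotype": format_genotype(self.mixture.fetal_genotype),
                "maternal_weight": str(self.mixture.maternal_weight),
                "fetal_weight": str(self.mixture.fetal_weight),
            },
            "molecules_per_group": self.molecules_per_group,
            "duplication_mean": self.duplication_mean,
            "substitution_error_rate": self.substitution_error_rate,
            "pcr_error_rate": self.pcr_error_rate,
            "umi_mode": self.umi_mode,
            "read_length": self.read_length,
            "amplification_bias": dict(self.amplification_bias)
            if self.amplification_bias
            else None,
        }


@dataclass(frozen=True)
class ReadProvenance:
    """Where one emitted read pair came from."""

    read_id: str
    molecule_id: int
    umi: str | None
    class_name: str
    duplicate_index: int
    pcr_error_offsets: tuple[int, ...]  # 1-based amplicon offsets
    read1_error_offsets: tuple[int, ...]
    read2_error_offsets: tuple[int, ...]


@dataclass
class GroundTruth:
    """True molecule counts and per-read provenance of a simulated run."""

    class_molecules: dict[str, int]
    provenance: list[ReadProvenance]
    umi_collisions: int
    mixture: MixtureSpec

    @property
    def n_reads(self) -> int:
        return len(self.provenance)

    def to_dict(self, include_provenance: bool = True) -> dict:
        d = {
            "class_molecules": dict(self.class_molecules),
            "n_reads": self.n_reads,
            "umi_collisions": self.umi_collisions,
            "mixture": {
                "maternal_genotype": format_genotype(self.mixture.maternal_genotype),
                "fetal_genotype": format_genotype(self.mixture.fetal_genotype),
                "maternal_weight": str(self.mixture.maternal_weight),
                "fetal_weight": str(self.mixture.fetal_weight),
            },
        }
        if include_provenance:
            d["provenance"] = [
                {
                    "read_id": p.read_id,
                    "molecule_id": p.molecule_id,
                    "umi": p.umi,
                    "class": p.class_name,
                    "duplicate_index": p.duplicate_index,
                    "pcr_error_offsets": list(p.pcr_error_offsets),
                    "read1_error_offsets": list(p.read1_error_offsets),
                    "read2_error_offsets": list(p.read2_error_offsets),
                }
                for p in self.provenance
            ]
        return d


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def make_synthetic_references(seed: int = 0) -> tuple[list[AmpliconRef], AlleleModel]:
    """Build the four synthetic reference amplicons and the allele model.

    Each group shares a random consensus; the members differ at exactly
    the diagnostic offsets. Genomic anchors place the diagnostic bases
    at their published hg19 coordinates (the *RHCE* amplicon runs on the
    minus strand, where genomic coordinates descend along the amplicon).
    """
    rng = np.random.default_rng(seed)

    box = _random_seq(rng, 105).copy()
    box_off = 53  # interior: outside primer footprints 1-20 / 81-105
    box_site = {"upstream_box": "G", "downstream_box": "A"}
    up_seq, down_seq = box.copy(), box.copy()
    up_seq[box_off - 1] = ord("G")
    down_seq[box_off - 1] = ord("A")

    ex9 = _random_seq(rng, 148).copy()
    # paralog-diagnostic offsets and the c.1227 variant offset; the
    # 34/62-base spacings match the published hg19 coordinate spacings.
    off1, offc, off2 = 23, 57, 119
    rhd_seq, rhce_seq = ex9.copy(), ex9.copy()
    for off, rhd_b, rhce_b in ((off1, "A", "T"), (offc, "G", "C"), (off2, "A", "G")):
        rhd_seq[off - 1] = ord(rhd_b)
        rhce_seq[off - 1] = ord(rhce_b)

    site1 = {"RHD": "A", "RHCE": "T"}
    sitec = {"RHD_wt": "G", "RHD_var": "A", "RHCE": "C"}
    site2 = {"RHD": "A", "RHCE": "G"}

    def mk(name, group, seq, start, strand, sites):
        from .reference_model import PRIMER_SPANS

        return AmpliconRef(
            name=name,
            group=group,
            sequence=seq.tobytes().decode(),
            primer_spans=PRIMER_SPANS[group],
            genomic_start=start,
            strand=strand,
            diagnostic_sites=tuple(
                DiagnosticSite(off, pos, dict(bases)) for off, pos, bases in sites
            ),
        )

    refs = [
        mk(
            "upstream_box",
            "rhesus_box",
            up_seq,
            25_592_628 - box_off + 1,
            "+",
            [(box_off, 25_592_628, box_site)],
        ),
        mk(
            "downstream_box",
            "rhesus_box",
            down_seq,
            25_662_955 - box_off + 1,
            "+",
            [(box_off, 25_662_955, box_site)],
        ),
        mk(
            "RHD_exon9",
            "exon9",
            rhd_seq,
            25_648_419 - off1 + 1,
            "+",
            [
                (off1, 25_648_419, site1),
                (offc, 25_648_453, sitec),
                (off2, 25_648_515, site2),
            ],
        ),
        mk(
            "RHCE_exon9",
            "exon9",
            rhce_seq,
            25_696_992 + off1 - 1,
            "-",
            [
                (off1, 25_696_992, site1),
                (offc, 25_696_958, sitec),
                (off2, 25_696_896, site2),
            ],
        ),
    ]
    from .reference_model import validate_references

    validate_references(refs)
    return refs, AlleleModel.default()


def _class_templates(refs: Sequence[AmpliconRef]) -> dict[str, str]:
    roles = infer_roles(refs)
    rhd = roles["RHD_exon9"]
    c1227 = next(s for s in rhd.diagnostic_sites if s.is_c1227)
    var_seq = (
        rhd.sequence[: c1227.amplicon_offset - 1]
        + c1227.expected_base_by_source["RHD_var"]
        + rhd.sequence[c1227.amplicon_offset :]
    )
    return {
        "upstream_box": roles["upstream_box"].sequence,
        "downstream_box": roles["downstream_box"].sequence,
        "RHD_wt": rhd.sequence,
        "RHD_var": var_seq,
        "RHCE": roles["RHCE_exon9"].sequence,
    }


def _class_probs(
    config: SimConfig, model: AlleleModel
) -> dict[str, list[float]]:
    exp = expected_ratios(config.mixture, model)
    frac_by_class = {
        "upstream_box": exp["upstream_frac"],
        "downstream_box": exp["downstream_frac"],
        "RHD_wt": exp["RHD_wt_frac"],
        "RHD_var": exp["RHD_var_frac"],
        "RHCE": exp["RHCE_frac"],
    }
    bias = config.amplification_bias or {}
    out: dict[str, list[float]] = {}
    for group, classes in GROUP_CLASSES.items():
        weights = [
            float(frac_by_class[c]) * float(bias.get(c, 1.0)) for c in classes
        ]
        total = sum(weights)
        if total <= 0:
            raise ValueError(f"group {group}: all class probabilities are zero")
        out[group] = [w / total for w in weights]
    return out


def _mutate(
    rng: np.random.Generator, seq_bytes: bytearray, start: int, end: int, rate: float
) -> tuple[int, ...]:
    """Substitute bases in seq_bytes[start:end] at the given per-base rate.

    Returns the 0-based positions (relative to ``start``) that were hit.
    """
    n = end - start
    if n <= 0 or rate <= 0:
        return ()
    k = rng.binomial(n, rate)
    if k == 0:
        return ()
    positions = rng.choice(n, size=k, replace=False)
    for pos in positions:
        old = seq_bytes[start + pos]
        choices = [b for b in b"ACGT" if b != old]
        seq_bytes[start + pos] = choices[rng.integers(0, 3)]
    return tuple(int(p) for p in sorted(positions))


def _qual_string(rng: np.random.Generator, length: int) -> str:
    q = np.clip(np.rint(rng.normal(35.0, 3.0, size=length)), 2, 40).astype(np.uint8)
    return (q + 33).tobytes().decode()


def simulate_reads(
    config: SimConfig,
    refs: Sequence[AmpliconRef],
    model: AlleleModel | None = None,
) -> tuple[list[ReadPair], GroundTruth]:
    """Generate paired-end reads for one run, with full ground truth.

    Molecules are drawn per group from the closed-form expected class
    fractions (optionally reweighted by the amplification bias), each
    molecule receives a unique random UMI (collisions are permitted and
    recorded), a geometric number of PCR duplicates, template-level PCR
    errors per duplicate, and independent per-read sequencing errors
    within the amplicon-derived bases. Reads are padded to
    ``read_length`` with read-through adaptor sequence and G fill.
    """
    model = model or AlleleModel.default()
    rng = np.random.default_rng(config.seed)
    templates = _class_templates(refs)
    probs = _class_probs(config, model)
    rl = config.read_length

    pairs: list[ReadPair] = []
    provenance: list[ReadProvenance] = []
    class_molecules: dict[str, int] = {c: 0 for cs in GROUP_CLASSES.values() for c in cs}
    seen_umis: set[str] = set()
    umi_collisions = 0
    p_geom = 1.0 / config.duplication_mean
    mol_id = 0

    for group, classes in GROUP_CLASSES.items():
        counts = rng.multinomial(config.molecules_per_group, probs[group])
        for cls, n_mol in zip(classes, counts):
            class_molecules[cls] += int(n_mol)
            template = templates[cls]
            lt = len(template)
            for _ in range(n_mol):
                mol_id += 1
                umi = None
                if config.umi_mode:
                    umi = _BASES[rng.integers(0, 4, size=12)].tobytes().decode()
                    if umi in seen_umis:
                        umi_collisions += 1
                    seen_umis.add(umi)
                n_dup = (
                    int(rng.geometric(p_geom)) if config.duplication_mean > 1 else 1
                )
                prefix = umi or ""
                for dup in range(n_dup):
                    tmpl = bytearray(template.encode())
                    pcr_hits = _mutate(rng, tmpl, 0, lt, config.pcr_error_rate)
                    molecule = prefix + tmpl.decode()
                    lm = len(molecule)

                    r1 = bytearray(molecule[:rl].encode())
                    n1 = len(r1)  # amplicon-derived bases in read 1
                    e1 = _mutate(rng, r1, 0, n1, config.substitution_error_rate)
                    r1_seq = r1.decode()
                    if n1 < rl:
                        fill = DEFAULT_ADAPTOR_R1 + "G" * rl
                        r1_seq += fill[: rl - n1]

                    rc = reverse_complement(molecule)
                    r2 = bytearray(rc[:rl].encode())
                    n2 = len(r2)
                    e2 = _mutate(rng, r2, 0, n2, config.substitution_error_rate)
                    r2_seq = r2.decode()
                    if n2 < rl:
                        fill = DEFAULT_ADAPTOR_R2 + "G" * rl
                        r2_seq += fill[: rl - n2]

                    read_id = f"sim:{cls}:{mol_id}:{dup}"
                    pairs.append(
                        ReadPair(
                            id=read_id,
                            read1_seq=r1_seq,
                            read1_quals=_qual_string(rng, rl),
                            read2_seq=r2_seq,
                            read2_quals=_qual_string(rng, rl),
                        )
                    )
                    provenance.append(
                        ReadProvenance(
                            read_id=read_id,
                            molecule_id=mol_id,
                            umi=umi,
                            class_name=cls,
                            duplicate_index=dup,
                            pcr_error_offsets=tuple(p + 1 for p in pcr_hits),
                            read1_error_offsets=tuple(p + 1 for p in e1),
                            read2_error_offsets=tuple(p + 1 for p in e2),
                        )
                    )

    truth = GroundTruth(
        class_molecules=class_molecules,
        provenance=provenance,
        umi_collisions=umi_collisions,
        mixture=config.mixture,
    )
    return pairs, truth


def simulate_twelve_panel(base_config: SimConfig) -> list[tuple[str, SimConfig]]:
    """Enumerate the 3 x 4 genotype-mixture validation panel.

    "A" (the mother analog) ranges over the three common RhD-negative
    genotypes; "B" (the fetus analog) over the RhD-positive
    *RHD\\*01*/*RHD\\*01N.01* genotype plus the same three negatives, at
    the base config's 10:1 weights. Returns (run name, config) pairs
    with per-run seeds derived deterministically from the base seed.
    """
    runs: list[tuple[str, SimConfig]] = []
    idx = 0
    for a in RHD_NEGATIVE_MATERNAL_GENOTYPES:
        for b in TWELVE_PANEL_FETAL_GENOTYPES:
            idx += 1
            mixture = MixtureSpec(
                maternal_genotype=a,
                fetal_genotype=b,
                maternal_weight=base_config.mixture.maternal_weight,
                fetal_weight=base_config.mixture.fetal_weight,
            )
            name = f"run{idx:02d}_A_{format_genotype(a)}_B_{format_genotype(b)}"
            name = name.replace("*", "x").replace("/", "-")
            runs.append(
                (
                    name,
                    replace(
                        base_config,
                        seed=(base_config.seed * 100 + idx) % (2**31),
                        mixture=mixture,
                    ),
                )
            )
    return runs


def write_reference_spec(
    refs: Sequence[AmpliconRef], fasta_path: str | Path, meta_path: str | Path
) -> None:
    """Serialize references to the FASTA + JSON interchange format."""
    with open(fasta_path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.name}\n{ref.sequence}\n")
    meta = [
        {
            "name": ref.name,
            "group": ref.group,
            "primer_spans": [list(s) for s in ref.primer_spans],
            "genomic_start": ref.genomic_start,
            "strand": ref.strand,
            "diagnostic_sites": [
                {
                    "amplicon_offset": s.amplicon_offset,
                    "genomic_pos": s.genomic_pos,
                    "expected_base_by_source": dict(s.expected_base_by_source),
                }
                for s in ref.diagnostic_sites
            ],
        }
        for ref in refs
    ]
    Path(meta_path).write_text(json.dumps(meta, indent=2) + "\n")


def write_run(
    config: SimConfig,
    refs: Sequence[AmpliconRef],
    out_dir: str | Path,
    model: AlleleModel | None = None,
    include_provenance: bool = True,
    gzip_fastq: bool = False,
) -> GroundTruth:
    """Simulate one run and write its artifacts to a directory.

    Writes reads_R1/R2.fastq(.gz), refs.fasta + refs.json, truth.json
    and sim_config.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs, truth = simulate_reads(config, refs, model)
    ext = ".fastq.gz" if gzip_fastq else ".fastq"
    fastq.write_read_pairs(pairs, out / f"reads_R1{ext}", out / f"reads_R2{ext}")
    write_reference_spec(refs, out / "refs.fasta", out / "refs.json")
    (out / "truth.json").write_text(
        json.dumps(truth.to_dict(include_provenance=include_provenance), indent=2) + "\n"
    )
    (out / "sim_config.json").write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    return truth
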