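"""Tests for the synthetic reference and read simulator."""

import json
import math
from collections import Counter
from fractions import Fraction

import pytest

from rhdamp import (
    FilterParams,
    MixtureSpec,
    SimConfig,
    dedup_umi,
    error_ratio_profile,
    make_synthetic_references,
    simulate_reads,
    simulate_twelve_panel,
    write_run,
)
from rhdamp.pipeline import classify_and_count, preprocess_pairs
from rhdamp.reference_model import infer_roles, validate_references

DEL = "RHD*01N.01"
WT = "RHD*01"


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestSyntheticReferences:
    @pytest.mark.parametrize("seed", [0, 1, 42])
    def test_structural_invariants_for_any_seed(self, seed):
        refs, _ = make_synthetic_references(seed)
        roles = validate_references(refs)  # raises on any violation
        assert set(roles) == {"upstream_box", "downstream_box", "RHD_exon9", "RHCE_exon9"}

    def test_box_references_differ_at_one_base(self, roles):
        assert (
            _hamming(roles["upstream_box"].sequence, roles["downstream_box"].sequence)
            == 1
        )

    def test_exon9_references_differ_at_paralog_and_variant_offsets(self, roles):
        rhd, rhce = roles["RHD_exon9"], roles["RHCE_exon9"]
        diff = {
            i + 1
            for i, (a, b) in enumerate(zip(rhd.sequence, rhce.sequence))
            if a != b
        }
        c1227 = next(s for s in rhd.diagnostic_sites if s.is_c1227)
        paralog = diff - {c1227.amplicon_offset}
        assert len(paralog) == 2  # two paralog-distinguishing bases
        assert c1227.amplicon_offset in diff

    def test_diagnostic_sites_at_published_coordinates(self, roles):
        coords = {
            s.genomic_pos
            for ref in roles.values()
            for s in ref.diagnostic_sites
        }
        assert {25_592_628, 25_662_955, 25_648_453, 25_696_958,
                25_648_419, 25_648_515, 25_696_992, 25_696_896} <= coords
        # each site's coordinate is consistent with the amplicon anchor
        for ref in roles.values():
            for s in ref.diagnostic_sites:
                assert ref.genomic_position(s.amplicon_offset) == s.genomic_pos


class TestSimulateReads:
    def test_same_seed_byte_identical_fastq(self, refs, model, tmp_path):
        config = SimConfig(seed=9, molecules_per_group=100, umi_mode=True)
        write_run(config, refs, tmp_path / "a", model)
        write_run(config, refs, tmp_path / "b", model)
        for name in ("reads_R1.fastq", "reads_R2.fastq", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_conservation_and_provenance_partition(self, refs, model):
        config = SimConfig(seed=2, molecules_per_group=200, duplication_mean=2.5)
        pairs, truth = simulate_reads(config, refs, model)
        assert len(pairs) == truth.n_reads
        assert len({p.read_id for p in truth.provenance}) == len(pairs)
        assert sum(truth.class_molecules.values()) == 2 * 200
        per_class = Counter(p.class_name for p in truth.provenance)
        dups_per_mol = Counter(p.molecule_id for p in truth.provenance)
        assert sum(dups_per_mol.values()) == len(pairs)
        for cls, n_mol in truth.class_molecules.items():
            mols = {p.molecule_id for p in truth.provenance if p.class_name == cls}
            assert len(mols) == n_mol

    def test_noise_free_run_recovers_truth_exactly(self, refs, model):
        config = SimConfig(
            seed=4,
            molecules_per_group=500,
            duplication_mean=1.0,
            substitution_error_rate=0.0,
            pcr_error_rate=0.0,
        )
        pairs, truth = simulate_reads(config, refs, model)
        reads, ledger, _ = preprocess_pairs(pairs, FilterParams())
        assert ledger["merge_rejected"] == 0
        _, matrices, _ = classify_and_count(reads, refs)
        from rhdamp import extract_diagnostics

        d = extract_diagnostics(matrices, refs)
        assert d.to_dict() == truth.class_molecules

    def test_dedup_recovers_molecule_count(self, refs, model):
        config = SimConfig(
            seed=6,
            molecules_per_group=400,
            duplication_mean=3.0,
            substitution_error_rate=0.0,
            pcr_error_rate=0.0,
            umi_mode=True,
        )
        pairs, truth = simulate_reads(config, refs, model)
        assert truth.umi_collisions == 0
        reads, _, _ = preprocess_pairs(pairs, FilterParams(umi_mode=True))
        molecules, stats = dedup_umi(reads)
        assert stats.unique_molecules == sum(truth.class_molecules.values())
        assert stats.duplicates_removed == len(pairs) - stats.unique_molecules

    def test_binomial_calibration_of_upstream_fraction(self, refs, model):
        config = SimConfig(
            seed=8,
            mixture=MixtureSpec((DEL, DEL), (WT, DEL)),
            molecules_per_group=20_000,
            duplication_mean=1.0,
            substitution_error_rate=0.0,
            pcr_error_rate=0.0,
        )
        pairs, truth = simulate_reads(config, refs, model)
        p = 1 / 23
        n = config.molecules_per_group
        se = math.sqrt(p * (1 - p) / n)
        assert truth.class_molecules["upstream_box"] / n == pytest.approx(p, abs=3 * se)
        assert truth.class_molecules["RHD_wt"] / n == pytest.approx(p, abs=3 * se)

    def test_median_error_ratio_matches_injected_rate(self, refs, model):
        # template-level errors at duplication 1 are the substitutions the
        # merged, counted reads can carry; the interior median must track them
        eps = 0.001
        config = SimConfig(
            seed=12,
            molecules_per_group=20_000,
            duplication_mean=1.0,
            substitution_error_rate=0.0,
            pcr_error_rate=eps,
        )
        pairs, _ = simulate_reads(config, refs, model)
        reads, _, _ = preprocess_pairs(pairs, FilterParams())
        _, matrices, _ = classify_and_count(reads, refs)
        for group in ("rhesus_box", "exon9"):
            profile = error_ratio_profile(matrices, refs, group)
            n = config.molecules_per_group  # pooled reads per position per group
            se = math.sqrt(eps * (1 - eps) / n)
            assert float(profile.median_ratio) == pytest.approx(eps, abs=3 * se)

    def test_umi_dedup_lowers_error_ratio(self, refs, model):
        config = SimConfig(
            seed=13,
            molecules_per_group=4_000,
            duplication_mean=3.0,
            substitution_error_rate=0.0,
            pcr_error_rate=0.001,
            umi_mode=True,
        )
        pairs, _ = simulate_reads(config, refs, model)
        reads, _, _ = preprocess_pairs(pairs, FilterParams(umi_mode=True))

        def interior_max(read_set):
            _, matrices, _ = classify_and_count(read_set, refs)
            return {
                g: error_ratio_profile(matrices, refs, g).median_ratio
                for g in ("rhesus_box", "exon9")
            }

        pre = interior_max(reads)
        molecules, _ = dedup_umi(reads)
        post = interior_max(molecules)
        for g in ("rhesus_box", "exon9"):
            assert post[g] < pre[g]

    def test_amplification_bias_shifts_class_fractions(self, refs, model):
        biased = SimConfig(
            seed=14,
            mixture=MixtureSpec((DEL, DEL), (DEL, DEL)),
            molecules_per_group=5_000,
            duplication_mean=1.0,
            amplification_bias={"RHCE": 4.0, "RHD_wt": 1.0},
        )
        _, truth = simulate_reads(biased, refs, model)
        # del/del mixture has only RHCE in exon9, so bias must not break totals
        assert truth.class_molecules["RHCE"] == 5_000

    def test_read_layout_umi_mode(self, refs, model):
        config = SimConfig(
            seed=15,
            molecules_per_group=20,
            duplication_mean=1.0,
            substitution_error_rate=0.0,
            pcr_error_rate=0.0,
            umi_mode=True,
        )
        pairs, truth = simulate_reads(config, refs, model)
        templates = {r.name: r.sequence for r in refs}
        by_id = {p.read_id: p for p in truth.provenance}
        for pair in pairs:
            prov = by_id[pair.id]
            assert len(pair.read1_seq) == 151
            assert pair.read1_seq.startswith(prov.umi)


class TestTwelvePanel:
    def test_panel_structure(self):
        base = SimConfig(seed=1, molecules_per_group=10)
        runs = simulate_twelve_panel(base)
        assert len(runs) == 12
        names = [name for name, _ in runs]
        assert len(set(names)) == 12
        positives = [
            cfg for _, cfg in runs if "RHD*01" in cfg.mixture.fetal_genotype
        ]
        assert len(positives) == 3
        mothers = {cfg.mixture.maternal_genotype for _, cfg in runs}
        assert len(mothers) == 3
        seeds = {cfg.seed for _, cfg in runs}
        assert len(seeds) == 12  # per-run seeds are distinct
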