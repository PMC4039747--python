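"""Generator honesty: determinism, planted structure, dosage and depth laws."""

import dataclasses

import numpy as np
import pytest

from balscan.callset_io import read_calls
from balscan.errors import ValidationError
from balscan.genome_model import extract_cds, translate_cds
from balscan.strain_qc import ems_spectrum
from balscan.strain_simulator import (
    SimulationParams,
    SimVariant,
    StrainTruth,
    read_truth,
    sample_reads,
    simulate_parental,
    simulate_reference,
    simulate_strain,
    write_strain,
)

SMALL = SimulationParams(
    chromosome_length=1_500_000,
    dup_end=730_000,
    n_genes=60,
    parental_snvs=80,
    parental_indels=20,
    seed=5,
)


class TestReference:
    def test_deterministic_under_fixed_seed(self):
        a = simulate_reference(SMALL)
        b = simulate_reference(SMALL)
        assert a.genome.sequences == b.genome.sequences
        assert a.genes == b.genes
        assert a.essential_ids == b.essential_ids

    def test_gene_structure_is_frame_safe_and_translatable(self, reference):
        for gene in reference.genes[:40]:
            assert gene.cds_length % 3 == 0
            protein = translate_cds(extract_cds(gene, reference.genome))
            assert protein[0] == "M"
            assert protein[-1] == "*"
            assert "*" not in protein[:-1]

    def test_no_genes_degenerate_case(self):
        params = dataclasses.replace(SMALL, n_genes=0)
        ref = simulate_reference(params)
        assert ref.genes == []
        assert len(ref.genome.sequences[params.chromosome]) == params.chromosome_length

    def test_marker_geometry(self, reference):
        dup_s, dup_e = reference.balancer.dup_interval
        inside, outside = reference.balancer.markers
        assert dup_s <= inside.position < dup_e
        assert (inside.copies_mutant, inside.copies_total) == (2, 3)
        assert outside.position >= dup_e
        assert (outside.copies_mutant, outside.copies_total) == (2, 2)
        assert len(reference.balancer.zones) == 60

    def test_zones_tile_the_duplication(self, reference):
        zones = reference.balancer.zones
        assert zones[0].interval[0] == 0
        assert zones[-1].interval[1] == reference.balancer.dup_interval[1]
        for z0, z1 in zip(zones, zones[1:]):
            assert z0.interval[1] == z1.interval[0]


class TestParental:
    def test_default_background_load(self, parental):
        assert sum(v.kind == "SNV" for v in parental) == 571
        assert sum(v.kind != "SNV" for v in parental) == 167
        assert all(v.origin == "parental" for v in parental)
        assert all(1 <= abs(len(v.ref) - len(v.alt)) <= 2 for v in parental if v.kind != "SNV")

    def test_zero_snvs_requested(self):
        ref = simulate_reference(SMALL)
        params = dataclasses.replace(SMALL, parental_snvs=0, parental_indels=3)
        out = simulate_parental(ref.genome, params)
        assert sum(v.kind == "SNV" for v in out) == 0
        assert len(out) == 3

    def test_different_seeds_place_different_positions(self):
        ref = simulate_reference(SMALL)
        a = simulate_parental(ref.genome, SMALL, seed=1)
        b = simulate_parental(ref.genome, SMALL, seed=2)
        assert {v.position for v in a} != {v.position for v in b}


class TestStrain:
    def test_nonsense_causal_truncates_the_translated_protein(self, reference, parental, default_params):
        truth = simulate_strain(reference, parental, default_params, seed=11)
        causal = truth.causal
        assert causal is not None and causal.category == "nonsense"
        gene = next(g for g in reference.genes if g.gene_id == causal.gene_id)
        assert gene.gene_id in reference.essential_ids
        seq = reference.genome.sequences[causal.chromosome]
        mutated = reference.genome.sequences.copy()
        mutated[causal.chromosome] = (
            seq[: causal.position] + causal.alt + seq[causal.position + 1 :]
        )
        from balscan.genome_model import Genome

        ref_protein = translate_cds(extract_cds(gene, reference.genome))
        alt_protein = translate_cds(extract_cds(gene, Genome(mutated)))
        assert "*" in alt_protein[:-1]
        assert len(alt_protein) == len(ref_protein)

    def test_splice_causal_hits_an_intron_end(self, reference, parental, default_params):
        params = dataclasses.replace(default_params, causal_class="splice")
        truth = simulate_strain(reference, parental, params, seed=12)
        causal = truth.causal
        gene = next(g for g in reference.genes if g.gene_id == causal.gene_id)
        assert causal.position in gene.splice_positions()

    def test_indel_causal_is_a_frameshift_deletion_in_cds(self, reference, parental, default_params):
        params = dataclasses.replace(default_params, causal_class="indel")
        truth = simulate_strain(reference, parental, params, seed=13)
        causal = truth.causal
        gene = next(g for g in reference.genes if g.gene_id == causal.gene_id)
        deleted = len(causal.ref) - len(causal.alt)
        assert deleted in (1, 2)
        assert all(gene.contains_cds(p) for p in range(causal.position + 1, causal.position + 1 + deleted))

    def test_unbalanced_strain_has_no_causal_and_homozygous_markers(
        self, reference, parental, default_params
    ):
        truth = simulate_strain(
            reference, parental, default_params, seed=14, has_duplication=False
        )
        assert truth.causal is None
        assert all(state == (2, 2) for state in truth.marker_states.values())
        assert all(v.copies_mut == v.copies_total for v in truth.variants)

    def test_causal_always_at_two_of_three_dosage(self, reference, parental, default_params):
        for seed in (21, 22, 23):
            truth = simulate_strain(reference, parental, default_params, seed=seed)
            assert (truth.causal.copies_mut, truth.causal.copies_total) == (2, 3)
            assert truth.causal.position < reference.balancer.dup_interval[1]

    def test_ems_spectrum_recovers_the_transition_fraction(self, reference, parental):
        params = dataclasses.replace(
            SimulationParams(seed=7), strain_snvs_mean=1000.0, strain_indels_mean=0.0
        )
        truth = simulate_strain(reference, parental, params, seed=31)
        ems = [v for v in truth.variants if v.origin == "ems"]
        from balscan.callset_io import VariantCall

        spectrum = ems_spectrum(
            [VariantCall(v.chromosome, v.position, v.ref, v.alt, 10, 10) for v in ems]
        )
        assert spectrum.transition_fraction == pytest.approx(0.9, abs=0.03)


class TestReadSampling:
    def test_balanced_allele_fraction_converges_to_two_thirds(self):
        variants = [
            SimVariant("chrI", p, "A", "G", 2, 3, "ems") for p in range(0, 100_000, 10)
        ]
        truth = StrainTruth(
            "s", True, variants, None, frozenset(), {}, None, "chrI", 200_000, (0, 150_000)
        )
        calls, _ = sample_reads(truth, coverage=30, seed=3)
        ratios = [c.alt_count / c.depth for c in calls if c.depth > 0]
        assert np.mean(ratios) == pytest.approx(2 / 3, abs=0.01)

    def test_reference_dosage_site_never_shows_alt_reads(self):
        variants = [SimVariant("chrI", p, "A", "G", 0, 2, "ems") for p in range(100)]
        truth = StrainTruth(
            "s", False, variants, None, frozenset(), {}, None, "chrI", 10_000, (0, 5_000)
        )
        calls, _ = sample_reads(truth, coverage=30, seed=4)
        assert all(c.alt_count == 0 for c in calls)

    def test_depth_ratio_reflects_copy_number(self, reference, parental, default_params):
        truth = simulate_strain(reference, parental, default_params, seed=41)
        _, track = sample_reads(truth, coverage=30, seed=42)
        dup_s, dup_e = truth.dup_interval
        inside = track.mean_depth("chrI", dup_s, dup_e)
        outside = track.mean_depth("chrI", dup_e, truth.chromosome_length)
        assert inside / outside == pytest.approx(1.5, abs=0.02)

        flat = simulate_strain(
            reference, parental, default_params, seed=43, has_duplication=False
        )
        _, flat_track = sample_reads(flat, coverage=30, seed=44)
        assert flat_track.mean_depth("chrI", dup_s, dup_e) / flat_track.mean_depth(
            "chrI", dup_e, truth.chromosome_length
        ) == pytest.approx(1.0, abs=0.02)

    def test_invalid_coverage_rejected(self, reference, parental, default_params):
        truth = simulate_strain(reference, parental, default_params, seed=45)
        with pytest.raises(ValidationError):
            sample_reads(truth, coverage=0, seed=1)

    def test_sampling_is_deterministic(self, reference, parental, default_params):
        truth = simulate_strain(reference, parental, default_params, seed=46)
        a_calls, a_track = sample_reads(truth, coverage=30, seed=47)
        b_calls, b_track = sample_reads(truth, coverage=30, seed=47)
        assert a_calls == b_calls
        assert a_track.windows == b_track.windows


class TestStrainArtifacts:
    def test_vcf_and_truth_round_trip(self, tmp_path, reference, parental, default_params):
        truth = simulate_strain(
            reference, parental, default_params, seed=51, strain_id="s51"
        )
        calls, track = sample_reads(truth, coverage=30, seed=52)
        paths = write_strain(truth, calls, track, tmp_path)
        loaded = read_calls(paths["vcf"])
        assert sorted(c.key for c in loaded) == sorted(c.key for c in calls)
        assert {c.key: (c.ref_count, c.alt_count) for c in loaded} == {
            c.key: (c.ref_count, c.alt_count) for c in calls
        }
        # VCF is 1-based on disk
        line = next(
            l for l in paths["vcf"].read_text().splitlines() if not l.startswith("#")
        )
        first = sorted(calls, key=lambda c: c.position)[0]
        assert int(line.split("\t")[1]) == first.position + 1

        truth_back = read_truth(paths["truth"])
        assert truth_back.causal == truth.causal
        assert sum(v.origin == "causal" for v in truth_back.variants) == 1
        assert truth_back.zone_id == truth.zone_id
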