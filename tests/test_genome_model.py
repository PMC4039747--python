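"""Genome/gene-model representation: I/O round trips, CDS extraction, translation."""

import pytest

from balscan.errors import FormatError, ValidationError
from balscan.genome_model import (
    GeneModel,
    Genome,
    extract_cds,
    load_gene_models,
    load_genome,
    load_markers,
    load_zones,
    translate_cds,
    write_gene_models,
    write_genome,
    write_markers,
    write_zones,
)


class TestGenomeIO:
    def test_fasta_round_trip(self, tmp_path, toy_genome):
        path = tmp_path / "g.fa"
        write_genome(toy_genome, path)
        assert load_genome(path).sequences == toy_genome.sequences

    def test_lowercase_input_is_uppercased(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chrI\nacgt\n")
        genome = load_genome(path)
        assert genome.sequences["chrI"] == "ACGT"
        assert genome.lengths == {"chrI": 4}

    def test_empty_file_is_a_format_error(self, tmp_path):
        path = tmp_path / "empty.fa"
        path.write_text("")
        with pytest.raises(FormatError):
            load_genome(path)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValidationError):
            Genome({"chrI": "ACGU"})
        with pytest.raises(ValidationError):
            Genome({"chrI": ""})


class TestGeneModels:
    def test_two_cds_lines_make_one_gene_with_intron(self, tmp_path):
        path = tmp_path / "m.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chrI\tsrc\tgene\t101\t260\t.\t+\t.\tID=g1\n"
            "chrI\tsrc\tCDS\t101\t160\t.\t+\t0\tID=g1.c1;Parent=g1\n"
            "chrI\tsrc\tCDS\t201\t260\t.\t+\t0\tID=g1.c2;Parent=g1\n"
        )
        (gene,) = load_gene_models(path)
        assert gene.cds_segments == ((100, 160), (200, 260))
        assert gene.introns == ((160, 200),)
        assert gene.cds_length == 120

    def test_minus_strand_segments_stay_in_genomic_order(self, tmp_path):
        path = tmp_path / "m.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chrI\tsrc\tCDS\t201\t260\t.\t-\t0\tID=g1.c2;Parent=g1\n"
            "chrI\tsrc\tCDS\t101\t160\t.\t-\t0\tID=g1.c1;Parent=g1\n"
        )
        (gene,) = load_gene_models(path)
        assert gene.strand == "-"
        assert gene.cds_segments == ((100, 160), (200, 260))

    def test_gff3_round_trip(self, tmp_path, toy_genes):
        path = tmp_path / "rt.gff3"
        write_gene_models(toy_genes, path)
        loaded = load_gene_models(path)
        assert sorted(loaded, key=lambda g: g.gene_id) == sorted(
            toy_genes, key=lambda g: g.gene_id
        )

    def test_cds_without_gene_attribute_is_a_format_error(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("##gff-version 3\nchrI\tsrc\tCDS\t101\t160\t.\t+\t0\tID=orphan\n")
        with pytest.raises(FormatError):
            load_gene_models(path)

    def test_overlapping_cds_within_gene_rejected(self, tmp_path):
        path = tmp_path / "ovl.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chrI\tsrc\tCDS\t101\t160\t.\t+\t0\tParent=g1\n"
            "chrI\tsrc\tCDS\t150\t200\t.\t+\t0\tParent=g1\n"
        )
        with pytest.raises(ValidationError):
            load_gene_models(path)

    def test_coding_offset_roundtrips_with_genomic_position(self, toy_genes):
        for gene in toy_genes:
            for offset in range(gene.cds_length):
                pos = gene.genomic_position(offset)
                assert gene.coding_offset(pos) == offset


class TestExtractTranslate:
    def test_plus_strand_extraction_spells_the_coding_sequence(self, toy_genome, toy_genes):
        from conftest import TOY_CODING

        gene = next(g for g in toy_genes if g.strand == "+")
        assert extract_cds(gene, toy_genome) == TOY_CODING

    def test_minus_strand_extraction_reverse_complements(self, toy_genome, toy_genes):
        from conftest import TOY_CODING

        gene = next(g for g in toy_genes if g.strand == "-")
        assert extract_cds(gene, toy_genome) == TOY_CODING

    def test_multi_segment_extraction_skips_intron_bases(self, toy_genome, toy_genes):
        gene = toy_genes[0]
        assert len(extract_cds(gene, toy_genome)) == gene.cds_length

    @pytest.mark.parametrize(
        "cds,protein", [("ATGCAATAA", "MQ*"), ("TGG", "W"), ("ATGGCC", "MA")]
    )
    def test_translation_examples(self, cds, protein):
        assert translate_cds(cds) == protein

    def test_partial_codon_rejected(self):
        with pytest.raises(ValidationError):
            translate_cds("ATGC")

    def test_all_64_codons_match_the_standard_genetic_code(self):
        # frozen copy of the standard (NCBI table 1) genetic code
        published = {
            "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
            "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
            "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
            "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
            "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
            "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
            "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
            "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
            "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
            "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
            "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
            "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
            "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
            "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
            "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
            "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
        }
        assert len(published) == 64
        for codon, aa in published.items():
            assert translate_cds(codon) == aa

    def test_translated_length_is_cds_length_over_three(self, toy_genome, toy_genes):
        for gene in toy_genes:
            protein = translate_cds(extract_cds(gene, toy_genome))
            assert len(protein) == gene.cds_length // 3


class TestZoneMarkerIO:
    def test_zone_tsv_round_trip(self, tmp_path, reference):
        path = tmp_path / "zones.tsv"
        zones = reference.balancer.zones
        write_zones(zones, reference.balancer.chromosome, path)
        assert load_zones(path) == zones

    def test_marker_tsv_round_trip(self, tmp_path, reference):
        path = tmp_path / "markers.tsv"
        write_markers(reference.balancer.markers, path)
        assert load_markers(path) == reference.balancer.markers
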