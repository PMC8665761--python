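"""Variant graph construction, aligned positions and MSA emission."""

import numpy as np
import pytest

import founderpan as fp
from founderpan.errors import (
    OverlappingVariantError,
    ReferenceMismatchError,
    UnphasedGenotypeError,
    UnsupportedAlleleError,
)
from founderpan.msa_graph import REFERENCE_LABEL, VariantRecordLite

from oracles import (
    exhaustive_aligned_positions,
    random_nonoverlapping_variants,
    random_sequence,
    splice_haplotype,
)


class TestGraphConstruction:
    def test_worked_example_nodes_and_alt_edges(self, table1_graph):
        assert table1_graph.nodes == [1, 2, 4, 5, 6, 7, 12, 16, 17, 18, 19]
        alt = {(e.source, e.target, e.label) for e in table1_graph.alt_edges}
        assert alt == {
            (1, 2, "TAA"),
            (4, 7, "AAAAAA"),
            (5, 6, "CC"),
            (12, 17, "T"),
            (16, 18, "T"),
            (16, 18, "A"),
        }

    def test_reference_edges_concatenate_to_reference(self, table1_graph, table1):
        labels = [
            table1_graph.ref_edges[q].label for q in table1_graph.nodes[:-1]
        ]
        assert "".join(labels) == table1.reference

    def test_no_variants_single_reference_edge(self):
        g = fp.build_variant_graph("ACGT", [])
        assert g.nodes == [1, 5]
        assert g.ref_edges[1].label == "ACGT"
        assert g.width == 4

    def test_single_snp_nodes(self):
        v = VariantRecordLite(2, "C", ("G",), {"s": 1})
        g = fp.build_variant_graph("ACGT", [v])
        assert g.nodes == [1, 2, 3, 5]
        assert any(
            (e.source, e.target, e.label) == (2, 3, "G") for e in g.alt_edges
        )

    def test_duplicate_alt_edges_merged(self):
        v1 = VariantRecordLite(2, "C", ("G",), {"a": 1}, id="x")
        v2 = VariantRecordLite(2, "C", ("G",), {"b": 1}, id="y")
        g = fp.build_variant_graph("ACGT", [v1, v2])
        assert len(g.alt_edges) == 1

    def test_variant_past_reference_end_rejected(self):
        v = VariantRecordLite(4, "TA", ("G",), {"s": 1})
        with pytest.raises(Exception):
            fp.build_variant_graph("ACGT", [v])

    def test_node_count_bound(self):
        rng = np.random.default_rng(0)
        ref = random_sequence(rng, 120)
        variants = random_nonoverlapping_variants(rng, ref, 15, ["s1", "s2"])
        g = fp.build_variant_graph(ref, variants)
        assert len(g.nodes) <= 2 * len(variants) + 2


class TestAlignedPositions:
    def test_worked_example_values(self, table1_graph):
        assert table1_graph.aligned_pos == {
            1: 1, 2: 4, 4: 6, 5: 7, 6: 9, 7: 12,
            12: 17, 16: 21, 17: 22, 18: 23, 19: 24,
        }
        assert table1_graph.width == 23

    def test_no_variants_identity(self):
        g = fp.build_variant_graph("ACGTACGT", [])
        assert g.aligned_pos[9] == 9

    def test_single_insertion_widens_by_inserted_length(self):
        v = VariantRecordLite(3, "G", ("GAAAA",), {"s": 1})
        g = fp.build_variant_graph("ACGT", [v])
        assert g.width == 4 + 4

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_longest_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_sequence(rng, 60)
        variants = random_nonoverlapping_variants(rng, ref, 8, ["s1", "s2", "s3"])
        g = fp.build_variant_graph(ref, variants)
        assert g.aligned_pos == exhaustive_aligned_positions(g)


class TestHaplotypeSequences:
    def test_worked_example_haplotypes(self, table1, table1_graph):
        for s in table1.samples:
            assert (
                fp.haplotype_sequence(table1_graph, table1.records, s)
                == table1.haplotypes[s]
            )

    def test_reference_path_uses_reference_edges_only(self, table1, table1_graph):
        path = fp.haplotype_paths(table1_graph, table1.records, [])[REFERENCE_LABEL]
        assert all(e.kind == "reference" for e in path)
        assert "".join(e.label for e in path) == table1.reference

    def test_overlapping_variants_error_names_records(self):
        ref = "ACGTACGT"
        v1 = VariantRecordLite(2, "CGT", ("A",), {"s": 1}, id="first")
        v2 = VariantRecordLite(3, "G", ("T",), {"s": 1}, id="second")
        g = fp.build_variant_graph(ref, [v1, v2])
        with pytest.raises(OverlappingVariantError, match="first.*second"):
            fp.haplotype_sequence(g, [v1, v2], "s")

    def test_overlapping_variants_drop_flag_keeps_earlier(self):
        ref = "ACGTACGT"
        v1 = VariantRecordLite(2, "CGT", ("A",), {"s": 1}, id="first")
        v2 = VariantRecordLite(3, "G", ("T",), {"s": 1}, id="second")
        g = fp.build_variant_graph(ref, [v1, v2])
        with pytest.warns(UserWarning, match="second"):
            seq = fp.haplotype_sequence(g, [v1, v2], "s", drop_overlaps=True)
        assert seq == "AAACGT"


class TestMSAEmission:
    def test_worked_example_rows(self, table1, table1_graph):
        msa = fp.emit_msa(table1_graph, table1.records, table1.samples)
        assert msa.rows[0] == "T--TCTG-G--GAGGCAGTTACC"
        assert msa.row("s3") == "TAATCTCCG--GAGGCAGTTA-C"
        assert msa.width == 23

    def test_rows_equal_width_and_ungap_to_haplotypes(self, table1, table1_graph):
        msa = fp.emit_msa(table1_graph, table1.records, table1.samples)
        assert {len(r) for r in msa.rows} == {msa.width}
        assert msa.ungapped(0) == table1.reference
        for s in table1.samples:
            assert msa.row(s).replace("-", "") == table1.haplotypes[s]

    def test_no_variants_msa_is_reference(self):
        g = fp.build_variant_graph("ACGT", [])
        msa = fp.emit_msa(g, [], [])
        assert msa.rows == ["ACGT"]

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_matches_splice_oracle(self, seed):
        """Ungapped MSA rows equal direct variant application for random
        non-overlapping VCF-style inputs."""
        rng = np.random.default_rng(100 + seed)
        ref = random_sequence(rng, 150)
        samples = [f"s{i}" for i in range(4)]
        variants = random_nonoverlapping_variants(rng, ref, 20, samples)
        g = fp.build_variant_graph(ref, variants)
        msa = fp.emit_msa(g, variants, samples)
        assert msa.ungapped(0) == ref
        for s in samples:
            assert msa.row(s).replace("-", "") == splice_haplotype(
                ref, variants, s
            )

    def test_gapped_fasta_round_trip(self, table1, table1_graph, tmp_path):
        msa = fp.emit_msa(table1_graph, table1.records, table1.samples)
        path = str(tmp_path / "msa.fa")
        msa.write_fasta(path)
        back = fp.ReferenceGuidedMSA.read_fasta(path)
        assert back.labels == msa.labels
        assert back.rows == msa.rows

    def test_column_position_maps(self, table1, table1_graph):
        msa = fp.emit_msa(table1_graph, table1.records, table1.samples)
        row = 0
        assert msa.column_of(row, 2) == 4  # second base of "T--TC..."
        for pos in range(1, len(table1.reference) + 1):
            col = msa.column_of(row, pos)
            assert msa.position_of(row, col) == pos
        with pytest.raises(IndexError):
            msa.column_of(row, len(table1.reference) + 1)


class TestVCFReading:
    def _write_inputs(self, tmp_path, table1):
        vcf = str(tmp_path / "t.vcf")
        fasta = str(tmp_path / "ref.fa")
        table1.write_vcf(vcf)
        table1.write_reference_fasta(fasta)
        return vcf, fasta

    def test_worked_example_round_trip(self, tmp_path, table1):
        vcf, fasta = self._write_inputs(tmp_path, table1)
        ref, variants, labels = fp.read_vcf_haplotypes(vcf, "ref", fasta)
        assert ref == table1.reference
        assert labels == table1.samples
        assert len(variants) == 5
        s3 = {
            v.id: v.genotypes["s3"] for v in variants
        }
        assert s3 == {"a": 1, "b": 0, "c": 1, "d": 0, "e": 2}
        g = fp.build_variant_graph(ref, variants)
        for s in labels:
            assert fp.haplotype_sequence(g, variants, s) == table1.haplotypes[s]

    def test_empty_vcf(self, tmp_path, table1):
        fasta = str(tmp_path / "ref.fa")
        table1.write_reference_fasta(fasta)
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=ref,length=18>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        )
        ref, variants, labels = fp.read_vcf_haplotypes(str(vcf), "ref", fasta)
        assert variants == []
        assert ref == table1.reference

    def test_diploid_phased_copies(self, tmp_path):
        fasta = tmp_path / "ref.fa"
        fasta.write_text(">ref\nACGTACGT\n")
        vcf = tmp_path / "d.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=ref,length=8>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\td1\n"
            "ref\t2\tb\tC\tG\t.\t.\t.\tGT\t1|0\n"
        )
        _, variants, labels = fp.read_vcf_haplotypes(str(vcf), "ref", str(fasta))
        assert labels == ["d1_1", "d1_2"]
        assert variants[0].genotypes == {"d1_1": 1, "d1_2": 0}

    def test_unphased_strict_raises_and_lenient_warns(self, tmp_path):
        fasta = tmp_path / "ref.fa"
        fasta.write_text(">ref\nACGTACGT\n")
        vcf = tmp_path / "u.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=ref,length=8>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\td1\n"
            "ref\t2\tb\tC\tG\t.\t.\t.\tGT\t1/0\n"
        )
        with pytest.raises(UnphasedGenotypeError, match="d1"):
            fp.read_vcf_haplotypes(str(vcf), "ref", str(fasta))
        with pytest.warns(UserWarning, match="lenient"):
            _, variants, _ = fp.read_vcf_haplotypes(
                str(vcf), "ref", str(fasta), strict_phasing=False
            )
        assert variants[0].genotypes["d1_1"] == 1

    def test_symbolic_allele_rejected(self, tmp_path):
        fasta = tmp_path / "ref.fa"
        fasta.write_text(">ref\nACGTACGT\n")
        vcf = tmp_path / "s.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=ref,length=8>\n'
            '##ALT=<ID=DEL,Description="Deletion">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\td1\n"
            "ref\t2\tb\tC\t<DEL>\t.\t.\t.\tGT\t1\n"
        )
        with pytest.raises(UnsupportedAlleleError):
            fp.read_vcf_haplotypes(str(vcf), "ref", str(fasta))

    def test_ref_mismatch_reports_position(self, tmp_path):
        fasta = tmp_path / "ref.fa"
        fasta.write_text(">ref\nACGTACGT\n")
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=ref,length=8>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\td1\n"
            "ref\t2\tb\tA\tG\t.\t.\t.\tGT\t1\n"
        )
        with pytest.raises(ReferenceMismatchError, match="2"):
            fp.read_vcf_haplotypes(str(vcf), "ref", str(fasta))

    def test_node_table_sidecar(self, table1_graph, tmp_path):
        path = tmp_path / "nodes.tsv"
        fp.msa_graph.write_node_table(table1_graph, str(path))
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "node\taligned_pos"
        assert lines[1] == "1\t1"
        assert lines[-1] == "19\t24"
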