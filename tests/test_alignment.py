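import numpy as np
import pandas as pd
import pytest

from popfrag.alignment import (
    GeneAnnotation,
    call_sites,
    classify_effects,
    filter_maf,
    read_alignment,
    read_annotation,
    site_genotypes,
    write_annotation,
)
from popfrag._codon import translate_codon
from tests.conftest import make_alignment


def _write_pops(path, entries):
    path.write_text("line_id,population\n" +
                    "".join(f"{k},{v}\n" for k, v in entries))


class TestReadAlignment:
    def test_three_record_fasta(self, tmp_path):
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">a\nACGT\n>b\nACGA\n>c\nACTT\n")
        pops = tmp_path / "pops.csv"
        _write_pops(pops, [("a", "p1"), ("b", "p1"), ("c", "p2")])
        aln = read_alignment(fasta, None, pops)
        assert aln.n_rows == 3
        assert aln.populations == ["p1", "p1", "p2"]

    def test_unknown_line_errors(self, tmp_path):
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">a\nACGT\n>zz\nACGT\n")
        pops = tmp_path / "pops.csv"
        _write_pops(pops, [("a", "p1")])
        with pytest.raises(ValueError, match="zz"):
            read_alignment(fasta, None, pops)

    def test_ragged_alignment_errors(self, tmp_path):
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">a\nACGT\n>b\nACG\n")
        pops = tmp_path / "pops.csv"
        _write_pops(pops, [("a", "p1"), ("b", "p1")])
        with pytest.raises(ValueError, match="ragged"):
            read_alignment(fasta, None, pops)

    def test_high_missing_rows_dropped(self, tmp_path):
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">a\nACGTACGTAC\n>b\nNNNNNACGTA\n>c\nACGTACGTAA\n")
        pops = tmp_path / "pops.csv"
        _write_pops(pops, [("a", "p1"), ("b", "p1"), ("c", "p1")])
        aln = read_alignment(fasta, None, pops)
        assert aln.line_ids == ["a", "c"]


class TestAnnotation:
    def test_roundtrip(self, tmp_path):
        ann = GeneAnnotation(((0, 50, "5UTR"), (50, 200, "exon"),
                              (200, 260, "intron"), (260, 320, "exon"),
                              (320, 400, "3UTR")), frame_offset=2)
        path = tmp_path / "g.bed"
        write_annotation(ann, path)
        assert read_annotation(path) == ann

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            GeneAnnotation(((0, 10, "exon"), (5, 20, "intron")), 0)

    def test_region_lookup(self):
        ann = GeneAnnotation(((0, 10, "5UTR"), (10, 40, "exon")), 0)
        assert ann.region_at(0) == "5UTR"
        assert ann.region_at(10) == "exon"
        assert ann.region_at(40) is None
        assert list(ann.exon_columns()) == list(range(10, 40))


class TestCallSites:
    def test_monomorphic_empty(self):
        aln = make_alignment(["ACGT", "ACGT", "ACGT"])
        assert len(call_sites(aln)) == 0

    def test_one_snp_one_indel(self):
        # column 1 A/A/G/G; rows 0 carries a 2-column gap at 4..6
        aln = make_alignment([
            "TATA--CC",
            "TATAGGCC",
            "TGTAGGCC",
            "TGTAGGCC",
        ])
        sites = call_sites(aln)
        assert list(sites["kind"].value_counts().items()) in (
            [("SNP", 1), ("indel", 1)], [("indel", 1), ("SNP", 1)])
        snp = sites[sites["kind"] == "SNP"].iloc[0]
        assert snp["position"] == 1
        assert set(snp["alleles"]) == {"A", "G"}
        indel = sites[sites["kind"] == "indel"].iloc[0]
        assert indel["position"] == 4 and indel["length"] == 2
        assert indel["maf"] == 0.25

    def test_row_order_invariant(self, small_study):
        aln = small_study[0][0]
        rng = np.random.default_rng(0)
        perm = rng.permutation(aln.n_rows)
        shuffled = aln.subset_rows(perm)
        a = call_sites(aln)
        b = call_sites(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_distinct_gap_extents_are_distinct_sites(self):
        aln = make_alignment([
            "AA--CCGG",
            "AA---CGG",
            "AACCCCGG",
            "AACCCCGG",
        ])
        sites = call_sites(aln)
        indels = sites[sites["kind"] == "indel"]
        assert len(indels) == 2
        assert sorted(indels["length"]) == [2, 3]

    def test_triallelic_supported(self):
        aln = make_alignment(["AAAA", "ACAA", "AGAA", "ACAA"])
        sites = call_sites(aln)
        assert len(sites) == 1
        assert len(sites.iloc[0]["alleles"]) == 3
        # MAF is the second most frequent allele's frequency
        assert sites.iloc[0]["maf"] == 0.25

    def test_n_excluded_from_counts(self):
        aln = make_alignment(["ANGT", "AAGT", "ATGT", "AAGT"])
        sites = call_sites(aln)
        assert sites.iloc[0]["counts"] == (2, 1)

    def test_synthetic_truth_recovered(self, small_study):
        alignments, _ssr, truth = small_study
        for aln in alignments:
            sites = call_sites(aln)
            snp_pos = sorted(sites[sites["kind"] == "SNP"]["position"])
            assert snp_pos == sorted(truth.gene_snp_positions[aln.gene_id])
            n_indels = int((sites["kind"] == "indel").sum())
            assert n_indels == len(truth.gene_indels[aln.gene_id])


class TestClassifyEffects:
    def _single_codon_aln(self, codons, pad="ACGTACGTA"):
        # one exon covering the codon, flanked by a 5'UTR
        rows = [pad + c for c in codons]
        ann = GeneAnnotation(((0, len(pad), "5UTR"),
                              (len(pad), len(pad) + 3, "exon")), 0)
        return make_alignment(rows, annotation=ann)

    def test_synonymous(self):
        aln = self._single_codon_aln(["GGA", "GGG", "GGA", "GGG"])
        sites = classify_effects(call_sites(aln), aln)
        assert sites.iloc[0]["coding_effect"] == "synonymous"
        assert sites.iloc[0]["polarity_change"] is None

    def test_nonsynonymous_same_polarity(self):
        # AAA (Lys) -> GAA (Glu): both charged
        aln = self._single_codon_aln(["AAA", "GAA", "AAA", "GAA"])
        sites = classify_effects(call_sites(aln), aln)
        assert sites.iloc[0]["coding_effect"] == "non-synonymous"
        assert sites.iloc[0]["polarity_change"] is False

    def test_nonsynonymous_polarity_change(self):
        # GAT (Asp, charged) -> GCT (Ala, nonpolar)
        aln = self._single_codon_aln(["GAT", "GCT", "GAT", "GCT"])
        sites = classify_effects(call_sites(aln), aln)
        assert sites.iloc[0]["polarity_change"] is True

    def test_intron_snp_noncoding(self):
        ann = GeneAnnotation(((0, 4, "intron"),), 0)
        aln = make_alignment(["ACGT", "AAGT", "ACGT"], annotation=ann)
        sites = classify_effects(call_sites(aln), aln)
        assert sites.iloc[0]["coding_effect"] == "non-coding"

    def test_inframe_exonic_indel(self):
        ann = GeneAnnotation(((0, 9, "exon"),), 0)
        aln = make_alignment(["ATGAAATGG", "ATG---TGG", "ATGAAATGG"],
                             annotation=ann)
        sites = classify_effects(call_sites(aln), aln)
        indel = sites[sites["kind"] == "indel"].iloc[0]
        assert indel["coding_effect"] == "frameshift-free-indel"

    def test_frameshift_indel_flagged(self):
        ann = GeneAnnotation(((0, 9, "exon"),), 0)
        aln = make_alignment(["ATGAAATGG", "ATGA--TGG", "ATGAAATGG"],
                             annotation=ann)
        sites = classify_effects(call_sites(aln), aln)
        indel = sites[sites["kind"] == "indel"].iloc[0]
        assert indel["coding_effect"] == "NA"
        assert "frameshift" in indel["flags"]

    def test_agrees_with_full_translation(self, small_study):
        """Oracle: classify vs brute-force translation of the whole exon
        sequence under each allele on a consensus background."""
        alignments, _, _ = small_study
        checked = 0
        for aln in alignments:
            sites = classify_effects(call_sites(aln), aln)
            exon_cols = aln.annotation.exon_columns()
            usable = exon_cols[:(len(exon_cols) // 3) * 3]
            consensus = []
            for c in usable:
                col = aln.seqs[:, c]
                keep = (col != "N") & (col != "-")
                vals, cnts = np.unique(col[keep], return_counts=True)
                consensus.append(str(vals[np.argmax(cnts)]))
            col_index = {int(c): i for i, c in enumerate(usable)}
            for _, site in sites.iterrows():
                if site["kind"] != "SNP" or site["region"] != "exon":
                    continue
                if site["position"] not in col_index:
                    continue
                i = col_index[site["position"]]

                def protein(base):
                    cds = list(consensus)
                    cds[i] = base
                    return "".join(
                        translate_codon("".join(cds[k:k + 3]))
                        for k in range(0, len(cds) - 2, 3))

                major = protein(site["alleles"][0])
                all_same = all(protein(a) == major
                               for a in site["alleles"][1:])
                expected = "synonymous" if all_same else "non-synonymous"
                assert site["coding_effect"] == expected
                checked += 1
        assert checked > 0


class TestFilterMaf:
    def test_all_half_unchanged(self):
        sites = pd.DataFrame({"maf": [0.5, 0.5, 0.5]})
        assert len(filter_maf(sites)) == 3

    def test_removes_rare(self):
        sites = pd.DataFrame({"maf": [0.02, 0.3, 0.5]})
        assert len(filter_maf(sites)) == 2

    def test_boundary_kept(self):
        sites = pd.DataFrame({"maf": [0.05]})
        assert len(filter_maf(sites, 0.05)) == 1

    def test_zero_threshold_identity(self):
        sites = pd.DataFrame({"maf": [0.01, 0.2]})
        assert len(filter_maf(sites, 0.0)) == 2


class TestSiteGenotypes:
    def test_snp_and_indel_codes(self):
        aln = make_alignment(["TATA--CC", "TATAGGCC", "TGTAGGCC", "TGTAGGCC"])
        sites = call_sites(aln)
        geno = site_genotypes(aln, sites)
        assert set(geno["SNP@1"]) == {"A", "G"}
        assert list(geno["indel@4"]) == ["del", "ref", "ref", "ref"]
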