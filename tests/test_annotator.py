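"""Peptide filtering, mapping, start-codon assignment and SNP-mutant flagging."""

from __future__ import annotations

import pytest

from orfweave.annotator import (
    PeptideHit,
    assign_start,
    filter_annotated,
    flag_snp_mutants,
    map_peptide,
    normalize_il,
)
from orfweave.translator import ORFRecord, translate


def make_orf(
    cds_nt,
    contig="c",
    start=100,
    strand="+",
    upstream_flank="TAA",
    downstream_flank="TAA",
    bounded=True,
):
    assert len(cds_nt) % 3 == 0
    return ORFRecord(
        orf_id="o1",
        transcript_id="t1",
        contig=contig,
        strand=strand,
        frame=0,
        aa_sequence=translate(cds_nt),
        cds_nt=cds_nt,
        cds_spans=((start, start + len(cds_nt)),),
        has_upstream_stop=bounded,
        has_downstream_stop=bounded,
        upstream_flank=upstream_flank,
        downstream_flank=downstream_flank,
    )


class TestFilterAnnotated:
    PROTEOME = {"P1": "MKTAYIAKQRQISFVK", "P2": "MSLNWQE"}

    def test_verbatim_peptide_removed(self):
        novel, removed = filter_annotated(["TAYIAKQR"], self.PROTEOME)
        assert removed == ["TAYIAKQR"] and novel == []

    def test_one_residue_difference_retained(self):
        novel, removed = filter_annotated(["TAYIAKQW"], self.PROTEOME)
        assert novel == ["TAYIAKQW"]

    def test_il_equivalence(self):
        # reference has ...ISFVK; a peptide with L in place of I still matches
        novel, removed = filter_annotated(["QRQLSFVK"], self.PROTEOME)
        assert removed == ["QRQLSFVK"]

    def test_empty_proteome_warns_and_passes_all(self):
        with pytest.warns(UserWarning):
            novel, removed = filter_annotated(["AAA"], {})
        assert novel == ["AAA"]


class TestMapPeptide:
    def test_single_hit_with_offset(self):
        orf = make_orf("ATG" + "GCT" * 5 + "TGG" * 3)  # MAAAAAWWW
        [hit] = map_peptide("AAWW", [orf])
        assert hit.aa_offset == 4

    def test_multiple_orfs_multiple_hits(self):
        a, b = make_orf("ATGGCTGCTGCT"), make_orf("AAAGCTGCTGCT")
        hits = map_peptide("AAA", [a, b])
        assert len(hits) == 2

    def test_absent_peptide_no_hits(self):
        assert map_peptide("WWWW", [make_orf("ATGGCTGCT")]) == []

    def test_il_equivalent_mapping(self):
        orf = make_orf("ATGCTGATT")  # M L I
        assert len(map_peptide("MLL", [orf])) == 1


def _codons(*cs):
    return "".join(cs)


class TestAssignStart:
    def test_inframe_atg_wins(self):
        orf = make_orf(_codons("GCT", "ATG", "GCC", "AAA", "GAT"))
        call = assign_start(PeptideHit("KD", orf, 3))
        assert call.start_class == "AUG" and call.start_codon == "ATG"
        assert call.start_offset == 1 and call.orf_length_codons == 4
        assert call.is_smORF

    def test_upstream_most_atg_taken(self):
        orf = make_orf(_codons("ATG", "GCC", "ATG", "AAA"))
        call = assign_start(PeptideHit("K", orf, 3))
        assert call.start_offset == 0  # longest-ORF reading

    def test_near_cognate_needs_kozak(self):
        # no ATG; CTG at codon 1 with purine at -3 (first base of codon 0 = A)
        orf = make_orf(_codons("AGT", "CTG", "CCC", "AAA"))
        call = assign_start(PeptideHit("K", orf, 3))
        assert call.start_class == "near-cognate-Kozak" and call.start_codon == "CTG"
        assert call.start_offset == 1
        # pyrimidine at -3 and no G at +4: Kozak fails, falls through
        orf = make_orf(_codons("TGT", "CTG", "CCC", "AAA"))
        call = assign_start(PeptideHit("K", orf, 3))
        assert call.start_class == "stop-bounded"

    def test_kozak_plus4_g_alone_suffices(self):
        orf = make_orf(_codons("TGT", "CTG", "GCC", "AAA"))
        call = assign_start(PeptideHit("K", orf, 3))
        assert call.start_class == "near-cognate-Kozak"
        # 'both' mode demands purine at -3 as well
        call = assign_start(PeptideHit("K", orf, 3), kozak_mode="both")
        assert call.start_class == "stop-bounded"

    @pytest.mark.parametrize("n_codons, smorf", [(149, True), (151, False)])
    def test_stop_bounded_150_codon_rule(self, n_codons, smorf):
        orf = make_orf(_codons(*(["CCC"] * n_codons)))
        call = assign_start(PeptideHit("PPPP", orf, 10))
        assert call.start_class == "stop-bounded"
        assert call.orf_length_codons == n_codons
        assert call.is_smORF is smorf

    def test_unbounded_orf_never_smorf(self):
        orf = make_orf(_codons(*(["CCC"] * 20)), bounded=False)
        call = assign_start(PeptideHit("PPPP", orf, 5))
        assert not call.is_smORF

    def test_invariant_to_peptide_choice(self):
        orf = make_orf(_codons("GCT", "ATG", "GCC", "AAA", "GAT", "TTT"))
        c1 = assign_start(PeptideHit("KD", orf, 3))
        c2 = assign_start(PeptideHit("DF", orf, 4))
        assert (c1.start_class, c1.start_offset) == (c2.start_class, c2.start_offset)


class TestFlagSnpMutants:
    def test_single_mismatch_at_called_snp_flagged(self):
        # ORF encodes MKD; reference protein has MKE; codon 2 overlaps a SNP
        orf = make_orf(_codons("ATG", "AAA", "GAT"), start=100)
        call = assign_start(PeptideHit("MKD", orf, 0))
        call = flag_snp_mutants(call, {"P": "AAMKEAA"}, {("c", 107)})
        assert call.snp_mutant_of_known

    def test_mismatch_away_from_snp_not_flagged(self):
        orf = make_orf(_codons("ATG", "AAA", "GAT"), start=100)
        call = assign_start(PeptideHit("MKD", orf, 0))
        call = flag_snp_mutants(call, {"P": "AAMKEAA"}, {("c", 55)})
        assert not call.snp_mutant_of_known

    def test_minus_strand_codon_positions(self):
        # same cds on the minus strand: genomic positions run right-to-left
        orf = make_orf(_codons("ATG", "AAA", "GAT"), start=100, strand="-")
        pos = orf.genomic_positions()
        assert pos[0] == 108 and pos[-1] == 100
        call = assign_start(PeptideHit("MKD", orf, 0))
        # codon 2 occupies genomic 100..102 on the minus strand
        call = flag_snp_mutants(call, {"P": "AAMKEAA"}, {("c", 101)})
        assert call.snp_mutant_of_known


def test_normalize_il():
    assert normalize_il("MLIl") == "MIII"
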