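"""Three-frame translation, ORF extraction and genomic ORF extension."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from orfweave.consensus import build_consensus
from orfweave.io_formats import GenomeSequence, TranscriptModel
from orfweave.translator import (
    build_orf_records,
    three_frame_orfs,
    transcript_sequence,
    translate,
)

from conftest import make_read


def _stretches(seq, frame):
    return [(o.aa, o.nt_start, o.open5, o.open3) for o in three_frame_orfs(seq) if o.frame == frame]


class TestThreeFrame:
    def test_basic_frames(self):
        out = {o.frame: o.aa for o in three_frame_orfs("ATGGCC")}
        assert out == {0: "MA", 1: "W", 2: "G"}

    def test_all_stop_sequence_emits_nothing(self):
        assert _stretches("TAATAA", 0) == []

    def test_stop_splits_stretches(self):
        assert [(aa, s) for aa, s, *_ in _stretches("ATGTGAAAA", 0)] == [("M", 0), ("K", 6)]

    def test_open_flags(self):
        [(aa, s, open5, open3)] = _stretches("ATGGCC", 0)
        assert open5 and open3
        [(aa, s, open5, open3)] = _stretches("TAAATGGCCTGA", 0)
        assert aa == "MA" and not open5 and not open3

    def test_n_codons_translate_to_x(self):
        assert translate("ATGNNA") == "MX"

    def test_against_biopython_oracle(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            seq = "".join(bases[rng.integers(0, 4, int(rng.integers(3, 60)))])
            for frame in range(3):
                tail = seq[frame:]
                tail = tail[: len(tail) - len(tail) % 3]
                expect = [s for s in str(Seq(tail).translate()).split("*") if s]
                got = [aa for aa, *_ in _stretches(seq, frame)]
                assert got == expect, (seq, frame)


class TestTranscriptSequence:
    def test_concatenation_and_revcomp(self):
        genome = {"c": GenomeSequence("c", "ATGTTCCC")}
        plus = TranscriptModel("p", "c", "+", ((0, 3), (5, 8)))
        minus = TranscriptModel("m", "c", "-", ((0, 3), (5, 8)))
        assert transcript_sequence(plus, genome)[0] == "ATGCCC"
        assert transcript_sequence(minus, genome)[0] == "GGGCAT"

    def test_consensus_substitution_in_exon(self):
        genome = {"c": GenomeSequence("c", "ATGAAA")}
        reads = [make_read(f"r{i}", [(3, 4)], bases=["C"]) for i in range(6)]
        db = build_consensus(reads, {"c": 6})
        seq, subs = transcript_sequence(TranscriptModel("t", "c", "+", ((0, 6),)), genome, db)
        assert seq == "ATGCAA" and subs == [(3, "A", "C")]


def _genome_with(center: str, flank_left: str = "", flank_right: str = "", pad=30):
    """Build a genome 'NNN… flank_left | center | flank_right …NNN' and
    return (genome dict, start of center)."""
    left = "C" * pad + flank_left
    seq = left + center + flank_right + "C" * pad
    return {"c": GenomeSequence("c", seq)}, len(left)


class TestExtension:
    def test_3prime_extension_to_nearest_stop(self):
        # transcript ends mid-ORF; genome continues TTT TAA in frame
        genome, s = _genome_with("ATGGCC", flank_right="TTTTAA")
        model = TranscriptModel("t", "c", "+", ((s, s + 6),))
        recs = [r for r in build_orf_records(model, genome, min_aa=1) if r.frame == 0]
        [rec] = recs
        assert rec.aa_sequence.endswith("MAF") or rec.aa_sequence == "MAF"
        assert rec.extended_3p and rec.ext3_nt == 3
        assert rec.has_downstream_stop
        # the cds ends exactly before the genomic TAA
        assert rec.genomic_span[1] == s + 9

    def test_stop_flanking_transcript_means_zero_extension(self):
        genome, s = _genome_with("ATGGCC", flank_left="TAA", flank_right="TGA")
        model = TranscriptModel("t", "c", "+", ((s, s + 6),))
        [rec] = [r for r in build_orf_records(model, genome, min_aa=1) if r.frame == 0]
        assert rec.aa_sequence == "MA"
        assert not rec.extended_3p and rec.ext3_nt == 0
        assert rec.extended_5p is False and rec.ext5_nt == 0
        assert rec.has_upstream_stop and rec.has_downstream_stop

    def test_5prime_extension_recovers_upstream_atg(self):
        # upstream genome: stop, ATG, then filler codons before the transcript
        genome, s = _genome_with("GCCGCC", flank_left="TAAATGAAA", flank_right="TGA")
        model = TranscriptModel("t", "c", "+", ((s, s + 6),))
        [rec] = [r for r in build_orf_records(model, genome, min_aa=1) if r.frame == 0]
        assert rec.aa_sequence == "MKAA"
        assert rec.extended_5p and rec.ext5_nt == 6
        assert rec.start_class == "AUG" and rec.start_codon_offset == 0
        assert rec.genomic_span[0] == s - 6

    def test_contig_edge_sets_boundary_flag(self):
        genome = {"c": GenomeSequence("c", "GCCGCCGCC")}
        model = TranscriptModel("t", "c", "+", ((0, 9),))
        [rec] = [r for r in build_orf_records(model, genome, min_aa=1) if r.frame == 0]
        assert rec.hit_boundary_5p and rec.hit_boundary_3p
        assert not rec.has_upstream_stop and not rec.has_downstream_stop

    def test_max_ext_cap(self):
        genome, s = _genome_with("ATGGCC", flank_right="GGC" * 50)
        model = TranscriptModel("t", "c", "+", ((s, s + 6),))
        [rec] = [
            r
            for r in build_orf_records(model, genome, min_aa=1, max_ext=9)
            if r.frame == 0
        ]
        assert rec.ext3_nt <= 9 and rec.hit_boundary_3p

    def test_minus_strand_extension(self):
        # minus-strand transcript: 3' continuation lies at lower genomic coords
        center = "GGCCAT"  # revcomp -> ATGGCC
        genome, s = _genome_with(center, flank_left="TTAAAA")  # revcomp of left ext: TTTTAA
        model = TranscriptModel("t", "c", "-", ((s, s + 6),))
        [rec] = [r for r in build_orf_records(model, genome, min_aa=1) if r.frame == 0]
        assert rec.aa_sequence.endswith("MAF")  # 5' side runs into the contig pad
        assert rec.extended_3p and rec.ext3_nt == 3


class TestSelfConsistency:
    def test_cds_spans_retranslate_to_aa(self, mixed_bundle):
        results = mixed_bundle["results"]
        genome = results["genome"]
        db = results["consensus"]
        from orfweave.consensus import apply_consensus
        from orfweave.io_formats import revcomp

        for rec in results["orfs"][:200]:
            pieces = [
                apply_consensus(genome[rec.contig], db, s, e)[0] for s, e in rec.cds_spans
            ]
            nt = "".join(pieces)
            if rec.strand == "-":
                nt = revcomp(nt)
            assert nt == rec.cds_nt
            assert translate(nt) == rec.aa_sequence
            assert "*" not in rec.aa_sequence

    def test_consensus_db_differs_only_at_snp_peptides(self, mixed_bundle):
        from orfweave.annotator import normalize_il
        from orfweave.translator import build_orf_database

        truth = mixed_bundle["truth"]
        results = mixed_bundle["results"]
        plain = build_orf_database(results["models"], results["genome"], None)
        cons_seqs = [o.aa_sequence for o in results["orfs"]]
        plain_seqs = [o.aa_sequence for o in plain]
        for snp in truth.snps:
            mut = normalize_il(snp.mutant_peptide)
            assert any(mut in normalize_il(s) for s in cons_seqs)
            assert not any(mut in normalize_il(s) for s in plain_seqs)
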