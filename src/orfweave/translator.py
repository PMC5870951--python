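"""Consensus-corrected transcript sequences, three-frame translation and
ORF extension.

Each assembled transcript is spliced together from consensus-corrected
exon slices (minus-strand transcripts reverse-complemented) and
translated in the three sense frames; translating the sense strand only
reflects stranded library preparation — antisense coding is handled by
assembling the antisense transcript itself, not by reverse-frame
translation (``six_frame`` exists for unstranded input).

Maximal stop-free amino-acid stretches are extracted per frame.  A
stretch that touches the transcript's 5' and/or 3' terminus in its
frame is *extended* along the genome beyond the terminal exon (no
splicing is imputed), in frame, using the consensus-corrected sequence:
downstream until the nearest in-frame stop, upstream until one codon
after the nearest upstream in-frame stop.  Extensions are capped at
``max_ext`` nt per side and flagged when they hit a contig edge or the
cap instead of a stop.  This recovers full-length ORFs for transcripts
whose ends are under-covered, so that truncated proteins are not
reported with spurious non-AUG starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .consensus import ConsensusDB, apply_consensus
from .io_formats import STOP_CODONS, GenomeSequence, TranscriptModel, revcomp

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    _CODON_TABLE[_stop] = "*"

#: codons one nucleotide substitution away from ATG (possible near-cognate starts)
NEAR_COGNATE_CODONS = frozenset(
    {
        "TTG", "CTG", "GTG",  # first position
        "AAG", "ACG", "AGG",  # second position
        "ATA", "ATC", "ATT",  # third position
    }
)


def translate_codon(codon: str) -> str:
    """Standard-code translation; codons with ambiguity become X."""
    if len(codon) != 3:
        raise ValueError(f"not a codon: {codon!r}")
    return _CODON_TABLE.get(codon.upper(), "X")


def translate(seq: str) -> str:
    """Translate a nucleotide string codon-by-codon ('*' for stops)."""
    return "".join(
        translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def kozak_ok(minus3: str, plus4: str, mode: str = "either") -> bool:
    """Minimal Kozak-context test: purine at -3 and/or G at +4.

    ``mode='either'`` (default) is the weakest standard criterion and
    avoids over-filtering; ``mode='both'`` requires both features.
    """
    purine = minus3 in ("A", "G")
    g4 = plus4 == "G"
    return (purine and g4) if mode == "both" else (purine or g4)


@dataclass(frozen=True)
class OrfStretch:
    """A maximal stop-free stretch in one frame of a transcript sequence.

    ``nt_start``/``nt_end`` are transcript-coordinate offsets of the
    translated codons; ``open5``/``open3`` mark stretches not bounded by
    a stop codon on that side within the transcript.
    """

    frame: int
    aa: str
    nt_start: int
    nt_end: int
    open5: bool
    open3: bool


def three_frame_orfs(seq: str) -> list[OrfStretch]:
    """All maximal stop-free stretches in the three sense frames."""
    out: list[OrfStretch] = []
    for frame in range(3):
        n_codons = (len(seq) - frame) // 3
        start_codon = 0
        aa_buf: list[str] = []
        for ci in range(n_codons):
            codon = seq[frame + 3 * ci : frame + 3 * ci + 3]
            if codon.upper() in STOP_CODONS:
                if aa_buf:
                    out.append(
                        OrfStretch(
                            frame,
                            "".join(aa_buf),
                            frame + 3 * start_codon,
                            frame + 3 * ci,
                            open5=start_codon == 0,
                            open3=False,
                        )
                    )
                aa_buf = []
                start_codon = ci + 1
            else:
                aa_buf.append(translate_codon(codon))
        if aa_buf:
            out.append(
                OrfStretch(
                    frame,
                    "".join(aa_buf),
                    frame + 3 * start_codon,
                    frame + 3 * n_codons,
                    open5=start_codon == 0,
                    open3=True,
                )
            )
    return out


@dataclass(frozen=True)
class ORFRecord:
    """A translated (possibly extended, consensus-corrected) ORF.

    ``aa_sequence`` is the full stop-free stretch (no internal stops);
    when an in-frame ATG exists, ``start_codon_offset`` marks the
    upstream-most one and ``start_class`` is AUG — the full stretch is
    still written to the database so peptides upstream of the ATG remain
    searchable.  ``cds_spans`` are ascending genomic half-open intervals
    covering exactly the translated nucleotides, extensions included.
    """

    orf_id: str
    transcript_id: str
    contig: str
    strand: str
    frame: int
    aa_sequence: str
    cds_nt: str
    cds_spans: tuple[tuple[int, int], ...]
    extended_5p: bool = False
    ext5_nt: int = 0
    extended_3p: bool = False
    ext3_nt: int = 0
    has_upstream_stop: bool = True
    has_downstream_stop: bool = True
    hit_boundary_5p: bool = False
    hit_boundary_3p: bool = False
    upstream_flank: str = ""
    downstream_flank: str = ""
    snp_substitutions: tuple[tuple[int, str, str], ...] = ()
    start_class: str = "open-ended"  # AUG | near-cognate | open-ended
    start_codon_offset: int | None = None

    @property
    def n_codons(self) -> int:
        return len(self.aa_sequence)

    def codons(self) -> list[str]:
        return [self.cds_nt[i : i + 3] for i in range(0, len(self.cds_nt), 3)]

    def genomic_positions(self) -> list[int]:
        """Genomic coordinate of every cds nucleotide, in cds order."""
        pos: list[int] = []
        if self.strand == "+":
            for s, e in self.cds_spans:
                pos.extend(range(s, e))
        else:
            for s, e in reversed(self.cds_spans):
                pos.extend(range(e - 1, s - 1, -1))
        return pos

    @property
    def genomic_span(self) -> tuple[int, int]:
        return self.cds_spans[0][0], self.cds_spans[-1][1]

    def fasta_header(self) -> str:
        s, e = self.genomic_span
        return (
            f"{self.orf_id}|{self.contig}:{s}-{e}:{self.strand}"
            f"|ext5:{self.ext5_nt}|ext3:{self.ext3_nt}"
            f"|snps:{len(self.snp_substitutions)}"
        )


def _corrected(genome_seq: GenomeSequence, db: ConsensusDB | None, start: int, end: int):
    return apply_consensus(genome_seq, db, start, end)


def transcript_sequence(
    model: TranscriptModel,
    genome: dict[str, GenomeSequence],
    consensus: ConsensusDB | None = None,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Spliced, consensus-corrected transcript sequence.

    Returns the sequence in transcript orientation (minus-strand models
    are reverse-complemented) together with the genomic substitutions
    applied within its exons.
    """
    gseq = genome[model.contig]
    pieces: list[str] = []
    subs: list[tuple[int, str, str]] = []
    for s, e in model.exons:
        piece, piece_subs = _corrected(gseq, consensus, s, e)
        pieces.append(piece)
        subs.extend(piece_subs)
    seq = "".join(pieces)
    if model.strand == "-":
        seq = revcomp(seq)
    return seq, subs


def _tx_to_genomic(
    exons: Sequence[tuple[int, int]], strand: str, t0: int, t1: int
) -> tuple[tuple[int, int], ...]:
    """Map a transcript-coordinate window [t0, t1) to ascending genomic spans."""
    order = list(exons) if strand == "+" else list(exons)[::-1]
    spans: list[tuple[int, int]] = []
    off = 0
    for s, e in order:
        L = e - s
        a, b = max(t0 - off, 0), min(t1 - off, L)
        if a < b:
            spans.append((s + a, s + b) if strand == "+" else (e - b, e - a))
        off += L
    spans.sort()
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s == merged[-1][1]:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def _walk_beyond(
    model: TranscriptModel,
    genome: dict[str, GenomeSequence],
    consensus: ConsensusDB | None,
    side: str,
    n: int,
) -> tuple[str, int, bool]:
    """Genomic sequence beyond the transcript terminus, transcript orientation.

    Returns (sequence, nt obtained, hit_contig_edge).
    """
    gseq = genome[model.contig]
    L = len(gseq)
    s_first, e_last = model.exons[0][0], model.exons[-1][1]
    toward_right = (model.strand == "+") == (side == "3p")
    if toward_right:
        lo, hi = e_last, min(e_last + n, L)
        edge = hi == L and hi - lo < n
    else:
        lo, hi = max(0, s_first - n), s_first
        edge = lo == 0 and hi - lo < n
    seq, _ = _corrected(gseq, consensus, lo, hi)
    if model.strand == "-":
        seq = revcomp(seq)
    return seq, hi - lo, edge


def extend_orf(
    stretch: OrfStretch,
    model: TranscriptModel,
    seq: str,
    genome: dict[str, GenomeSequence],
    consensus: ConsensusDB | None = None,
    max_ext: int = 10_000,
) -> dict:
    """Extend an open stretch to the nearest in-frame stops along the genome.

    Returns a dict of the extension outcome: prefix/suffix amino acids,
    genomic nt added on each side, stop/boundary flags, and the final
    cds window in extended-transcript coordinates.
    """
    L = len(seq)
    nt_start, nt_end = stretch.nt_start, stretch.nt_end
    aa5: list[str] = []
    aa3: list[str] = []
    u_seq = ""
    d_seq = ""
    found_stop5 = not stretch.open5
    found_stop3 = not stretch.open3
    edge5 = edge3 = False
    hit_cap5 = hit_cap3 = False

    if stretch.open5:
        u_seq, _, edge5 = _walk_beyond(model, genome, consensus, "5p", max_ext + 3)
        combined = u_seq + seq[:nt_start]
        i = len(combined)
        while i - 3 >= 0:
            codon = combined[i - 3 : i]
            if codon.upper() in STOP_CODONS:
                found_stop5 = True
                break
            used_genomic = (len(combined) - (i - 3)) - nt_start
            if used_genomic > max_ext:
                hit_cap5 = True
                break
            aa5.append(translate_codon(codon))
            i -= 3
        aa5.reverse()

    if stretch.open3:
        d_seq, _, edge3 = _walk_beyond(model, genome, consensus, "3p", max_ext + 3)
        tail = seq[nt_end:]
        combined = tail + d_seq
        j = 0
        while j + 3 <= len(combined):
            codon = combined[j : j + 3]
            if codon.upper() in STOP_CODONS:
                found_stop3 = True
                break
            used_genomic = (j + 3) - len(tail)
            if used_genomic > max_ext:
                hit_cap3 = True
                break
            aa3.append(translate_codon(codon))
            j += 3

    u = len(u_seq)
    k5, k3 = len(aa5), len(aa3)
    cs = u + nt_start - 3 * k5
    ce = u + nt_end + 3 * k3
    ext_seq = u_seq + seq + d_seq
    return {
        "aa": "".join(aa5) + stretch.aa + "".join(aa3),
        "cs": cs,
        "ce": ce,
        "u": u,
        "ext_seq": ext_seq,
        "ext5_nt": max(0, u - cs),
        "ext3_nt": max(0, ce - (u + L)),
        "has_upstream_stop": found_stop5,
        "has_downstream_stop": found_stop3,
        "hit_boundary_5p": (not found_stop5) and (edge5 or hit_cap5 or cs < 3),
        "hit_boundary_3p": (not found_stop3) and (edge3 or hit_cap3),
    }


def _classify_start(codons: list[str], upstream_flank: str, downstream_flank: str, cds_nt: str) -> tuple[str, int | None]:
    """Translator-level start class: first in-frame ATG wins; otherwise a
    near-cognate codon in Kozak context; otherwise open-ended."""
    for i, codon in enumerate(codons):
        if codon.upper() == "ATG":
            return "AUG", i
    for i, codon in enumerate(codons):
        if codon.upper() in NEAR_COGNATE_CODONS:
            minus3 = cds_nt[3 * i - 3] if i > 0 else (upstream_flank[0] if len(upstream_flank) == 3 else "")
            plus4 = (
                cds_nt[3 * i + 3]
                if 3 * i + 3 < len(cds_nt)
                else (downstream_flank[0] if downstream_flank else "")
            )
            if kozak_ok(minus3, plus4):
                return "near-cognate", i
    return "open-ended", None


def build_orf_records(
    model: TranscriptModel,
    genome: dict[str, GenomeSequence],
    consensus: ConsensusDB | None = None,
    min_aa: int = 8,
    max_ext: int = 10_000,
) -> list[ORFRecord]:
    """All three-frame ORFs of one transcript, extended where open."""
    seq, exon_subs = transcript_sequence(model, genome, consensus)
    records: list[ORFRecord] = []
    counter: dict[int, int] = {0: 0, 1: 0, 2: 0}
    for stretch in three_frame_orfs(seq):
        ext = extend_orf(stretch, model, seq, genome, consensus, max_ext)
        if len(ext["aa"]) < min_aa:
            continue
        cs, ce, u = ext["cs"], ext["ce"], ext["u"]
        ext5, ext3 = ext["ext5_nt"], ext["ext3_nt"]
        # map through the exon chain with terminal exons grown by the
        # genomic nucleotides the extension actually used
        exons = [list(x) for x in model.exons]
        if model.strand == "+":
            exons[0][0] -= ext5
            exons[-1][1] += ext3
        else:
            exons[-1][1] += ext5
            exons[0][0] -= ext3
        offset = u - ext5  # ext_seq coordinate of extended-chain position 0
        spans = _tx_to_genomic([tuple(x) for x in exons], model.strand, cs - offset, ce - offset)
        cds_nt = ext["ext_seq"][cs:ce]
        upstream_flank = ext["ext_seq"][max(0, cs - 3) : cs]
        downstream_flank = ext["ext_seq"][ce : ce + 3]
        pos_set: set[int] = set()
        for s, e in spans:
            pos_set.update(range(s, e))
        # substitutions inside the cds: exon-level calls plus any applied
        # within the extension slices
        all_subs = dict()
        for p, r, a in exon_subs:
            all_subs[p] = (r, a)
        if consensus is not None and (ext5 or ext3):
            gseq = genome[model.contig]
            for s, e in spans:
                for p, r, a in _corrected(gseq, consensus, s, e)[1]:
                    all_subs[p] = (r, a)
        snp_subs = tuple(
            (p, r, a) for p, (r, a) in sorted(all_subs.items()) if p in pos_set
        )
        codons = [cds_nt[i : i + 3] for i in range(0, len(cds_nt), 3)]
        start_class, start_off = _classify_start(
            codons, upstream_flank, downstream_flank, cds_nt
        )
        idx = counter[stretch.frame]
        counter[stretch.frame] += 1
        records.append(
            ORFRecord(
                orf_id=f"{model.transcript_id}|f{stretch.frame}.{idx}",
                transcript_id=model.transcript_id,
                contig=model.contig,
                strand=model.strand,
                frame=stretch.frame,
                aa_sequence=ext["aa"],
                cds_nt=cds_nt,
                cds_spans=spans,
                extended_5p=ext5 > 0,
                ext5_nt=ext5,
                extended_3p=ext3 > 0,
                ext3_nt=ext3,
                has_upstream_stop=ext["has_upstream_stop"],
                has_downstream_stop=ext["has_downstream_stop"],
                hit_boundary_5p=ext["hit_boundary_5p"],
                hit_boundary_3p=ext["hit_boundary_3p"],
                upstream_flank=upstream_flank,
                downstream_flank=downstream_flank,
                snp_substitutions=snp_subs,
                start_class=start_class,
                start_codon_offset=start_off,
            )
        )
    return records


def build_orf_database(
    models: Iterable[TranscriptModel],
    genome: dict[str, GenomeSequence],
    consensus: ConsensusDB | None = None,
    min_aa: int = 8,
    max_ext: int = 10_000,
    six_frame: bool = False,
) -> list[ORFRecord]:
    """Translate every transcript; optionally also the antisense strand."""
    db: list[ORFRecord] = []
    for model in models:
        db.extend(build_orf_records(model, genome, consensus, min_aa, max_ext))
        if six_frame:
            flipped = TranscriptModel(
                model.transcript_id + ".rc",
                model.contig,
                "-" if model.strand == "+" else "+",
                model.exons,
                model.source,
            )
            db.extend(build_orf_records(flipped, genome, consensus, min_aa, max_ext))
    return db


def write_orf_tsv(orfs: Sequence[ORFRecord], path) -> None:
    cols = [
        "orf_id", "transcript_id", "contig", "strand", "frame", "n_codons",
        "genomic_start", "genomic_end", "ext5_nt", "ext3_nt",
        "has_upstream_stop", "has_downstream_stop", "start_class",
        "start_codon_offset", "n_snps",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for o in orfs:
            s, e = o.genomic_span
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        o.orf_id, o.transcript_id, o.contig, o.strand, o.frame,
                        o.n_codons, s, e, o.ext5_nt, o.ext3_nt,
                        int(o.has_upstream_stop), int(o.has_downstream_stop),
                        o.start_class,
                        "" if o.start_codon_offset is None else o.start_codon_offset,
                        len(o.snp_substitutions),
                    ]
                )
                + "\n"
            )
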