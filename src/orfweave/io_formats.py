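"""Readers and writers for genome FASTA, SAM/BAM alignments, GTF models and protein FASTA.

Coordinate contract
-------------------
Everything inside the package uses 0-based, half-open intervals on the
forward genome strand.  SAM (1-based) and GTF (1-based, end-inclusive)
are converted at the boundary and nowhere else.

Spliced alignments are decomposed into genomic *blocks*: maximal
reference-consuming CIGAR runs (M/=/X/D) separated by N (intron)
operations.  Deletions are absorbed into the surrounding block; the read
bases facing a deleted reference position are recorded as ``N`` so that
block length always equals the length of the bases string (deleted
positions then simply do not contribute to the consensus tally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# stop codons of the standard genetic code
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse-complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MalformedRecordError(ValueError):
    """A single alignment record could not be interpreted."""

    def __init__(self, read_id: str, message: str):
        super().__init__(f"{read_id}: {message}")
        self.read_id = read_id


@dataclass(frozen=True)
class GenomeSequence:
    """One reference contig held in memory."""

    contig_name: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for contig {self.contig_name!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Substring over [start, end); out-of-bounds lookups are errors."""
        if start < 0 or end > len(self.sequence) or start > end:
            raise IndexError(
                f"{self.contig_name}:{start}-{end} outside [0, {len(self.sequence)})"
            )
        return self.sequence[start:end]


def load_genome(path) -> dict[str, GenomeSequence]:
    """Read a genome FASTA into memory, keyed by contig name."""
    from Bio import SeqIO

    genome: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = GenomeSequence(rec.id, str(rec.seq).upper())
    if not genome:
        raise ValueError(f"no sequences found in {path}")
    return genome


def write_genome_fasta(genome: dict[str, GenomeSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name].sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class AlignedRead:
    """One spliced alignment: genomic blocks plus the read bases per block.

    ``library_strand`` is the inferred *transcript* strand under the
    fr-firststrand convention (read1 antisense to the transcript,
    read2 sense; single-end reads are treated as read1).
    """

    read_id: str
    contig: str
    blocks: tuple[tuple[int, int], ...]
    block_bases: tuple[str, ...]
    n_hits: int = 1
    library_strand: str = "+"

    def __post_init__(self):
        prev_end = None
        for (s, e), bases in zip(self.blocks, self.block_bases):
            if e <= s:
                raise ValueError(f"{self.read_id}: empty block ({s},{e})")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.read_id}: blocks overlap or touch")
            if e - s != len(bases):
                raise ValueError(f"{self.read_id}: block length != bases length")
            prev_end = e

    @property
    def footprint(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive blocks (the N-spanned introns)."""
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        ]


def _infer_library_strand(rec: "pysam.AlignedSegment") -> str:
    # fr-firststrand: read1 maps antisense to the transcript.
    if rec.is_paired and rec.is_read2:
        return "-" if rec.is_reverse else "+"
    return "+" if rec.is_reverse else "-"


def _blocks_from_cigar(
    rec: "pysam.AlignedSegment", min_intron: int
) -> tuple[list[tuple[int, int]], list[str]]:
    seq = rec.query_sequence
    if seq is None:
        raise MalformedRecordError(rec.query_name or "?", "missing SEQ")
    blocks: list[tuple[int, int]] = []
    bases: list[str] = []
    ref = rec.reference_start
    qpos = 0
    cur_start = ref
    cur_bases: list[str] = []

    def close_block(end):
        if end > cur_start:
            blocks.append((cur_start, end))
            bases.append("".join(cur_bases))

    for op, ln in rec.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            cur_bases.append(seq[qpos : qpos + ln])
            qpos += ln
            ref += ln
        elif op == 1:  # I — consumes query only
            qpos += ln
        elif op == 2:  # D — absorbed into the block
            cur_bases.append("N" * ln)
            ref += ln
        elif op == 3:  # N — splice gap (unless shorter than min_intron)
            if ln < min_intron:
                cur_bases.append("N" * ln)
                ref += ln
            else:
                close_block(ref)
                ref += ln
                cur_start = ref
                cur_bases = []
        elif op == 4:  # S
            qpos += ln
        elif op in (5, 6):  # H, P
            pass
        else:
            raise MalformedRecordError(
                rec.query_name or "?", f"unsupported CIGAR op {op}"
            )
    close_block(ref)
    if not blocks:
        raise MalformedRecordError(rec.query_name or "?", "no reference-consuming ops")
    return blocks, bases


def read_alignments(
    path,
    drop_multimappers: bool = True,
    min_intron: int = 20,
    contigs: Iterable[str] | None = None,
) -> Iterator[AlignedRead]:
    """Stream AlignedReads from a SAM/BAM file.

    Secondary, supplementary and unmapped records are skipped.  With
    ``drop_multimappers`` (the default) any read reported at more than
    one location (NH tag > 1, or the secondary bit as a fallback) is
    removed entirely, matching the multi-mapper removal applied before
    assembly.
    """
    known = set(contigs) if contigs is not None else None
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        if known is None:
            known = set(fh.references or [])
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            n_hits = rec.get_tag("NH") if rec.has_tag("NH") else 1
            if drop_multimappers and n_hits > 1:
                continue
            if known and rec.reference_name not in known:
                raise ValueError(
                    f"alignment contig {rec.reference_name!r} absent from genome"
                )
            blocks, bases = _blocks_from_cigar(rec, min_intron)
            yield AlignedRead(
                read_id=rec.query_name or "?",
                contig=rec.reference_name,
                blocks=tuple(blocks),
                block_bases=tuple(bases),
                n_hits=int(n_hits),
                library_strand=_infer_library_strand(rec),
            )


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered exon chain (0-based half-open exons)."""

    transcript_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source: str = "orfweave"

    def __post_init__(self):
        prev = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
            if prev is not None and s < prev:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def total_nt(self) -> int:
        return sum(e - s for s, e in self.exons)


def _model_sort_key(t: TranscriptModel):
    return (t.contig, t.exons[0][0], t.exons[-1][1], t.transcript_id)


def write_gtf(transcripts: Sequence[TranscriptModel], path, source: str = "orfweave") -> None:
    """Emit transcript models as GTF 2.2 (1-based, end-inclusive).

    Output order is deterministic (contig, start, end, id); exon lines
    are always in ascending genomic order, also on the minus strand.
    """
    with open(path, "w") as fh:
        fh.write("##gtf — transcript models (orfweave)\n")
        for t in sorted(transcripts, key=_model_sort_key):
            attrs = f'gene_id "{t.transcript_id}"; transcript_id "{t.transcript_id}";'
            src = t.source or source
            s0, e0 = t.span
            fh.write(
                f"{t.contig}\t{src}\ttranscript\t{s0 + 1}\t{e0}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.contig}\t{src}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def _parse_gtf_attrs(field: str) -> dict[str, str]:
    attrs = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, val = chunk.partition(" ")
            attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon features from a GTF into TranscriptModels (sorted)."""
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "exon":
                continue
            contig, src, _, start, end, _, strand, _, attr = parts[:9]
            tid = _parse_gtf_attrs(attr).get("transcript_id")
            if tid is None:
                raise ValueError(f"exon line without transcript_id in {path}")
            exons.setdefault(tid, []).append((int(start) - 1, int(end)))
            meta[tid] = (contig, strand, src)
    models = []
    for tid, ex in exons.items():
        contig, strand, src = meta[tid]
        ex = sorted(ex)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"{tid}: overlapping exons in {path}")
        models.append(TranscriptModel(tid, contig, strand, tuple(ex), source=src))
    return sorted(models, key=_model_sort_key)


def write_protein_fasta(orfs, path, width: int = 60) -> None:
    """Write ORF records as a protein FASTA searchable by MS pipelines.

    Headers encode transcript id, frame, genomic span, extension and SNP
    flags so every hit is traceable; duplicate headers are fatal.  Two
    ORFs with identical peptide sequence but different genomic origin
    are both kept — downstream searches need every provenance.
    """
    seen = set()
    with open(path, "w") as fh:
        for orf in orfs:
            header = orf.fasta_header()
            if header in seen:
                raise ValueError(f"duplicate protein FASTA header: {header}")
            seen.add(header)
            fh.write(f">{header}\n")
            seq = orf.aa_sequence.rstrip("*")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_protein_fasta(path) -> dict[str, str]:
    """Load a protein FASTA (e.g. a reference proteome) as name -> sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper().rstrip("*") for rec in SeqIO.parse(str(path), "fasta")}
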