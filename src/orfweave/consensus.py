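"""Per-position consensus from aligned read bases.

Read bases replace the reference wherever they agree strongly enough,
so that downstream translation reflects sample-specific point mutations
(cell-line SNPs) instead of the reference genome.  Only substitutions
are modelled: read insertions/deletions are ignored for consensus, and
counts are pooled across read strands (a genomic SNP is
strand-symmetric).

A position gets a consensus call only when its coverage reaches
``min_cov`` and the majority base reaches a fraction ``maj_frac`` of the
(A/C/G/T) tally; N bases never count.  With ``maj_frac`` > 0.5 a tie can
never be called, so the lexicographic argmax used internally is
irrelevant to the output.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .io_formats import AlignedRead, GenomeSequence

_BASES = "ACGT"
_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


class ConsensusDB:
    """Base tallies over every covered genomic position.

    Parameters
    ----------
    contig_lengths:
        mapping contig -> length; tallies are dense uint32 arrays.
    min_cov, maj_frac:
        call thresholds (defaults 5 and 0.8; chosen to suppress
        sequencing-error miscalls at typical depth).
    """

    def __init__(self, contig_lengths: dict[str, int], min_cov: int = 5, maj_frac: float = 0.8):
        self.min_cov = int(min_cov)
        self.maj_frac = float(maj_frac)
        self.counts: dict[str, np.ndarray] = {
            c: np.zeros((4, L), dtype=np.uint32) for c, L in contig_lengths.items()
        }

    def add_read(self, read: AlignedRead) -> None:
        arr = self.counts[read.contig]
        for (s, e), bases in zip(read.blocks, read.block_bases):
            idx = _LUT[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]
            mask = idx >= 0
            if mask.any():
                np.add.at(arr, (idx[mask], np.arange(s, e)[mask]), 1)

    def base_counts(self, contig: str, pos: int) -> dict[str, int]:
        col = self.counts[contig][:, pos]
        return {b: int(col[i]) for i, b in enumerate(_BASES)}

    def coverage(self, contig: str, pos: int) -> int:
        return int(self.counts[contig][:, pos].sum())

    def call(self, contig: str, pos: int) -> str | None:
        """Consensus base at one position, or None below thresholds."""
        mask, bases = self.call_interval(contig, pos, pos + 1)
        return bases[0] if mask[0] else None

    def call_interval(self, contig: str, start: int, end: int):
        """Vectorised calls over [start, end): (called mask, base array)."""
        sub = self.counts[contig][:, start:end]
        cov = sub.sum(axis=0)
        best = sub.argmax(axis=0)
        best_n = sub.max(axis=0)
        called = (cov >= self.min_cov) & (best_n >= self.maj_frac * cov) & (cov > 0)
        bases = np.frombuffer(_BASES.encode(), dtype="S1")[best].astype("U1")
        return called, bases


def build_consensus(
    reads: Iterable[AlignedRead],
    contig_lengths: dict[str, int],
    min_cov: int = 5,
    maj_frac: float = 0.8,
) -> ConsensusDB:
    """Tally every covered position once per read and return the database."""
    db = ConsensusDB(contig_lengths, min_cov=min_cov, maj_frac=maj_frac)
    for read in reads:
        db.add_read(read)
    return db


def apply_consensus(
    genome_seq: GenomeSequence, db: ConsensusDB | None, start: int, end: int
) -> tuple[str, list[tuple[int, str, str]]]:
    """Reference slice with consensus substitutions applied.

    Returns the corrected sequence over [start, end) and the list of
    substitutions as (genomic position, ref base, alt base).  Idempotent:
    re-applying to the output changes nothing.
    """
    ref = genome_seq.slice(start, end)
    if db is None or genome_seq.contig_name not in db.counts:
        return ref, []
    called, bases = db.call_interval(genome_seq.contig_name, start, end)
    if not called.any():
        return ref, []
    seq = np.array(list(ref), dtype="U1")
    diff = called & (bases != seq)
    subs = [
        (start + int(i), str(seq[i]), str(bases[i]))
        for i in np.nonzero(diff)[0]
    ]
    seq[diff] = bases[diff]
    return "".join(seq), subs


def write_substitutions_tsv(subs, db: ConsensusDB, path) -> None:
    """Dump substitutions as a VCF-lite TSV: contig, 1-based pos, ref, alt, depth, fraction."""
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\tdepth\tfraction\n")
        for contig, pos, ref, alt in sorted(subs):
            counts = db.base_counts(contig, pos)
            depth = sum(counts.values())
            frac = counts.get(alt, 0) / depth if depth else 0.0
            fh.write(f"{contig}\t{pos + 1}\t{ref}\t{alt}\t{depth}\t{frac:.4f}\n")
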