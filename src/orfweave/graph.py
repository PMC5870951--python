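"""Exon/junction graph construction from spliced alignments.

Junctions (intron calls) are tallied from gapped reads, filtered by
count-based heuristics, and then used to subdivide contiguous
read-covered regions into *all possible* read-supported exon variants:
for every combination of boundary choices (coverage edge or junction
point) on each side, one candidate exon — except variants that straddle
a retained junction's intron, which are emitted only when
intron-retention output is switched on (and then flagged).

Filtering heuristics:

* junctions below ``min_junction_reads`` supporting reads are dropped;
* introns longer than ``max_intron`` (default 1,000,000 nt; boundary
  inclusive — exactly 1 Mb is kept) are biologically implausible and
  dropped;
* among junctions sharing one endpoint whose other endpoints lie within
  ``endpoint_window`` nt of each other, only the best-supported one is
  kept (the "most probable intron endpoints" rule);
* exons below ``min_exon_support`` reads/kb are dropped, and short
  (<``short_single_exon_len``) purely coverage-bounded exons — would-be
  single-exon transcripts — need ``short_single_exon_support`` reads.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io_formats import AlignedRead


@dataclass(frozen=True)
class Junction:
    """An intron call: exon end (donor_end, exclusive) to next exon start."""

    contig: str
    donor_end: int
    acceptor_start: int
    strand: str
    count: int = 1

    def __post_init__(self):
        if self.acceptor_start <= self.donor_end:
            raise ValueError("acceptor_start must exceed donor_end")

    @property
    def intron_length(self) -> int:
        return self.acceptor_start - self.donor_end


@dataclass(frozen=True)
class CoverageContig:
    """A maximal contiguous read-covered region (after gap filling)."""

    contig: str
    start: int
    end: int


@dataclass(frozen=True)
class CandidateExon:
    """A read-supported interval with its length-normalised count X.

    ``X`` is reads overlapping the exon per kilobase of exon length.
    Boundary flags record whether each side was defined by a junction
    point or by the edge of read coverage.
    """

    contig: str
    start: int
    end: int
    strand: str
    X: float
    n_reads: int
    left_junction_bounded: bool = False
    right_junction_bounded: bool = False
    retained_intron: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def coords(self) -> tuple[int, int]:
        return self.start, self.end


def collect_junctions(reads: Iterable[AlignedRead]) -> list[Junction]:
    """One Junction per distinct (contig, donor, acceptor, strand), with
    the number of supporting reads as its count."""
    tally: dict[tuple[str, int, int, str], int] = defaultdict(int)
    for read in reads:
        for d, a in read.introns():
            tally[(read.contig, d, a, read.library_strand)] += 1
    return sorted(
        (Junction(c, d, a, s, n) for (c, d, a, s), n in tally.items()),
        key=lambda j: (j.contig, j.donor_end, j.acceptor_start, j.strand),
    )


def _dominant_per_endpoint(junctions: list[Junction], shared: str, window: int) -> set[Junction]:
    """Cluster junctions sharing one endpoint whose *other* endpoints lie
    within ``window`` nt; keep the highest-count junction per cluster."""
    groups: dict[tuple, list[Junction]] = defaultdict(list)
    for j in junctions:
        key = (
            (j.contig, j.strand, j.donor_end)
            if shared == "donor"
            else (j.contig, j.strand, j.acceptor_start)
        )
        groups[key].append(j)
    keep: set[Junction] = set()
    for members in groups.values():
        other = (lambda j: j.acceptor_start) if shared == "donor" else (lambda j: j.donor_end)
        members.sort(key=lambda j: (other(j), -j.count))
        cluster: list[Junction] = []

        def flush():
            if cluster:
                best = max(cluster, key=lambda j: (j.count, -other(j)))
                keep.add(best)

        for j in members:
            if cluster and other(j) - other(cluster[-1]) > window:
                flush()
                cluster = []
            cluster.append(j)
        flush()
    return keep


def filter_junctions(
    junctions: Sequence[Junction],
    min_junction_reads: int = 2,
    max_intron: int = 1_000_000,
    endpoint_window: int = 10,
) -> list[Junction]:
    """Apply the junction heuristics (support, intron cap, endpoint plausibility)."""
    kept = [
        j
        for j in junctions
        if j.count >= min_junction_reads and j.intron_length <= max_intron
    ]
    by_donor = _dominant_per_endpoint(kept, "donor", endpoint_window)
    by_acceptor = _dominant_per_endpoint(kept, "acceptor", endpoint_window)
    return sorted(
        by_donor & by_acceptor,
        key=lambda j: (j.contig, j.donor_end, j.acceptor_start, j.strand),
    )


def build_contigs(
    reads: Iterable[AlignedRead], max_fill_gap: int = 50
) -> list[CoverageContig]:
    """Contiguous regions of read coverage, bridging internal zero-coverage
    gaps of at most ``max_fill_gap`` nt that are flanked by coverage."""
    blocks: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for read in reads:
        blocks[read.contig].extend(read.blocks)
    contigs: list[CoverageContig] = []
    for contig in sorted(blocks):
        merged: list[list[int]] = []
        for s, e in sorted(blocks[contig]):
            if merged and s - merged[-1][1] <= max_fill_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        contigs.extend(CoverageContig(contig, s, e) for s, e in merged)
    return contigs


class ReadIndex:
    """Interval index of read footprints for overlap counting."""

    def __init__(self, reads: Sequence[AlignedRead]):
        self.reads = list(reads)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for i, read in enumerate(self.reads):
            for s, e in read.blocks:
                self._trees[read.contig].addi(s, e, i)

    def overlapping(self, contig: str, start: int, end: int) -> set[int]:
        return {iv.data for iv in self._trees[contig].overlap(start, end)}

    def count(self, contig: str, start: int, end: int) -> int:
        return len(self.overlapping(contig, start, end))

    def strand_majority(self, contig: str, start: int, end: int) -> str:
        votes = defaultdict(int)
        for i in self.overlapping(contig, start, end):
            votes[self.reads[i].library_strand] += 1
        if votes.get("-", 0) > votes.get("+", 0):
            return "-"
        return "+"


def make_exons(
    contigs: Sequence[CoverageContig],
    junctions: Sequence[Junction],
    reads: Sequence[AlignedRead] | ReadIndex,
    min_exon_support: float = 1.0,
    short_single_exon_len: int = 1000,
    short_single_exon_support: int = 4,
    emit_retained_introns: bool = False,
) -> list[CandidateExon]:
    """Subdivide coverage contigs at retained junction points into all
    possible candidate exons, then apply read-support filters."""
    index = reads if isinstance(reads, ReadIndex) else ReadIndex(reads)
    by_contig: dict[str, list[Junction]] = defaultdict(list)
    for j in junctions:
        by_contig[j.contig].append(j)

    placed: set[Junction] = set()
    exons: list[CandidateExon] = []
    for cov in contigs:
        cands = by_contig.get(cov.contig, [])
        strands = sorted({j.strand for j in cands}) or [None]
        emitted_any = False
        for strand in strands:
            if strand is None:
                starts, ends, introns = {cov.start}, {cov.end}, []
            else:
                sj = [j for j in cands if j.strand == strand]
                starts = {cov.start} | {
                    j.acceptor_start for j in sj if cov.start <= j.acceptor_start < cov.end
                }
                ends = {cov.end} | {
                    j.donor_end for j in sj if cov.start < j.donor_end <= cov.end
                }
                introns = [
                    (j.donor_end, j.acceptor_start)
                    for j in sj
                    if j.donor_end < cov.end and j.acceptor_start > cov.start
                ]
                for j in sj:
                    if cov.start <= j.acceptor_start < cov.end or cov.start < j.donor_end <= cov.end:
                        placed.add(j)
            acceptor_set = starts - {cov.start}
            donor_set = ends - {cov.end}
            for s in sorted(starts):
                for e in sorted(ends):
                    if e <= s:
                        continue
                    retained = any(min(e, a) - max(s, d) > 0 for d, a in introns)
                    if retained and not emit_retained_introns:
                        continue
                    n = index.count(cov.contig, s, e)
                    if n == 0:
                        continue
                    x = n / ((e - s) / 1000.0)
                    exon_strand = (
                        strand
                        if strand is not None
                        else index.strand_majority(cov.contig, s, e)
                    )
                    left_j = s in acceptor_set or (strand is not None and s == cov.start and _touches(cands, strand, acceptor=s))
                    right_j = e in donor_set or (strand is not None and e == cov.end and _touches(cands, strand, donor=e))
                    exon = CandidateExon(
                        cov.contig,
                        s,
                        e,
                        exon_strand,
                        X=x,
                        n_reads=n,
                        left_junction_bounded=left_j,
                        right_junction_bounded=right_j,
                        retained_intron=retained,
                    )
                    if exon.X < min_exon_support:
                        continue
                    if (
                        not exon.left_junction_bounded
                        and not exon.right_junction_bounded
                        and exon.length < short_single_exon_len
                        and exon.n_reads < short_single_exon_support
                    ):
                        continue
                    exons.append(exon)
                    emitted_any = True
    stray = [j for j in junctions if j not in placed and not _inside_any(j, contigs)]
    if stray:
        warnings.warn(f"{len(stray)} junction endpoint(s) fall outside all coverage contigs")
    return sorted(
        exons, key=lambda e: (e.contig, e.start, e.end, e.strand, e.retained_intron)
    )


def _touches(junctions: Sequence[Junction], strand: str, acceptor: int | None = None, donor: int | None = None) -> bool:
    for j in junctions:
        if j.strand != strand:
            continue
        if acceptor is not None and j.acceptor_start == acceptor:
            return True
        if donor is not None and j.donor_end == donor:
            return True
    return False


def _inside_any(j: Junction, contigs: Sequence[CoverageContig]) -> bool:
    for cov in contigs:
        if cov.contig != j.contig:
            continue
        if cov.start < j.donor_end <= cov.end or cov.start <= j.acceptor_start < cov.end:
            return True
    return False


def write_junction_bed(junctions: Sequence[Junction], path) -> None:
    """6-column BED of retained junctions (score = supporting reads)."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                f"{j.contig}\t{j.donor_end}\t{j.acceptor_start}\t"
                f"junction\t{j.count}\t{j.strand}\n"
            )


def write_exon_bed(exons: Sequence[CandidateExon], path) -> None:
    with open(path, "w") as fh:
        for e in exons:
            fh.write(
                f"{e.contig}\t{e.start}\t{e.end}\texon\t{e.X:.3f}\t{e.strand}\n"
            )
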