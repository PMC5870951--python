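"""Greedy transcript assembly over the exon/junction graph.

From each seed exon the chain is grown one junction at a time.  The next
endpoint is the one maximising

    score(p) = ( C(E_i, p) / sum_f C(E_i, f) ) * w(D(E_i, p))

where C is the junction's supporting read count (normalised over all
junctions leaving E_i) and D the intron length.  The next exon is then
the candidate starting at that endpoint with the largest
length-normalised read count X(e).  The distance weight w(D) is
switchable: ``inverse`` (default, 1 / (1 + D/D0): proximal acceptors
preferred, the anti-artifact reading), ``linear`` (w = D: distal
acceptors rewarded) or ``none``.

Controlled branching keeps isoform diversity without combinatorial
explosion: any endpoint whose *normalised support* reaches
``candidate_branch_cutoff`` spawns an extra chain, up to
``max_transcripts_per_seed`` per seed.

Transcript-level filtering realises the stringency/diversity trade-off
through a single parameter ``s`` in [0, 1]: transcripts are sorted by
exon count, dropped when their mean exon expression falls below
``s * expression_threshold_base``, and — walking the sorted list — a
transcript whose internal junction chain is a subset of an already
accepted, genomically overlapping transcript's chain is kept only if
its mean expression is at least ``s`` times the accepted one's.  At
s = 0 nothing is filtered (maximal diversity); the output shrinks
monotonically as s rises.
"""

from __future__ import annotations

import statistics
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .graph import CandidateExon, Junction
from .io_formats import TranscriptModel


@dataclass
class AssemblerConfig:
    stringency: float = 0.3
    max_transcripts_per_seed: int = 16
    expression_threshold_base: float | None = None  # default: median X over exons
    candidate_branch_cutoff: float = 0.15
    distance_weight: str = "inverse"  # inverse | linear | none
    distance_scale: float = 10_000.0
    seed_all: bool = False

    def __post_init__(self):
        if not 0.0 <= self.stringency <= 1.0:
            raise ValueError("stringency must lie in [0, 1]")
        if self.distance_weight not in ("inverse", "linear", "none"):
            raise ValueError(f"unknown distance weight {self.distance_weight!r}")


@dataclass(frozen=True)
class Transcript:
    """An assembled, ordered exon chain joined by retained junctions."""

    id: str
    contig: str
    strand: str
    exons: tuple[CandidateExon, ...]
    junctions: tuple[Junction, ...]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_coords(self) -> tuple[tuple[int, int], ...]:
        return tuple(e.coords for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    @property
    def total_nt(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def mean_expression(self) -> float:
        return sum(e.X for e in self.exons) / len(self.exons)

    @property
    def junction_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((j.donor_end, j.acceptor_start) for j in self.junctions)

    def to_model(self, source: str = "orfweave") -> TranscriptModel:
        return TranscriptModel(self.id, self.contig, self.strand, self.exon_coords, source)


def distance_weight_fn(config: AssemblerConfig) -> Callable[[int], float]:
    if config.distance_weight == "inverse":
        d0 = config.distance_scale
        return lambda d: 1.0 / (1.0 + d / d0)
    if config.distance_weight == "linear":
        return lambda d: float(d)
    return lambda d: 1.0


def score_endpoint(junction: Junction, total_count: int, config: AssemblerConfig) -> float:
    """Normalised junction support times the distance weight; deterministic."""
    ns = junction.count / total_count
    return ns * distance_weight_fn(config)(junction.intron_length)


def _strand_compatible(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


class _Graph:
    """Deterministic junction/exon indexes for chain extension."""

    def __init__(self, exons: Sequence[CandidateExon], junctions: Sequence[Junction]):
        self.exons = sorted(exons, key=lambda e: (e.contig, e.start, e.end, e.strand))
        self.junctions = list(junctions)
        self.by_donor: dict[tuple[str, int], list[Junction]] = defaultdict(list)
        for j in junctions:
            self.by_donor[(j.contig, j.donor_end)].append(j)
        self.by_start: dict[tuple[str, int], list[CandidateExon]] = defaultdict(list)
        for e in self.exons:
            self.by_start[(e.contig, e.start)].append(e)
        self.acceptors: dict[str, set[tuple[int, str]]] = defaultdict(set)
        for j in junctions:
            self.acceptors[j.contig].add((j.acceptor_start, j.strand))

    def outgoing(self, exon: CandidateExon, chain_strand: str) -> list[Junction]:
        return [
            j
            for j in self.by_donor[(exon.contig, exon.end)]
            if _strand_compatible(chain_strand, j.strand)
        ]

    def exons_at(self, contig: str, start: int, chain_strand: str) -> list[CandidateExon]:
        return [
            e
            for e in self.by_start[(contig, start)]
            if _strand_compatible(chain_strand, e.strand)
        ]

    def has_incoming(self, exon: CandidateExon) -> bool:
        return any(
            _strand_compatible(exon.strand, s)
            for (a, s) in self.acceptors[exon.contig]
            if a == exon.start
        )


def choose_endpoint(
    exon: CandidateExon,
    graph: _Graph,
    chain_strand: str,
    config: AssemblerConfig,
) -> list[tuple[Junction, float, float]]:
    """Candidate endpoints from ``exon``, best first.

    Returns (junction, normalised support, score) sorted by score, with
    ties broken by higher raw support, then by distance weight, then by
    leftmost acceptor coordinate.  Empty list signals chain termination.
    """
    cands = graph.outgoing(exon, chain_strand)
    if not cands:
        return []
    total = sum(j.count for j in cands)
    w = distance_weight_fn(config)
    scored = [(j, j.count / total, (j.count / total) * w(j.intron_length)) for j in cands]
    scored.sort(
        key=lambda t: (-t[2], -t[1], -w(t[0].intron_length), t[0].acceptor_start)
    )
    return scored


def next_exon(
    candidates: Sequence[CandidateExon],
) -> CandidateExon | None:
    """argmax X(e); ties broken by longer exon, then leftmost end."""
    if not candidates:
        return None
    return min(candidates, key=lambda e: (-e.X, -e.length, e.end))


def assemble(
    exons: Sequence[CandidateExon],
    junctions: Sequence[Junction],
    config: AssemblerConfig | None = None,
) -> list[Transcript]:
    """Greedily chain exons across retained junctions into transcripts.

    Seeds are exons with no incoming retained junction (every exon with
    ``seed_all``).  Branching follows ``candidate_branch_cutoff`` and is
    capped at ``max_transcripts_per_seed`` chains per seed; the
    best-scoring branch is always explored first, so the single emitted
    chain under disabled branching is the pure greedy chain.
    """
    config = config or AssemblerConfig()
    graph = _Graph(exons, junctions)
    seeds = [e for e in graph.exons if config.seed_all or not graph.has_incoming(e)]

    chains: list[tuple[str, tuple[CandidateExon, ...], tuple[Junction, ...]]] = []
    seen: set = set()

    for seed in seeds:
        emitted = 0

        def grow(chain: list[CandidateExon], juncs: list[Junction], strand: str):
            nonlocal emitted
            if emitted >= config.max_transcripts_per_seed:
                return
            last = chain[-1]
            endpoints = choose_endpoint(last, graph, strand, config)
            taken = False
            for rank, (j, ns, _score) in enumerate(endpoints):
                if rank > 0 and ns < config.candidate_branch_cutoff:
                    continue
                if emitted >= config.max_transcripts_per_seed:
                    return
                assert j.acceptor_start > last.end  # genomic coordinates: no cycles
                nxt = next_exon(graph.exons_at(last.contig, j.acceptor_start, j.strand))
                if nxt is None:
                    continue
                new_strand = j.strand if strand == "." else strand
                grow(chain + [nxt], juncs + [j], new_strand)
                taken = True
            if not taken:
                final_strand = strand if strand != "." else chain[0].strand
                key = (chain[0].contig, final_strand, tuple(e.coords for e in chain))
                if key not in seen:
                    seen.add(key)
                    chains.append((final_strand, tuple(chain), tuple(juncs)))
                emitted += 1

        grow([seed], [], seed.strand)

    chains.sort(key=lambda c: (c[1][0].contig, c[1][0].start, c[1][-1].end, c[0], tuple(e.coords for e in c[1])))
    return [
        Transcript(f"OW.{i + 1}", chain[0].contig, strand, chain, juncs)
        for i, (strand, chain, juncs) in enumerate(chains)
    ]


def _spans_overlap(a: Transcript, b: Transcript) -> bool:
    return a.contig == b.contig and a.span[0] < b.span[1] and b.span[0] < a.span[1]


def filter_transcripts(
    transcripts: Sequence[Transcript],
    config: AssemblerConfig | None = None,
    all_exons: Sequence[CandidateExon] | None = None,
) -> list[Transcript]:
    """Stringency-modulated expression and similarity filtering.

    The expression threshold base defaults to the median X(e) over the
    candidate exon set (``all_exons``), so the threshold scales with
    dataset depth.
    """
    config = config or AssemblerConfig()
    s = config.stringency
    base = config.expression_threshold_base
    if base is None:
        pool = (
            [e.X for e in all_exons]
            if all_exons
            else [e.X for t in transcripts for e in t.exons]
        )
        base = statistics.median(pool) if pool else 0.0
    threshold = s * base

    ordered = sorted(
        transcripts,
        key=lambda t: (-t.n_exons, t.contig, t.span, t.strand, t.id),
    )
    accepted: list[Transcript] = []
    for t in ordered:
        if t.mean_expression < threshold:
            continue
        chain = set(t.junction_chain)
        blockers = [
            a
            for a in accepted
            if a.strand == t.strand
            and _spans_overlap(a, t)
            and chain <= set(a.junction_chain)
        ]
        if blockers:
            ceiling = max(a.mean_expression for a in blockers)
            if t.mean_expression < ceiling * s:
                continue
        accepted.append(t)
    return accepted
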