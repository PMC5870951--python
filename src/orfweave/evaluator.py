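"""Exon-overlap evaluation of an assembly against a reference annotation.

A reference transcript counts as *recovered* when at least one of its
exons overlaps (by >= 1 nt) an exon of at least one assembled
transcript; an assembled transcript with no such overlap is a false
positive.  This is deliberately permissive transcript matching — it
asks whether the locus was represented at all, not whether the exact
intron chain was reproduced — and it is strand-silent by default (a
flag enables strand-aware matching).  Recovery is a set property: a
reference transcript counts once no matter how many assembled
transcripts hit it.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .io_formats import TranscriptModel


@dataclass
class EvalResult:
    n_reference: int
    n_assembled: int
    n_recovered: int  # TP
    n_unmatched_assembled: int  # FP
    n_missed: int  # FN
    total_transcriptome_nt: int

    @property
    def precision(self) -> float | None:
        denom = self.n_recovered + self.n_unmatched_assembled
        return self.n_recovered / denom if denom else None

    @property
    def recall(self) -> float | None:
        denom = self.n_recovered + self.n_missed
        return self.n_recovered / denom if denom else None

    def to_dict(self) -> dict:
        return {
            "n_reference": self.n_reference,
            "n_assembled": self.n_assembled,
            "n_recovered": self.n_recovered,
            "n_unmatched_assembled": self.n_unmatched_assembled,
            "n_missed": self.n_missed,
            "precision": self.precision,
            "recall": self.recall,
            "total_transcriptome_nt": self.total_transcriptome_nt,
        }


def transcripts_overlap(
    a: TranscriptModel, b: TranscriptModel, strand_aware: bool = False
) -> bool:
    """True iff some exon of ``a`` intersects some exon of ``b`` by >= 1 nt
    (same contig; same strand only when ``strand_aware``).  Symmetric."""
    if a.contig != b.contig:
        return False
    if strand_aware and a.strand != b.strand:
        return False
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            if min(e1, e2) - max(s1, s2) > 0:
                return True
    return False


def evaluate(
    assembled: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    strand_aware: bool = False,
) -> EvalResult:
    """Precision/recall of the assembly under the exon-overlap rule.

    With an empty reference both precision and recall are undefined
    (None).  The result is invariant to input ordering.
    """
    trees: dict = defaultdict(IntervalTree)
    for ri, ref in enumerate(reference):
        for s, e in ref.exons:
            trees[(ref.contig, ref.strand if strand_aware else None)].addi(s, e, ri)

    recovered: set[int] = set()
    n_fp = 0
    for t in assembled:
        keys = (
            [(t.contig, t.strand)] if strand_aware else [(t.contig, None)]
        )
        hit_refs: set[int] = set()
        for key in keys:
            tree = trees.get(key)
            if tree is None:
                continue
            for s, e in t.exons:
                hit_refs.update(iv.data for iv in tree.overlap(s, e))
        if hit_refs:
            recovered.update(hit_refs)
        else:
            n_fp += 1

    return EvalResult(
        n_reference=len(reference),
        n_assembled=len(assembled),
        n_recovered=len(recovered),
        n_unmatched_assembled=n_fp,
        n_missed=len(reference) - len(recovered),
        total_transcriptome_nt=sum(t.total_nt for t in assembled),
    )


def write_eval_json(result: EvalResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_match_table(
    assembled: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    path,
    strand_aware: bool = False,
) -> None:
    """Per-reference-transcript TSV of which assembled transcripts hit it."""
    with open(path, "w") as fh:
        fh.write("reference_id\trecovered\tassembled_ids\n")
        for ref in reference:
            hits = [
                t.transcript_id
                for t in assembled
                if transcripts_overlap(t, ref, strand_aware)
            ]
            fh.write(f"{ref.transcript_id}\t{int(bool(hits))}\t{','.join(hits)}\n")
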