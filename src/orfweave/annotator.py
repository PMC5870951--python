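"""Microprotein identification downstream of the database search.

Given a list of detected peptides, this module (1) removes peptides
already present in an annotated reference proteome, (2) maps the
survivors back onto the translated ORF database, (3) assigns a start
codon to each supporting ORF and (4) classifies the call:

* an in-frame ATG upstream of (or at) the peptide → canonical AUG start
  (the upstream-most qualifying codon is taken: longest-ORF reading);
* otherwise the upstream-most in-frame near-cognate codon (one
  substitution away from ATG) in a Kozak context;
* otherwise the ORF is judged by its stop-to-stop extent: fewer than
  150 codons between the flanking stops annotates a smORF.

Peptide matching applies I/L equivalence throughout, because leucine
and isoleucine are isobaric and indistinguishable in the shotgun-MS
workflow this database serves.  Calls whose only disagreements with an
annotated protein are explained by consensus-called SNPs are flagged as
cell-line-specific mutants of known proteins and excluded from the
novel list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .translator import NEAR_COGNATE_CODONS, ORFRecord, kozak_ok

SMORF_MAX_CODONS = 150


def normalize_il(seq: str) -> str:
    """Collapse I/L (isobaric residues) for MS-level sequence identity."""
    return seq.upper().replace("L", "I")


def filter_annotated(
    peptides: Sequence[str], reference_proteome: dict[str, str]
) -> tuple[list[str], list[str]]:
    """Split peptides into (novel, annotated) by exact substring search
    against the reference proteome under I/L equivalence."""
    if not reference_proteome:
        warnings.warn("empty reference proteome: all peptides pass as novel")
        return list(peptides), []
    prots = [normalize_il(p) for p in reference_proteome.values()]
    novel, removed = [], []
    for pep in peptides:
        pn = normalize_il(pep)
        (removed if any(pn in prot for prot in prots) else novel).append(pep)
    return novel, removed


@dataclass(frozen=True)
class PeptideHit:
    peptide: str
    orf: ORFRecord
    aa_offset: int


def map_peptide(peptide: str, orf_db: Sequence[ORFRecord]) -> list[PeptideHit]:
    """All ORFs containing the peptide (I/L-equivalent), with offsets."""
    pn = normalize_il(peptide)
    hits: list[PeptideHit] = []
    for orf in orf_db:
        hay = normalize_il(orf.aa_sequence)
        start = hay.find(pn)
        while start != -1:
            hits.append(PeptideHit(peptide, orf, start))
            start = hay.find(pn, start + 1)
    return hits


@dataclass
class SmORFCall:
    peptide: str
    orf_id: str | None
    orf: ORFRecord | None
    start_codon: str | None
    start_class: str  # AUG | near-cognate-Kozak | stop-bounded | unmappable
    start_offset: int | None
    orf_length_codons: int | None
    is_smORF: bool
    known_protein_hit: bool = False
    snp_mutant_of_known: bool = False
    unmappable: bool = False


def assign_start(
    hit: PeptideHit, kozak_mode: str = "either", smorf_max_codons: int = SMORF_MAX_CODONS
) -> SmORFCall:
    """Start-codon assignment and smORF classification for one ORF hit.

    Deterministic, and invariant to the peptide chosen within the same
    ORF as long as the peptide lies downstream of the assigned start.
    """
    orf = hit.orf
    assert 0 <= hit.aa_offset and hit.aa_offset + len(hit.peptide) <= orf.n_codons, (
        "peptide not inside the stop-to-stop frame"
    )
    codons = orf.codons()
    p0 = hit.aa_offset

    atg = [i for i in range(p0 + 1) if codons[i].upper() == "ATG"]
    if atg:
        start = atg[0]
        length = orf.n_codons - start
        return SmORFCall(
            hit.peptide, orf.orf_id, orf, "ATG", "AUG", start, length,
            is_smORF=orf.has_downstream_stop and length < smorf_max_codons,
        )

    for i in range(p0 + 1):
        codon = codons[i].upper()
        if codon not in NEAR_COGNATE_CODONS:
            continue
        minus3 = (
            orf.cds_nt[3 * i - 3]
            if i > 0
            else (orf.upstream_flank[0] if len(orf.upstream_flank) == 3 else "")
        )
        plus4 = (
            orf.cds_nt[3 * i + 3]
            if 3 * i + 3 < len(orf.cds_nt)
            else (orf.downstream_flank[0] if orf.downstream_flank else "")
        )
        if kozak_ok(minus3, plus4, kozak_mode):
            length = orf.n_codons - i
            return SmORFCall(
                hit.peptide, orf.orf_id, orf, codon, "near-cognate-Kozak", i, length,
                is_smORF=orf.has_downstream_stop and length < smorf_max_codons,
            )

    bounded = orf.has_upstream_stop and orf.has_downstream_stop
    return SmORFCall(
        hit.peptide, orf.orf_id, orf, None, "stop-bounded", None, orf.n_codons,
        is_smORF=bounded and orf.n_codons < smorf_max_codons,
    )


def flag_snp_mutants(
    call: SmORFCall,
    reference_proteome: dict[str, str],
    substitutions: Iterable[tuple[str, int]],
    peptide_offset: int | None = None,
) -> SmORFCall:
    """Mark calls whose peptide only differs from an annotated protein at
    consensus-called SNP codons (cell-line mutants of known proteins)."""
    if call.orf is None:
        return call
    orf = call.orf
    pep = normalize_il(call.peptide)
    lp = len(pep)
    if peptide_offset is None:
        peptide_offset = normalize_il(orf.aa_sequence).find(pep)
    if peptide_offset < 0:
        return call
    sub_pos = set(substitutions)
    gpos = orf.genomic_positions()
    explained = []
    for j in range(lp):
        codon_pos = gpos[3 * (peptide_offset + j) : 3 * (peptide_offset + j) + 3]
        explained.append(any((orf.contig, p) in sub_pos for p in codon_pos))

    for prot in reference_proteome.values():
        hay = normalize_il(prot)
        for w in range(len(hay) - lp + 1):
            window = hay[w : w + lp]
            mismatches = [j for j in range(lp) if window[j] != pep[j]]
            if mismatches and all(explained[j] for j in mismatches):
                call.snp_mutant_of_known = True
                return call
    return call


def annotate_peptides(
    peptides: Sequence[str],
    orf_db: Sequence[ORFRecord],
    reference_proteome: dict[str, str] | None = None,
    substitutions: Iterable[tuple[str, int]] = (),
    kozak_mode: str = "either",
) -> list[SmORFCall]:
    """The full peptide-level decision tree; one call per input peptide.

    A peptide with several ORF hits keeps the hit giving the most
    confident start class (AUG, then near-cognate, then stop-bounded),
    ties broken deterministically by ORF id.
    """
    proteome = reference_proteome or {}
    novel, removed = filter_annotated(peptides, proteome) if proteome else (list(peptides), [])
    calls: list[SmORFCall] = []
    rank = {"AUG": 0, "near-cognate-Kozak": 1, "stop-bounded": 2}
    for pep in peptides:
        if pep in removed:
            calls.append(
                SmORFCall(pep, None, None, None, "annotated", None, None,
                          is_smORF=False, known_protein_hit=True)
            )
            continue
        hits = map_peptide(pep, orf_db)
        if not hits:
            calls.append(
                SmORFCall(pep, None, None, None, "unmappable", None, None,
                          is_smORF=False, unmappable=True)
            )
            continue
        best: SmORFCall | None = None
        best_key = None
        for hit in hits:
            c = assign_start(hit, kozak_mode=kozak_mode)
            c = flag_snp_mutants(c, proteome, substitutions, hit.aa_offset)
            key = (rank[c.start_class], c.orf_id)
            if best_key is None or key < best_key:
                best, best_key = c, key
        calls.append(best)
    return calls


def novel_smorfs(calls: Sequence[SmORFCall]) -> list[SmORFCall]:
    """The reported novel smORF list: mappable smORF calls that are
    neither annotated peptides nor SNP mutants of annotated proteins."""
    return [
        c
        for c in calls
        if c.is_smORF and not c.known_protein_hit and not c.snp_mutant_of_known and not c.unmappable
    ]


def write_smorf_report(calls: Sequence[SmORFCall], path) -> None:
    cols = [
        "peptide", "orf_id", "contig", "coords", "strand", "start_codon",
        "start_class", "orf_length_codons", "is_smORF",
        "known_protein_hit", "snp_mutant_of_known", "unmappable",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            if c.orf is not None:
                s, e = c.orf.genomic_span
                contig, coords, strand = c.orf.contig, f"{s}-{e}", c.orf.strand
            else:
                contig = coords = strand = ""
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        c.peptide, c.orf_id or "", contig, coords, strand,
                        c.start_codon or "", c.start_class,
                        "" if c.orf_length_codons is None else c.orf_length_codons,
                        int(c.is_smORF), int(c.known_protein_hit),
                        int(c.snp_mutant_of_known), int(c.unmappable),
                    ]
                )
                + "\n"
            )
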