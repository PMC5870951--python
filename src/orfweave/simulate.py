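"""Toy-scale RNA-Seq simulator: genome, transcript truth, spliced reads.

The simulator emits a random genome, a transcript set with isoforms,
optional planted SNPs, designed small ORFs (with chosen start classes),
annotated "known" proteins, SNP-mutant decoys of known proteins, and
deliberately truncated ORFs — plus error-bearing spliced single-end
reads in SAM, written under the fr-firststrand convention (the read
aligns antisense to its transcript).  Everything is driven by one seed
and is byte-for-byte reproducible.

Designed genes (smORFs, known proteins, SNP carriers, truncations) are
placed on the forward strand inside a single exon so their reading
frame survives splicing; the surrounding genome and all ordinary genes
are random.  Reads are drawn uniformly along each transcript with a
depth proportional to expression; one anchoring fragment is pinned to
each transcript end so that simulated coverage reaches the annotated
boundaries (partial 5'/3' coverage is exercised separately through the
truncated-ORF designs, whose *annotation* stops mid-ORF by
construction).  Planted SNPs appear in every read covering them
(clonal, pure-alt), while the genome FASTA keeps the reference base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_formats import (
    GenomeSequence,
    TranscriptModel,
    revcomp,
    write_genome_fasta,
    write_gtf,
)
from .translator import NEAR_COGNATE_CODONS, translate

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
#: codons that are not stops, not ATG and not near-cognate starts
_SAFE_CODONS = [
    c for c in _ALL_CODONS if c not in _STOPS and c != "ATG" and c not in NEAR_COGNATE_CODONS
]


@dataclass
class SimConfig:
    seed: int = 42
    n_genes: int = 50
    isoforms_per_gene: tuple[int, int] = (1, 3)
    exons_per_gene: tuple[int, int] = (1, 5)
    exon_len: tuple[int, int] = (150, 450)
    intron_len: tuple[int, int] = (200, 1200)
    expr_mu: float = 1.0
    expr_sigma: float = 0.75
    read_length: int = 75
    coverage: float = 15.0
    error_rate: float = 0.002
    n_snps: int = 0
    n_smorfs: int = 0
    smorf_classes: tuple[str, ...] = ("AUG", "near-cognate", "stop-bounded")
    n_annotated: int = 0
    n_snp_mutants: int = 0
    n_truncated: int = 0
    antisense_fraction: float = 0.0
    n_multimapper_reads: int = 0
    contig_name: str = "chrS"
    spacing: int = 600
    flank: int = 2000


@dataclass
class PlantedSNP:
    contig: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    ref_peptide: str
    mutant_peptide: str


@dataclass
class PlantedSmORF:
    gene_id: str
    transcript_id: str
    start_class: str  # AUG | near-cognate | stop-bounded
    n_codons: int  # start-to-stop (or stop-to-stop) codon count
    peptide: str
    protein: str
    start_genomic: int | None  # first nt of the designed start codon
    upstream_stop_genomic: int
    downstream_stop_genomic: int


@dataclass
class PlantedTruncation:
    transcript_id: str
    frame_offset: int
    true_start_genomic: int  # first nt of the true upstream ATG
    true_stop_genomic: int  # first nt of the true downstream stop codon
    protein: str


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, GenomeSequence]
    transcripts: list[TranscriptModel]
    expression: dict[str, float]
    coverage: dict[str, float] = field(default_factory=dict)
    snps: list[PlantedSNP] = field(default_factory=list)
    smorfs: list[PlantedSmORF] = field(default_factory=list)
    truncations: list[PlantedTruncation] = field(default_factory=list)
    proteins: dict[str, str] = field(default_factory=dict)
    annotated_peptides: list[str] = field(default_factory=list)


def _rand_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _safe_codons(rng, n: int, first_char: str | None = None) -> list[str]:
    codons = [_SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), n)]
    if first_char is not None and n:
        pool = [c for c in _SAFE_CODONS if c[0] == first_char]
        codons[-1] = pool[int(rng.integers(0, len(pool)))]
    return codons


def _design_orf_insert(rng, start_class: str, n_codons: int) -> tuple[str, dict]:
    """A stop-bounded designed region ``TAA + body + TAA``.

    ``n_codons`` is the start-to-stop length (aa count including the
    start residue) for AUG/near-cognate classes, and the full
    stop-to-stop codon count for the stop-bounded class.
    """
    if start_class == "AUG":
        body = ["ATG"] + _safe_codons(rng, n_codons - 1)
        start_idx = 0
    elif start_class == "near-cognate":
        # the -3 Kozak position of the CTG at index 1 is the first base of
        # the preceding codon, so the filler starts with a purine (A);
        # everything else avoids ATG and near-cognate codons entirely
        body = _safe_codons(rng, 1, first_char="A") + ["CTG"] + _safe_codons(rng, n_codons - 2)
        start_idx = 1
    elif start_class == "stop-bounded":
        body = _safe_codons(rng, n_codons)
        start_idx = None
    else:
        raise ValueError(f"unknown smORF class {start_class!r}")
    nt = "TAA" + "".join(body) + "TAA"
    aa = translate("".join(body))
    assert "*" not in aa
    protein = aa[start_idx:] if start_idx is not None else aa
    pep_from = (start_idx or 0) + 1
    peptide = aa[pep_from : pep_from + 10]
    return nt, {
        "start_idx": start_idx,
        "aa": aa,
        "protein": protein,
        "peptide": peptide,
        "peptide_body_offset": pep_from,
    }


def _mutate_codon(codon: str) -> tuple[str, int, str]:
    """Return (mutant codon, position within codon, alt base); always a
    non-synonymous, non-stop change."""
    for pos in (1, 0, 2):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in _STOPS:
                continue
            if translate(mutant) != translate(codon):
                return mutant, pos, alt
    raise AssertionError(f"no non-synonymous substitution for {codon}")


@dataclass
class _GeneDesign:
    gene_id: str
    kind: str  # random | smorf | annotated | snp | snp_mutant | truncated
    strand: str = "+"
    exon_lens: list[int] = field(default_factory=list)
    intron_lens: list[int] = field(default_factory=list)
    isoform_drops: list[tuple[int, ...]] = field(default_factory=list)
    min_expr: float = 0.0
    smorf_class: str | None = None
    orf_codons: int = 0


def simulate_genome_and_truth(config: SimConfig) -> SimResult:
    """Lay out genes, stamp designed content, and build the truth tables."""
    rng = np.random.default_rng(config.seed)
    designs: list[_GeneDesign] = []
    gi = 0

    def new_id():
        nonlocal gi
        gi += 1
        return f"G{gi:03d}"

    for k in range(config.n_smorfs):
        cls = config.smorf_classes[k % len(config.smorf_classes)]
        designs.append(
            _GeneDesign(new_id(), "smorf", smorf_class=cls,
                        orf_codons=int(rng.integers(40, 90)), min_expr=1.0)
        )
    for _ in range(config.n_annotated):
        designs.append(
            _GeneDesign(new_id(), "annotated", orf_codons=int(rng.integers(60, 110)), min_expr=1.0)
        )
    for _ in range(config.n_snp_mutants):
        designs.append(
            _GeneDesign(new_id(), "snp_mutant", orf_codons=int(rng.integers(60, 110)), min_expr=1.0)
        )
    for _ in range(config.n_snps):
        designs.append(
            _GeneDesign(new_id(), "snp", orf_codons=int(rng.integers(60, 110)), min_expr=1.0)
        )
    for _ in range(config.n_truncated):
        designs.append(_GeneDesign(new_id(), "truncated", orf_codons=60, min_expr=1.0))

    n_random = max(0, config.n_genes - len(designs))
    n_antisense = int(round(config.antisense_fraction * config.n_genes))
    strands = ["-"] * min(n_antisense, n_random) + ["+"] * (n_random - min(n_antisense, n_random))
    rng.shuffle(strands)
    for s in strands:
        designs.append(_GeneDesign(new_id(), "random", strand=s))

    # geometry
    for d in designs:
        if d.kind == "random":
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            d.exon_lens = [
                int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
                for _ in range(n_ex)
            ]
        elif d.kind == "truncated":
            d.exon_lens = [300]
        else:
            # single designed exon holding the whole insert plus padding
            insert_len = 3 * d.orf_codons + 6
            d.exon_lens = [insert_len + 60]
        d.intron_lens = [
            int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            for _ in range(len(d.exon_lens) - 1)
        ]
        n_iso = int(rng.integers(config.isoforms_per_gene[0], config.isoforms_per_gene[1] + 1))
        drops: list[tuple[int, ...]] = [()]
        internal = list(range(1, len(d.exon_lens) - 1))
        for _ in range(n_iso - 1):
            if internal:
                drops.append((int(internal[int(rng.integers(0, len(internal)))]),))
        d.isoform_drops = sorted(set(drops))

    # layout
    cursor = config.flank
    exon_coords: dict[str, list[tuple[int, int]]] = {}
    for d in designs:
        coords = []
        pos = cursor
        for i, L in enumerate(d.exon_lens):
            coords.append((pos, pos + L))
            pos += L
            if i < len(d.intron_lens):
                pos += d.intron_lens[i]
        exon_coords[d.gene_id] = coords
        cursor = pos + config.spacing
    genome_len = cursor + config.flank
    seq = np.array(list(_rand_seq(rng, genome_len)))

    result = SimResult(
        config=config,
        genome={},
        transcripts=[],
        expression={},
    )

    def stamp(start: int, content: str):
        seq[start : start + len(content)] = list(content)

    median_expr = float(np.exp(config.expr_mu))

    for d in designs:
        coords = exon_coords[d.gene_id]
        if d.kind in ("smorf", "annotated", "snp", "snp_mutant"):
            cls = d.smorf_class or "AUG"
            insert, info = _design_orf_insert(rng, cls, d.orf_codons)
            ex_s, ex_e = coords[0]
            offset = 30  # padding inside the exon
            insert_start = ex_s + offset
            stamp(insert_start, insert)
            tid = f"{d.gene_id}.T1"
            body_start = insert_start + 3
            start_gen = (
                body_start + 3 * info["start_idx"] if info["start_idx"] is not None else None
            )
            smorf = PlantedSmORF(
                gene_id=d.gene_id,
                transcript_id=tid,
                start_class=cls,
                n_codons=len(info["protein"]),
                peptide=info["peptide"],
                protein=info["protein"],
                start_genomic=start_gen,
                upstream_stop_genomic=insert_start,
                downstream_stop_genomic=insert_start + len(insert) - 3,
            )
            if d.kind == "smorf":
                result.smorfs.append(smorf)
            elif d.kind == "annotated":
                result.proteins[f"SP_{d.gene_id}"] = info["protein"]
                pep = info["protein"][2:12]
                result.annotated_peptides.append(pep)
            elif d.kind in ("snp", "snp_mutant"):
                aa = info["protein"]
                m = len(aa) // 2
                codon_idx = (info["start_idx"] or 0) + m
                codon_start = body_start + 3 * codon_idx
                codon = "".join(seq[codon_start : codon_start + 3])
                mutant, cpos, alt = _mutate_codon(codon)
                aa_alt = aa[:m] + translate(mutant) + aa[m + 1 :]
                lo, hi = max(0, m - 4), m + 5
                result.snps.append(
                    PlantedSNP(
                        contig=config.contig_name,
                        pos=codon_start + cpos,
                        ref=codon[cpos],
                        alt=alt,
                        gene_id=d.gene_id,
                        ref_peptide=aa[lo:hi],
                        mutant_peptide=aa_alt[lo:hi],
                    )
                )
                if d.kind == "snp_mutant":
                    result.proteins[f"SP_{d.gene_id}"] = aa  # reference version
        elif d.kind == "truncated":
            ex_s, ex_e = coords[0]
            body = _safe_codons(rng, (ex_e - ex_s) // 3)
            stamp(ex_s, "".join(body))
            up = "TAA" + "ATG" + "".join(_safe_codons(rng, 5))  # 21 nt, ends at exon start
            stamp(ex_s - len(up), up)
            down = "".join(_safe_codons(rng, 5)) + "TAA"
            stamp(ex_e, down)
            full_nt = up[3:] + "".join(body) + down[:-3]
            result.truncations.append(
                PlantedTruncation(
                    transcript_id=f"{d.gene_id}.T1",
                    frame_offset=0,
                    true_start_genomic=ex_s - len(up) + 3,
                    true_stop_genomic=ex_e + len(down) - 3,
                    protein=translate(full_nt),
                )
            )

    result.genome = {
        config.contig_name: GenomeSequence(config.contig_name, "".join(seq))
    }

    # transcripts + expression
    for d in designs:
        coords = exon_coords[d.gene_id]
        for k, drop in enumerate(d.isoform_drops):
            tid = f"{d.gene_id}.T{k + 1}"
            exons = tuple(c for i, c in enumerate(coords) if i not in drop)
            result.transcripts.append(
                TranscriptModel(tid, config.contig_name, d.strand, exons, source="truth")
            )
            expr = float(rng.lognormal(config.expr_mu, config.expr_sigma))
            if d.min_expr > 0:
                expr = max(expr, median_expr * d.min_expr)
            result.expression[tid] = expr
    return result


def _tx_window_to_blocks(
    exons: tuple[tuple[int, int], ...], strand: str, t0: int, t1: int
) -> list[tuple[int, int]]:
    order = list(exons) if strand == "+" else list(exons)[::-1]
    spans = []
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
    return [(s, e) for s, e in merged]


def simulate_reads(result: SimResult, sam_path) -> None:
    """Draw spliced reads from the truth transcripts and write a
    coordinate-sorted SAM (updates ``result.coverage`` in place)."""
    config = result.config
    rng = np.random.default_rng(config.seed + 1)
    contig = config.contig_name
    gseq = np.array(list(result.genome[contig].sequence))
    alt = gseq.copy()
    for snp in result.snps:
        alt[snp.pos] = snp.alt

    rl = config.read_length
    mean_expr = float(np.mean(list(result.expression.values()))) or 1.0
    records: list[tuple[int, str]] = []
    rid = 0

    def emit(model: TranscriptModel, t0: int, t1: int, n_hits: int = 1):
        nonlocal rid
        blocks = _tx_window_to_blocks(model.exons, model.strand, t0, t1)
        bases = []
        for s, e in blocks:
            piece = alt[s:e].copy()
            errs = rng.random(e - s) < config.error_rate
            if errs.any():
                shift = rng.integers(1, 4, int(errs.sum()))
                idx = np.nonzero(errs)[0]
                lut = {b: i for i, b in enumerate("ACGT")}
                for ii, sh in zip(idx, shift):
                    piece[ii] = "ACGT"[(lut[str(piece[ii])] + sh) % 4]
            bases.append("".join(piece))
        seq_out = "".join(bases)
        cigar = ""
        for bi, (s, e) in enumerate(blocks):
            if bi:
                cigar += f"{s - blocks[bi - 1][1]}N"
            cigar += f"{e - s}M"
        flag = 16 if model.strand == "+" else 0  # fr-firststrand, single-end
        rid += 1
        line = (
            f"r{rid:06d}\t{flag}\t{contig}\t{blocks[0][0] + 1}\t255\t{cigar}\t*\t0\t0\t"
            f"{seq_out}\t{'I' * len(seq_out)}\tNH:i:{n_hits}"
        )
        records.append((blocks[0][0], line))

    for model in result.transcripts:
        L = model.total_nt
        expr = result.expression[model.transcript_id]
        cov = config.coverage * expr / mean_expr
        if cov <= 0:
            result.coverage[model.transcript_id] = 0.0
            continue
        flen = min(rl, L)
        n = max(1, int(round(cov * L / flen)))
        starts = list(rng.integers(0, L - flen + 1, n)) + [0, L - flen]
        for p in starts:
            emit(model, int(p), int(p) + flen)
        result.coverage[model.transcript_id] = (n + 2) * flen / L

    for _ in range(config.n_multimapper_reads):
        model = result.transcripts[int(rng.integers(0, len(result.transcripts)))]
        L = model.total_nt
        flen = min(rl, L)
        p = int(rng.integers(0, L - flen + 1))
        emit(model, p, p + flen, n_hits=3)

    records.sort(key=lambda r: (r[0], r[1]))
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{contig}\tLN:{len(gseq)}\n")
        for _, line in records:
            fh.write(line + "\n")


def write_truth(result: SimResult, outdir) -> dict[str, Path]:
    """Write the whole fixture bundle; returns the path of each artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "truth_gtf": outdir / "truth.gtf",
        "snps": outdir / "truth_snps.tsv",
        "smorfs": outdir / "truth_smorfs.tsv",
        "proteins": outdir / "reference_proteome.fa",
        "peptides": outdir / "peptides.txt",
        "expression": outdir / "truth_expression.tsv",
    }
    write_genome_fasta(result.genome, paths["genome"])
    write_gtf(result.transcripts, paths["truth_gtf"], source="truth")
    with open(paths["snps"], "w") as fh:
        fh.write("contig\tpos\tref\talt\tgene_id\tref_peptide\tmutant_peptide\n")
        for s in result.snps:
            fh.write(
                f"{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.gene_id}\t"
                f"{s.ref_peptide}\t{s.mutant_peptide}\n"
            )
    with open(paths["smorfs"], "w") as fh:
        fh.write(
            "gene_id\ttranscript_id\tstart_class\tn_codons\tpeptide\tprotein\t"
            "start_genomic\tupstream_stop\tdownstream_stop\n"
        )
        for m in result.smorfs:
            fh.write(
                f"{m.gene_id}\t{m.transcript_id}\t{m.start_class}\t{m.n_codons}\t"
                f"{m.peptide}\t{m.protein}\t"
                f"{'' if m.start_genomic is None else m.start_genomic}\t"
                f"{m.upstream_stop_genomic}\t{m.downstream_stop_genomic}\n"
            )
    with open(paths["proteins"], "w") as fh:
        for name in sorted(result.proteins):
            fh.write(f">{name}\n{result.proteins[name]}\n")
    with open(paths["peptides"], "w") as fh:
        for m in result.smorfs:
            fh.write(m.peptide + "\n")
        for s in result.snps:
            fh.write(s.mutant_peptide + "\n")
        for pep in result.annotated_peptides:
            fh.write(pep + "\n")
    with open(paths["expression"], "w") as fh:
        fh.write("transcript_id\texpression\tcoverage\n")
        for t in result.transcripts:
            tid = t.transcript_id
            fh.write(
                f"{tid}\t{result.expression[tid]:.4f}\t"
                f"{result.coverage.get(tid, float('nan')):.3f}\n"
            )
    return paths


def simulate_bundle(config: SimConfig, outdir) -> dict[str, Path]:
    """Genome + truth + reads in one call (the no-download test surface)."""
    result = simulate_genome_and_truth(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sam = outdir / "reads.sam"
    simulate_reads(result, sam)
    paths = write_truth(result, outdir)
    paths["reads"] = sam
    paths["result"] = result  # in-memory truth for tests
    return paths
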