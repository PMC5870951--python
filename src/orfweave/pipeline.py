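"""End-to-end orchestration: alignments -> consensus -> graph -> assembly
-> translation -> annotation -> evaluation.

Every stage writes its outputs under one directory together with a
manifest (inputs, parameters, version), and reruns on identical inputs
and configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotator import annotate_peptides, novel_smorfs, write_smorf_report
from .assembler import AssemblerConfig, assemble, filter_transcripts
from .consensus import build_consensus, write_substitutions_tsv
from .evaluator import evaluate, write_eval_json, write_match_table
from .graph import (
    ReadIndex,
    build_contigs,
    collect_junctions,
    filter_junctions,
    make_exons,
    write_exon_bed,
    write_junction_bed,
)
from .io_formats import (
    load_genome,
    read_alignments,
    read_gtf,
    read_protein_fasta,
    write_gtf,
    write_protein_fasta,
)
from .translator import build_orf_database, write_orf_tsv

ALL_STAGES = ("consensus", "graph", "assemble", "translate", "annotate", "evaluate")


@dataclass
class PipelineConfig:
    genome: str | Path = ""
    alignments: str | Path = ""
    out_dir: str | Path = "orfweave_out"
    reference_gtf: str | Path | None = None
    reference_proteome: str | Path | None = None
    peptides: str | Path | None = None
    drop_multimappers: bool = True
    min_intron: int = 20
    # consensus
    min_cov: int = 5
    maj_frac: float = 0.8
    # graph
    min_junction_reads: int = 2
    max_intron: int = 1_000_000
    endpoint_window: int = 10
    max_fill_gap: int = 50
    min_exon_support: float = 1.0
    short_single_exon_len: int = 1000
    short_single_exon_support: int = 4
    emit_retained_introns: bool = False
    # assembly
    assembler: AssemblerConfig = field(default_factory=AssemblerConfig)
    # translation
    min_orf_aa: int = 8
    max_ext: int = 10_000
    six_frame: bool = False
    # annotation / evaluation
    kozak_mode: str = "either"
    strand_aware_eval: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("genome", "alignments", "out_dir", "reference_gtf",
                  "reference_proteome", "peptides"):
            if d[k] is not None:
                d[k] = str(d[k])
        return d

    def validate(self) -> None:
        for key in ("genome", "alignments"):
            p = getattr(self, key)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{key} path missing or nonexistent: {p!r}")
        for key in ("reference_gtf", "reference_proteome", "peptides"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} path nonexistent: {p!r}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, stages=ALL_STAGES) -> dict:
    """Run the requested stages and return an in-memory results bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome = load_genome(config.genome)
    reads = list(
        read_alignments(
            config.alignments,
            drop_multimappers=config.drop_multimappers,
            min_intron=config.min_intron,
            contigs=genome.keys(),
        )
    )
    results: dict = {"genome": genome, "reads": reads, "outputs": {}}

    consensus = None
    if "consensus" in stages:
        consensus = build_consensus(
            reads,
            {c: len(g) for c, g in genome.items()},
            min_cov=config.min_cov,
            maj_frac=config.maj_frac,
        )
        results["consensus"] = consensus

    junctions = exons = None
    if "graph" in stages or "assemble" in stages:
        junctions = filter_junctions(
            collect_junctions(reads),
            min_junction_reads=config.min_junction_reads,
            max_intron=config.max_intron,
            endpoint_window=config.endpoint_window,
        )
        contigs = build_contigs(reads, max_fill_gap=config.max_fill_gap)
        index = ReadIndex(reads)
        exons = make_exons(
            contigs,
            junctions,
            index,
            min_exon_support=config.min_exon_support,
            short_single_exon_len=config.short_single_exon_len,
            short_single_exon_support=config.short_single_exon_support,
            emit_retained_introns=config.emit_retained_introns,
        )
        results["junctions"] = junctions
        results["exons"] = exons
        write_junction_bed(junctions, out / "junctions.bed")
        write_exon_bed(exons, out / "exons.bed")
        results["outputs"]["junctions_bed"] = out / "junctions.bed"
        results["outputs"]["exons_bed"] = out / "exons.bed"

    transcripts = None
    if "assemble" in stages:
        transcripts = filter_transcripts(
            assemble(exons, junctions, config.assembler), config.assembler, exons
        )
        results["transcripts"] = transcripts
        models = [t.to_model() for t in transcripts]
        results["models"] = models
        write_gtf(models, out / "transcripts.gtf")
        results["outputs"]["gtf"] = out / "transcripts.gtf"

    orfs = None
    subs: set = set()
    if "translate" in stages and transcripts is not None:
        orfs = build_orf_database(
            results["models"],
            genome,
            consensus,
            min_aa=config.min_orf_aa,
            max_ext=config.max_ext,
            six_frame=config.six_frame,
        )
        results["orfs"] = orfs
        for o in orfs:
            for p, r, a in o.snp_substitutions:
                subs.add((o.contig, p, r, a))
        results["substitutions"] = sorted(subs)
        write_protein_fasta(orfs, out / "proteins.fa")
        write_orf_tsv(orfs, out / "orfs.tsv")
        results["outputs"]["proteins"] = out / "proteins.fa"
        results["outputs"]["orfs_tsv"] = out / "orfs.tsv"
        if consensus is not None:
            write_substitutions_tsv(sorted(subs), consensus, out / "substitutions.tsv")
            results["outputs"]["substitutions"] = out / "substitutions.tsv"

    if "annotate" in stages and config.peptides is not None and orfs is not None:
        with open(config.peptides) as fh:
            peptides = [
                line.strip() for line in fh if line.strip() and not line.startswith(">")
            ]
        proteome = (
            read_protein_fasta(config.reference_proteome)
            if config.reference_proteome
            else {}
        )
        calls = annotate_peptides(
            peptides,
            orfs,
            proteome,
            substitutions={(c, p) for c, p, _r, _a in subs},
            kozak_mode=config.kozak_mode,
        )
        results["calls"] = calls
        results["novel_smorfs"] = novel_smorfs(calls)
        write_smorf_report(calls, out / "smorf_report.tsv")
        results["outputs"]["smorf_report"] = out / "smorf_report.tsv"

    if "evaluate" in stages and config.reference_gtf is not None and transcripts is not None:
        reference = read_gtf(config.reference_gtf)
        ev = evaluate(results["models"], reference, strand_aware=config.strand_aware_eval)
        results["evaluation"] = ev
        write_eval_json(ev, out / "evaluation.json")
        write_match_table(results["models"], reference, out / "match_table.tsv")
        results["outputs"]["evaluation"] = out / "evaluation.json"

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": list(stages),
        "inputs": {
            "genome": _sha256(config.genome),
            "alignments": _sha256(config.alignments),
        },
        "counts": {
            "reads": len(reads),
            "junctions": len(junctions) if junctions is not None else None,
            "exons": len(exons) if exons is not None else None,
            "transcripts": len(transcripts) if transcripts is not None else None,
            "orfs": len(orfs) if orfs is not None else None,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["outputs"]["manifest"] = out / "manifest.json"
    return results
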