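"""Shared fixtures: synthetic alignment builders and a mixed simulated bundle."""

from __future__ import annotations

import pathlib

import pytest

from orfweave.io_formats import AlignedRead
from orfweave.pipeline import PipelineConfig, run_pipeline
from orfweave.simulate import SimConfig, simulate_bundle


def make_read(
    read_id: str,
    blocks,
    contig: str = "c",
    strand: str = "+",
    n_hits: int = 1,
    bases=None,
) -> AlignedRead:
    """AlignedRead with A-filled bases unless given explicitly."""
    blocks = tuple(tuple(b) for b in blocks)
    if bases is None:
        bases = tuple("A" * (e - s) for s, e in blocks)
    return AlignedRead(read_id, contig, blocks, tuple(bases), n_hits, strand)


def write_sam(path, records, contigs=(("c", 100000),)):
    """Write a minimal SAM file.

    ``records``: (qname, flag, contig, pos1, cigar, seq, nh) tuples.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in contigs:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for qname, flag, contig, pos1, cigar, seq, nh in records:
            fh.write(
                f"{qname}\t{flag}\t{contig}\t{pos1}\t255\t{cigar}\t*\t0\t0\t"
                f"{seq}\t{'I' * len(seq)}\tNH:i:{nh}\n"
            )
    return path


@pytest.fixture(scope="session")
def mixed_bundle(tmp_path_factory):
    """One simulated dataset exercising every planted-feature kind, plus a
    full pipeline run over it."""
    tmp = tmp_path_factory.mktemp("mixed")
    cfg = SimConfig(
        seed=11,
        n_genes=20,
        n_smorfs=3,
        n_snps=3,
        n_annotated=5,
        n_snp_mutants=2,
        n_truncated=2,
        coverage=25,
        error_rate=0.0,
        antisense_fraction=0.1,
    )
    paths = simulate_bundle(cfg, tmp)
    pcfg = PipelineConfig(
        genome=paths["genome"],
        alignments=paths["reads"],
        out_dir=tmp / "out",
        reference_gtf=paths["truth_gtf"],
        reference_proteome=paths["proteins"],
        peptides=paths["peptides"],
    )
    results = run_pipeline(pcfg)
    return {"config": cfg, "paths": paths, "truth": paths["result"], "results": results}
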