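# Methods

## Model and assumptions

`orfweave` treats transcript assembly as path selection on an
exon/junction graph derived from spliced read alignments against a
reference genome. The assumptions are those of a stranded
(fr-firststrand) short-read RNA-Seq experiment aligned by a splice-aware
mapper: intron calls come only from N CIGAR operations; reads reported
at more than one genomic location carry no usable evidence and are
removed before any tallying; a genomic point mutation in the sample is
clonal enough to dominate the pileup at its position. The assembler is
deliberately permissive — the downstream consumer is a proteomics
search whose own statistics control false discoveries, so recall is
bought at the price of precision, and a single stringency parameter
exposes that trade.

All internal coordinates are 0-based half-open on the forward genome
strand; SAM (1-based) and GTF (1-based inclusive) are converted only at
the I/O boundary.

## Graph construction

Coverage contigs are maximal read-covered regions after bridging
internal zero-coverage gaps of at most `max_fill_gap` (default 50 nt) —
short dips in coverage within an expressed exon are sampling noise, not
structure. Junctions are keyed by (contig, donor, acceptor, strand)
with the supporting read count as weight, then filtered by:

* minimum support `min_junction_reads` (default 2; a single spliced
  read is indistinguishable from a mapping artifact);
* intron span at most 1,000,000 nt (inclusive — exactly 1 Mb is kept);
* an endpoint-plausibility rule: junctions sharing one endpoint whose
  other endpoints fall within `endpoint_window` (default 10 nt) of one
  another collapse to the best-supported member. This is one concrete
  reading of "keep only the most probable intron endpoints"; the window
  is configurable for sensitivity analysis.

Junction points then cut every contig into all boundary-choice
combinations of candidate exons. Variants straddling a retained
junction's intron are intron-retention candidates: they are emitted
only under `emit_retained_introns` (off by default, to keep database
size controlled) and flagged when they are. Exon support
`X(e)` is the number of overlapping reads per kilobase of exon. Exons
below `min_exon_support` (default 1 read/kb) are dropped, and
purely coverage-bounded exons shorter than 1,000 nt — would-be
single-exon transcripts — additionally need
`short_single_exon_support` (default 4) reads, since unfiltered short
single-exon fragments would otherwise dominate the database.

Intron calls shorter than `min_intron` (default 20 nt) are treated as
deletions, following standard aligner conventions.

## Greedy assembly and stringency

From each seed exon (every exon without an incoming retained junction;
`--seed-all` seeds everywhere) the chain extends by choosing the
endpoint maximizing normalized junction support times a distance weight
`w(D)`, then the exon at that endpoint maximizing `X(e)`. The printed
form of the endpoint score multiplies support by the raw distance `D`,
which rewards distal acceptors; the accompanying intent — suppressing
spurious long-range joins — points the other way. Both readings are
provided through `--distance-weight`: the default `inverse` uses
`w(D) = 1/(1 + D/D₀)` with `D₀ = 10,000` nt (proximal preference),
`linear` reproduces the literal product, `none` removes the distance
term. This genuinely open choice is a package decision, not a derived
fact; the default reflects splice biology (most acceptor competition is
local) and the artifact-suppression motivation.

Ties break deterministically: higher raw support, then larger distance
weight, then leftmost acceptor; exon ties by longer exon, then leftmost
end. Branching is the combinatorial-explosion control: any endpoint
with normalized support ≥ `candidate_branch_cutoff` (default 0.15)
spawns an extra chain, capped at `max_transcripts_per_seed` (default
16) per seed, best-first, so disabling branching leaves exactly the
greedy chain.

Transcript filtering applies the stringency `s ∈ [0, 1]` twice:
transcripts (sorted by exon count) must have mean exon expression at
least `s` times a base threshold — defaulting to the median `X(e)` over
all candidate exons so the threshold scales with sequencing depth — and
a transcript whose internal junction chain is a subset of an already
accepted, overlapping transcript's chain survives only with mean
expression at least `s` times the accepted one's. Both rules are
monotone in `s` by construction (anything blocked by the similarity
rule has lower expression than its blocker, so it can never outlive the
blocker under the expression rule), giving the size/stringency
trade-off a clean guarantee: `s = 0` is the identity, and transcript
count and total nucleotides never increase with `s`. The default
stringency is 0.3. Similarity is judged on internal junction chains
only; terminal exon boundaries are coverage artifacts and are ignored.

## Consensus and translation

The consensus database tallies A/C/G/T per covered position (N bases
and deleted positions are skipped; counts pool across strands since a
genomic SNP is strand-symmetric). A position is called at coverage ≥
`min_cov` (default 5) and majority fraction ≥ `maj_frac` (default 0.8)
— values chosen to suppress sequencing-error miscalls at typical
depth; with `maj_frac > 0.5` ties can never be called. Only
substitutions are modelled: indel-aware consensus would shift
coordinates globally for marginal benefit at this stage. Consensus is
applied within the exons of emitted transcripts (and extension slices),
which is cheaper than genome-wide application with the same effect on
the protein database.

Transcripts are translated in the three sense frames (stranded
libraries; `--six-frame` exists for unstranded data — antisense coding
is otherwise represented by assembling the antisense transcript
itself). Codons containing N translate to X. A stop-free stretch that
reaches a transcript terminus in its frame is extended along the
genome beyond the terminal exon — no splicing is imputed —
consensus-corrected, up to `max_ext` (default 10,000 nt) per side:
downstream to the nearest in-frame stop, upstream to one codon past the
nearest upstream in-frame stop (not beyond: the nearest-stop reading).
Extensions that hit a contig edge or the cap are flagged rather than
silently truncated. Records keep the full stop-to-stop amino-acid
stretch — peptides upstream of an internal ATG stay searchable — with
the upstream-most in-frame ATG annotated as the start when present.
The minimum reported ORF length is 8 aa, about the shortest reliably
detectable tryptic peptide. FASTA headers encode transcript, frame,
genomic span, extension lengths and SNP count so every search hit is
traceable.

## Annotation rules

Peptide/protein comparisons collapse I and L, which are isobaric and
indistinguishable by the MS workflow the database serves. The start
decision tree per ORF hit: (1) the upstream-most in-frame ATG at or
before the peptide (longest-ORF reading); (2) else the upstream-most
near-cognate codon — any of the nine single-nucleotide substitutions of
ATG — in a Kozak context, operationalized as purine at −3 *or* G at +4
(the weakest standard criterion, to avoid over-filtering; a
both-required mode is available); (3) else the call is stop-bounded and
is a smORF iff the stop-to-stop extent is under 150 codons. Calls whose
only disagreements with an annotated protein sit at consensus-called
SNP codons are flagged as cell-line mutants of known proteins and
excluded from the novel list.

## The simulator

The simulator is the package's no-download test surface: a random
genome on one contig, genes laid out without overlap (antisense genes
are strand-flipped), 1–5 exons of 150–450 nt, introns of 200–1,200 nt,
up to 3 isoforms per gene by internal-exon skipping, log-normal
expression (μ = 1.0, σ = 0.75) to create the low-abundance isoforms
whose recovery motivates the tool, 75 nt single-end reads at a
configurable mean coverage (default 15×) with uniform per-base
substitution errors (default 0.2%). Designed content — smORFs of each
start class, annotated proteins, SNP carriers, SNP-mutant decoys,
truncated ORFs with their true flanking starts/stops in the genome — is
stamped into single exons on the forward strand so frames survive
splicing, and written to truth tables in the same formats the pipeline
reads. One read is pinned to each transcript end so simulated coverage
reaches annotated boundaries (partial-coverage behaviour is exercised
through the truncated-ORF designs instead, whose annotation stops
mid-ORF by construction). Planted SNPs are clonal: every covering read
carries the alternate base while the genome FASTA keeps the reference.

What the simulator does *not* model — paired ends, fragment-size and GC
bias, PCR duplicates, misalignment, genomic repeats, expression-level
intron retention — bounds what passing tests show: they validate the
algorithmic contracts (graph construction, greedy optimality,
stringency monotonicity, consensus and extension correctness,
annotation logic) on clean inputs, not performance on real libraries,
where alignment artifacts and repeat-derived multimapping dominate the
error budget.

## Problem sizes and verification

The test suite and `scripts/acceptance.py` run at desk scale, chosen so
every check completes in seconds while keeping each measured subset
non-trivial: 200 random junction graphs of ≤ 8 exons against an
exhaustive enumeration oracle; an 11-point stringency sweep and a
50-gene / ~15× end-to-end recovery run (recall measured on transcripts
with ≥ 10× realized coverage, precision on the full set); 10 planted
clonal SNPs at ≥ 10× for the consensus database; 4 truncated ORFs for
extension; and a 5 smORF + 20 known protein + 3 SNP-decoy annotation
fixture. Determinism is enforced at the byte level: identical inputs
and configuration reproduce identical GTF/FASTA/TSV outputs.

## Known limitations

No probabilistic abundance estimation (no EM over isoforms), no
paired-end fragment modelling, no guide-annotation-based assembly, no
fusion/chimeric junctions, no indel or phased variant calling, and no
spectral search — the package ends at the database and the peptide
annotation logic. Junction strand comes from the library-strand vote of
supporting reads; motif-based (GT-AG) disambiguation of genuinely
unstranded data is not attempted.
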