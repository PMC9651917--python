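# Methods

## Problem and model

Community RNA-Seq assemblies are degraded by two properties of microbial
metatranscriptomes: coverage spans orders of magnitude across genes (so
weakly expressed genes assemble into fragments or truncated contigs) and
homologous genes recur across community members (so assembly graphs
collapse and chimeras appear). When the same sample has been sequenced
at the DNA level, the assembled and annotated metagenome provides a
per-gene coordinate frame. `txweld` treats each annotated CDS as the
unit of reconstruction: transcript evidence is projected into CDS
coordinates, and one output mRNA per sufficiently covered CDS is built
by a per-position consensus in which transcript bases take priority over
genome bases.

The assumptions this rests on:

- transcripts are unspliced and collinear with the genome (prokaryotic
  mRNA); spliced alignments are out of scope;
- the CDS annotation is trustworthy: output length is locked to the
  annotated interval, so mis-annotated boundaries propagate;
- one output per CDS is the right contract — alternative or overlapping
  isoforms are not represented;
- transcript-level *substitutions* are biology (or useful signal) and are
  preserved; transcript *insertions* relative to the genome would shift
  the annotated reading frame and are dropped (each dropped event is
  counted and reported in the run summary).

## Coordinates and projection

All internal coordinates are 0-based half-open; GFF's 1-based inclusive
intervals are converted at parse time and nowhere else. Alignment
projection clips the PAF target interval to the CDS. Query coordinates
for the clipped window are exact when a `cg` CIGAR tag is present (a
linear walk mapping each target position to its aligned query offset,
with deletion positions mapping to no base); without a CIGAR the block is
treated as gapless and query offsets are interpolated proportionally.
The synthetic truth alignments always carry CIGARs, so interpolation is
only exercised on user-supplied coordinate-only PAF. A projected segment
whose query image is empty (the window lies entirely inside a deletion)
is discarded rather than carried with an empty interval.

PAF strand convention follows minimap2: for `-` records the CIGAR walks
the target forward over the reverse-complemented query, so consensus
lookups orient the query first and convert offsets back to original
coordinates.

## Selection, consensus, tie-breaking

A CDS is selected when the union of its projected segment intervals
covers ≥ θ of its length; θ defaults to 0.5 and the boundary is
inclusive ("at least"). Union size is computed with an interval tree.

Within a selected CDS, each position covered by ≥1 segment takes the
base of the winning segment: most alignment `matches`, ties by higher
MAPQ, then lexicographically smallest query name, then input order —
fully deterministic under input permutation. The implementation sorts
segments by this priority once and lets each segment claim still-free
positions, which is equivalent to a per-position argmax but linear in
total segment length. Positions inside a transcript deletion take the
genome base and the `G` provenance label: the transcript contributes no
base there, so this is gap-fill, not evidence.

Operon splitting and intergenic trimming are not separate passes: a
contig overlapping k CDS simply contributes segments to k
reconstructions, and bases outside every CDS have no position to land
in.

## Unaligned-transcript path

Contigs with no surviving genomic alignment are screened by a six-frame
maximal-ORF scan (bacterial translation table 11; accepted starts ATG,
GTG, TTG; ≥100 aa by default; 3'-partial ORFs allowed since assembled
contigs are often truncated). Survivors are deduplicated against the
corrected set by greedy centroid clustering: corrected transcripts are
seeded as centroids first, candidates join the first centroid reaching
≥95% identity, computed by aligning the shorter sequence as an infix of
the longer (both orientations, edit distance via edlib) so the coverage
requirement on the shorter sequence is met by construction; a 15-mer
sharing prefilter skips hopeless pairs. This is a deterministic,
desk-scale stand-in for a general clustering tool; it does not do
protein-level clustering or coding-potential scoring, and its identity
is edit-distance based rather than alignment-scored. The whole path can
be disabled (`--no-orphans`).

## Evaluation rules

- **Capture**: per reference, the maximum over single alignments of
  (aligned reference bases)/(reference length); captured iff ≥ 0.95,
  inclusive. Unions of alignments never qualify, by design — the metric
  must penalise fragmentation.
- **Misassembly (genomic rule)**: among the query-disjoint parts of one
  contig (overlapping supplementary hits are first reduced to the
  best-matching part; >10% mutual overlap disqualifies), parts on
  different genomes give an `inter_genome` call; otherwise two
  query-adjacent parts whose target intervals are ≥1000 bp apart
  (inclusive, distance between nearer ends) give an `intra_gap` call.
  One call per contig.
- **Truth filter**: simulated truth sets keep transcripts with TPM ≥ 1,
  inclusive.
- Completeness histograms bin capture fractions over [0,1] with a
  right-inclusive last bin; counts conserve input cardinality.

`align_to_references` provides PAF for these metrics at desk scale by
best-infix edit-distance placement (≤20% divergence per query base). It
exists so evaluation of synthetic runs needs no external aligner; real
assemblies should be aligned with a production aligner and the PAF fed
in. A consequence of infix placement worth knowing: a contig that
*contains* a full reference plus flanks aligns with fraction 1.0 and
counts as captured, while with ≤20% divergence budget long flanks can
also push a contig past the threshold into "unaligned" — both behaviours
only affect the raw-assembly baseline, which this aligner deliberately
scores conservatively.

## Quantification

Counting, not EM: each read contributes total weight 1, split equally
among the targets tying at maximal `matches` (fractional policy;
`unique` zeroes multi-mappers instead). Fractional is the default
because zeroing multi-mappers systematically under-counts exactly the
homologous families that motivate the package. TPM is
`10^6·(c_i/l_i)/Σ(c_j/l_j)`; the sum is 10^6 whenever any count is
positive. No bootstrap, no fragment-length model.

## Synthetic community generator

The generator defines the conditions the test-suite and acceptance run
measure under; its defaults are fixed here and not tuned per run.

- **Genomes**: i.i.d. uniform base composition, default 5 genomes of
  50 kb. CDS are placed left-to-right with intergenic gaps of 60–150 bp
  (room for flank extraction and operon adjacency), default 20 per
  genome, lengths uniform in 300–900 nt rounded to codons, random
  strand, framed ATG…stop with stop-free bodies. Optional homolog pairs
  copy a CDS into the next genome at a stated identity, re-sanitised to
  stay stop-free.
- **Abundances**: log-normal(0, σ=1.5), normalised to 1 — heavy-tailed
  like real community profiles.
- **Expression**: per-gene log-normal(0, σ=1.0) with 10% silent genes;
  effective TPM ∝ expression × abundance of the carrying genome,
  normalised to 10^6. Silent genes give the truth filter something to
  exclude.
- **Artifact contigs** (one class drawn per expressed CDS; default mix
  0.25 each over fragmented / partial / fragmented+partial /
  intergenic-extended): fragmented = two pieces jointly covering the CDS
  with 10 bp overlap; partial = one piece covering 50–95% (the
  acceptance run passes 60–95% to satisfy its stated ≥60% coverage
  condition); fragmented+partial = two flanking pieces with an internal
  gap, joint coverage ≥60%; intergenic-extended = full CDS plus ≤50 bp
  genomic flanks. `operon_span` (contig covering two adjacent
  same-strand CDS, falling back to clean when no partner exists),
  `chimeric` (halves of CDS from two genomes, for misassembly tests) and
  `clean` are available off the default mix. All pieces are ≥100 nt so
  the default alignment length filter keeps them. Truth PAF records
  carry exact placements with full-length CIGARs and replay exactly at
  error rate 0.
- **Reads**: sampled with probability ∝ effective TPM × number of start
  positions, uniform starts, error-free by default; the truth table maps
  each read to its source and position. The default read PAF is the
  truth placement (unique, exact); an exhaustive exact-substring
  multi-map mode exists for homolog fixtures.

Determinism: one global seed fans out per operation as
`default_rng([seed, crc32(op_name)])`, so each generator is
independently reproducible and adding an operation never shifts another
operation's stream.

What the generator does **not** emulate: sequencing error profiles and
quality scores, indel errors, rRNA contamination, GC bias, strand
bleed-through, real genome composition, and assembler-specific artifact
correlations. Passing tests therefore demonstrate correctness of the
algorithms under their stated contracts — exact interval arithmetic,
consensus priority, metric boundaries — not robustness to real-data
noise, which depends chiefly on the upstream aligner's handling of
divergent or repetitive sequence.

## Numerical and degenerate-input choices

- Thresholds at stated boundaries are inclusive everywhere (coverage θ,
  capture 0.95, TPM 1.0, gap 1000 bp).
- CDS with zero evidence appear in `skipped_cds` with fraction 0 rather
  than vanishing.
- All-zero counts produce all-zero TPM (no 0/0).
- Empty FASTA files parse to empty lists; empty alignment sets yield
  empty outputs, never errors.
- Sequence alphabet is strict {A,C,G,T,N}: IUPAC ambiguity codes are
  rejected at parse time so consensus arithmetic stays deterministic.
  Soft-masked (lowercase) input is uppercased.
- Problem sizes in the test-suite and acceptance run (5 genomes × 20
  CDS, 50 kb genomes, 50,000 reads) are the package's chosen desk-scale
  defaults: large enough that every artifact class, strand and
  tie-break path is exercised many times, small enough to iterate on.

## Known limitations

- Insertion dropping means RNA-level insertions are invisible in output
  sequences (the event count is the only trace).
- A transcript supporting multiple homologous CDS on different contigs
  contributes to all of them; paralog-rich communities may over-count
  support.
- The greedy clustering is order-dependent by design (length-sorted,
  corrected-first) and has no protein-level awareness.
- `capture_fractions` keys on PAF target names; assemblies aligned to a
  reference whose ids collide across files will mix records.
- Coverage of a CDS counts target bases with a non-empty query image;
  windows inside transcript deletions do not count toward selection.
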