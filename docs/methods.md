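# Methods

## Graph representation

The colored compacted de Bruijn graph (CCDBG) is bidirected: every vertex
stores the canonical form of its unitig (the lexicographic minimum of the
spelled sequence and its reverse complement) and can be traversed in either
orientation. Edges are orientation-typed 4-tuples `(u, ou, v, ov)`; an edge
exists iff the (k−1)-suffix of `u` read in `ou` equals the (k−1)-prefix of
`v` read in `ov`, and every edge's mirror `(v, ~ov, u, ~ou)` is stored
explicitly. `k` must be odd so no k-mer equals its own reverse complement.
k-mers containing non-ACGT symbols are skipped (contigs are split at
ambiguous bases first).

Each unitig carries one color bitvector per constituent k-mer (one bit per
input genome). `first(v)` and `last(v)` are the bitvectors of the first and
last k-mer *in traversal orientation*; reversing a unitig swaps them. The
Jaccard index of two all-zero bitvectors is defined as 0 — it cannot occur
for k-mers present in the graph, but keeps the function total.

Canonical storage has a consequence worth knowing when reading tiny
examples: a k-mer and its reverse complement are a single vertex, so a
sequence containing a (k−1)-palindromic junction (e.g. `ACGT` inside a
k = 3 or k = 5 example) produces a hairpin edge between the two orientations
of one vertex rather than two distinct vertices, and compaction stops
there. At the default k = 63 (or the validation k = 31) such junctions are
vanishingly rare in real or simulated sequence.

Unitigs are numbered by lexicographic order of their canonical sequence.
Together with deterministic tie-breaks in every traversal this makes all
output byte-reproducible. Cyclic components (every vertex with in- and
out-degree 1) are linearized at their smallest canonical k-mer.

GFA1 output writes one `S` line per unitig and one `L` line per bidirected
edge (the mirror is implied), with `KL:i:<k>` and `NC:i:<n>` header tags;
per-k-mer colors go to a sidecar TSV keyed by unitig id and offset.

## Merging as a weighted path cover

Candidate NRS are extracted as source-to-sink paths of the CCDBG,
prioritized by color consistency (see README for the φ definition; the
minimum is taken over *all* consecutive junctions of the path, and a
single-vertex path has φ = 0). The greedy search:

* **Sources** are oriented vertices with successors but no predecessors;
  in a bidirected graph every forward sink is a reverse source, so both
  flanks of an insertion family seed traversals. Singleton vertices are
  emitted directly.
* From each source (visited in lexicographic order of canonical sequence,
  `+` before `−`) a DFS follows the unseen successor minimizing
  `1 − J(last(u), first(v))`; ties break on the smaller canonical sequence,
  then `+` before `−`. Vertices already on the current path are never
  revisited (paths, not walks). If every successor of the current vertex
  has been seen, the DFS backtracks; a traversal that exhausts without
  reaching a sink emits nothing.
* On reaching a sink, the path is emitted iff it contains **more than τ**
  k-mers belonging to unitigs not yet in the covered set D (strict
  inequality; counting is at unitig granularity). Emitted paths add their
  vertices to D; one path is emitted per source, and seen-marks reset
  between sources.
* After the source pass, any unitig still uncovered with more than τ
  k-mers (source-free, i.e. cyclic, substructures) is emitted as a
  single-unitig NRS. Silently dropping such sequence would violate the
  cover intent.

τ defaults to k − 1, so an emitted path must contribute at least one
uncovered stretch of roughly 2k − 2 novel bases. The emitted set is not
guaranteed optimal: a greedy pass started from a reverse-orientation flank
source can pair flanks of different colors across a shared segment,
producing a chimeric extra path; the evaluation counts such paths as false
positives. τ-monotonicity (a larger τ can only remove emitted paths) holds
when candidate paths live in separate components — the typical
one-component-per-insertion regime — but not in general: suppressing one
path shrinks D and can enable an overlapping later path.

## Read selection and assembly

A read is selected for assembly if it is unmapped or its `AS`-tag score
divided by the read length is below the ASF (default 0.67; strict `<`).
Mapped reads lacking `AS` are selected with a warning. If either mate of a
pair is selected, both are; duplicate-marked, QC-fail, secondary and
supplementary records are ignored. The internal assembler counts canonical
k-mers over the selected reads (k_a = 31), drops multiplicity < c_min
(default 2) and compacts the surviving single-color graph; contigs shorter
than 2·k_a are discarded. It deliberately does no error correction,
scaffolding or gap filling — external Minia/Velvet assemblies can be
supplied to the merge step instead.

## Placing

Fragment-size statistics (mean, SD) are estimated from proper pairs. For
every pair with exactly one mapped mate, the unmapped mate is screened
against all NRS with an infix edit-distance filter (both strands) and the
winner re-scored with an end-gap-free DP (match +1, mismatch −2, gap −3);
a unique best NRS scoring ≥ 0.67 × read length yields an anchor interval
`[mate 3′ end, mate 3′ end + mean + 3·SD)` (mirrored for reverse-strand
mates). The NRS orientation follows from the strand combination of the two
mates. Anchors within one fragment mean are pooled per (NRS, chromosome);
the pooled interval is the intersection of member intervals (their span if
the intersection is empty), which at deep support narrows to the insertion
point itself.

Breakpoint refinement exploits that assembled NRS carry reference flanks of
up to roughly a fragment length at their ends (mates of junction-spanning
reads are co-assembled). Up to 700 bp of each oriented NRS end is
split-aligned against the reference window around the anchor: an
**ungapped** prefix alignment selects the flank diagonal (gaps are
excluded on purpose — a gapped alignment can bridge across the insertion
to the far flank), and the junction is set at the end of the initial
exact-match run on that diagonal, so any extension past the true
breakpoint is pure breakpoint homology and therefore an equivalent
representation of the same variant. A split needs ≥ 15 aligned flank bases
at ≥ 0.8 identity-equivalent score. When both ends split, the two
junctions may sit Δ ≥ 0 bases apart (homology); the right trim is reduced
by Δ so that position and inserted sequence stay a consistent
representation. Variants with no acceptable split keep interval
resolution (`CIPOS` over the pooled interval) and are not genotyped.

Exact insertions are written as two VCF 4.2 BND records (left and right
junction) whose mate coordinates point into the NRS FASTA contig; INFO
fields carry the NRS id, orientation, flank trims, resolution and support
so the variants round-trip through the VCF.

## Genotyping

For each exactly placed variant, the reference allele is the ±150 bp
window around the insertion point (truncated at contig ends) and the
alternative allele the same window with the oriented, flank-trimmed NRS
inserted. Reads collected within flank + read length of the position
(unmapped mates inherit their mapped mate's position) are aligned to both
alleles with infix edit distance (both strands). A read is informative iff
it fits at least one allele cleanly (edit distance ≤ 0.1·L + 2 — without
this, window-edge reads forced inside the allele smear across the junction
and systematically inflate the heterozygous likelihood) and its alignment
on the allele it fits better crosses a junction by ≥ 10 bp. Per-read
likelihoods are `P(r|A) = eps^d (1−eps)^(L−d)` with eps = 0.01, combined
into the standard diploid mixture
`GL(g) = Σ_r log10[(2−g)/2 · P(r|ref) + g/2 · P(r|alt)]`; the genotype is
the argmax and GQ the phred-scaled gap to the runner-up. The likelihood
formula is this package's own choice of the standard diploid model; reads
with equal distances to both alleles cancel out of the argmax.

## Simulation

The generator emulates a cut-and-reinsert design entirely in silico: a
uniform-random 200 kb reference; 20 insertion sequences cut from it
(truncated log-normal lengths with mean 1455.17 and SD 1526.08, truncated
to [100, 2000]; pairwise spacing ≥ 1000 bp), leaving the depleted
reference; allele frequencies uniform on [0.05, 0.95]; 5 diploid
individuals whose haplotypes carry each insertion independently with its
frequency; paired reads (100 bp, fragment 350 ± 50, 30×) with
substitution errors at rate 0.001. These defaults are the package's
standard validation conditions; the log-normal moments echo the length
spectrum of real human non-reference insertions while the [100, 2000]
truncation keeps the run at desk scale.

Alignment records are *derived from the simulation coordinates* instead of
running a mapper: reads fully inside retained reference are mapped at
their true position with `AS = matches − 2·mismatches`; reads fully inside
an insertion are unmapped (inheriting the mate's position); junction
reads are soft-clipped with AS computed over the aligned part only. This
reproduces exactly the signal the pipeline consumes — unmapped flags,
soft-clips, AS ratios, one-end-anchored pairs — but not mapper-specific
artifacts: no mismapping in repeats, no indel errors, no quality-dependent
error profile, no chimeric alignments. Passing tests therefore demonstrate
the algorithmic chain under clean mapping semantics, not robustness to
real-mapper noise; a `--bam-in`-style substitution of real mappings is the
CLI's assemble/place/genotype path, which accepts any SAM/BAM.

## Validation protocol and problem sizes

The evaluation aligns every truth sequence against every candidate
(biopython local alignment, match 2, mismatch −3, gap −5, both strands,
minimum 50 aligned truth bases at ≥ 0.95 identity). A truth sequence is a
true positive if a *single* alignment covers ≥ 90% of it and a bipartite
matching pairs it with a distinct candidate; FP = |C| − TP, so redundant
or chimeric candidates directly lower precision. The matching is greedy by
covered fraction and then completed with augmenting paths, making TP equal
to the maximum matching cardinality with deterministic tie-breaking.

Test-suite problem sizes: 100 random instances for the graph-construction
oracle (1–5 colors, k ∈ {5, 7, 11}); ≥ 50 connected graphs of ≤ 7 unitigs
for the path-cover oracle (exhaustive set-cover minimization over all
source-to-sink paths); one full pipeline run at the default simulation
conditions (fixed seed) for end-to-end precision/recall, placement
resolution and genotype concordance. Placement error is scored by
haplotype equivalence: a call is exact when applying its (position,
inserted sequence) to the reference spells the same sequence as the truth
insertion — breakpoint-homology shifts are the same variant.

## Known limitations

* The greedy cover emits occasional chimeric paths when insertion families
  share sequence (measured directly as the false-positive component of
  precision, ~0.7–0.85 under the default conditions).
* Interval-resolution variants are left ungenotyped.
* The assembler has no error correction; at higher error rates than the
  simulated 0.001 the c_min filter starts to fragment low-coverage
  insertions.
* Repeat-aware placement and population-scale position reconciliation are
  out of scope; one anchor locus (the best-supported) is placed per NRS.
* Color bitvectors are dense; the implementation targets cohorts of tens
  of genomes at desk scale, not compressed population-scale color
  matrices.
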