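# Methods

This note documents the model implemented by `splicemap`, the parameters
that matter, the design choices made where the published description leaves
the design open, and what the simulator does and does not emulate.

## Model and assumptions

`splicemap` maps single-end short reads (50–150 nt; the simulator's default
is 76 nt) against one or more reference sequences. Its central assumption is
that the best placement of a read is decided not by its own mismatch count
alone but by the *context*: the set of alignments of all reads in the same
genomic neighbourhood. Junctions, deletions and insertions are treated as a
single phenomenon — a gap at a split position whose signed size (reference
span minus read span) falls into one of three legal classes:

| class     | gap size g          |
|-----------|---------------------|
| insertion | −10 ≤ g ≤ −1        |
| deletion  | 1 ≤ g ≤ 10          |
| intron    | 50 ≤ g ≤ 300,000    |

Split alignments with any other gap size are never created, and a zero gap
is a structural error (adjacent blocks must be merged).

The aligner behind step 1 is pluggable. The contract: index arbitrary
references, perform seeded alignments with adjustable seed length reporting
*every* placement whose seed matches (up to `max_hits`), and do no gapped
alignment of its own. The built-in implementation is an exact-seed k-mer
hash with ungapped extension; reverse-strand placements align the reverse
complement of the read against the forward reference, and all internal
coordinates of a '-' alignment refer to that oriented sequence (the same
orientation SAM stores), so the single 0-based→1-based conversion at SAM
output is the only coordinate transformation in the package.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `seed_len` | 25 nt | initial anchored seed; midpoint of the recommended 20–30 nt range |
| `window_seed_len` | 12 nt | completion seed in sliding windows; midpoint of 10–15 nt |
| `local_seed_len` | 16 nt | built-in local mode seed; must fit inside a minimum-size internal exon (20 nt) |
| `max_mismatches` (m) | 4 | mismatch budget per alignment; unaligned read positions count as mismatches during classification |
| `mismatch_end_dist` (D) | 8 nt | candidate-split vs partial boundary. At ~75 % mismatch density beyond a gap, the last allowed mismatch sits ~5 nt past it, so D≈8 admits exactly the candidates whose remainder can host the 12-nt completion seed. Larger D silently declares every gap lying 9–D nt from a read end "partial", and gaps that *only* occur at such offsets (an indel a few bases inside a short exon) would never be discovered by any read |
| `min_exon` (e) | 20 nt | minimum internal exon; applied to blocks flanked by intron-sized gaps on **both** sides — a block bounded by an indel gap is a piece of one exon, not an exon, and only needs to be non-empty |
| `min_junction_anchor` | 8 nt | read bases required on each side of an intron gap created de novo; junctions with shorter anchors are unverifiable and a fertile source of false sites |
| `avg_intron` (x) | 1,000 nt | sliding-window extension distance; matches the simulator's intron length scale (60–900 nt) so completions are always reachable |
| `max_window` | 10,000 nt | maximum sliding-window length; covers a gene-dense span while keeping window indexes tiny |
| `d_min` / `d_max` | 1,000 / 300,000 nt | context clustering gap / span cap; d_min exceeds the simulated intron lengths so one gene stays in one context |
| `evidence_w` (w) | 0.3 | geometric down-weighting of higher-mismatch site supporters |
| `support_window` (W) | 100 nt | flank window of the support score |
| `support_lambda_in` / `_flank` | 1.0 / 0.1 | support score weights (see below) |
| `support_tie_tolerance` | 0.02 | relative support differences below this count as ties |
| `variant_cap` | 16 | step-3 variants retained per read per context |
| `max_hits` | 10 | seed placements retained per read per anchor |

## Reconstructed components

Several ingredients are described only at a high level in the method this
package implements; their concrete forms here are the package's own design,
all configurable.

**Support score.** `support = λ_in · body + λ_flank · (up + down)` where
*body* is the coverage mass under the aligned blocks divided by the read
length (the average per-base support of the placement, with inserted read
bases credited the point coverage at their site), and *up*/*down* are the
mean coverages in the W-nt windows flanking the *projected read extent*
(aligned span plus soft-clipped overhang). The coverage profile counts each
read once, via its minimum-mismatch variant. Three alternatives were
rejected after they mis-resolved constructed cases: per-block maxima
*averaged* under-score true splits whose exons have unequal coverage;
per-block maxima *summed* double-count blocks in one pile and let spurious
re-splits win; flank *maxima* anchored at the aligned span let heavily
clipped variants harvest support from the pile their own unaligned tail
belongs to. The flank weight is deliberately small (0.1) because a read that
genuinely starts at an exon boundary has an intron — zero coverage — on one
side, and a strong flank bonus systematically rewards false junction-backed
placements borrowing the neighbouring exon's coverage; the body term carries
the locus discrimination and the flanks only break body ties (e.g. a decoy
copy of an exon interior, which has no flanking coverage).

**Support ties.** Supports within 2 % (relative) count as equal and fall
through to a fixed tie cascade: fewer effective mismatches (substitutions +
soft-clipped bases), fewer blocks, leftmost start, reference name. Per-base
coverage jitter between almost identical placements must not override the
mismatch count.

**Overlapping-site selection.** Two sites overlap when their intron
intervals intersect or share a donor/acceptor coordinate. A site is
discarded when at least three *directly overlapping* sites carry better
evidence (ties to the leftmost donor). The relation is deliberately not
taken transitively: a false intron interval can span hundreds of kilobases
and chaining components through it would pit distant, unrelated sites
against each other.

**Trusted sites.** Re-splitting other reads across a known site uses 1-nt
anchors only when the site is supported by ≥ 2 distinct reads or by one
mismatch-free read; a site seen once, with mismatches, may be a chance
completion of a noisy read and only supports re-splits that leave
`min_junction_anchor` on both sides.

**Annotation.** When an annotation table is supplied, a site whose intron
interval exactly matches an annotated intron receives an additive evidence
bonus (default 1.0 — one mismatch-free supporting read). Additive rather
than multiplicative so zero-evidence sites stay at zero; annotation affects
scoring only, never creates alignments.

**Split-point ties and canonical representations.** When several split
points explain a completion equally well, the canonical splice motif
(GT..AG forward, CT..AC reverse-gene) is preferred for intron-sized gaps,
then the leftmost point. Indels are therefore reported left-aligned. The
simulator writes canonical motifs at generated junctions and left-aligns its
recorded indel loci for the same reason: without a shared canonical
representation, roughly a quarter of junctions in a random genome are
coordinate-ambiguous and exact-coordinate evaluation would be meaningless
for any mapper.

**Two-gap completions.** If the best single-gap split of a completion span
still carries ≥ 3 substitutions, a bounded three-block decomposition is
attempted: the middle diagonal is enumerated at every indel-sized offset
from the two seeded diagonals and the two split points are optimised in
O(read length). The result is accepted only when it is near-perfect (≤ 1
substitution), its middle piece matches the reference exactly, the piece is
shorter than two completion seeds, and it beats the single-gap optimum by
≥ 3 substitutions. This recovers reads whose indel lies within a seed length
of an exon boundary — the in-between piece can never anchor a seed, so
without this search such loci are undiscoverable by *any* read and their
reads collapse onto a fused false junction. The tight acceptance guards
against overfitting: with a free middle diagonal almost any mismatched span
could be "improved".

**Window membership.** A window opens at the left-most unprocessed
candidate and admits every candidate starting within `max_window`; its
sequence spans to the furthest member end and is extended by x up- or
downstream when a member whose completion lies on that side ends within x of
the window edge. The next window opens at the first member not completely
contained within the cap, so candidates near the cap are processed twice and
de-duplicated.

## The simulator

`read_simulator` generates the study conditions: a uniform random genome
(GC configurable), non-overlapping multi-exon genes on both strands (exons
80–220 nt with two short 22–36 nt internal exons in genes of ≥ 5 exons, to
host multi-junction reads; introns 60–900 nt; canonical motifs written at
the boundaries), and reads drawn uniformly over the feasible placements for
their junction count, which follows `multi_junction_weights`. Substitution
errors are per-read, per-base. Indels are *genomic polymorphism loci* shared
by every read covering them (left-aligned, 1–10 nt, margins of a few bases
from exon boundaries and ≥ 12 nt between loci): per-read random indels would
make context-based indel detection impossible by construction, since every
site would have exactly one supporting read. A read whose walk crosses a
deletion near a junction spills into the next exon, exactly as a transcript
does — never into an intron.

What the simulator does **not** emulate: paired ends, quality-correlated
error profiles, expression-level variation between genes, isoform diversity
(one transcript per gene), overlapping genes, repetitive sequence beyond
what a uniform random genome contains, and intron length distributions of
mammalian scale. Passing tests therefore demonstrate the mapping logic under
controlled conditions, not performance on real libraries; in particular a
random 500 kb genome makes 76-mers essentially unique, so multi-mapping is
rarer than in a real genome.

## Numerical and degenerate-input choices

- Reads shorter than twice the initial seed are rejected with a warning and
  emitted unmapped.
- Reference N bases match nothing: they always count as mismatches and
  k-mers containing N are not indexed.
- FDR is defined as 0 when no splices are predicted; evaluation cells where
  nothing of an indel size was predicted are reported as undefined rather
  than 0.
- "Perfectly mapped" is strict: every read base's placement (reference
  position, or none for inserted bases) must equal the truth placement;
  soft-clipped bases count as not placed.
- A read whose junction-count differs from the truth scores a false negative
  at its true count and a false positive at the predicted count; the right
  count with wrong coordinates scores both a false positive and a false
  negative at that count, so per-count tallies conserve the number of
  spliced reads.
- Determinism: no stage depends on input order or dict iteration; two runs
  on identical inputs produce byte-identical SAM, and shuffling the input
  changes only record order.

## Problem sizes

The acceptance checks run a 500 kb genome with 40 genes and 20,000 reads
(clean and noisy regimes), a 500-read three-exon merge fixture, and a
4,000-read two-copy ambiguity fixture — sizes chosen so the whole suite
completes in a few minutes on one core while every code path (windows,
fragmentation, merging, extension rounds, local and global resolution) is
exercised at meaningful coverage (~35× per transcript).

## Known limitations

- Single-end only; mate information is never used.
- One alignment per read is reported; no secondary alignments, no mapping
  quality model (MAPQ is 255).
- Gaps are found one (or, in the bounded two-gap search, two) at a time per
  completion; reads with three or more gaps rely on iterative re-splitting
  across sites discovered by other reads, so isolated loci stacking three
  gaps within one read may be missed.
- A junction whose flank is shorter than the completion seed in *every*
  covering read cannot be discovered (only rescued if some other read
  establishes the site).
- Fusion junctions across references and annotation-driven junction
  injection are out of scope; annotation only adjusts site evidence.
- The built-in aligner is exact-seed: a mismatch inside the seed region of
  both read ends hides a placement from the anchored stage (the local stage
  usually rescues it).
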