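# Methods

## The objects

A mitogenome is modelled as a circle of length *L* bp carrying gene features
with 0-based half-open coordinates; a feature spanning the origin is stored
with `end > L` (its bases are `start..L-1` then `0..end mod L - 1`), which
keeps the gap between consecutive features a plain difference everywhere on
the circle.  Gene names are normalized to a fixed 37-token vocabulary;
duplicated genes (e.g. two trnK copies) become suffixed tokens `trnK.1`,
`trnK.2` assigned in positional order, so adjacency arithmetic stays
well-defined.  For cross-taxon operations (NCR flank matching, arrangement
diffs) the suffix is stripped and, where one genome has two copies and
another one, copy 1 is used unless the caller states a preference.

The comparative object is the **signed circular gene order**: the cyclic
sequence of `(token, strand)` pairs in positional order.  Two reads of the
same molecule are related by *reflection* (reverse the order, flip every
sign); canonicalization picks one read deterministically by rotating the
anchor gene (`cox1`, falling back to `cox2`, `cox3`, `cob`, `rrnS`) to the
front and reflecting if the anchor is on the minus strand.  The canonical
form is invariant under every rotation and under reflection of the input,
and idempotent; both properties are tested against a brute-force
canonicalizer that enumerates all 2*n* variants.

## Cluster-orientation calls

Two conserved lophotrochozoan protein-coding/rRNA clusters serve as the
reference: cluster 1 `cox3-nad3-nad2-cox1-cox2-atp8-atp6` and cluster 2
`rrnS-rrnL-nad1-nad6-cob-nad4L-nad4-nad5`, both forward in the ground
pattern.  To call one cluster, every gene not in its pattern is deleted from
the cyclic order (tRNAs and the other cluster therefore never break
contiguity), and the remaining positional order is compared with the
pattern: pattern order → `forward`, reversed pattern order → `inverted`;
with genes missing the same comparison against the reduced pattern yields
`partial_forward` / `partial_inverted`; an order matching neither direction
is `disrupted`, no genes at all is `absent`.

A deliberate design point: the call is made from positional order in the
record's own strand frame, and the consensus transcription strand of the
cluster genes is reported separately rather than folded into the call.  Two
reasons.  First, which strand an annotation pipeline labels "plus" is a
convention of the deposit; an order-based call is insensitive to it.
Second, in the published monoplacophoran arrangements the cluster-1 genes
read in reversed pattern order on the *plus* strand — a naive
"reversed-and-strand-flipped" criterion would refuse to call them inverted,
yet the cluster-level inversion against the ground pattern is exactly the
biological signal.  With the order-based rule the published arrow table
reproduces in full (ground →→, monoplacophorans and *Sypharochiton* ←→,
*Katharina* →←), and a single simulated inversion spanning cluster 1 of the
ground pattern flips cluster 1's call and nothing else.

## Arrangement diffs and conserved blocks

Adjacencies are unoriented neighborhoods of signed genes: the pair
`(a,+)→(b,+)` is the same physical junction as `(b,−)→(a,−)` and both map to
one key.  Comparing two genomes restricts both orders to the shared gene
set, counts adjacencies of A absent from B (breakpoints), and reports as
"moved" the genes *both* of whose flanking adjacencies are non-shared — a
single translocated gene thus names itself (three breakpoints: old site,
new site, vacated junction) without implicating its former neighbors.

Conserved blocks across ≥2 genomes are maximal chains of adjacencies present
in every input (again on the shared gene set, so a gene annotated in only
some genomes never breaks a block).  A block may appear globally reflected
in some genomes; internal relative orientation must be identical.  The
implementation is checked against an oracle that enumerates every cyclic
window of every length and tests contiguity in every input directly.

tRNA complexes ("GEWDCYKNM", "KARNI", ...) are located by scanning the
cyclic order for the named tRNAs in consecutive positions, in either reading
direction; tRNAs not in the complex that interrupt it are reported
explicitly, and any intervening non-tRNA gene breaks the complex.

## Non-coding regions and overlaps

Features of kind PCG/rRNA/tRNA are chained in start order around the circle;
each consecutive pair contributes its raw gap: positive → NCR, negative →
overlap, zero → nothing.  Because the gaps telescope, Σfeature lengths +
ΣNCR lengths − Σoverlap lengths = *L* holds exactly on every circular
record; the test suite verifies it on randomized layouts and on 100 seeded
synthetic genomes.  Annotation fragments of kind `other` (e.g. residual gene
copies inside a control region) do not bound NCRs; they are attached to the
containing NCR as sub-annotations, so a 2-kb control region stays one region
even when a pseudogene fragment sits inside it.  NCRs of 1 bp count
(the smallest published size class is "<10 bp"); abutting genes produce
nothing.  Size bins are <10, 10–100 (inclusive on both boundaries) and
>100 bp.  On a non-circular record the wrap gap is still reported but
flagged as a terminal artifact.

Cross-taxon NCR matching uses ordered (upstream flank, downstream flank)
token pairs after orienting each record by its canonical reading direction;
`relaxed` mode first projects flank genes missing from the common annotation
onto the nearest annotated neighbor, so one genome's unannotated tRNA does
not spoil a match.

GC content is (G+C)/(A+C+G+T), case-insensitive, with ambiguity codes
excluded from numerator and denominator, and is reported to one decimal in
percent outputs.

## Motifs and repeats

Motif patterns are strict character-class strings over {A,C,G,T} (literal or
bracketed alternatives per position; no mismatches, no gaps).  Scanning
reports all non-overlapping leftmost matches with 1-based starts within the
NCR, single-strand by default (`both_strands` exists but is off, as the
published hits are all on the annotated strand).  The scanner is
property-tested against a sliding-window oracle.

`(AT)_n` runs are counted phase-free: a maximal alternating A/T stretch of
length ℓ counts ⌊ℓ/2⌋ complete units, so `TATA…` and `ATAT…` score alike.
In interrupted mode two stretches may be bridged across exactly one non-AT
dinucleotide; when only one base separates the stretches the interrupting
unit absorbs the first base of the following stretch (dinucleotide framing:
`TATA|CA|TATATATA` reads as 6 units with one CA), which is the convention
needed to reproduce the published interrupted counts.  Every reported run
re-read from the sequence satisfies its own definition.

Shared motifs between taxa are maximal exact substrings (default minimum
18 bp, the length of the known shared 18-mer) present in NCRs of ≥2 taxa.
Maximality is per support level: a core shared by three taxa is reported
alongside a longer extension shared by only two; a reported motif is never a
substring of another reported motif with at least the same taxa.  Checked
against full substring enumeration on small inputs.

## Synthetic genomes

The generator's defaults emulate the architecture of the study system:
~37-gene molluscan orders (the published monoplacophoran arrangement or the
two-cluster ground pattern as base), gene lengths of typical molluscan mtDNA
(cox1 ≈ 1.5 kb, tRNAs ≈ 65 bp, configurable), a genome-wide GC target
(default 0.36, matching the observed 35–39% range), planted NCRs of
controlled lengths carrying motif instances and `(AT)_n` runs at recorded
1-based offsets, planted overlaps realized by shifting the downstream gene's
start into its neighbor, and a small default intergenic spacer (2 bp)
between unconstrained neighbors.  Around every planted signal a short
guard region is set to G/C so the planted offset is recovered exactly rather
than extended by chance.  Rearrangement events are applied in list order;
inversion reverses and sign-flips a contiguous run, translocation moves a
run unchanged to a destination index, and TDRL duplicates the run in tandem
and keeps, per gene, the first or second copy.  All randomness flows from
one seeded numpy generator; a fixed seed yields byte-identical GenBank
output.

What the generator does *not* emulate: sequence homology between genes
(gene bodies are i.i.d. random at the GC target), codon structure, tRNA
secondary structure, rate variation, or annotation error.  Passing recovery
tests therefore demonstrates that the measurement code inverts the
generative model exactly — coordinates, gaps, motif offsets, repeat counts,
cluster calls — not that MITOS-style annotation of real reads would be
error-free.

## Numerical and procedural choices

* Tie-break for equally largest NCRs: smallest start coordinate.
* Conserved-block ties are reported fully, sorted lexicographically.
* MITOS split-gene parts are merged when same-name, same-strand and
  separated by ≤10 bp (covers overlapping and abutting parts); farther
  apart they are kept as genuine copies.
* GenBank writing uses 1-based inclusive coordinates with `join()` for
  origin-spanning features; a read–write cycle preserves names, strands and
  coordinates exactly.  An all-N sequence is treated as "no sequence".
* The comparison pipeline contains no randomness; regenerating a report
  from the same inputs is byte-identical.
* Problem sizes in the validation sweeps (orders of ≤10 genes for the
  exhaustive canonicalization oracle, 10-kb random sequences for motif
  scanning, 100 seeded genomes for the conservation identity, 20 order sets
  for block detection) were chosen to make brute-force oracles exact yet
  keep the whole suite in seconds.

## Known limitations

* Cluster calls on a genome whose PCG+rRNA content is exactly the two
  adjacent clusters cannot distinguish arrangements that differ only by
  which strand the annotator called plus; with real annotations the tRNA
  context and junctions break that symmetry, and the reported consensus
  strand makes the frame explicit.
* The relaxed NCR-matching projection is greedy to the nearest annotated
  neighbor; pathological annotations with long unannotated stretches could
  over-merge boundaries.
* Shared-motif search is exact-match only (no degenerate positions, no
  statistical significance); it is a replacement for probabilistic motif
  discovery only in the regime the package targets — short, literally
  conserved control-region markers.
* Reproduction of deposit-derived numbers (genome lengths, NCR censuses,
  shared-boundary counts) requires the deposited GenBank records on disk;
  the corresponding test states exactly which files it needs.
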