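# Methods

## Coordinate system

Target regions are extended CDS intervals, `(s_i, e_i) = (CDS_start − l_ext,
CDS_end + l_ext)`, collected per transcript (or per gene after deduplicating
CDSs identical in start, end and frame). Within each chromosome regions are
sorted by start position, then element id; ties beyond that are broken by end
coordinate and frame so the stitched layout is fully deterministic.
Chromosomes are concatenated in natural-sort order into a single logical
vector — this keeps per-chromosome construction parallelizable in principle
while presenting one coordinate space. Cumulative offsets `ν_{<i}` give the
maps

- vector → genomic: `c(ν) = s_k + (ν − ν_{<k} − 1)` with `k` found by binary
  search over the offsets. The `−1` makes `ν = 1` map to the first base of
  the first region, so the round trip genomic → vector → genomic is the
  identity over the whole domain `1 ≤ ν ≤ l_T`; this identity is the
  governing law for all coordinate arithmetic and is property-tested against
  an explicitly constructed stitched position array.
- genomic → vector: one coordinate per containing region (interval-tree
  lookup); redundancy across overlapping transcripts is intentional, because
  every transcript must receive its own annotation.

All genomic coordinates are 1-based inclusive throughout (GTF/VCF native);
BED output converts to 0-based half-open at the boundary.

## Gene model conventions

- Transcripts tagged as nonsense-mediated decay, or carrying
  start/stop-not-found tags, are excluded at load time. "Incomplete coding
  sequence" is additionally operationalized as a phase-adjusted CDS length
  that is not a multiple of 3 — annotation formats do not agree on flag
  names, so the arithmetic test is the portable part of the filter.
- CDS intervals *include* the terminal stop codon. GENCODE-style files that
  exclude it still parse, but the built-in annotator's stop-codon terms are
  defined relative to the last three coding bases; the synthetic generator
  always emits stop-inclusive CDSs.
- Minus-strand transcripts are stored in genomic orientation; translation
  order is derived where needed (codon assembly, junction reconstruction).

## Consequence semantics (built-in annotator)

The annotator enumerates the six point-mutation alleles
({A, C, G, T} SNVs, 1-bp deletion δ, 1-bp insertion ι) at every target
position. Splice acceptor/donor terms cover exactly the 2 intronic bases
flanking each internal exon junction; `splice_region_variant` covers 1–3
exonic and 3–8 intronic bases from a junction. Coding SNVs are resolved by
codon substitution on the transcript strand (synonymous / missense /
stop_gained / stop_lost / stop_retained / start_lost; `start_retained` is
never emitted because start codons depend on surrounding initiation context,
unlike stop codons). Coding 1-bp deletions and insertions are frameshift by
construction. The packed 58-bit value stores the coding frame as the
position's offset within its codon (0 for non-coding positions), and the
6-nt neighborhood in genomic plus-strand orientation:

- SNV/δ slots: 3 bp each side of the position, excluding it — exactly what
  junction reconstruction needs after the base is substituted or deleted;
- ι slots: `(p−2..p, p+1..p+3)` around the junction after position `p` — the
  base before the junction is part of any codon the insertion splits, so it
  must be stored.

An insertion is attributed to the base it follows; it counts as coding only
when both junction neighbors are coding and adjacent in translation order,
splits a splice motif only when strictly inside the 2-bp window, and
otherwise takes the non-coding class of the junction (falling back to the
base after the junction when the base before it is coding, e.g. insertions
immediately after a stop codon are 3'-UTR).

## Indel merge translation

Deletions travel as runs of 1-bp deletion slots. The client's own variant
list delimits spans (adjacent distinct deletions would otherwise fuse); run
boundaries in the decrypted product serve only as a consistency check — a
zero slot inside a span is an error. Per deletion and element:

1. coding-base count = slots carrying the frameshift bit; `count mod 3`
   decides `frameshift_variant` vs `inframe_deletion`;
2. start/stop/splice loss terms are the union over the span;
3. the junction codon is rebuilt from the first/last deleted base's stored
   neighborhoods and the first base's frame (reverse-complemented and
   mirrored for minus-strand elements) and checked against {TAA, TAG, TGA}:
   a stop there is `stop_gained`, or `stop_retained_variant` when the
   deletion also destroyed the original stop.

The junction check is skipped when the deletion ablates a splice site or the
start codon (the downstream reading frame is undefined then — the same rule
applies in the full-variant oracle so the two paths are comparable), and when
a codon-aligned in-frame deletion forms no new codon (unless the stop was
lost, in which case the junction is exactly where a compensating stop would
re-form). Insertions are translated by reading codons across
`left-flank + inserted sequence + right-flank` starting at the frame-derived
offset.

Two blind spots are inherent to the one-codon window and are left as
documented divergences (asserted as such in the tests, and counted by the
reproduction script): (1) stop codons created *downstream* of the junction
window by a frameshift — the merge reports the frameshift but cannot see the
stop; (2) stop codons formed *across spliced exon junctions* — the stored
neighborhood is genomic, not spliced mRNA. The full-variant oracle flags
these via `stop_offset > 0` and `flank_contiguous = False` respectively. On
the study-scale fixture they affect well under 0.1% of comparisons, and all
six HIGH-impact terms agree everywhere else.

The full-variant oracle itself rebuilds the spliced coding sequence with the
variant applied. It traces downstream codons only to find the compensating
stop after a stop-loss; otherwise it examines the junction (for deletions)
or the inserted codons (for insertions) — mirroring how the external
annotators this oracle stands in for actually report these classes, rather
than performing open-ended downstream ORF scanning.

## Secure compute contract

The backend algebra is: chunked encryption (`⌈length/l⌉` ciphertexts at slot
bound `l`, default 32 768 — a typical SIMD slot count for the lattice scheme
family this models; only the last chunk may be short), slot-wise add/multiply
(ciphertext-ciphertext and ciphertext-plaintext), logical slot shifts with
zero fill (rotation + masking in a real scheme), and directional key
switching. The mandatory mock backend stores plaintext integers tagged with
a key id and refuses mismatched-key operations, making protocol errors
testable; it declares a headroom bound (2⁶² by default) checked at
encryption, which callers must respect for reachable sums (58-bit packed
values; `2·n_G` for dosage aggregation). Server-side operations never take a
secret key — enforced at the type level and by the CLI's role checks. A real
homomorphic adapter must either place 58-bit payloads in a single
large-modulus slot or decompose them into limbs invisibly beneath this
contract.

## Aggregation

Counts are kept as raw integers; allele frequency `count / (2·n_G)` is a
presentation-layer division so encrypted results stay exact. The exact-span
deletion statistic follows the printed index convention in which "length
`l_δ`" spans `l_δ + 1` positions (`∀l ∈ [0, l_δ]`); the deleted-base-count
wrapper `aggregate_deletion_span(G, deleted_bases)` is the off-by-one-safe
API. Flanks outside the vector or outside the containing stitched region
read as 0, and spans crossing a region boundary never count — only deletions
engulfed in a target region are aggregated. The encrypted evaluation uses
`l_δ + 1` shifted ciphertext copies multiplied together, times the
complemented flanks, with the (public) region-boundary masks applied as
plaintext; both the plaintext and encrypted paths are provided and tested
for equality, since the statistic's deployment point (before or after
decryption) is an open choice.

## Synthetic data

The generator emulates the study conditions end to end: 1 Mb chromosomes
carrying 50 protein-coding genes (defaults), 1–3 isoforms per gene sharing
exons, exons of 15–45 whole codons with no in-frame stops (so exon-skipping
isoforms remain valid ORFs and shared exons are exact), 5–20 bp UTRs,
250–600 bp introns, both strands, occasional NMD-tagged / incomplete
isoforms and small genes nested in introns. Variants are placed per unique
covered position with Bernoulli probability 0.25 (the simulation probability
used throughout), SNV alternates uniform over the 3 non-reference bases,
indel lengths uniform on [1, 10] with uniform random inserted sequence.
Genotypes are Hardy–Weinberg draws at per-site allele frequencies from
Beta(0.8, 8) — a rare-skewed spectrum resembling population sequencing — and
all randomness flows through one seeded generator, so fixed seeds give
byte-identical FASTA/GTF/VCF output.

What the generator does **not** emulate: mutation-rate heterogeneity,
linkage disequilibrium, population structure, non-canonical splice sites,
overlapping reading frames, and reference N-runs. Passing tests therefore
demonstrate the correctness of the vectorized machinery on well-formed gene
models, not robustness to the full messiness of real annotation files.

## Problem sizes and numerical choices

The test suite and reproduction script run the SNV and indel comparisons on
the 1 Mb / 50-gene fixture (~100 k vector slots, ~13 k variants per type,
100 bp extensions as in the simulation protocol; the package default
`l_ext = 10` bp and a 5 bp preset remain available), aggregation on ~10 kb
of targets with 50 + 100 samples, and coordinate checks on 10⁵ random
positions. All comparisons are exact (integer) — there are no numerical
tolerances anywhere in the pipeline. Degenerate inputs are defined: empty
variant sets give zero vectors; positions outside all regions map to the
empty coordinate set; out-of-chromosome neighborhood bases encode as N;
deletions extending past a region edge are annotated over the overlapping
part only and excluded from span aggregation.

## Known limitations

Besides the two merge blind spots above: insertions are aggregated by
position only (distinguishing inserted sequences would require enumerating
them); gene-specific mode reports one record per deduplicated CDS region —
a deletion overlapping several regions of one gene yields several records
rather than a single worst-case collapse; indels are assumed left-normalized
upstream (only VCF anchor stripping is performed, since re-alignment would
change the deletion spans being aggregated); and multi-key homomorphic
encryption is deliberately out of scope — federated pooling relies on key
switching through a trusted key manager instead.
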