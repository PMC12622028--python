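# Methods

This note documents the models and procedures implemented in `teinvader`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data generators do and do not
emulate.

## Discovery of reference-absent elements

**Model.** A TE family that invaded after the reference strain was
sampled has no reference counterpart, so its reads either fail to map or
map to a distant relative with high divergence. The discovery chain
operates on a SAM alignment plus the read set:

1. *Selection.* A read is a candidate iff it is unmapped, or mapped with
   divergence strictly above `max_divergence` (default 0.05). Divergence
   is `NM / Σlen(M, =, X, I, D)`: the edit distance over aligned plus
   indel bases, clips excluded, so the ratio is bounded by 1. Secondary
   and supplementary records are ignored; each read is emitted once.
   Mapped reads without an NM tag are conservatively kept with the
   reference. An optional rule (off by default) also selects reads with
   ≥ 50% soft-clipped bases.
2. *Contaminant filtering.* Instead of re-aligning against contaminant
   genomes, reads are screened by canonical k-mer containment (k = 31): a
   read is dropped when ≥ 50% of its k-mers occur in the contaminant
   index. This is deterministic, has no alignment heuristics, and the
   hit fraction is tunable. Reads shorter than k pass through.
3. *Assembly.* A unitig-only canonical de Bruijn assembler (k = 31, odd to
   avoid reverse-complement palindromes). k-mers below a coverage floor
   are removed; maximal unambiguous paths are walked out; contigs < 2k are
   dropped; orientation and output order are canonical, so assembly is
   reproducible bit for bit. There is no bubble popping or scaffolding —
   for deeply covered, recently expanded families unitigs suffice, and
   externally assembled contigs can be fed to the same downstream filters.
4. *Translated search.* Contigs are translated in six frames, split at
   stop codons, and each peptide is locally aligned (Smith–Waterman,
   BLOSUM62) against the TE protein library. Affine gap costs follow the
   BLAST existence/extension convention: a gap of length L costs 11 + L.
   Identity is matched residues over alignment columns; the reported span
   is 3× the aligned query residues, i.e. a nucleotide span on the contig.
5. *Candidate filter.* A contig is retained when its best passing hit has
   identity > 80 (strict) and span > 250 nt (strict). Ties between
   equal-score hits resolve lexicographically.

**Coverage floor selection.** At high redundancy the same sequencing
error recurs independently in several reads, so a fixed floor of 2 no
longer removes error k-mers: at 100× with a 1% error rate roughly one
position in eight acquires a duplicated error k-mer, shattering unitigs.
The assembler therefore raises the floor to the first valley of the
k-mer count histogram when — and only when — the histogram is descending
at the base floor (the classic solid-k-mer cutoff between the error slope
and the true-coverage peak). Clean or low-coverage data has no such
slope and keeps the configured floor, so sparse inputs are not penalized.

**Interpretation of the span cutoff.** Whether a "> 250 bp" alignment
length refers to amino-acid columns or nucleotides is ambiguous in
translated searches; the nucleotide-span interpretation (3× aa) is used
and the threshold is configurable.

## Consensus and structural annotation

**Majority consensus.** Per alignment column the most frequent base among
{A, C, G, T} wins; N never votes; ties break in alphabet order. A column
in which the gap strictly outnumbers the best base is dropped entirely,
which keeps the consensus ungapped and usable as a mapping reference.
Presence/absence variants among insertions (segments carried by only part
of the family) therefore fall out of the consensus; they remain visible
through the per-column occupancy report emitted alongside. Columns with
only N/gap symbols emit N with a warning.

**Terminal repeats.** LTR pairs are found by exact k-mer seeding (k = 15)
between the first and last quarters of the sequence followed by ungapped
extension, one extension per diagonal. Extension is *anchored*: a
mismatch column is absorbed only when at least 9 of the following 10
columns match and cumulative identity stays at or above the threshold
(default 95%). A plain "extend while identity ≥ threshold" rule would
absorb ~5% of random flanking columns and systematically overshoot the
repeat boundary; anchoring pins the reported repeat to the true edge, so
a planted identical pair is recovered at exactly its length and 100%
identity, while pairs with scattered internal mismatches (e.g. 99%
identity) still extend through them. The longest qualifying pair wins.
Indel-containing LTR pairs are out of scope: recent insertions have
essentially identical LTRs, which is the use case here.

**Self dot plot and tandem repeats.** Exact k-mer self-matches (k = 10,
both strands, main diagonal excluded) are merged into collinear
segments. A forward off-diagonal segment long enough to wrap its own
offset indicates a tandem array; it is summarized as (start, end,
unit_length = offset, copy_count = span/unit), with overlapping
candidates merged onto the smallest unit. Reported boundaries can shift
by a base or two when a flanking base happens to match the repeat edge.

**ORFs.** All six frames are scanned for ATG-to-stop spans of at least
`min_aa` codons (default 200, the scale of retroviral genes); within each
stop-to-stop interval the first ATG wins, the stop codon is excluded from
the coordinates, and minus-strand ORFs are reported in forward
coordinates. The standard genetic code only; alternative starts are not
considered. When a protein library is supplied, each ORF is labelled with
its best-scoring protein (gag/pol/env assignment).

## Copy number and presence

Copy number follows the normalized-coverage approach: per-position read
depth over the TE consensus divided by the mean depth over single-copy
genes (SCGs), so one haploid copy corresponds to normalized depth 1.
Depth counts reads whose reference-consuming CIGAR span covers a
position; deletions count as covered, clips do not. The SCG factor pools
all SCG positions before averaging — for the three similar-length
BUSCO-style genes used in practice this is indistinguishable from a
gene-wise mean and simpler to reason about. The summary copy number is
the mean normalized depth (a median option exists for robustness to
internal deletions, and the maximum is also reported since "peak copy
number" is sometimes the quantity quoted).

A sample is called *present* when the breadth — the fraction of positions
with normalized depth strictly > 1 — is at least 0.9. The per-position
comparison is strict per the rule's wording ("coverage > 1"); the breadth
comparison is inclusive, a convention this package fixes explicitly. The
LTRs are counted once as part of the full-length consensus (no LTR
collapsing), matching mapping against the full consensus. Note that a
single-copy sample hovers around normalized depth 1 and is usually called
absent under the strict rule; the caller is deliberately conservative at
the one-copy boundary.

## Invasion timeline

Presence calls are joined to per-sample metadata (collection year,
biogeographic realm) and aggregated into exact counts per (year, region).
Years inside the sampled range with zero samples are emitted with
`samples_total = 0` rather than omitted, so a gap between an early first
detection and the next positive year is visibly a *sampling* gap. First
detection is the earliest year with ≥ 1 present sample, overall and per
region; when the element is absent everywhere it is reported as
undefined. Region labels are free categorical strings; no gazetteer
lookup is attempted. Input order never affects the output.

## piRNA profiling and the ping-pong signature

Reads in the piRNA length window (23–29 nt — standard for *Drosophila*;
the bounds are parameters) are placed at every position of both strands
of the consensus with up to 2 mismatches, no indels; the consensus is
short enough that a seed-free full scan is exact and fast. A read with n
placements contributes weight 1/n to each, a deterministic alternative to
random assignment of multi-mappers. The 5′ end of an antisense hit is the
rightmost covered position.

The ping-pong signature is the weighted histogram of 5′–5′ overlap
offsets between sense and antisense hits for offsets 1–20, computed as a
cross-correlation of the two 5′-end weight vectors. Germline ping-pong
amplification produces pairs overlapping by exactly 10 nt; the summary
statistic is the z-score of the offset-10 count against the other 19
offsets (sample standard deviation), with the fraction of pair mass at
offset 10 reported alongside since conventions differ. Degenerate cases:
an all-zero histogram has an undefined z-score; an all-at-10 histogram
(zero variance elsewhere) reports an infinite z-score, i.e. maximal
signal. Pair counts are products of weights, so doubling every read
quadruples counts but leaves the z-score unchanged.

## Assembly screening

Exact 13-mer seeds between the consensus and both strands of each contig
are extended without gaps under an X-drop rule (+1 match, −3 mismatch,
drop 15, trimmed back to the best-scoring extent); one extension per
diagonal, segments ≥ 50 bp kept. Segments are chained by dynamic
programming — the match-maximizing collinear chain with gaps ≤ 1 kb on
both sequences is extracted repeatedly — rather than greedily:
self-homology of the consensus (the LTR pair, internal tandem repeats)
otherwise hijacks chains of diverged insertions. Hits whose contig span
is ≥ 90% covered by a hit at least twice as long are suppressed as
shadows of the dominant hit.

Per hit: identity is matches over aligned columns of the chained
(ungapped) segments — interior unaligned gaps reduce the matched length
but not the identity, which mirrors how cross-species screens separate
alignment span from similarity; `matched_length` is the number of
distinct consensus positions covered; `full_length` is
`matched_length > 0.8 ×` consensus length. On 100 kb backgrounds, planted
full copies at 0–11% divergence return a single full-length chained hit
with identity within half a point of 100 − d, and chance 13-mer seeds
never survive the 50 bp segment floor.

For donor-species analyses, hits are extracted with up to 3 kb of flank
on each side (clipped at contig ends, minus-strand hits
reverse-complemented), and an optional filter retains only insertions
bounded by a terminal-repeat pair of ≥ 100 bp at ≥ 85% identity, trimmed
to LTR-to-LTR extent — solo LTRs and truncated copies fail. Insertion
counting collapses nearby fragments whose consensus projections overlap
by ≤ 50%, so one fragmented insertion is not counted twice.

## Synthetic data

The generators produce every input the pipeline consumes, with exact
ground truth, deterministically per seed:

- *Genomes*: i.i.d. bases at 42% GC (Drosophila-like).
- *The model element*: ~8.4 kb with two identical 514 bp LTRs, a 3 × 270 bp
  tandem repeat in the 5′ non-coding region, and random-codon gag
  (400 aa), pol (1100 aa) and env (450 aa) ORFs — the structure of a
  full-length insect endogenous retrovirus, with its true protein
  sequences available as the search library.
- *Planted copies*: substitution-only mutation at a stated per-copy
  divergence, inserted at spaced uniform positions; truth tables record
  exact coordinates and realized substitution counts, so truth CIGARs
  stay trivial. Discovery scenarios plant identical copies
  (divergence 0), emulating a very recent expansion from a single
  introduction; diverged and fragmented copies (e.g. a 4 kb relic at 11%)
  exercise the assembly screen. An indel mutation mode is a possible
  extension, not implemented.
- *Reads*: uniform single-end 100 nt reads at a deterministic count
  (coverage × length / read length), strand Bernoulli(0.5), per-base
  error rate, constant quality. The truth alignment is computed by
  bookkeeping against a caller-designated reference: reads fully inside a
  reference-derived segment are mapped all-M with NM equal to the actual
  mismatch count; reads touching inserted sequence are unmapped — exactly
  the signature a reference-absent invasion produces.
- *Small RNAs*: n antisense reads placed uniformly; a stated fraction
  receive a sense partner at exactly 10 nt 5′–5′ overlap, the remaining
  sense reads are uniform.
- *Cohorts*: per-region arrival years with logistic establishment
  (probability 0.5 in the arrival year, 0 strictly before), sampled
  according to a stated plan.

**What the generators do not emulate** — and hence what passing tests do
not demonstrate about real data: indels and structural variation within
the invading family, sequencing-quality profiles and GC bias, paired-end
structure, real contaminant genomes (contaminants are random synthetic
sequences), pervasive genomic repeats competing with the new element,
piRNA biogenesis beyond 5′-end geometry, and mapping-induced biases
(truth alignments are exact, a real mapper is not). The desk-scale
problem sizes used throughout — 100 kb backgrounds, ≤ 50 copies, 20–30×
coverage, 3 kb single-copy genes, 300–500 read small-RNA libraries — were
chosen as the smallest sizes at which each recovery property is
comfortably away from its noise floor.

## Known limitations

- The assembler produces unitigs only; families with internal repeats
  longer than k collapse those repeats into shared unitigs, and highly
  polymorphic families fragment. This is by design: the discovery logic
  lives in the surrounding filters.
- The protein search reports raw scores and identities, not E-values.
- LTR detection assumes ungapped, near-identical repeat pairs.
- The presence caller is conservative near one haploid copy (see above).
- Screening identity is computed over ungapped segments; for highly
  indel-rich homologs the identity is an overestimate of a full
  alignment's identity while matched length is an underestimate.
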