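# Methods

## Scope and model

The package analyzes transgene integrations created by an engineered R2
retrotransposon system. R2 elements nick the bottom strand of the 28S
rDNA and use the nicked strand to prime reverse transcription of a donor
RNA (target-primed reverse transcription, TPRT). An engineered donor
carries, 5′→3′: a short 28S homology (tens of nt), the transgene cargo, a
structured 3′ UTR (~67–100 nt, required to initiate TPRT) and a short
(4–8 nt) 3′ homology that base-pairs with the nicked strand. On perfect
integration both homologies merge into the locus, so the integrated scar
is `transgene + 3′ UTR` placed at the nick site. Imperfect outcomes are
5′ truncations (reverse transcription terminated early, removing a prefix
of the transgene), template jumps (rearranged or duplicated insert
segments; also internal deletions that retain the transgene 5′ end) and
snap-backs (inverted duplications).

Three read-level assays are modeled:

* **locus-spanning long reads** (Cas9-enrichment nanopore style):
  kilobase reads covering ≥400 nt of locus flank on both sides of the
  insertion point;
* **UTR-anchored read pairs** (tagmentation integration-site sequencing,
  TTISS): read 1 begins with the 3′-most bases of the donor 3′ UTR and
  continues into downstream genomic flank at the insertion junction;
  read 2 is the opposite-strand mate;
* **amplicon reads** over a 59-nt junction amplicon for base-frequency
  quantification.

## Alignment engine

`r2scribe.align` is a deterministic affine-gap dynamic-programming engine
(numba-compiled kernels, exhaustive O(nm) — no seeding heuristics, which
desk-scale inputs do not need).

* `align_local`: Smith–Waterman/Gotoh. Default scoring +2/−3 with gap
  open −5, extend −2 (a gap of length L costs 5+2L). Ties are broken
  deterministically: every maximal-score end cell is traced back and the
  alignment minimizing (ref start, query start, ref end, query end) wins;
  the forward strand wins score ties.
* `align_spliced`: glocal (query aligned end-to-end, reference ends
  free) with a two-piece gap cost on both gap sides; the long class
  (open −24, extend −1) overtakes the short class at ~19 nt and makes
  insert-sized gaps affordable. Reference-consuming gaps ≥50 nt are
  reported as skip (N), shorter ones as deletion (D); a query-side long
  gap (e.g. the insert, aligned against the insert-less wild-type
  reference) appears as one long insertion (I). Glocal rather than local
  alignment is essential here: with a zero score floor the optimal local
  alignment would split at any gap whose cost exceeds the flank anchor
  score, and truncations would never surface as interior gap runs.
* `consecutive_gap_runs` merges adjacent D/N ops (insertions break a
  run) and reports maximal runs above a threshold, in reference order —
  the primitive behind the ≥4-consecutive-base rule.

Identity is matches / aligned query bases (M+X+I). CIGAR bookkeeping
(query- and reference-consuming op sums equal the interval lengths, no
unmerged adjacent ops) is validated on every constructed alignment and
property-tested.

## Long-read classification

Per read: annotate all six features on both strands by iterated
best-local-alignment with masking (so duplicated segments give separate
hits), splitting alignments at internal gaps ≥20 nt before thresholding —
a feature interrupted by a large deletion is reported as two hits, the
way repeat annotators do, instead of one low-identity hit that would fall
below threshold. Hit acceptance: identity ≥0.8 and ≥30 aligned nt
(tolerant of the default error model, stringent enough that random 4-kb
background yields no spurious hits; validated in tests).

The informative-read filter pools annotated length across the two
segments of each flank side (≥100 nt of 5′-end and of 3′-end features in
one orientation). Trimming groups each side's flank hits into blocks
(intervals merged when within 30 nt — the two adjacent features form one
block) and picks the same-orientation block pair furthest apart on the
read; the trimmed interval is strictly between the blocks, reported in
insert-forward orientation.

Gap runs for the integrity rule are measured on the glocal spliced
alignment of the *flank-inclusive* segment (outer boundaries of the
chosen pair) against the integrated reference, counting only runs that
overlap the insert span [nick, nick+insert_len). The flanks anchor the
alignment — an insert-only glocal alignment of a 5′-truncated read would
simply start downstream and show no gap at all — while sequencing
dropouts confined to the flanks do not count against insert integrity.

Classification precedence is full_length → jump → five_prime_truncation →
other (the literal jump clause — "a single transgene feature aligning
within the first 10 nt of the transgene 5′ end" — would otherwise swallow
every full-length read). "Does not align to the 5′ end" is
operationalized as transgene projection start ≥10, reusing the jump
clause's bound. The jump multiplicity clause ("projections do not overlap
on the reference") tolerates ≤10 nt of overlap, because local-alignment
boundaries jitter by a few chance-match bases; genuine duplications and
snap-backs overlap by hundreds.

Consequences worth knowing: an internal deletion ≥4 nt that retains the
transgene 5′ end classifies as *jump* (5′-anchored, broken insert), and a
snap-back whose inverted segment re-covers part of the transgene
classifies as *other* — both follow from the rule set, and the synthetic
panel encodes these expectations as truth.

ddPCR-detectable reads contain the probe site and both primer sites, each
within ≤2 substitutions (no gaps; Hamming scan over all read offsets,
both strands), primers convergent and flanking the probe.

## Insertion-site analysis

Anchor: read 1 must begin with the UTR tail within ceil(0.1·|tail|)
edits (indels allowed, adapter-trimming convention); the tail is trimmed
off. Mapping is two-tier, mirroring the 28S-then-genome contract:
fragments within 5% edit distance of the 28S reference are on-target;
the rest map to the genome (edlib bounded edit distance, both strands,
unique best placement required — ties are counted as ambiguous, never
assigned), with the mate required to map convergently within 600 nt.
Junction coordinate: fragment start on '+', fragment end on '−'. Every
rejected pair is tallied (anchor-rejected / unmapped / improper /
ambiguous), so reads are conserved by construction.

Site classification extracts the 120-bp window centred on the junction
and takes the maximum number of matching bases over all ungapped offsets
against wild-type 28S, both strands (the centred, ungapped-maximum
reading of "a 120 bp window around the insertion site"; an exhaustive
scan that is oracle-checkable). ≥108 matches → pseudo-28S on-target;
otherwise off-target. Sites inside the annotated 28S locus interval are
on-target regardless. Windows truncated by a genome end are classified
on the available bases and flagged partial.

The off-target logo covers positions [−30, +7) relative to the junction
(position 0 = first downstream base, read in insertion orientation;
upstream negative), accumulating base counts × read count and
normalizing per position. The range covers the three motif regions: the
upstream recognition patch around −25…−19 (conserved T at −20), the −9
region, and the downstream 3′-homology match at +1…+5.

Junction base frequencies follow amplicon-quantification convention:
reads failing mean or single-base phred <20, or aligning to the amplicon
with homology (matches / amplicon length) <60%, are excluded; surviving
reads' bases at the 5 window positions centred on the junction are
tallied (a deletion contributes '−', so each position's frequencies sum
to 1).

## Quantification

* ddPCR copies/genome = 2 × target / RPP30 (two reference-gene copies
  per genome). Zero reference concentration raises a named error.
* Full-length copies/genome = junction copies × n_full / n_detectable
  (linear in both numerators; displayed at one decimal, round-half-even,
  raw value retained).
* %-processed, top strand = 100 × cleaved / total lane intensity; bottom
  strand = 100 × (cleaved + TPRT) / total. "Other" bands (template
  jumping) count toward total only — they are neither cleaved substrate
  nor TPRT product.

## Synthetic data: what it emulates, and what it does not

`refsim` is first-class, tested code. The toy locus is a fixed-seed
random 4-kb sequence with the nick at 2 kb (the real 28S sequence is not
required by any analysis rule — every rule is positional or
identity-based); transgene 720 nt (a GFP-sized cargo), 3′ UTR 100 nt (the
mini-donor length), homologies 36/5 nt. Long reads span the insert plus
uniform 500–800 nt of flank per side; half are emitted
reverse-complemented; qualities are constant phred 30 because the
quality filters apply only to the amplicon analysis. The error model
(substitution 0.02, insertion 0.01, deletion 0.01 per base, plus one
10–100 nt deletion per read with probability 0.1) exercises the
≥4-consecutive-D/N rule without overwhelming feature annotation: per-base
deletions essentially never chain into runs of 4, so run-triggering
events are the long deletions, about 40% of which land in the insert
span — which is why full-length recall under the default model sits a
few percent below 1 while zero-error classification is exact.

The toy genome plants one exact 28S locus, pseudo-28S copies (600 nt
centred on the nick; the requested 120-window identity is produced by
evenly spaced substitutions inside the window, ~5% divergence outside)
and motif off-target sites in random background: the donor's 3′-homology
prefix (4 or 5 nt) immediately downstream of the junction and a T at −20
with probability 0.9; ~10% of off-target sites are on the minus strand.
Read counts: one on-target site at 2400 reads, pseudo sites 20–60,
off-target sites geometric (p=0.35). A deliberately unmodeled corner: a
pseudo copy ≥~115/120 identity becomes indistinguishable from the true
locus at the fragment level (it would tier-1 map or multi-map); default
identities (114/111/108) keep planted sites uniquely recoverable, which
is what the plant-and-recover tests verify.

Not emulated: real 28S sequence content, nanopore signal-level error
structure (homopolymer bias, quality correlation), chimeric reads, PCR
duplicates and tagmentation bias, multi-chromosome genomes. Passing
tests therefore demonstrate correctness of the rules and their
boundaries on structurally faithful inputs, not robustness to every
artifact of real libraries.

## Problem sizes and determinism

The test suite runs the classifier on 200 zero-error and 400
error-model reads (10 outcome alleles), the TTISS analysis on ~3,300
pairs over 244 planted sites, and the alignment/window oracles on 200+
random instances up to 500 nt — sizes chosen so the full suite completes
in a few minutes on one core while keeping binomial noise well inside
the asserted margins. Every stage is a pure function of (inputs, seed):
numpy `default_rng` throughout, one generator per simulation, fixed
seeds in tests (refset 1, genome 3, error model 42).

## Known limitations

* The aligner is exhaustive O(nm); it is not meant for genome-scale
  mapping (that step uses edlib's bounded search).
* `align_local` returns the single best alignment; feature annotation
  recovers multiple hits by masking, which cannot resolve two
  overlapping occurrences on the same read interval.
* The jump/other boundary for exotic rearrangements follows the literal
  rule set; outcomes outside the synthetic panel's structure (e.g.
  nested inversions) fall to *other* without further subdivision.
* Copy-number estimation ignores droplet-level Poisson statistics (the
  instrument reports concentrations directly) and assumes detectable
  reads are an unbiased denominator for the full-length fraction.
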