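# Methods

## Model and assumptions

`pefrag` treats fragment recovery as a graph problem.  A paired-end (PE)
library of fragments drawn from one genome is assembled into a de Bruijn
unitig graph; every fragment then corresponds to a walk through that graph,
anchored at the two mapped mate loci and bounded in spelled length by the
library's insert-size distribution.  The method assumes:

* fragments are contiguous genomic sequence (no structural rearrangement
  between the mates);
* mates face inward (Illumina FR chemistry) — outward or same-strand
  placements are rejected as non-authentic;
* sequencing errors are substitutions (indel-free reads), which keeps all
  alignment gapless;
* the insert-size distribution is unimodal enough that its histogram,
  thresholded at a frequency cutoff, brackets the authentic lengths.

## Pipeline stages and parameters

### Assembly (`assembler`)

K-mers are counted canonically (a k-mer pooled with its reverse
complement); k-mers seen fewer than `min_kmer_count` (default 2) times are
discarded as noise, which removes the great majority of error k-mers since
a specific substitution must recur at the same locus to survive.  Contigs
are unitigs: maximal paths in which every interior node has exactly one
predecessor and one successor.  Per-base depth is the mean count of the
k-mers covering the base; bases at depth ≤ `unreliable_depth` (default 1)
are written lowercase as unreliable (with the default count filter this
only occurs when `min_kmer_count` is lowered to 1).  Unitigs sharing a
(k−1)-overlap at a branch point become oriented edges, stored closed under
reverse-complement symmetry.

The default k is 60 % of the read length, rounded **down to the nearest odd
integer** (odd k avoids self-reverse-complement k-mers; the rounding
direction is this package's choice).  No tip-clipping or bubble-popping is
performed beyond the count filter — a deliberate simplification relative to
full assemblers.  Its practical consequence: recurrent sequencing errors
(≥ 2 identical substitutions at one locus) create short branches that break
unitigs.  The break points retain their graph edges, so the bridging search
still crosses them; true coverage gaps (a genome k-mer sampled error-free
fewer than `min_kmer_count` times) disconnect the graph and are
unrecoverable.  Recovery performance is therefore sensitive to the ratio of
coverage to `0.99^k`-style error attrition; with 1 % errors and k = 59 the
per-k-mer error-free sampling rate is ≈ 0.55, so libraries below roughly
40× read coverage begin to fragment the default-k assembly.

Memory note: for `min_kmer_count` ≥ 2 the counter uses a saturating
128 M-slot hash prefilter so that singleton error k-mers (the bulk of the
k-mer volume at realistic error rates) never enter the exact-count table.
False positives of the prefilter are removed by the exact second pass, so
counts are exact and results are independent of the hash seed.

### Mapping (`mapper`)

A placement is reported when the read's first `seed_length` (40) bases — in
the read's own orientation, i.e. at the right end of the reverse-complement
on the minus strand — align with ≤ `seed_max_mm` (2) mismatches and the
whole read with ≤ `total_max_mm` (5).  Alignment is gapless; all qualifying
placements on both strands are returned, sorted by mismatch count.  A read
is *uniquely mapped* when exactly one hit attains the minimal mismatch
count.  Candidates come from a pigeonhole q-gram index: the seed is split
into `seed_max_mm + 1` disjoint chunks (q = 13 at the defaults), so any
in-budget placement matches at least one chunk exactly; chunk lookups are
binary searches on a sorted integer array and candidates are verified by
vectorised mismatch counting.  Contigs shorter than the seed are excluded
from the index (no full alignment could fit on them anyway).

### Classification and insert-size estimation (`classify`)

Fragment length is the **end-inclusive outer distance**: rightmost mate end
minus leftmost mate start.  This equals the simulated fragment length,
which makes correct-merge evaluation exact.  A PE with hits of both mates
on a shared contig is regular even when other contigs are also hit (regular
takes precedence over bridging).  The authentic range takes the smallest
and largest histogram bins whose frequency reaches `cutoff` (default 5) —
a global scan, chosen over an outward-from-mode scan for determinism on
noisy histograms.  A consequence worth knowing: at finite library size the
extreme tails of the true insert distribution fall below the cutoff, so a
fraction of genuinely authentic pairs (≈ 0.2 % at 50,000 pairs with a
normal insert distribution) lies outside the estimated range and is
deliberately not recovered.  The recovery percentage for regular PEs
approaches, but never exactly reaches, 100 % — at multi-million-pair scale
the shortfall is below two-decimal display precision.

### Recovery (`recover`)

All three procedures work in the *fragment frame*: the frame is anchored on
a mapped mate, oriented so the fragment reads 5'→3' from that mate, with
the fragment start at offset `off` on the anchor contig.

* **Regular**: the contig substring between mate start and mate end
  (inclusive of both mapped loci).  If a pair is authentic on several
  contigs the one with the highest mean depth wins.
* **Bridging**: bounded DFS over oriented edges from the anchor contig to
  the mate contig in the orientation that makes the second mate face
  inward.  A partial path is abandoned once its spelled extent beyond the
  fragment start reaches the range maximum; revisits are allowed (the bound
  terminates cycles).  The fragment length implied by each path must fall
  inside the full range — the minimum is enforced too, since a sub-minimum
  fragment would contradict the authenticity rule applied to regular PEs.
* **Single-mappable-end**: DFS extension sequences from the mapped locus
  are scanned for an exact occurrence of the unmapped mate's first
  `head_length` (10) bases, reverse-complemented into the frame; junction-
  straddling occurrences are caught by carrying a (head−1)-base tail across
  edges.  Each in-range occurrence is a candidate placement.

Selection among multiple candidates: highest length-weighted mean read
coverage of the path (weights = bases each contig contributes to the
spelled sequence), then fewest path steps, then the lexicographically
smallest step list, then the shortest fragment.  All tie-breaks are
deterministic.  Searches that hit the `max_paths` cap (200) or the DFS
expansion budget (100 × `max_paths`) return nothing rather than a guess.

### Consensus correction (`correct`)

Only reads that are (a) mates of an authentic, in-range regular PE and
(b) uniquely mapped contribute to the pileup.  At each position where the
strict-plurality consensus differs from the contig base, the base is
replaced if it is lowercase/unreliable (any coverage ≥ 1) or if the
consensus holds ≥ `min_fraction` (0.6) of ≥ `min_depth` (10) covering
bases.  Exact plurality ties change nothing.  Replacements are emitted
uppercase; correction is substitution-only by construction.  When enabled
in the pipeline, recovery always re-maps reads against the corrected
contigs.  Note that correcting a base inside an overlap region can make an
assembly edge's sequences disagree by that base; path spelling takes
junction bases from the downstream contig, so spelled output remains
single-valued.

### Simulation (`simulate`)

The simulator emulates three features of real PE data: a read-start
profile (uniform by default; proportional to observed read starts when
derived from mappings), fragment lengths `round(Normal(frag_mean,
frag_sd))` with `frag_sd` defaulting to 10 % of the mean, and per-cycle
substitution rates scaled so the expected overall error rate meets
`error_rate` (1 % default).  Pairs are drawn until read bases reach
`coverage` × genome length (default 100×).  Fragments overhanging the
genome end are clamped to the remainder; a remainder shorter than one read
forces a start redraw, and the run aborts when more than 10 % of draws
needed clamping.  Coordinates are 0-based half-open; the truth table's
fragment sequence is strand-oriented, so slicing the genome and applying
the strand reproduces it exactly.  Qualities encode the per-cycle error
rate as phred scores (capped at 40, the cap also standing in for
"error-free").  When an error profile is derived from real qualities, the
per-cycle average is taken in probability space (mean of 10^(−q/10)), not
on the phred scale.  Everything is deterministic under the seed.

What the simulator does **not** model: indels, GC-dependent coverage bias,
adapter read-through, chimeric fragments, quality-value noise.  Passing
tests on these libraries therefore demonstrate the graph algorithms and
calibration, not robustness to indel errors or biased coverage.

### Evaluation (`evaluate`)

*Correct* merge: recovered length equals the true fragment length (bases
may differ).  *Perfect* merge: sequence identical to the truth, with
reverse-complement equality accepted since fragment orientation relative to
the genome is arbitrary.  Report percentages follow the recovery-table
convention: recovered over PE counts, correct/perfect over recovered
counts.  N50 is the largest L such that contigs ≥ L hold at least half the
assembled bases.  Evaluation requires a simulator truth table; scoring real
data against a reference via best placement is out of scope.

## I/O conventions

FASTQ qualities use offset 33 throughout.  Mate identity strips `/1`/`/2`
suffixes and SRA/CASAVA-style blank-separated `1`/`2` comment fields;
anything else must match exactly.  The contig graph interchange format is
GFA 1.0 with `<n>M` overlap CIGARs; lowercase S-line bases carry the
unreliable flag and a `dp:f` tag carries mean depth (absent → 1.0).
Parse errors name the offending record; Biopython handles FASTA/FASTQ
parsing underneath, so line numbers for those formats are approximate
(record-derived).

## Test and acceptance problem sizes

The test suite validates the pipeline end to end on 10–100 kb synthetic
genomes (seconds each); the acceptance script runs the short-fragment
merging experiment on a 1-Mb genome with 100,000 PEs, which completes in
about a minute on one CPU.  Oracle tests compare the DFS path search, the
mapper, and the path speller against brute-force enumeration/scan
implementations on hundreds of randomized instances.

## Known limitations

* No tip/bubble cleanup means assembly contiguity — and with it the
  correct-merge rate — degrades at low coverage or high error rates faster
  than a full assembler's would; the default k (60 % of read length) wants
  roughly ≥ 40× coverage at 1 % error.  A smaller k is the practical remedy
  at higher error rates (`pefrag recover -k 31 ...`).
* The unitig assembler never miscalls an interior contig base under the
  default count filter (wrong bases segregate onto low-depth branches), so
  consensus correction mainly matters for imported external graphs or
  `min_kmer_count=1` assemblies.
* Multi-mapped single-mappable-ends anchor on their best (fewest-mismatch)
  hit only.
* Circular genomes and multi-replicon references are not modelled by the
  simulator (fragments never wrap).
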