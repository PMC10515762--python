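# Methods

## Problem and model

Given coordinate-sorted long-read alignments of a diploid sample, the task
is to label each read with the haplotype it derives from (haplotag 1 or 2,
or untagged) using only *local* evidence. The model is deliberately
minimal: heterozygous SNVs partition reads into two groups, and reads that
co-occur on the same alleles at neighbouring sites belong to the same
haplotype. No genotype likelihoods, no chromosome-scale phasing, no
realignment.

The unit of inference is the **allele graph** of an interval: a vertex for
every allele at every candidate heterozygous site, an edge between alleles
at consecutive sites supported by at least one common read. Three read
sets drive scoring: per-vertex support R(V), per-edge spanning support
R(U, V), and per-vertex "fresh" reads R\*(V) — reads whose first
overlapped site is the vertex's site, which would otherwise never be
counted.

## Dynamic program

The phaser maximizes read support for an assignment of one allele per
phase per site, over ordered pairs (i assigned phase-1, j assigned
phase-2), including the diagonal i = j so that sites without real
heterozygosity can pass through without forcing a block break.

- Initialization at a block's first site: S(1, i, j) = |R(i) ∪ R(j)|.
- Recursion: S(n, i, j) is the maximum over *unordered* predecessor pairs
  {k, l}, taken in canonical orientation (k extends phase-1 into i, l
  extends phase-2 into j, k ≤ l), of the predecessor pair's best
  orientation score plus |R(k→i) ∪ R(l→j) ∪ R\*(i) ∪ R\*(j)|.

The canonical-orientation cell convention needs a word. Phase labels are
symmetric — flipping every state of a scoring path preserves its score —
so the two orientation cells (i, j) and (j, i) jointly cover every ordered
transition, and propagating the pairwise maximum is provably equivalent to
the unrestricted recursion over all ordered predecessor pairs (the test
suite checks this against exhaustive enumeration on randomized instances).
The individual cells, however, are *not* symmetric: (i, j) and (j, i) can
differ because each maximizes only over canonically oriented predecessors.
Both are exposed in the score table.

Backtracking selects the best final-site cell per block and follows
backpointers; when a predecessor's best score lives in its mirrored
orientation cell, the walk switches to the mirror chain and un-mirrors the
emitted states (a flip flag). Ties are broken deterministically
everywhere: smallest (k, l) predecessor in the max, smallest (i, j) cell
in backtracking. All scores are exact integers — set cardinalities and
sums of them — so there is no floating point anywhere in the phaser.

Degenerate connectivity: a vertex with no incoming edge is joined to every
previous-site vertex by artificial edges carrying empty read sets (they
keep the recursion defined without adding support); if *no* vertex at a
site has an incoming edge, phasing cannot be extended, scores reinitialize
and a new phase block begins. Blocks are anchored at their first site's
position; the 1-based anchor is the PS value written downstream.

## Candidate refinement

A candidate site that is really homozygous (typically a pileup of
sequencing errors) is poison for a consecutive-edge graph: both haplotypes
pass through its major allele, so every path through the site loses the
relative orientation of the flanking segments. The dynamic program
identifies these sites itself — their backtracked pair is the diagonal
(same allele in both slots), since the diagonal's transition gain counts
both haplotypes' reads — and the transition *out* of a diagonal is
identical for both orientations, making the downstream orientation
mathematically arbitrary rather than merely uncertain.

The phaser therefore iterates: phase, drop every site whose backtracked
pair is diagonal, re-phase. Removal makes the flanking true sites
consecutive, so the reads spanning them form real edges and their direct
linkage is restored. The loop ends when no diagonal remains on the path;
intervals whose first pass is diagonal-free (clean HiFi-like data, the
worked example) are returned unchanged. At ONT-like error rates
(3% substitutions, 30× coverage) roughly two error-pileup candidates
appear per true heterozygous site under the default filters, and this
refinement is what keeps haplotag accuracy high there; without it,
orientation scrambles at every false site.

## Candidate detection

Pileup columns are screened with permissive, fully configurable
thresholds; the phaser, with the refinement above, tolerates noisy
candidates, whereas a missed site costs linkage:

| parameter | default | meaning |
| --- | --- | --- |
| `min_alt_count` | 2 reads | minimum alternate-allele support |
| `min_alt_fraction` | 0.12 | alternate fraction must lie in [f, 1−f] |
| `min_base_quality` | 10 | per-base Phred floor |
| `min_mapping_quality` | 5 | per-read MAPQ floor |
| `max_alleles` | 4 | alleles kept per site (ref + 3 alt, by support) |

Only SNVs are candidates by default; an optional flag admits length-1
indel alleles (keyed at the anchor position), at the cost of the slower
full-column scan. The allele cap exists because the recursion is quartic
in alleles per site. For speed, a vectorized prescan over reads flags
positions where any alternate base reaches `min_alt_count`; the exact
column logic then runs only at flagged positions. A candidate VCF can be
supplied instead, in which case detection is skipped and only the per-read
observations are recomputed from the pileup.

## Chunking and merging

Contigs are tiled into 25 kb chunks processed independently (the method is
local by design; there is no chromosome-scale phase). Each chunk scans
reads overlapping the chunk ± a 5 kb margin but emits tags only for reads
starting before the chunk end, so reads starting inside the preceding
margin are deliberately emitted by both neighbours. Merging walks chunks
in coordinate order: a chunk's labels are globally flipped when the
majority of these shared reads disagree with the already-merged output; a
read tagged in several chunks keeps the tag backed by more votes; a
conflict that survives flipping untags the read. This majority-flip rule
is the natural order-independent reconciliation using only information the
chunks emit; a `merge=False` mode keeps per-chunk phase sets instead.
Phase-set identifiers remain globally unique because they are genomic
anchor positions.

## Read tagging

Each read votes with the phased alleles it overlaps: a phase-1 allele is a
vote for haplotag 1, a phase-2 allele for haplotag 2; alleles in neither
slot, and sites whose two slots hold the same allele, contribute nothing.
A strict majority decides; ties and empty votes stay untagged (a 1–1 read
is unphaseable, and no extra margin is required beyond the strict
majority). Phase labels are only comparable within a block, so a read
spanning several blocks votes inside the block holding most of its
vote-eligible observations (ties to the earlier block). Reads with no
observation at any candidate site are emitted untagged with zero votes.

In the output BAM, `HP` ∈ {1, 2} is set for tagged reads and absent
otherwise, and `PS` (1-based block anchor) is written exactly when `HP`
is; stale HP/PS on input records are stripped first, and secondary or
supplementary alignments inherit their primary's tag.

## Synthetic data

The simulator generates a uniform-random reference, plants heterozygous
SNVs as a Bernoulli process per bp (default 10⁻³, a human-scale
heterozygosity), assigns each alternate allele to a random haplotype, and
draws reads with a fair haplotype coin, uniform starts, lognormal lengths
and i.i.d. substitution errors:

- HiFi-like default: 18 kb mean length (log-sd 0.3), 0.2% error, 30×;
- ONT-like preset: 30 kb mean length, 3% error.

Errors are substitution-only by design: indel errors would entangle
candidate detection with alignment conventions, while SNV phasing is what
the dynamic program actually consumes. Base qualities are flat (derived
from the error rate), so quality-based filtering cannot rescue errors the
way it partially can on real data. Read starts are uniform, so coverage is
thinner near contig ends. Everything derives from one seeded generator:
the same seed gives byte-identical outputs, and the aligned-BAM mode and
the direct observation-table mode are built from the same per-read
sequences, so they agree exactly.

Consequently, passing tests show that the algorithm recovers phase under
calibrated error and coverage regimes; they do not exercise mapping
artifacts, reference bias, non-uniform error profiles, indels, or somatic
mixtures.

## Evaluation

Haplotag labels are arbitrary within a phase set, so accuracy is
switch-aware: predicted-tagged reads are grouped by phase set, and within
each group the orientation (identity or 1↔2 swap) maximizing agreement
with truth is chosen before counting. Reads untagged in either input are
excluded from the compared set and reported as an untagged fraction;
a stricter normalization (correct reads over all truth-tagged reads, so
that leaving reads untagged counts against the method) is reported
alongside, since either convention is defensible.

## Problem sizes and verification

The exhaustive-enumeration oracle re-scores every per-site assignment
sequence with the same transition counting as the recursion and is
feasible up to ~8 sites × 3 alleles; the suite compares it against the
dynamic program on hundreds of randomized instances (up to 6 sites, 3
alleles, 20 reads, seeded). End-to-end checks simulate 200 kb at 30×
(≈ 330 HiFi-like or 200 ONT-like reads, ≈ 200 heterozygous sites, 8
chunks) — large enough for several phase blocks and chunk merges while
keeping the whole suite fast — and require ≥ 99% (HiFi-like) and ≥ 95%
(ONT-like) switch-aware accuracy against the simulator's truth; both
presets currently achieve 100% at the tested seeds. Determinism is checked
by byte-comparing repeated pipeline outputs.

## Known limitations

- Phase blocks are local by construction; no attempt is made to stitch
  blocks across low-heterozygosity deserts beyond the chunk-merge rule.
- The chunk-merge flip is a single orientation per chunk; a chunk
  containing several internal blocks with inconsistent orientations
  relative to its neighbour can only be partially reconciled.
- Candidate detection assumes SNVs; dense indels or alignment artifacts
  around repeats will surface as missing or false candidates.
- The per-phase-set orientation in the evaluator makes accuracy on very
  small phase sets optimistic; the untagged fraction and the stricter
  normalization should be read alongside it.
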