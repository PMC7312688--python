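# Methods

This note documents the models, conventions and numerical choices behind
`mitokit`, module by module, including the design decisions that were
genuinely open and the limitations of the synthetic fixtures.

## Genome records and composition accounting

Coordinates are 1-based inclusive everywhere, matching the convention of
published organelle feature tables; intervals may wrap the origin of the
circular molecule (`wraps_origin`), in which case `start > end` is allowed.
Multi-copy genes (duplicated tRNA loci, typically) are collapsed into one
`GeneModel` with `copy_count` set, so "unique gene" counts follow the
organelle-literature convention.

CDS extraction joins exons in annotation (transcript) order, reverse
complementing each exon per its own strand. This handles trans-spliced
genes — whose mature mRNA is assembled from non-contiguous, even
opposite-strand genomic segments — without a special case; the only
assumption is that the annotation lists exons in transcript order, which is
the sole reproducible convention when segments are not colinear.

Composition tables partition every base into exactly one region using the
precedence **protein exon > cis-spliced intron > tRNA > rRNA > non-coding**.
This makes region sizes sum to the genome length, which published
genome-feature tables implicitly assume but never state; other overlap
conventions would shift intron/tRNA sizes slightly. Cis introns are the
gaps between genomically adjacent exons of one gene; for trans-spliced genes
only gaps inside a colinear block of exons count. Ambiguity code N is
accepted, contributes to region sizes, and is excluded from both numerator
and denominator of the base percentages.

## Repeat census

**SSRs.** A maximal lag-*p* run scanner (NumPy vectorized) over motif sizes
1–6 with per-class minimum full-copy counts (defaults 8, 4, 4, 3, 3, 3).
Runs are trimmed to whole motif copies, reported only at the minimal period
of the motif (an `ATAT…` array is one dinucleotide SSR, not two interleaved
mononucleotide runs), and deduplicated across the origin of circular
sequences by scanning with a virtual overhang (capped at 1 kb). Only
perfect repeats are reported; compound or interrupted SSRs are out of
scope.

**Tandem repeats.** The same run scanner over unit sizes 7–200 (the 7 bp
floor separates the tandem census from the SSR census; published plant
mitogenome tandem units are ≥ 13 bp). An array qualifies with ≥ 2 copies, a
trailing partial copy yields a fractional copy number, and each array is
reported once at its smallest period (KMP minimal-period check on the
spanned sequence; nested reports are suppressed by containment). This is a
deterministic perfect/partial-copy scanner, not a reimplementation of
heuristic score-based tandem finders, so counts on real genomes are
expected to be close to, but not identical with, those tools' output.

**Dispersed repeats.** A genome-vs-self `blastn` search under unit scoring
(reward 1, penalty −3, gap open/extend 3/3, word size 7, E < 1). Hits are
filtered to length ≥ 30 bp and identity > 80%, the trivial self-diagonal and
symmetric duplicates removed, and hit pairs merged into a single repeat
unit whenever either projection overlaps by ≥ 1 bp (union–find); the merged
unit's footprint is the union of its intervals, the representative length
is the longest member hit. The dispersed scan runs on the linearized
sequence: an origin-spanning block would be reported as two blocks. Since
the operative filters are length and identity, the E-value cutoff is
applied directly by BLAST at the genome's search-space size.

## Codon statistics and RNA editing

The standard genetic code applies (plant mitochondria use it). Codon totals
exclude a *standard* terminal stop (TAA/TAG/TGA) per CDS but retain a
non-stop terminal codon: a gene ending in CGA is counted as ending in a
sense (arginine) codon until C-to-U editing converts it to UGA. This
convention is what reconciles summed gene lengths with genome-wide codon
totals (e.g. 28,725 bp / 3 = 9575 codons, minus 30 standard stops = 9545
for the common-bean reference set). Internal in-frame stops — legitimate in
pre-editing sequences — are tallied in the counts table but never inflate
the sense-codon total, and are dropped from amino-acid profiles with a
logged warning.

RSCU is reported as 0 for every member of an unobserved family (with the
family flagged) to keep tables rectangular. Editing sites are inputs (TSV:
gene, codon index, position in codon), applied as C→T in DNA
representation; a site addressing an already-edited T is a no-op, which
makes application idempotent, while A/G/N raise. Editing-site *prediction*
is deliberately not implemented — published predictors are trained models
and their output is treated as given data.

## Ka/Ks (selection screen)

Orthologous CDS pairs are aligned through their protein translations
(global Needleman–Wunsch, BLOSUM62, gap open 10 / extend 0.5 — the default
protein-aligner behavior of common codon-alignment wrappers), back-translated
to codons, with gapped and stop-containing columns dropped.

The estimator follows the Yang–Nielsen counting framework with these
pinned choices:

* **kappa** — estimated from the four-fold degenerate and non-degenerate
  position classes (positions classified in both sequences), a K80 inversion
  per class combined by site-count weighting; identical sequences leave
  kappa undefined and it falls back to 2 with a flag (the rates are 0
  regardless).
* **sites** — per codon, S is three times the synonymous fraction of the
  mutational flux to all non-stop single-nucleotide neighbors, each
  weighted by kappa (transitions) and the position-specific F3×4 target
  frequency estimated jointly from both sequences; S and N are averaged
  over the two sequences. N + S = 3 × (aligned codons).
* **differences** — equal weighting over the orderings of multi-position
  codon differences, pathways through stop codons excluded when any
  stop-free pathway exists; transitions and transversions tracked
  separately for each class.
* **correction** — a two-parameter (K80) multiple-hit correction applied
  separately to the synonymous and nonsynonymous classes. The
  frequency-corrected (F84-style) variant would differ only at divergences
  approaching saturation; at the moderate divergences where counting
  estimators are reliable the two agree closely.

Ks = 0 leaves the ratio undefined (printed as NA), never infinite. A
saturated class (correction log argument ≤ 0) flags the result
`saturated`. The validity screen is a two-sided Fisher's exact test on the
2×2 table (synonymous, nonsynonymous) × (differences, non-differing
sites), fractional counts rounded half-up; a zero margin is degenerate and
scores p = 1 with a flag.

**Validated regime.** On sequences simulated with the package's codon-wise
substitution process (ω ∈ {0.1, 1, 4}, 300 codons, synonymous divergence
≈ 0.08), the rank order of ω is recovered in ≥ 96% of 50 replicates and
mean estimates are within 30% of truth. At deep divergence (Ks ≳ 0.25 with
ω = 4, i.e. nonsynonymous distances approaching 1), counting estimators
compress large ratios — a known property of the method class, not a defect
of this implementation; results there carry the saturation caveat.

## Conformation resolution

Contigs have a head (H) and tail (T); traversing `+` runs H→T. A
conformation is a circular walk using every contig exactly `copy_number`
times, enumerated by exhaustive DFS and deduplicated up to rotation and
reflection (reverse complement of the whole circle). For the canonical
two-inverted-repeat graph (four unique contigs, two copy-2 repeats) exactly
three single-circle walks exist — the master and two single-flip isomers;
the "double flip" is not a single circle for inverted repeats, which is
why such genomes are reported as one master plus two isomers. Graphs where
the double flip does remain a single circle list it as a `candidate`,
never as an isomer.

Junction references pair each upstream flanking context of a copy-2 repeat
with each downstream context (four references), with 200 bp flanks by
default, truncated when a flanking contig is shorter. Reads are matched by
edit-distance alignment (edlib): either the whole reference embedded in the
read, or the read embedded in the reference provided the alignment reaches
at least within 10 bp of both flank boundaries — both orientations tried.
A read counts for the variant with the strictly best (identity, length)
qualifying hit; ties across variants leave the read uncounted. Identity is
`1 − edits/alignment length` against thresholds of 80% and a configurable
minimum hit length (3000 bp for real long reads; synthetic tests scale
this down with their genome sizes). The published E-value cutoff for this
step is subsumed by the identity × hit-length contract, which is the
operative filter at these lengths.

The master is the conformation consistent with the top-supported flank
pairing at every repeat (the two complementary variants of a pairing pool
their read counts); isomers differ from it at exactly one repeat. Tied
support at any repeat is flagged ambiguous and no master is named;
pairings that are jointly unrealizable raise an error listing the
conflict. Link overlaps default to 0 (blunt joins); an overlap column is
honored during sequence realization.

## Synthetic data

The generator emulates a papilionoid-legume-like mitogenome at desk scale:
default 120 kb circular (tests use 50–60 kb), GC 0.45, i.i.d. background,
an A/T-biased SSR spectrum, tandem arrays with units 15–27 bp (kept below
the 30 bp dispersed-repeat floor so the manifests of the two censuses stay
disjoint), two large inverted repeats at copy number 2 (4866 and 3529 bp,
the sizes characteristic of master/isomer-mediating repeats), and ~14
genes including multi-exon, trans-spliced (opposite strands), ACG-start and
CGA-stop cases plus a duplicated tRNA locus (which is itself recorded as a
direct dispersed repeat).

Exactness of the manifests is engineered, not hoped for: the background is
scrubbed of any run a detector could report, planted repeats get guard
bases so maximal runs end exactly at the planted coordinates, dispersed
copies get mismatch-forcing bases just outside their boundaries so local
alignment cannot extend past them, and a post-assembly polish pass rewrites
junction artifacts (codon-wise inside genes) until the detectors report
exactly the planted sets. Generation is fully deterministic per seed
(byte-identical FASTA), with a bounded internal retry (`salt`) recorded in
the manifest.

Long reads are sampled uniformly around the circle with log-normal lengths
and substitution errors only by default; indels are not modeled, so the
read-matching thresholds are exercised through substitution identity. The
codon-divergence simulator proposes uniform single-nucleotide changes and
accepts synonymous ones with probability min(1, 1/ω) and nonsynonymous with
min(1, ω), never creating stops and sparing start/stop codons; it drives
synonymous divergence to a target Ks (default 0.1).

**What passing these tests does and does not show.** The background has no
higher-order composition structure, planted repeats are perfect copies and
read errors are substitutions only; recovery at 100% precision/recall here
validates the detectors' logic and coordinate arithmetic, not their
behavior on diverged repeat families, indel-rich long reads, or
heteroplasmy — real-genome counts from heuristic tools (tandem finders,
E-value-based repeat censuses) are expected to differ modestly and are
treated as soft checks.

## Numerical conventions

Percentages are rounded to 2 decimals, rates to 4 in TSV output; sort
orders are fixed so re-runs are byte-identical. Fisher tables round
fractional counts half-up. The circular-scan overhang is capped (1 kb for
SSRs, 2 × max unit + 1 kb for tandems). All RNG flows through
`numpy.random.default_rng` seeded from explicit arguments.
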