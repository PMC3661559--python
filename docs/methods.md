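# Methods

This note documents the models, parameter choices and numerical conventions
behind `intromir`, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinates and intron semantics

Internally every interval is 0-based half-open; GFF3 (1-based inclusive) is
converted only at the I/O boundary.  Intron ordinals are transcript-relative
(counted 5′→3′ along the mRNA), so for minus-strand genes ordinal 1 is the
genomically *rightmost* intron and intron sequences are reverse-complemented.
Introns identical across multiple transcript models of a gene are
deduplicated by interval.  Read counts are normalized to RPM with a
configurable scale factor (default 2, `expr_rpm_factor`); setting the factor
to 1 yields plain RPM.

## Inverted-repeat detection

Bl2seq-style self-alignment is implemented as seed-and-extend: exact 11-nt
seeds between the intron and its reverse complement (the BLASTN word size),
ungapped extension with +1/−2 scoring and an X-drop of 6, trimmed to the
maximum-scoring extent, and a final identity filter at 80%.  Hits are
canonically oriented (query arm left of subject arm) and deduplicated, so
each physical arm pair appears once.  Hit footprints within `ir_join_gap`
(15 nt) are merged single-linkage into fragments; a fragment is an IR iff
its span is strictly greater than 50 nt and the union of footprints covers
at least 30% of the span.  Overlapping IRs on the chromosome are reduced to
the longest (ties: leftmost start, then intron id).  Detected IR boundaries
are accurate to a few nucleotides: extension can overrun a stem end when
flanking bases happen to match, which matters only when measuring
nucleotide-exact distances between adjacent loci (see Clustering).

## Folding and the "good hairpin" gate

The default engine is Nussinov base-pair maximization over {AU, GC, GU}
pairs with a minimum hairpin loop of 3 nt.  The O(n³) fill is
numba-compiled (about a second for the longest ~1.7-kb hairpins considered);
the traceback is deterministic — pairing is preferred over leaving a base
unpaired, and the smallest admissible partner wins ties — so identical
inputs give identical structures.  Any external folder that maps sequence →
dot-bracket (e.g. ViennaRNA MFE via `viennarna_fold`) can be substituted;
all downstream logic only consumes the pair table.

"Good hairpin" is operationalized as: at least `fold_min_paired_fraction`
(default 0.5) of positions paired, and a **single dominant stem-loop**.
Because pair maximization happily folds a handful of incidental bases into
tiny parasite hairpins (inside the terminal loop, in flanking sequence, or
at a stem mismatch), raw hairpin-loop counting would reject genuine
precursors.  Stems are therefore counted after pruning: a hairpin loop
whose exclusive helix support is below 25% of all pairs is removed
(weakest first, support recomputed) and only the surviving stem-loops are
counted.  Two genuinely comparable stems still count as two and are
rejected.

## Read mapping and siRNA exclusion

Mapping is exact-substring only (18–25-nt reads), matching the collapsed,
error-free libraries the generator emits.  On a fold-back locus the reverse
complement of a 5′-arm read is itself present on the 3′ arm, so strand
classification is sense-priority: a read matching the sense strand is
attributed to it, and only reads matching exclusively the reverse strand
count as antisense — the signature of a genuine antisense transcript.
(`dual_strand="both"` records both placements when a symmetric view is
needed.)

Two signals exclude siRNA loci before calling: "continuous" coverage,
defined as more than `sirna_min_starts` (10) distinct sense 5′ start
positions inside any `sirna_window` (30 nt) sliding window — an
operationalization of low cleavage precision — and an antisense unique-read
fraction above 10%.  The 100-read expression gate sums mapped reads across
all libraries pooled.

## Duplex calling

For a mature candidate at interval *(s, e)* on the hairpin, the expected
star interval under 2-nt 3′ overhangs on both strands is
`[pt[e−3], pt[s]+3)`; candidates whose anchors are unpaired or whose star
would overlap the mature (loop-spanning reads) get no star.  A duplex is
retained when mature **or** star support exceeds 20 reads; star-deficient
calls (structure valid, star unsequenced) are allowed by default and
flagged.  Duplex defects are counted by walking the mature core against the
star-strand register: symmetric unpaired runs are mismatches, asymmetric
excess is a bulge on the longer side.  Accepted calls have ≤ 4 mismatches
and at most one bulge of ≤ 2 nt.  Reciprocal calls (the star observed as
its own candidate) collapse to one duplex, keeping the more abundant strand
as mature; overlapping candidates collapse to the highest-count
representative; survivors are ranked by total duplex reads.  The precursor
passes when duplex reads are ≥ 40% of all stack reads.  Hairpins ≥ 1000 nt
with ≥ 8 accepted products are flagged miRNA-like long hairpins and
reported regardless of the ratio gate.

## Classification and composition

Clustering is single-linkage within a host gene: two precursors join when
the gap between their genomic spans is strictly less than 3000 nt.  The
strict boundary (2999 clusters, 3000 does not) is exercised on exact
coordinates at the operation level; the synthetic genome plants its
boundary pairs at 2999 and 3500 nt because detected IR ends carry a few nt
of uncertainty.  Categories: cluster members are CP; otherwise ≥ 2 matures
is MMP, else UMP.  Composition statistics bucket matures into 20–22 / 23 /
24-nt classes with per-class 5′ base tallies; percentages are rounded
half-up to integers, which reproduces the printed reference values
exactly.

## Expression analyses

miRNA RPM profiles are log2(x + 1)-transformed (pseudocount configurable)
and clustered with Euclidean k-means (k-means++ with a mandatory seed;
defaults k = 10, 50 iterations; the synthetic demo uses k = 4 for its 12
profiles).  Host correlation uses Spearman's rho with average ranks over
matched samples; pairs with fewer than 3 matched samples are skipped and
miRNAs with zero RPM in ≥ 3 samples are dropped as unexpressed; |rho| > 0.5
defines the positive/negative categories.  Category comparisons use the
two-sided Wilcoxon rank-sum test — exact null for tie-free samples of ≤ 25
each, normal approximation otherwise — and expression histograms are binned
right-closed over (0, 16] in 8 intervals (a value on an edge falls in the
lower bin).

## Target prediction

The miRNA is aligned against candidate windows in antiparallel orientation
by a minimum-penalty global DP (mismatch 1, G:U 0.5, bulge 2; ties broken
toward fewer bulges, then earlier pairing).  Working in the
reverse-complement frame, a Watson–Crick pair is base equality and G:U
appears as (G,A)/(U,C).  Rules: total ≤ 2.5; at least one of positions 10
and 11 a perfect match (strict "both" mode available — the requirement is
stated ambiguously in common usage, and the literal "or" is the default);
at most one mismatch/wobble/bulge event touching positions 2–9 (wobbles
score 0.5 but count as full seed events).  A second bulge alone costs 4 and
can never pass, so one bulge is an effective maximum.  Note the penalty is
symmetric under swapping which strand is the query, but not under naive
joint reverse-complement (G:U would map to the unpairable C:A).  Scanning
evaluates every window of length m±1 on one or both strands; a
numba-compiled score-only DP prefilters windows before the full alignment
is produced.  Sites are collapsed per gene/strand to the best-scoring
representative, with flags for sites in the miRNA's own host gene and
overlapping its own precursor locus.

## Synthetic data: what it emulates, and what it does not

The generator is a pure function of (config, seed) — identical inputs give
byte-identical files.  Defaults define the clean study: 20 genes (alternate
strands, 2 introns each, 200-nt exons), 10 planted precursors — 4 UMP,
2 two-mature MMP, a clustered pair at a 2999-nt gap and an unclustered pair
at 3500 nt — plus 5 siRNA decoys.  Precursor stems are 80-bp arms with an
8-nt loop; 5% mismatches are sprinkled on the 3′ arm *outside* the duplex
and away from stem ends, keeping the annotation gates deterministic while
avoiding perfect palindromes.  Planted duplexes give 150 mature / 60 star
reads at exact 2-nt-overhang-consistent intervals; degradation background
is added to make the duplex ratio 0.8, spread over few distinct 5′ starts
with every unique background read kept below the 20-read gate (precise but
uninformative degradation).  Decoys are hairpins with 15% arm mismatches
carrying 150 sense reads over 50 uniform 5′ starts plus ~29% unique
antisense reads chosen to match only the reverse strand.  Counts are split
multinomially over 8 libraries.  Expression uses a Gaussian copula:
host latent z ~ N(0,1), miRNA latent sign·(0.9 z + 0.05 ε), giving near-1
latent correlation — the intended "monotone association with small noise";
hosts of clustered precursors get a +3 shift on the log2 scale.

Passing the recovery tests therefore shows the funnel is correct and
well-calibrated for clean, exactly-mapping reads with planted structure; it
does not demonstrate robustness to sequencing error, multi-mapping
ambiguity, partially-processed precursors, expression-dependent biases, or
real secondary-structure thermodynamics (pair maximization is not an energy
model).  Problem sizes throughout (20-gene genomes, ~4k reads, 200
correlation replicates, 100 oracle folds) were chosen so the full test
suite and the acceptance script each run in seconds on one CPU while still
exercising every gate and boundary.

## Known limitations

- No mirtron (splicing-dependent) biogenesis, methylation state, or
  degradome validation; own-locus/self-target flags are annotations only.
- Exact-match mapping; no mismatch tolerance or quality model.
- Nussinov folding has no free energy, partition function or suboptimal
  structures; GU is a full pair.
- The 100-read gate pools all libraries (per-library gating would need the
  per-sample stacks, which the mapper already provides).
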