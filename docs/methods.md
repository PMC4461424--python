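# Methods

## Scope and model

`mockotu` evaluates how OTU counts relate to known species composition in
mock zooplankton communities amplified for the 18S V4 region. The package
has two halves: a seeded generator that emulates the community designs and
the read process, and an analysis chain (filtering → clustering →
taxonomy → evaluation) that mirrors the standard greedy-clustering
workflow for tagged pyrosequencing amplicons. Because community
composition is known by construction (and recorded per read in a truth
table), every analysis output can be checked against ground truth.

## Community and read simulation

**Reference templates.** Species are simulated as V4-like templates
descending from a common random ancestor by substitutions, with
per-species lengths drawn from 440–480 nt (V4 length varies substantially
across eukaryotes; the default range keeps every insert longer than the
400-nt trim so no reads are lost to length in error-free runs). Candidate
templates are accepted only if their measured divergence to every accepted
template lies in the requested range. The check uses the package's own
aligner under the `INTERNAL_GAPS_ONLY` convention: with a shared-ancestor
construction, length variation shows up purely as terminal overhang, which
is an artifact of the construction rather than substitutional divergence.
The default range for pipeline runs is 13–30%: comfortably above every
clustering threshold in the 1–10% scan (including at the 400-nt read
level, where the per-pair divergence estimate fluctuates by roughly one
percentage point around the template value), so species never merge and
OTU inflation can be attributed entirely to within-genome variation.

**Intragenomic variants.** Each genome carries one dominant rDNA copy (the
template itself) plus optional variants defined by an explicit mutation
record: substitutions and insertions/deletions of 1–36 nt with per-variant
copy frequencies. Edit sites are sampled on template coordinates with
enforced separation and applied right to left, so edits never overlap and
a variant's edit distance to its template is exactly one per substitution
plus the summed indel lengths; replaying the record always reproduces the
variant. The `calibrated` pipeline plan draws 1–6 variants per individual
with a mean near 2.6 and indels up to 14 nt, matching published surveys of
intragenomic V-region length variation in *Daphnia*; these are scenario
parameters, not estimates for any particular taxon.

**Designs.** Four community designs are supported: tagged individuals (one
individual per species, one 10-nt MID tag each), tagged populations
(~5/~10/~30 conspecific individuals per sample — the default set is 24
populations over 13 species), and untagged pools of the same members. MID
tags are generated with pairwise Hamming distance ≥ 3 so that a single tag
error can never cross-assign a read under exact matching. Per-individual
weights are equal; per-sample read counts are allocated proportionally to
total member weight with the overall total fixed at
`reads_per_sample × n_samples` (largest-remainder rounding), so a
10-individual population receives twice the reads of a 5-individual one
while read counts stay exactly conserved.

**Reads.** Each read is `[MID] + forward primer + insert`, truncated to
450 nt. Degenerate primer positions (K, Y, R in the
`AGGGCAAKYCTGGTGCCAGC` / `GRCGGTATCTRATCGYCTT` pair) are resolved
uniformly at random per amplicon. Reads are single-direction and need not
reach the reverse primer, which only bounds the insert. The per-read
(individual, variant) choice is proportional to member weight × rDNA copy
number × copy frequency. Error model, in order: PCR substitutions on the
insert; a chimera branch that joins a prefix of one amplicon to the suffix
of another at a uniform crossover ≥ 50 nt from each end (so both parents
contribute detectable segments); sequencing substitutions over the whole
read; ±1 nt slips in homopolymer runs ≥ 3 (the dominant pyrosequencing
error mode — restricting to ±1 keeps truth replay simple). Default rates
are 2×10⁻⁴ (PCR), 10⁻³ (sequencing), 5×10⁻³ per run (homopolymer) and 1%
chimeras — plausible for Taq + pyrosequencing; pipeline scenarios override
them explicitly (the benchmark recovery scenarios run error-free).
Qualities follow a linear Phred decay (mean 38, 0.012/position, floor 28,
capped at 40) with per-read and per-base Gaussian jitter, reproducing the
observation that quality declines along the read without flowgram-level
modelling; occasional low-offset reads fail the expected-error filter, as
real reads do.

All randomness flows from `numpy` generators seeded per run, with
per-sample streams spawned from a `SeedSequence`, so identical
(design, config, seed) yields byte-identical FASTQ and truth files.

## Read processing

Processing order is demultiplex → trim → expected-error filter →
dereplicate → singleton policy. Tag and primer must match exactly (IUPAC
degeneracies honoured, zero mismatches): reads with errors in those
regions are discarded, not corrected. Reads are cut to exactly 400 nt;
shorter reads are discarded rather than padded, since the clustering stage
requires globally comparable fixed-length sequences. The expected-error
statistic E = Σᵢ 10^(−Qᵢ/10) is computed over the 400 retained positions
and reads with E > 0.5 are dropped. Dereplication is exact string
grouping, ordered by decreasing abundance with lexicographic tie-breaks so
results are independent of read order. Singletons (abundance-1 uniques)
are defined within the set being clustered — per population for the
populations design, pooled for the individuals design — and either kept or
dropped per policy. Phred encoding is +33 only.

## Alignment and divergence

Pairwise alignment is global with free (unscored but recorded) terminal
gaps and affine penalties: match +1, mismatch −2, first gap column −10,
each further gap column −1. The heavy gap-open keeps alignments of
substitution-only pairs gapless while still preferring a single clean gap
over a cascade of mismatches for genuine indels. Tie-breaking is fixed —
diagonal preferred over a gap consuming the first sequence, over a gap
consuming the second; end points scanned from the corner outward so
smaller overhangs win — making every alignment deterministic. The kernels
are numba-compiled; an independent plain-Python dynamic-programming oracle
in the test suite reproduces every column count on randomized pairs.

Divergence is computed per alignment column, not per gap run:

- `ALL_GAPS_COUNTED` (default): (mismatch + internal gap + terminal gap
  columns) / total columns;
- `INTERNAL_GAPS_ONLY`: (mismatch + internal gap columns) / (total −
  terminal gap columns).

Both conventions are first-class because they bracket the behaviour of
greedy clustering tools on trimmed, indel-bearing reads: a lone 36-nt
indel between 400-nt reads measures 72/436 ≈ 16.5% under the first and
36/400 = 9.0% under the second. Which is "right" depends on whether one
regards the trim-induced terminal overhang as signal; the package takes no
position and reports both.

## Clustering

Greedy abundance-ordered centroid clustering: uniques are processed in
decreasing abundance (ties lexicographic); each joins the centroid of
minimal divergence if that divergence is within the threshold radius
(boundary merges), else seeds a new OTU. Assignment is to the *best*
centroid, not the first within range, for order-robustness; divergence
ties go to the higher-abundance, then earlier-created centroid. All merge
comparisons use exact integer arithmetic on column counts
(`num × 100 ≤ t × den`), so threshold boundaries behave exactly rather
than at floating-point mercy. A post-hoc validator asserts on every result
that members lie within the radius of their centroid and that each
centroid exceeds the radius to all earlier centroids.

The optional bimera screen flags a candidate when a prefix matches one
more-abundant centroid and the complementary suffix another with at most
one total mismatch, no gap run ≥ 2 columns, a crossover ≥ 50 columns from
either end, and the candidate itself beyond the threshold from both
parents. It is off by default in analysis runs (the benchmark reports no
chimera counts) and on in simulator validation.

## Taxonomy

Queries are aligned to every record of the local reference FASTA by exact
Smith–Waterman with the same scoring scheme — local databases here hold at
most hundreds of records, so exactness is affordable and fully
deterministic, with no seeded-heuristic compatibility to chase. A hit is
positive at ≥ 90% identity over ≥ 330 aligned columns; identity counts gap
columns in its denominator (conservative). References are ranked by
alignment score, with identity, alignment length and species id as
successive tie-breaks: ranking by raw identity would let a chance ~9-nt
perfect match (100% identity) outrank a genuine full-length 95% hit.
No e-values are computed — the criteria are identity and length only.
Raw-read screening (which species demonstrably entered the data) collapses
identical read sequences before alignment, since the hit depends only on
the sequence.

## Evaluation

Per-sample OTU counts come either from per-sample clustering (populations)
or from pooled clustering with OTUs attributed to every sample
contributing a member read (individuals). A sample is 1:1 when it yields
exactly one OTU; a zero-OTU sample (e.g. all its uniques were excluded
singletons) counts as non-1:1. Aggregate percentages round half-up
(15/24 → 63). The minimum single-OTU threshold is the smallest t ∈ 1..10
giving exactly one OTU, else the sentinel `>10`. Detection curves count,
per threshold and singleton policy, OTUs and expected species with at
least one positively assigned OTU. Pearson correlations use the classical
product-moment estimate with a two-sided t-transform p-value (n−2 df);
zero-variance input fails loudly rather than returning NaN.

## Problem sizes

Default pipeline scenarios use 20 species (individuals) or 24 populations
over 13 species, 60 reads per sample, and the full 1–10% threshold scan —
sizes chosen so a complete run, including the pooled threshold scan at
400 nt, completes in seconds to a couple of minutes on one core while
still exercising every mechanism (variant injection, singleton policies,
terminal-gap inflation). The clustering-versus-reference equivalence suite
uses 200 random fixtures of up to 20 uniques at 60–100 nt, where the
plain-Python oracle is the cost bottleneck.

## Known limitations

- No flowgram-level 454 simulation, paired-end reads, reverse-strand
  orientation or PCR-cycle-resolved amplification bias.
- The bimera screen is deliberately simple (two parents, ≤ 1 mismatch,
  crossover scan) and not comparable to production chimera detectors.
- Synthetic templates share a single ancestor, so interspecific divergence
  is substitutional by construction; real V4 length variation between
  species (hundreds of nt) is represented only via the template length
  range, not via deep indel histories.
- Passing tests demonstrate internal consistency and correct mechanism
  arithmetic on simulated data; they do not certify behaviour on real
  reads, whose error structure (notably context-dependent homopolymer
  noise and chimera formation rates) is richer than the model here.
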