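# Methods

`mirmod` implements a desk-scale pipeline for discovering candidate
stress-tolerance miRNA–mRNA regulatory modules from a factorial tri-omics
experiment: two contrasting genotypes (salt-tolerant **ST**, salt-sensitive
**SS**) × four timepoints after salt treatment (0.5, 3, 8, 27 h) × two
conditions (control **CT**, 150 mM NaCl) × three replicates = 48 libraries,
profiled at the small-RNA, transcript, and degradome (PARE) levels. This
note records the models, the parameters that matter, what the synthetic
generator does and does not emulate, and the numerical choices made where
the design was open.

## Coordinate and alphabet conventions

All transcript positions are 1-based, fully closed; miRNA positions are
numbered 1..L from the 5′ end (so "cleavage opposite position 10" follows
the degradome-literature convention). Sequences are normalized to uppercase
RNA (T→U) in memory; transcript FASTA is written back as DNA.

## Small-RNA profiling (`srna`)

Reads are collapsed to unique tags with per-library counts; tags shorter
than 18 nt or longer than 25 nt are discarded (with accounting). Tags are
classified against annotation sets by exact substring match with fixed
priority rRNA > tRNA > snoRNA > repeat — a desk-scale surrogate for
mapping-based removal; there is no alignment. Remaining tags are assigned to
known miRNAs by Hamming distance ≤ 2 among equal-length references
(substitutions only, matching the "one or two nucleotide mismatch"
convention for catalog assignment), ties broken by smallest reference id.

Precursor plausibility uses a Nussinov maximum-pairing recursion
(O(n³), hairpin loops ≥ 3 nt, AU/GC/GU pairs) instead of genome-based
hairpin-discovery tools. A precursor passes when (i) maximum pairs /
length ≥ 0.30, (ii) the miRNA:star duplex read off the symmetric fold
(position x pairs with n+1−x) is ≥ 60 % paired, (iii) the mature miRNA
occurs exactly once and lies entirely on one arm, and (iv) the length is
within 60–300 nt. The 0.30 / 0.60 / 60–300 thresholds are this package's
own defaults (flagged `artifact_default` in reports), tuned to separate
stem-loops from shuffled sequence, not literature constants; reports also
flag whether a precursor falls in the empirically typical 100–120 nt
window.

## Normalization and differential expression (`expression`)

* **miRNA**: counts-per-million. Because a handful of strongly responding,
  highly abundant miRNAs can shift a library's total — deflating every
  other miRNA's CPM in exactly the treated libraries and creating
  systematic false "down" calls — the pipeline's default scales CPM by TMM
  (trimmed mean of M-values) effective library sizes: reference = library
  with count sum closest to the median, 30 % two-sided trim on M, 5 % on A,
  precision-weighted mean, factors rescaled to geometric mean 1. Plain CPM
  is available via `mirna_normalization: CPM`.
* **mRNA**: FPKM = count × 10⁹ / (library total × length nt); a transcript
  is *expressed* in a genotype when FPKM ≥ 1 in at least one of that
  genotype's libraries. The same ≥ 1-in-one-library rule is applied to
  miRNA CPM for genotype-level "found / not found" calls. The FPKM layer is
  deliberately left on plain totals: the fold-change gate below makes the
  mRNA calls insensitive to the few-percent compositional shifts seen at
  this scale.
* **miRNA DE** at one (genotype, timepoint): equal-variance two-sample
  t-test on normalized values, NaCl vs CT (3 vs 3); significant at
  p < 0.05, direction from log2((mean_NaCl + 1)/(mean_CT + 1)) (pseudocount
  1 CPM). miRNAs with mean CPM < 1 across all 48 libraries are dropped
  first (the "middle or high expression" retention; the threshold is a
  package default and is surfaced in reports).
* **mRNA DE**: Welch t-test on log2(FPKM + 1); significant requires
  p < 0.05 **and** |log2FC| > 1. This is a documented surrogate for an
  exact negative-binomial test: with n = 3 per arm and the fold-change
  gate, the Welch test reproduces the operating characteristics the
  downstream rules need, and acceptance is scored by planted-effect
  recovery rather than concordance with any external implementation.
* Raw p-values are thresholded, matching the source thresholds; a
  Benjamini–Hochberg column is included for information only.
* qPCR-style quantification: 2^−ΔΔCt with ΔCt = Ct_target − Ct_reference
  per replicate, calibrated against the control group; group difference by
  Student's t-test on replicate ΔCt values.

Under a null simulation (effect 0) the miRNA test's positive rate is ~5 %
per contrast — the test suite checks 0.05 ± 0.015 over 2,000 features.

## Degradome-guided target calling (`degradome`)

Duplexes are scored with the plant-miRNA complementarity penalty scheme:
mismatch 1.0, G:U wobble 0.5, gap 2.0, all penalties doubled over miRNA
positions 2–13; score = sum, 0 is a perfect site. At most one gap is
allowed: an unpaired miRNA base at position i is doubled when 2 ≤ i ≤ 13;
an inserted (unpaired) site base between miRNA positions i and i+1 must be
internal and is doubled when both flanks lie in the core (2 ≤ i ≤ 12).
Sites with score ≤ 7.0 are candidate targets. All constants are
configurable and echoed in outputs.

The transcript scan is exact, not heuristic: for ≤ 1 gap the optimal
alignment at each site start decomposes into prefix/suffix sums of the
gapless penalty matrix, so every window (lengths L−1, L, L+1) is scored in
vectorized form and the best alignment per site start is reconstructed by
enumeration. The test suite verifies the scan against brute-force window
scoring and the single-window scorer against exhaustive alignment
enumeration.

A candidate site becomes a **cleavage event** only with degradome support:
≥ 1 five-prime read at the transcript coordinate paired with miRNA position
10 ± 1 (the common PARE window; configurable). The maximal-count position
in the window is recorded (ties: closest to the canonical position-10
coordinate, then smaller coordinate). Events get CleaveLand-style abundance
categories relative to all degradome signal on their transcript: 4 = single
read; 0 = unique transcript-wide maximum; 1 = tied maximum; 2 = above the
median of non-zero positions; 3 = otherwise (lower-middle median, so the
rule is deterministic). No noise p-value is computed; planted-recovery
testing takes its place. Pairs are keyed by (miRNA, transcript, cleavage
position) — the same duplex cut at a different position is a different
pair — and the catalog marks each pair ST-specific, SS-specific, or shared.

By default only differentially expressed miRNAs are scanned (the catalog
the downstream rules consume is defined on DEmiRNAs); scanning all miRNAs
is a switch.

## Coherent pairs and the four-class genotype contrast (`integration`)

A **coherent pair** at (genotype G, timepoint t) is a degradome pair, with
evidence from G's own degradome profile, whose miRNA and transcript are
both significant at that contrast with strictly opposite directions.

A coherent pair becomes a **candidate module** when the other genotype G′
shows the pair unresponsive: the miRNA is either *little changed*
(expressed in G′ but never significant at any of the four timepoints) or
*not found* (below the expressed threshold in every G′ library), the
target mirrors that condition, and the pair is not coherent in both
genotypes. "Little changed" is operationalized purely by significance,
matching the source definition ("expression levels did not change
significantly"); a |log2FC|-tolerance variant exists as configuration. The
four classes (DE in ST / flat in SS, DE in SS / flat in ST, ST-specific,
SS-specific) partition the candidates; the class label follows the miRNA's
situation in G′. A pair coherent at several timepoints yields one module
with merged timepoints, so module counts are counts of unique pairs.

## Co-expression neighborhoods (`coexpression`)

On all expressed transcripts' log2(FPKM+1) across the 48 libraries:
unsigned adjacency |r|^β (signed option available), β chosen as the
smallest power whose scale-free-topology fit R² ≥ 0.8 (log–log regression
of the connectivity histogram over 10 bins using per-bin mean connectivity;
fallback 6 with a warning). Topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), diagonal 1.
Modules come from average-linkage clustering on 1 − TOM with a **static**
cut at height 0.25 — a deterministic replacement for dynamic tree cutting,
sufficient for the pipeline's actual downstream product — and clusters
below 30 genes are relabeled "grey". For each candidate target the 20
most-overlapping genes are reported (ties by gene id; a target never lists
itself).

## The synthetic study generator (`sim`)

The generator emits the complete 48-library experiment plus a truth set.
Its defaults are the study conditions used throughout testing:

| parameter | default | note |
|---|---|---|
| n_mirna / n_transcripts / n_true_modules | 60 / 300 / 24 | modules span all four classes (equal mix; any weights configurable) |
| miRNA lengths | 18–25 nt, mode 21, 24 second | matches the reported catalog shape |
| GC target | 0.4274 | reported mean GC |
| hairpin length | 100–120 nt | symmetric stem-loop, loop 6–11 nt, star arm = mutated reverse complement (rate 0.08) |
| transcript length | 800–1200 nt | uniform |
| effect_log2fc | 2.0 | planted signed effect; target gets the negation |
| dispersion | 0.05 | NB (Gamma–Poisson), var = μ + 0.05 μ² |
| depth | 5 × 10⁶ (miRNA), 2 × 10⁶ (mRNA) per library | lognormal relative abundances (σ 1.2 / 1.0); planted features floored at 200 counts |
| silent baseline | 0.01 counts/library | "not found" genotype of specific-class modules |
| degradome | peak ~Poisson(100), background ~Poisson(0.02)/position | one pooled profile per genotype; no peak in a module's silent genotype |
| site mismatches | 1 | seed-distal (positions ≥ 14, never 9–11) |

Planted target sites are the reverse complement of the miRNA with the
configured mismatches, placed with ≥ 20 nt flanks; the recorded cleavage
position is the coordinate opposite miRNA position 10. Counts are NB draws
around baseline × 2^effect in the (DE genotype, NaCl, affected timepoint)
cells; genotype-specific modules get the silent baseline across the other
genotype. The silent baseline is kept small enough that, at the default
depths, stray counts stay below the expressed threshold across 24
libraries — the expressed filter makes the "not found" call, but the truth
labels stay truthful.

All randomness flows from one seed through named substreams
(sequences / counts / degradome / annotation), so a fixed seed reproduces
every output byte for byte.

**What the generator does not emulate:** adapter/quality artifacts and
sequencing error (the FASTQ emitter is minimal, for the length filter
only); isomiRs and multi-locus miRNA families; rRNA/tRNA contamination
beyond labeled decoys; correlated biological replicates or batch effects;
multi-mapping of degradome tags; transcript isoforms sharing targets;
realistic co-expression structure beyond what the planted effects induce.
Passing the recovery tests therefore shows the pipeline's rules and
plumbing are correct under the stated noise model — not that its operating
characteristics transfer to real libraries, where normalization stress,
annotation ambiguity, and dispersion heterogeneity are all harsher.

## Numerical and degenerate-input choices

Zero-variance replicate sets give NaN t-statistics → status `ns`. Zero
fold change is never called up/down regardless of p. All-zero libraries
normalize to zeros with a warning. Even-count medians use the lower middle.
Alignment ties prefer fewer gaps, then the gap closest to the site 5′ end;
cleavage-window ties prefer the canonical coordinate, then the smaller one.
Neighborhood and assignment ties break lexicographically. Module labels are
assigned in decreasing cluster-size order so detection is input-order
invariant. Scan hits are non-redundant by site start and sorted by score
then position.

## Problem sizes used in testing

The acceptance-scale run (60 miRNAs, 300 transcripts, 24 modules, 48
libraries) completes in well under a minute on one core; the type-I
calibration uses 2,000 null miRNAs at one contrast; oracle equivalence
suites use 200–500 randomized cases at lengths ≤ 12–13 where exhaustive
enumeration is cheap. These sizes were chosen to keep exhaustive oracles
exact and iteration fast while preserving every structural feature of the
full design.

## Known limitations

The hairpin check is a surrogate, not a secondary-structure prediction;
CleaveLand's degradome noise p-value is intentionally absent; the static
cut can merge adjacent co-expression modules that dynamic tree cutting
would split; Hamming-only miRNA assignment misses indel isomiRs; exact
substring annotation matching misses near matches; genome alignment,
transcript assembly, hairpin discovery from genomic context, ortholog
BLAST, and GO/KEGG enrichment are out of scope.
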