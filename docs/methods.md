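# Methods

## Problem and model

`vregions` quantifies the genus-level resolving power of 16S rRNA gene
variable regions. The object of study is a reference panel: one full-length
16S sequence per genus (for rhizobia, the 18 recognized *Alpha*- and
*Beta*-proteobacterial genera, each represented by its type species). For a
V-region bounded by a degenerate primer pair, the pipeline

1. locates both primer annealing sites on every panel sequence (in-silico
   PCR),
2. computes pairwise uncorrected identities among the primer-trimmed
   amplicons, and
3. partitions the panel at identity cut-offs, counting taxa that remain in
   singleton clusters ("uniquely distinguishable").

The model of taxonomic resolution is deliberately minimal: identity = 1 −
p-distance, no evolutionary-model correction, no tree inference. This
mirrors how OTU/ASV thresholds are actually applied in amplicon surveys and
keeps every number auditable against a hand calculation.

## Coordinates and the numbering reference

All user-facing coordinates are 1-based inclusive in *E. coli* K-12
numbering (the convention that names primers 27F, 515F, 1492R, ...);
internal coordinates are 0-based half-open. The packaged numbering
reference (`data/ecoli16s_synthetic.fasta`) is a synthetic 1542-nt
sequence, not the biological *E. coli* gene: every primer annealing window
of the packaged region table is placed at its nominal coordinate (with
degeneracies resolved reproducibly) over a random background. This fixes a
reproducible coordinate system without bundling third-party sequence data.
The placed windows reproduce the textbook amplicon spacings — V4 (515F/806R)
292 bp with primers and 253 bp trimmed; V4-V5 414 bp; V5-V7 413 bp — so
extraction arithmetic can be validated against published figures.

Consequence of the synthetic background: delineation of *real* 16S
sequences should be performed against a real numbering reference supplied
by the user (`delineate_16s(seq, ecoli_16s=...)`); against the synthetic
stand-in, real sequences share only the conserved primer sites and fail the
16S-likeness guard, by design rather than accident.

## Full-length delineation

`delineate_16s` aligns a candidate sequence to the numbering reference with
free end gaps on the reference side (so genomic flanks hang off the ends at
no cost) and firm linear internal gap costs (10 per gapped column, match
+5/mismatch −4). The returned subsequence spans the columns aligned to
reference positions 1..L, and the coordinate map records each aligned
column. Firm gap pricing matters: with cheap gap extension an optimal
alignment of *unrelated* sequence cherry-picks isolated matches and looks
~75% identical over its aligned columns. Two guards reject non-16S input:
identity over aligned columns < 0.60, or matched reference positions
< 50% of the reference length. The operation is idempotent.

## In-silico PCR

A primer code matches a template code when their IUPAC base sets intersect;
inosine ('I', present in 337R) matches everything and is legal in primers
only. The default mismatch budget is 0 (configurable to 3): exact-compatible
sites exist for all panel and study uses, and a tighter budget keeps site
choice honest. When several windows tie on mismatch count, the window whose
E. coli-mapped start lies nearest the primer's nominal position (the number
in its name) wins; a remaining tie is an error, never an arbitrary pick.
Amplicon length *with primers* runs from the first base of the forward site
to the last base of the reverse site; the analyzed ("edited") sequence
removes both windows, so trimmed length = with-primers − |fwd| − |rev|
always. One published size table violates this arithmetic by one base in a
single row; the package enforces the arithmetic.

## Identity and gap policies

`pairwise_deletion` (default) excludes, per pair, only columns gapped in
that pair; `complete_deletion` removes columns gapped in any row before any
pair is scored and therefore requires a shared multiple alignment. A pair
with zero compared sites is *missing*, never 0 or 1, and downstream
clustering treats it conservatively as "cannot distinguish", with the pair
flagged in the report. Ambiguity codes count as matches when base sets
intersect — conservative toward merging, consistent with OTU practice.
Identities can be computed either on re-aligned amplicon pairs (built-in
aligner, EDNAFULL-like scores: match +5, mismatch −4, gap open 10, extend
0.5) or on a region slice of an externally computed MSA; on gap-free
regions the two paths agree exactly (tested).

## Clustering semantics

"Merged with at least one other taxon" is a pairwise condition; its
transitive closure is single linkage, which is what `cluster_at_threshold`
computes (union-find over edges `identity ≥ cutoff − 1e−12`). For singleton
detection — the quantity reported — every linkage criterion coincides, so
the linkage choice affects only the composition of merged groups, not the
distinguishable counts. The 100% cut-off means zero observed differences
over compared sites (single-nucleotide, ASV-level resolution), not an
identity that rounds to 1.0.

## ASV assignment

Queries are scored against one region's reference amplicons by the same
identity definition. The call is the top genus when unique within
`tie_tol` (default 0: exact tie) and at or above `identity_floor` (default
0.90). Ties are reported as an alphabetically sorted ambiguity-group label
("GenusA-GenusB") — the honest output for reference sets in which two
genera share a region verbatim. No lowest-common-ancestor logic and no
external-database rescue: resolving such ties requires evidence outside
this tool's scope.

## Diversity statistics

All formula-level, on ASV-by-sample integer count tables:

- Hurlbert rarefaction via log-gamma (stable for large N); `n == N` returns
  observed richness exactly.
- Chao1 bias-corrected by default, `S_obs + F₁(F₁−1)/(2(F₂+1))`, defined
  even at F₂ = 0; the classic `S_obs + F₁²/(2F₂)` form is selectable and
  falls back to the standard `F₁(F₁−1)/2` correction at F₂ = 0.
- Shannon with natural log (base configurable); Simpson reported as
  Gini-Simpson 1 − D by default with D and 1/D selectable — surveys rarely
  state which variant they used, so all are exposed.
- Fisher's α by bracketed Brent root-finding on `S = α ln(1 + N/α)` to
  |Δ| < 1e−10. The defining function increases in α with supremum N, so
  S = N (all singletons) has no finite root: the package warns and returns
  infinity. S = 1 warns (degenerate estimate) but still solves.
- Bray-Curtis and presence/absence Jaccard; a pair of all-zero samples is
  missing, not 0.
- Rarefying subsamples each sample without replacement
  (multivariate-hypergeometric draw), deterministic under the seed.

## Synthetic data: what it emulates, and what it does not

`make_template` builds a 16S-scale template with every primer site placed
at its nominal coordinate; overlapping windows (e.g. 515F inside the 534R
window) are resolved by intersecting their base constraints, which is
guaranteed non-empty for the packaged table. `make_panel` derives taxa by
per-site substitution within selected regions' interiors; primer-site
columns are never mutated, so exact-match extraction always succeeds and
region-divergence behavior is cleanly separated from primer-failure
behavior (tests that want failing primers inject such mutations
explicitly). Between two taxa at per-site divergence d, sites differ
independently with probability 2d(1−d) + 2d²/3, giving binomial
expectations that the tests check at 3–4 standard deviations. Optional
single-base indels (default off, never inside primer sites) create the
length variation real panels show. Defaults used in the study-condition
experiments: 18 taxa, 5% gene-body divergence (typical inter-genus 16S
distance), and a near-twin pair differing by 7 substitutions confined to
the V6/V7 stretch — enough to sit between the 97% and 99% cut-offs for the
376-nt V5-V7 region (identity 369/376 ≈ 98.1%) while leaving V4-V5
identical.

Count tables: the log-series model draws, per sample,
S = round(α ln(1 + N/α)) abundances i.i.d. from a logarithmic distribution
with x = N/(N + α), so Fisher's α is recoverable from the generated sample
(within 10% at N = 5000, tested); the Dirichlet-multinomial model draws a
common mean composition once and per-sample compositions at a chosen
concentration, converging to the mean as concentration grows.

What the generator does *not* emulate: rRNA secondary-structure-constrained
evolution, chimeras, sequencing error, copy-number variation among rRNA
operons, or real phylogenetic correlation between regions. Passing tests
therefore demonstrate the correctness of the computations under known
structure, not field performance of any particular primer pair on real
communities.

## Problem sizes and numerical choices

The test suite and the acceptance script run on panels of 2–18 taxa,
regions of 250–1500 nt, and count tables of ≤ 77 ASVs × 7 samples at depths
≤ 5000 — sizes at which every quantity is recomputable in seconds while
exercising the same code paths as a full study. Cut-off comparisons use an
ε of 1e−12 on identities; alignment tie-breaking takes the aligner's first
(deterministic) traceback; all randomness flows from explicit integer
seeds.

## Known limitations

- The packaged numbering reference is synthetic; real-sequence delineation
  requires a user-supplied real reference (one alignment, seconds).
- Single linkage reports the maximal merged groups; average/complete
  linkage would split chained merges differently (singleton counts are
  identical).
- The built-in pairwise aligner is not a progressive MSA; for
  gap-heavy regions across distant taxa, an external MSA (importable as
  aligned FASTA) is the better identity substrate.
- Fisher's α assumes a log-series abundance model; its estimate on strongly
  non-log-series communities is a summary statistic, not a fit.
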