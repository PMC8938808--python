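# Methods

This note records the models, conventions and numerical choices behind
`seqlens`, and what the synthetic data does and does not establish about
real data.

## Coordinates and annotation

All internal coordinates are 0-based, half-open `[start, end)`. 1-based
inclusive coordinates exist only at the parse/print boundary: GTF input and
user query strings (`chrom:start-end`, browser convention). This makes
length arithmetic unambiguous (`length = end - start`) at the cost of a
single conversion at each boundary, which is where such bugs are easiest to
test.

A gene model is the union of all its transcripts' exons; transcript-level
(isoform) quantification is out of scope. The exon union is computed by a
sort-and-merge over intervals (adjacent intervals merge), and its total
length is the gene length used by RPKM. Symbol lookups return *all* genes
sharing the symbol, position-sorted, because silently picking one of several
homonymous loci is worse than surfacing the ambiguity.

## Coverage

BAM depth counts primary, QC-pass, non-duplicate alignments. CIGAR
semantics: `M/=/X` and `D` consume reference and count as covered (a read
with a small deletion still covers the locus); `N` consumes reference
uncovered (a spliced read must not paint its intron); `I/S/H/P` consume no
reference. Depth is accumulated with a difference array, and the same
`aligned_blocks` routine drives both coverage and read counting so the two
cannot drift apart.

BigWig tracks are taken as pre-normalized per-million signal; BAM-derived
depth is scaled by `10^6 / library_size` before cross-sample averaging so
conditions of different sequencing depth are comparable. Library size is
the number of primary, QC-pass, non-duplicate mapped records — the same
filter as the depth computation — computed from the BAM and cached when the
manifest does not state it.

Binning splits a region into `n_bins` near-equal spans; when `n_bins` does
not divide the length the remainder bases go to the leftmost bins (a fixed,
documented tie-break). Bin value is the mean of member bases, so a profile
whose bins divide the region conserves the region mean exactly. For `-`
strand regions the binned vector is reversed on request so index 0 is
always the 5′ end. The default bin count for gene profiles is 200 with no
smoothing; both are configurable, neither affects any other computation.
The condition band is the per-bin across-replicate SD (default) or SE; with
one replicate it is zero by definition, not an error.

## Counting and abundance scales

The counting contract: a read (or fragment, with `count_fragments`)
qualifies if it is primary, QC-pass, mapping quality ≥ 10 (configurable),
and not a duplicate (configurable); it counts for a feature iff its aligned
reference bases overlap the feature's intervals by ≥ `min_overlap_bp`
(default 1), at most once per feature regardless of how many exons it
touches. A read overlapping two genes counts for both — no ambiguity
resolution, since with union counting any other choice silently couples
neighboring genes' counts. Abutting half-open intervals share no base and
never count.

Size factors follow the median-of-ratios scheme: per feature the geometric
mean across samples; per sample the median over features (with positive
geometric mean) of `count / geomean`. Custom regions are normalized with
*gene-derived* factors and appended without influencing them — a handful of
user regions cannot support a median-of-ratios of their own.

RPKM uses the exon-union length for genes and the span for plain regions.
All log scales use `log2(x + 1)` by default; the pseudocount is a parameter
everywhere it appears.

Flags (`LOW_COUNT`: max count across samples < 10; `SHORT`: length
< 200 bp; `ZERO_IN_ALL`) annotate features for downstream, user-driven
filtering; nothing is ever removed from a table. The vocabulary is a
minimal, documented set; thresholds are parameters.

## Differential expression

Only the contrasted conditions' samples enter the pipeline (counts →
median-of-ratios normalization → tests → combination → BH). Both contrasted
conditions need ≥ 2 replicates.

**Dispersion.** The negative-binomial variance is `μ + φμ²` with one common
φ. Per gene, within-condition variances are pooled
(`ddof = Σ(n_c − 1)`) and the moment estimate is
`φ_g = max(0, (var − mean)/mean²)`; the common φ is the median of φ_g over
expressed genes. The raw median is biased down in small designs: the pooled
sample variance is approximately `true_var · χ²_d / d`, and the median of
`χ²_d/d` is below 1 (≈ 0.84 at d = 4), so the median over genes solves
`φ_med ≈ m_d φ + (m_d − 1)/μ` with `m_d = median(χ²_d)/d`. We invert this
analytically. In triplicate designs at φ = 0.1 the uncorrected estimate is
≈ 0.078 and leaves the Wald test anticonservative (null p < 0.05 rate up to
0.082); the corrected estimate is ≈ 0.095–0.098 and the rate ≈ 0.05. When
the raw median is exactly 0 (e.g. constant counts) no correction is
applied: zero means zero.

**NB Wald test.** Statistic `(log m_B − log m_A) / se` with the
delta-method variance `Σ (m + φm²)/(n m²)`, against a standard normal.
Genes with both group means zero get p = 1 by convention; genes with
exactly one zero mean fall back to the natural-scale statistic (the
log-scale one is undefined at zero). The test is symmetric in the contrast:
swapping A and B negates the statistic and log2FC and preserves p exactly.
Against a seeded parametric-bootstrap null at mean ≈ 100, 3v3, the Wald p
agrees within ≈ 0.02 absolute — the usual quality of the normal
approximation at these counts, and the tolerance the bootstrap test uses.

**Welch test.** Welch's two-sample t on `log2(normalized + 1)`. Degenerate
genes (zero variance in both groups) get p = 1 when the means are equal and
the smallest positive p otherwise, logged. At 3v3 on NB counts this test is
mildly conservative (null rate ≈ 0.035), which is inherent to a t-test on
log counts at this sample size.

**Combination.** Fisher (`−2Σ ln p` vs χ² with 2k df), Simes
(`min_i k·p_(i)/i`), min, max, and a user-weighted convex combination
`Σ w_i p_i` (weights non-negative, summing to 1 — a simple, transparent
stand-in for simulation-trained weighting schemes, which are out of scope).
**Simes is the default**: the two tests are computed from the same counts
and are strongly positively dependent, and Fisher's independence assumption
then inflates the joint null rate (measured ≈ 0.08 at nominal 0.05, pushing
the BH false-discovery proportion to ≈ 0.09–0.13), while Simes remains
valid under positive dependence (measured joint null rate ≈ 0.04, FDP
≤ 0.05 with sensitivity ≥ 0.95 in the recovery simulations). A single
selected test bypasses combination. p = 0 inputs are clamped to the
smallest positive float with a warning.

**FDR.** Benjamini–Hochberg step-up (via statsmodels), order restored to
the input. Fold change is `log2((m_B + 1)/(m_A + 1))` on normalized means;
the A coordinate is `log2(grand mean + 1)`.

## Analytics

Correlation uses pandas (`pearson`, `spearman`, `kendall` = tie-corrected
τ-b). Constant vectors give undefined entries reported as NaN and logged;
the diagonal is exactly 1 for non-constant vectors. The returned row order
is the average-linkage leaf order on `1 − r` so heatmaps arrive
pre-sorted.

Clustering is scipy agglomerative linkage (`single/complete/average/ward`)
on `euclidean`, `manhattan` or `1 − pearson` distances, or on a precomputed
matrix. Ward requires euclidean coordinates and is rejected otherwise
(ward.D2 contract). Leaf order and tie-breaks follow scipy's deterministic
input-index convention. Dendrograms export as Newick with branch lengths
derived from merge heights.

PCA treats samples as observations over feature dimensions (the sample-QC
orientation; transpose explicitly for gene-axis PCA) and is computed by SVD
after optional centering (default on) and standardization (default off;
zero-variance features are dropped with a warning when scaling). Component
signs are fixed by making each component's largest-magnitude loading
positive. Explained fractions are `s_i²/Σs²` over all computed components,
summing to 1 by construction.

Classical MDS double-centers the squared distance matrix
(`B = −½ J D² J`), eigendecomposes, and scales eigenvectors by √λ.
Asymmetry beyond 1e−9 or a nonzero diagonal is an error; negative
eigenvalues (non-euclidean input) are truncated to zero with a warning. On
euclidean distances of centered data this reproduces PCA scores up to sign,
which the tests verify via Procrustes residual; an independent cross-check
against scikit-bio's PCoA is also part of the suite.

## Synthetic data: what it emulates, what it does not

The generator draws per-gene counts `K_gc ~ NB(μ_gc, φ)` with
`μ_gc = baseline · 2^(lfc_g · [c ≠ reference])`, a DE subset of known signs
and magnitude, then *realizes* each count as that many reads placed
uniformly over the gene's exon union (fully exonic, single-`M` CIGAR,
MAPQ 60), writes sorted+indexed BAMs, per-million BigWig tracks computed
from the same placements, a GTF, a manifest and truth tables. Genes and
novel regions occupy disjoint slots, so counting the BAMs recovers the
drawn matrix *exactly* — the repository's master integration test — and
the BigWig equals the scaled BAM depth to float32 precision (relative
error < 1e−7; BigWig stores 32-bit floats, so agreement is asserted
relatively, not absolutely).

Defaults: 2 contigs × 100 kb, 20 genes of 1–3 exons on random strands, two
conditions × 3 replicates, baseline mean 100, φ = 0.1, 10% DE at
|log2FC| = 2, 50 bp reads, plus 2 unannotated single-exon "novel" regions
(mean 80) that receive reads but no GTF entry — the candidate-lincRNA use
case. These are ordinary values for a small pilot bulk RNA-Seq comparison:
φ = 0.1 is a typical biological coefficient of variation (~0.32), and
triplicates are the ubiquitous minimal design. Calibration and recovery
simulations use 2000 genes with the same 3v3/φ = 0.1 conditions, a size at
which a binomial fluctuation on an empirical rate is ±0.5% and the run
stays in seconds.

Deliberately not emulated: sequencing error, base qualities and sequence
content (placeholder bases), spliced and paired-end reads in the *default*
dataset (both are exercised by dedicated hand-built fixtures), multi-mapped
reads, GC/length biases, gene-gene correlation, and per-gene dispersion
variation. Consequently, passing tests demonstrate the correctness of the
arithmetic and the calibration of the tests under the stated model — not
robustness to mapping artifacts or dispersion outliers in real libraries;
on real data the common-φ assumption is the main simplification, and genes
with unusually high dispersion will be anticonservative relative to a
per-gene-dispersion method.

## Degenerate inputs and numeric conventions

- Regions must satisfy `0 ≤ start < end`; empty regions are unrepresentable.
- Counting a region on a contig absent from a BAM warns and returns 0;
  coverage extraction on an absent contig is an error (a profile of
  undefined length is not meaningful).
- `p`-values are clamped to `(tiny, 1]` before logs and combination.
- Size factors require at least one feature with all-positive counts;
  otherwise the error suggests quantifying more features.
- All tolerances in tests are stated where used: exact equality for
  integer counting, 1e−9 for closed-form arithmetic, 1e−6 relative for
  float32 round-trips.

## Reported quantities

`scripts/acceptance.py --seed S --out f.json` recomputes, at run time, with
every random stream derived from `S`: the counting-oracle agreement over
100 random regions (%), the max absolute error between counted and
generated matrices, the max relative BigWig/BAM discrepancy, the per-test
null p < 0.05 rates (%), the recovered dispersion at true φ = 0.1, the
false-discovery proportion and sensitivity at q ≤ 0.05 under 10% DE, the
PCA explained-fraction sum, the MDS↔PCA Procrustes residual, and the exit
code of a full CLI pipeline run. The note states no number that script and
test suite do not themselves compute.
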