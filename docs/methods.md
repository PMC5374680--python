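# Methods

## The problem

Most genome-wide association study (GWAS) risk variants for common cancers
fall outside coding sequence, and a recurring observation is that they
concentrate in tissue-specific regulatory elements. This package implements
an end-to-end procedure for asking that question quantitatively: given
(i) called peak intervals for enhancer-associated chromatin features —
H3K27Ac, the epigenetic reader BRD4, Mediator subunits (MED1/MED12),
lineage transcription factors (AR, ER), DNase hypersensitive sites — and
(ii) GWAS summary statistics (per-SNP p-values and minor allele
frequencies), decide whether genome-wide-significant risk SNPs are
over-represented inside rule-defined (super-)enhancer compendia, and guard
that conclusion against the two standard confounders: linkage
disequilibrium (LD) and the allele-frequency/LD profile of
enhancer-resident SNPs.

## Enhancer compendia (module `intervals`)

All interval algebra is 0-based half-open (BED convention). Three
primitives compose every recipe:

- `merge_within_gap(s, g)` — unite same-chromosome intervals whose gap is
  *strictly* less than `g` (default 100 bp; "closer than" is read as a
  strict inequality). Overlapping or abutting intervals always merge.
- `filter_by_length(s, lo, hi)` — keep stretches *strictly* longer than
  `lo` (2,000 bp for the generic stitched definition; 3,000 bp with an
  upper bound of 200 kb for the extended definition) and at most `hi` when
  bounded.
- `intersect_filter(stretches, marks, k)` — keep a stretch when it shares
  at least `k` bases (default 1) with the normalized mark set. The stretch
  is kept whole: the stretch, not a clipped fragment, is the analysis unit
  in super-enhancer practice. Shared bases are counted per base against the
  mark union, so two adjacent binding sites can jointly satisfy a larger
  `k`. A literal base-wise intersection (`intersect_clip`) is available for
  sensitivity analysis.

`build_compendium` wires these into named recipes: stitched H3K27Ac
stretches (optionally intersected with each of a list of binding marks,
the Hnisz-style generic recipe used for MCF7/H2171/Schwann-type compendia),
the extended 3 kb–200 kb definitions, BRD4 sites alone, and a
prostate-cancer consensus (LNCaP H3K27Ac+MED12 intervals that also overlap
both a VCaP H3K27Ac stretch and a VCaP BRD4 site). Every compendium records
its recipe id, parameters, and source marks, and identical inputs always
produce byte-identical BED output.

Boundary behaviour is parameterized because the verbal definitions do not
fix it: the defaults are strict lower bounds and an inclusive upper bound
(length in (2000, ∞) or (3000, 200000]).

## SNP annotation (module `gwas`)

Summary-statistic positions are 1-based; BED intervals are 0-based
half-open. The conversion lives in exactly one predicate: a SNP at 1-based
position p is inside [start, end) iff start ≤ p−1 < end. Chromosome
dialects ("1" vs "chr1") are canonicalized before overlap; unplaced or HLA
contig names pass through verbatim. Rows with p outside (0,1] are dropped
with a logged count; p of exactly 0 is floored to 1e-300 with a warning.
SNPs without MAF are kept for enrichment but excluded from MAF matching.
Annotation is a per-chromosome `searchsorted` sweep over normalized
intervals; membership is invariant under interval normalization.

## Enrichment (module `enrichment`)

**Stratified Q-Q.** For a stratum of n p-values, the j-th plotted point
pairs the j-th smallest expected quantile with the j-th smallest observed
−log10 p. Expected quantiles use the Weibull plotting position i/(n+1)
(options: i/n, (i−0.5)/n), which keeps the extreme rank finite. Under the
null the curve follows the identity line; an upward deflection means an
excess of small p-values in the stratum.

Order-statistic noise sets what "follows the identity line" can mean in
−log10 units: at rank m from the low-p tail, sd(−log10 p(m)) ≈
1/(√m·ln 10), i.e. ≈0.06 at m = 50 and ≈0.03 at m = 200. A 0.1 tolerance
band is therefore only meaningful once ~2% of ranks are trimmed per side at
n = 10⁴; the null-line tests use the central 96% of ranks. (Over the
central 99% the same band holds in only ~80% of seeds — the band would be
testing tail noise, not calibration.)

**Over-representation.** A SNP is genome-wide significant iff
−log10 p > 7.3, strictly (p < ~5.01e-8). For an annotation with n_in member
SNPs, k of them significant, in a universe of N SNPs with K significant,
the one-sided upper-tail hypergeometric p is P[X ≥ k] for
X ~ Hypergeom(N, K, n_in), computed with `scipy.stats.hypergeom.sf`
(validated exhaustively against exact rational enumeration for all tables
with N ≤ 60). The odds ratio is the unconditional sample OR with a
Haldane–Anscombe 0.5 correction when a cell is zero; saturated tables
report an unbounded OR. Bonferroni adjustment multiplies by the number of
annotations tested, capped at 1. The universe is either the whole panel or,
with `background=controls`, the annotation members plus a matched control
set.

## Random LD pruning (module `pruning`)

LD blocks are the connected components of the graph joining same-chromosome
SNP pairs closer than 1 Mb with r² ≥ 0.2. Transitive chaining guarantees
that no retained pair inside a block violates the threshold; consequently a
chained block can span more than 1 Mb (the distance rule is edge-level).
A greedy left-to-right clumping mode that also caps each block's span at
the window is provided for comparison. r² comes either from a genotype
dosage matrix (squared Pearson correlation; monomorphic SNPs get r² = 0
against every partner) or from a precomputed sparse pair table.

Pruning draws one uniformly-chosen representative per block; the
draw-then-test procedure runs `n_iter` (default 100) times and the
downstream statistic is averaged. Child seeds derive from the master seed
by a counter-based spawn, so any single iteration is reproducible in
isolation. Failed iterations are recorded as missing and excluded from the
mean; more than 50% failures is a hard error. Identical iteration values
report exactly zero spread.

## Matched controls (module `matching`)

"Numerically matched on MAF and mutual LD r²" is operationalized as joint
binning on (MAF, LD-partner count), where the LD-partner count — the number
of same-chromosome partners within 1 Mb at r² ≥ 0.2 — is an LD-score-like
scalar proxy; matching the full pairwise r² structure is underdetermined.
Bin edges default to MAF deciles and LD-count quartiles of the case set.
For each case SNP, `n_controls_per_case` non-member SNPs are drawn
uniformly without replacement from the same joint bin; a dry bin falls back
to the nearest neighbouring bin (logged and counted); with-replacement
sampling is available for thin pools. Controls are always disjoint from
cases, and the draw is deterministic given the seed.

## Synthetic data (module `synthetic`)

The generator emulates the statistical structure the analyses assume,
without attempting realistic human LD maps, recombination hotspots, or
reference allele-frequency spectra:

- **Panel**: SNP positions uniform per chromosome; LD blocks are
  consecutive runs of geometric mean size (default 5, capped at 25); all
  SNPs in a block share the block's MAF, drawn Uniform(0.01, 0.5) per
  block (so the marginal MAF distribution across SNPs is uniform).
- **Genotypes**: each haplotype copies a shared latent block allele with
  probability `within_block_r2 ** 0.25`, giving expected dosage correlation
  √r² within a block and hence expected pairwise r² ≈ the target (default
  0.8); blocks are independent. Defaults: 500 samples, 20,000 SNPs on
  2 × 10 Mb.
- **Marks**: 40 H3K27Ac clusters (20 "true", 20 decoy) placed on an even
  grid with random offsets; each cluster is 4–7 peaks of 500–1000 bp
  separated by 20–90 bp gaps, so clusters always stitch into one stretch
  longer than 2 kb. True clusters additionally carry 1–3 BRD4 and 1–2
  MED12 sub-peaks; decoys carry none. Hence the stitched-H3K27Ac recipe
  returns all clusters and the BRD4-intersected recipe exactly the true
  ones.
- **P-values**: null SNPs draw p ~ Uniform(0,1); causal SNPs draw
  z ~ Normal(μ, 1) with μ set so the median −log10 p is the uniform-null
  mean (log10 e ≈ 0.434) plus `effect_neglog10_mean` (default 10, μ ≈ 6.8),
  and take the two-sided normal tail. Non-causal block-mates inherit
  z' = √r²·z + √(1−r²)·ε, so tag SNPs show attenuated signal and pruning
  has something real to do.
- **Placement**: `enhancer` (each true-enhancer SNP causal with probability
  0.3 — the enriched alternative), `uniform` (the same number of causal
  SNPs placed uniformly), `uniform_block` (causal *blocks* placed
  uniformly, one causal SNP each), or `none`.

Everything is deterministic under the config seed (independent child
streams for panel, marks, causal draw, and p-values), and generated BED /
summary-statistic files round-trip through the interval and GWAS readers
unchanged.

What passing tests on this generator do **not** show: behaviour under real
human LD (long-range, variable-strength), population stratification,
array ascertainment, or genome-build mismatches. The generator's blocks are
clean and rectangular by construction; the pruning and matching machinery
is validated for its logic, not for robustness to messy empirical LD.

## Designed experiments (module `experiments`)

**Null calibration.** The enrichment test's type-I error is measured under
the null in which genome-wide-significant SNPs exist but are independent of
annotation membership. Two design choices matter and are deliberate:

1. *Block-level exchangeability*: the exact conditional test is valid when,
   given the margins, every assignment of significance to blocks is equally
   likely. Two things can break that. (a) With SNP-level uniform placement,
   large LD blocks are more likely to contain a causal SNP, so per-block
   significance probability is heterogeneous; conditional on the 2×2
   margins the overlap count is underdispersed relative to the
   hypergeometric and the exact test turns conservative (empirically ~0.015
   at nominal 0.05). Hence causal *blocks* are placed uniformly
   (`uniform_block`). (b) Even then, the pruned representative of a causal
   block crosses the threshold with different probability depending on
   whether it is the causal SNP or an r²-attenuated tag SNP; since larger
   blocks are likelier represented by a tag, a moderate effect re-introduces
   heterogeneity (measured rejection ~0.038). The calibration effect is
   therefore set so both probabilities are ≈1 (`effect_neglog10_mean = 24`,
   z-mean ≈ 10.3). A frozen-panel permutation check confirms the conditional
   z-scores then have unit variance.
2. *Scale*: an exact discrete test can only attain levels just below the
   nominal one when counts are large. The calibration panels (10,000 SNPs,
   ~3,300 blocks, ~10% of SNPs annotated, 800 causal blocks) give E[k] ≈ 70
   significant members, where the mean attainable level is ≈0.043–0.047. At
   small counts the experiment would measure the attainable level of a
   discrete test, not its calibration.

Each of 1000 replicates simulates a fresh panel, builds the
stitched-H3K27Ac annotation, prunes once, and tests at −log10 p > 7.3
against both the whole pruned panel and a 4:1 MAF/LD-matched control
background. Measured rates fall within 3 binomial standard errors of 0.05
for both backgrounds.

**Ordering (power).** With signal injected only into BRD4-positive clusters
(the default generator conditions), the BRD4-intersected compendium attains
a strictly smaller hypergeometric p than stitched H3K27Ac alone — the
qualitative signature that BRD4 intersection sharpens enrichment — in
effectively every seed (≥95% required, 100% observed over 100 seeds).

**Recovery.** With 10 true and 10 decoy clusters, the stitched + BRD4
recipe returns exactly the true clusters in every seed.

## Numerical and degenerate-input choices

- Empty annotation (n_in = 0): result flagged degenerate, p = 1.
- k = n_in = K = N: p = 1, odds ratio reported unbounded.
- Upper-tail p computed as `sf(k−1)` so the tail includes k itself; k = 0
  gives exactly 1.
- p-values of exactly 0 on input floored to 1e-300; simulated p clipped to
  the same floor.
- Ties in quantile-derived bin edges are collapsed so edges stay strictly
  increasing; values outside the edge range clamp to the end bins.
- Problem sizes in tests and in the acceptance script (panel sizes,
  replicate counts, prune iterations) are the package's standard desk
  scales: a full default-study pipeline runs in seconds and the complete
  validation suite in a few minutes on one CPU.

## Known limitations

- The matched-control construction matches an LD *summary* (partner
  count), not pairwise r² structure.
- Chained LD blocks may exceed the 1 Mb window (edge-level rule); the
  greedy mode bounds the span but can split genuine blocks.
- The pipeline assumes all inputs share one genome build; no liftover is
  performed.
- XLS supplementary interval lists are not parsed; inputs are BED/TSV.
- The hypergeometric test treats pruned SNPs as independent; residual
  within-window dependence beyond r² < 0.2 is ignored, as in the procedure
  it implements.
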