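# snpenrich

Tissue-specific enrichment of GWAS risk SNPs within BRD4 / Mediator /
H3K27Ac-defined (super-)enhancers.

Most cancer risk variants found by genome-wide association studies (GWAS)
are non-coding, and the working hypothesis in regulatory genomics is that
they act through tissue-specific enhancers. `snpenrich` is for statistical
geneticists and regulatory-genomics analysts who have (a) called peak
intervals (BED) for enhancer-associated features — H3K27Ac, BRD4, MED1/12,
AR/ER, DHS — and (b) GWAS summary statistics (SNP, position, p-value, MAF),
and want to test whether genome-wide-significant risk SNPs concentrate
inside rule-defined enhancer compendia, robustly to linkage disequilibrium
(LD) and allele-frequency confounding.

## What it computes

**Enhancer compendia.** Peaks are stitched (merge gaps < 100 bp), length
filtered (keep stretches > 2 kb, or 3 kb–200 kb for the extended
definition), and optionally required to contain binding sites of a second
mark (e.g. BRD4). Named recipes cover stitched-H3K27Ac, H3K27Ac ∩ BRD4,
H3K27Ac ∩ MED12, BRD4 alone, and a multi-cell-line consensus.

**Stratified Q-Q curves.** For SNP stratum s of size n, the curve plots the
ordered observed −log10 p against expected quantiles −log10(i/(n+1)),
i = 1…n. Under no association the curve follows the identity line; upward
deflection of an annotation's stratum relative to the all-SNP baseline
indicates enrichment of small p-values.

**Over-representation test.** With N SNPs of which K are genome-wide
significant (−log10 p > 7.3, strictly), and an annotation containing n_in
SNPs of which k are significant, the one-sided p-value is the upper
hypergeometric tail

    p = Σ_{x=k}^{min(K, n_in)} C(K, x) · C(N−K, n_in−x) / C(N, n_in),

Bonferroni-adjusted over the number of annotations tested. The universe is
either the whole panel or a control set matched to the annotation SNPs on
MAF and LD-partner count.

**LD pruning.** Blocks are connected components of the graph joining SNP
pairs < 1 Mb apart with r² ≥ 0.2; one random representative per block is
kept, the test re-run, and the statistic averaged over 100 draws.

A seeded synthetic-data generator (LD-block-structured panels, genotype
dosages, peak clusters with BRD4-positive "true" enhancers and decoys,
configurable signal placement) makes the whole pipeline testable without
external downloads.

## Worked example

```python
from snpenrich import (SimConfig, simulate_study, build_compendium,
                       annotate, fisher_enrichment, bonferroni)
from snpenrich.enrichment import fisher_table

study = simulate_study(SimConfig(seed=1))      # 20,000 SNPs, 2 x 10 Mb
comps = [
    build_compendium("HNISZ_generic", study.marks, name="H3K27Ac_stretch"),
    build_compendium("HNISZ_generic", study.marks,
                     binding_marks=["BRD4"], name="H3K27Ac_BRD4"),
]
results = bonferroni([
    fisher_enrichment(study.panel, annotate(study.panel, c)) for c in comps
])
print(fisher_table(results).to_string(index=False))
```

```
     annotation  background     N   K  n_in  k  odds_ratio       p_hyper  p_bonferroni  degenerate
H3K27Ac_stretch whole_panel 20000 125   180 60  151.961538  5.304794e-92  1.060959e-91       False
   H3K27Ac_BRD4 whole_panel 20000 125    98 60  481.870445 4.147102e-113 8.294204e-113       False
```

Reading the table: of 20,000 SNPs, 125 are genome-wide significant (K).
The stitched-H3K27Ac compendium contains 180 SNPs (n_in), the
BRD4-intersected one 98 — and both contain the same 60 significant SNPs
(k), because the simulated signal sits only in BRD4-positive clusters. The
BRD4-intersected compendium is therefore the sharper annotation: the same
hits in a smaller denominator give a larger odds ratio (482 vs 152) and a
smaller hypergeometric p (1e-113 vs 5e-92). That ordering — intersecting
stitched H3K27Ac with BRD4 concentrates the risk signal — is the package's
headline qualitative behaviour.

The same pipeline is scriptable from the shell:

```sh
snpenrich simulate --seed 1 --out study/
snpenrich run-all --study study/ --seed 1 --out run/
# run/: *.bed compendia, annotated_panel.tsv, counts.tsv, qq.tsv + qq.png,
#        fisher.tsv, fisher_pruned.tsv, manifest.json
```

Real data enters through the same doors: BED peak files per mark
(`define-enhancers`), a summary-statistics TSV (`annotate`), and either a
genotype dosage table or a sparse r² pair table for the LD-aware stages
(`prune`, `match-controls`).

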