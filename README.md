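# esnpipe

An integrative-genomics pipeline that connects GWAS summary statistics to
biological processes through eQTL-defined eSNP sets, and then to candidate
regulator genes through directed gene networks:

1. **gwas_meta** — per-study QC (MAF ≥ 1%, HWE p ≥ 1e-4, imputation
   quality ≥ 50%, call rate ≥ 75%, per-stage presence counts) and staged
   inverse-variance meta-analysis (Stage 1, Stage 2, combined Stage 1+2),
   switching to DerSimonian–Laird random effects when Cochran's Q
   heterogeneity p < 1e-4.
2. **esnp_catalog** — rank-scales expression-association p-values within
   each eQTL study, pools studies, greedily LD-prunes eSNPs (r² < 0.7,
   keeping the strongest expression association per LD clump) into
   tissue-specific backgrounds, and maps gene sets to eSNP sets.
3. **ssea** — SNP-set enrichment analysis: each gene set's eSNPs are
   tested against the tissue background with a one-sided K-S test on GWAS
   p-value rank fractions and a one-sided Fisher test on membership in the
   top 5% of GWAS signals; score = mean(−log10 p_KS, −log10 p_Fisher).
   FDR is estimated by permuting the p-value assignment over the background
   (1000 permutations by default); a set is significant when FDR < 20% in
   both independent stages and FDR < 5% combined.
4. **supersets** — merges significantly overlapping significant sets
   (overlap ratio r = √(r_AB·r_BA) with a Bonferroni-corrected Fisher
   gate, connected-component clustering) and trims each merged superset to
   its most-shared 200-gene core, iterating until pairwise overlap < 20%;
   supersets are annotated against reference categories or left "Unknown".
5. **kda** — key-driver analysis on directed gene networks: genes whose
   neighborhoods are Bonferroni-significantly enriched for a superset are
   drivers; cross-network ranking uses (N − 0.99) × mean(−log10 p). Also
   provides the neighbor-pool enrichment statistic for perturbation
   validation (observed/expected fold + Fisher p).
6. **synthetic_data** — generates every input with planted ground truth
   (causal gene sets with Beta(a, 1) GWAS p-values on their eSNPs,
   block-structured LD, overlapping gene sets, DAG networks with planted
   hub drivers) so the full pipeline is testable end to end.

## CLI

Every stage is exposed as a subcommand of `esnpipe`:

```bash
esnpipe simulate --out sim/ --seed 1 --networks 2
esnpipe meta --studies sim/gwas --stage-map sim/stage_map.tsv --out meta/
esnpipe map-esnps --eqtl sim/eqtl.tsv --ld sim/ld.tsv \
    --gmt sim/gene_sets.gmt --tissue all --out esnps/
esnpipe ssea --gmt sim/gene_sets.gmt --eqtl sim/eqtl.tsv --ld sim/ld.tsv \
    --meta meta/ --tissue all --nperm 1000 --seed 1 --out ssea.tsv
esnpipe merge --gmt significant.gmt --universe 20000 --out supersets/
esnpipe kda --networks sim/networks --gmt supersets/supersets.gmt --out kda/
esnpipe kda-enrich --networks sim/networks --seeds seeds.txt \
    --query query.txt --universe 21880 --depth 2
```

All formats are plain text: GWAS/eQTL/LD/edge-list TSVs, GMT gene sets,
JSON ground truth (see `esnpipe.io`).

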