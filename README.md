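# oppeqtl

Tissue-specific **opposite eQTL effects**: detection and biological
characterization of cis-eQTL signals whose direction of effect on the same
gene reverses between tissues, from per-tissue summary statistics.

A cis-eQTL is a variant associated with a nearby gene's expression; its
signed slope β (per alt allele) defines the effect direction. Most eQTLs
act in the same direction wherever they are active, but a biologically
interesting minority *flips sign* between tissues — a signature of
genuinely different gene regulation, and a useful annotation for
interpreting GWAS loci. Detecting the flip honestly requires comparing the
*primary* signals of the two tissues with linkage disequilibrium (LD) taken
into account: two tissues whose top SNPs sit in different LD blocks are not
evidence of reversed regulation, just of independent signals.

`oppeqtl` is for statistical geneticists who have per-tissue significant
variant–gene association tables (the `signif_variant_gene_pairs` TSV
dialect), a phased reference haplotype panel (VCF), a GWAS-catalog
association table and a per-SNP epigenetic annotation matrix — or who want
to study the method itself on fully synthetic cohorts with planted ground
truth, which the package generates.

## The procedure

For each gene and each unordered tissue pair (x, y), let SNP-x be the gene's
**top-eQTL-SNP** in tissue x (smallest nominal p; exact ties broken by
byte-wise rsID order) and β_ij the effect of SNP-i on the gene in tissue j,
with β_ij = 0 encoding "not significant in tissue j". A 2×2 analysis table
(β_xx, β_xy, β_yx, β_yy) is **eligible** when SNP-x = SNP-y, or at least one
of them is significant in both tissues. The direction is

    opposite  ⇔  β_xx · β_xy ≤ 0  and  β_yx · β_yy ≤ 0

and, with r² the LD between SNP-x and SNP-y over the reference panel
(r² = 1 when identical), the table falls in one of four groups:

|            | r² > 0.8 | r² ≤ 0.8 |
|------------|----------|----------|
| opposite   | **1a**   | 1b       |
| same       | **2a**   | 2b       |

Genes/SNPs appearing in any 1a∪2a table are the **multi-eQTL** sets (shared
primary signal); those in any 1a table are the **opp-multi-eQTL** sets
(shared primary signal with reversed direction). Downstream analyses:
per-tissue counts and ratios, a tissue × tissue opposite-β-fraction matrix
with hierarchical clustering, TSS-proximity enrichment (sample kurtosis of
TSS distances against a sharing-count-matched resampling null),
epigenetic-mark enrichment and GWAS-catalog LD overlap (both against a
TSS-distance-matched resampling null, plus Fisher's exact test), and
allele-harmonized locus views.

## Worked example

```python
from oppeqtl import synthetic_data, eqtl_io, pair_classifier, tss_enrichment

cohort = synthetic_data.simulate_cohort(synthetic_data.SimConfig(seed=1))
top = eqtl_io.extract_top_eqtl(cohort.tables.values())
analysis = pair_classifier.classify_tables(top, cohort.tables.values(),
                                           cohort.panel)
desig = pair_classifier.aggregate_designations(analysis, top)
print(desig.summary())

samples = tss_enrichment.distance_samples(cohort.tables.values(), top, desig)
result = tss_enrichment.tss_enrichment_pvalue(samples["opp"], samples["multi"],
                                              n_rep=10_000, seed=2)
print(f"opp kurtosis = {result.observed:.2f}, "
      f"null mean = {result.replicate_mean:.2f}, {result}")

planted = cohort.truth.opposite_genes()
print(f"planted opposite genes recovered: "
      f"{len(planted & desig.opp_genes)}/{len(planted)}")
```

prints

```
{'n_eqtl_genes': 200, 'n_top_eqtl_snps': 151, 'n_multi_genes': 129,
 'n_multi_snps': 110, 'n_opp_genes': 16, 'n_opp_snps': 16,
 'n_multi_pairs': 129, 'n_opp_pairs': 16}
opp kurtosis = 13.28, null mean = 4.52, p = 0.0008 (10000 replicates)
planted opposite genes recovered: 16/16
```

Reading: of 200 genes with an eQTL in the synthetic cohort, 129 share their
primary signal between at least one tissue pair (multi), and 16 of those
reverse direction (opp) — every one of them a planted reversal, with none
of the concordant genes miscalled. The opp SNPs' TSS-distance distribution
is sharply more peaked (kurtosis 13.3) than sharing-matched draws from the
multi SNPs (null mean 4.5), the planted TSS enrichment.

The same flow is available as a CLI for file-based work:

```
oppeqtl simulate --seed 7 --out sim/
oppeqtl filter   --eqtl-dir sim --panel sim/panel.vcf --out filtered/
oppeqtl top      --eqtl-dir filtered --out top.tsv
oppeqtl classify --top top.tsv --eqtl-dir filtered --panel sim/panel.vcf --out out/
oppeqtl tissue-stats / tss-enrich / epi-enrich / gwas-ld / locus ...
```

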