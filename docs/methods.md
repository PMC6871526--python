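# Methods

## The detection procedure and its assumptions

The pipeline consumes *summary statistics only*: per-tissue tables of
significant variant–gene associations (signed slope β, nominal p, signed
TSS distance), never genotypes or expression. Significance is extensional —
a (gene, SNP, tissue) triple is significant iff it appears in that tissue's
file — so the upstream study's multiple-testing machinery is inherited, not
re-derived. Coordinates are 1-based GRCh37; TSS distances are taken
verbatim from the input and never recomputed, so no gene model is needed.

For each gene and unordered tissue pair, the top-eQTL-SNPs of the two
tissues anchor a 2×2 β table. β = 0 encodes "not significant", which is why
the loader rejects rows whose stored slope is exactly 0.0: real slope
estimates are never exactly zero, and permitting them would make the
encoding ambiguous. The opposite-direction rule β_xx·β_xy ≤ 0 ∧
β_yx·β_yy ≤ 0 deliberately lets a zero cross-term count toward
"opposite": if SNP-x is not significant in tissue y, its product
contributes no contrary evidence, and the call rests on the other product
plus the eligibility condition (identical SNPs, or ≥1 of the two SNPs
significant in both tissues).

Top-SNP ties at identical p are broken by plain byte-wise string order of
the rsID ("rs10" < "rs2" < "rs7"). Numeric rs-number order would be the
other defensible reading; byte-wise order is what a naive sort of ID
strings produces and is applied consistently everywhere, so the choice
only affects which member of a perfect-LD tie is reported, never the
group assignment.

## LD

r² is computed from phased haplotypes by direct frequency counting:
r² = (p_AB − p_A·p_B)² / (p_A(1−p_A)p_B(1−p_B)), identical to the squared
Pearson correlation of the two 0/1 haplotype vectors (a property tests
verify to 1e-12). No EM estimation is attempted — the reference panel is
phased by construction. A pair involving a monomorphic site has undefined
r², mapped to "not in LD" in every caller, mirroring how standard tools
omit such pairs. The r² > 0.8 threshold is strict, and a SNP queried
against itself is r² = 1 by definition. LD partner scans are restricted to
±1 Mbp on the same chromosome; a cis analysis never needs more.

## Enrichment statistics

**TSS proximity.** The statistic is the Pearson (non-excess) sample
kurtosis m₄/m₂² of the raw signed TSS distances. "Kurtosis of the density
distribution" could also be read as kurtosis of KDE ordinates; the raw
sample moment is bandwidth-free and well-defined, so it is used. The null
matches the confounder "number of sharing tissues": each of n_rep
replicates draws, without replacement, multi-eQTL (gene, SNP) pairs whose
sharing-count histogram equals the opp set's. The test is one-sided (higher
kurtosis = more TSS-peaked, the direction of the hypothesis). With zero
exceedances the result is reported as the strict bound p < 1/n_rep rather
than p = 0. The density ratio at the TSS uses Gaussian KDEs with
Silverman's rule, evaluated at 0 bp, bandwidths recorded in the output.

**Epigenetic annotations and GWAS overlap.** Because opp SNPs sit closer
to the TSS, their null is TSS-distance-matched: opp pairs are counted in
half-open 1-kbp windows spanning −1000 to +1000 kbp of signed TSS
distance, and each replicate draws the same per-window counts from the
multi pairs, capped at availability with the deficit logged (never with
replacement — duplicated SNPs would distort fractions). The annotation
statistic is the mean annotated fraction across the cell lines that have
data for the mark; SNPs absent from the annotation matrix drop out of
numerator and denominator, counted. The GWAS statistic is the proportion
of SNPs with r² > 0.8 to at least one genome-wide-significant
(p < 5 × 10⁻⁸, strict, any trait) catalog SNP; a SNP that is itself in the
catalog hits via self-LD, which is also the only way a SNP absent from the
panel can hit. Class-vs-class comparison uses the two-sided Fisher exact
test with the sample odds ratio (sidedness is a convention choice; the
resampling tests carry the directional hypothesis). Hit status per SNP is
resolved once against the panel and replicates re-average flags, which is
exact because LD is a property of the SNP, not of the subsample.

**Tissue-pair discordance matrix.** The sharing unit is the (gene, SNP)
record, not the bare SNP — one SNP can regulate several genes with
different signs, and only the record makes "opposite" well-defined.
Fractions are #(β_i·β_j < 0)/#shared; pairs sharing nothing are flagged
undefined and imputed with column means (flagged) before clustering.
Clustering is agglomerative, complete linkage over Euclidean distances
between matrix rows — the conventional heatmap default; the method and
metric are arguments, not constants. The paired p-value maps use 0.25-unit
bins of −log10 p on [0, 30], overflow clipped into the last bin, each
histogram normalized to mass 1 so the opp−multi difference sums to 0.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, at
desk scale, with planted truth. Defaults (the study conditions):

| parameter | default | meaning |
|---|---|---|
| n_genes × n_tissues | 200 × 6 | cohort size |
| n_haplotypes | 200 | phased panel depth (EUR-like) |
| n_blocks × snps_per_block | 40 × 8 | LD blocks, >1 Mbp apart |
| block_r2_target | 0.9 | mean within-block pairwise r² |
| theta_opp | 0.1 | genes planted with a reversal |
| sharing_geom_p | 0.35 | truncated-geometric active-tissue count |
| secondary_rate | 0.2 | genes with an independent second block |
| beta_log_mu/sigma | ln 0.6 / 0.35 | log-normal slope magnitude |
| detect_slope/mid | 12 / 0.25 | logistic partner-record censoring |
| tss_peak_scale_bp | 25 000 | Laplace TSS peak scale |
| tss_peak_weight (opp) | 0.6 (0.85) | peak mass; enrichment knob |
| annot_background (+boost) | 0.2 (+0.2) | Bernoulli annotation rates |
| gwas_rho | 0.3 | opp causal SNPs given an LD partner |

Within a block, haplotypes descend from a complementary ancestral pair:
each haplotype picks an ancestor (frequency ≈ 0.5) and every site flips
independently at rate μ = (1 − t^{1/4})/2, which makes the expected
pairwise allele correlation (1−2μ)² and hence E[r²] = t, the target. Blocks
are placed 2 Mbp apart so LD never leaks across the scan window.

Per gene: one causal block and SNP, a truncated-geometric number of active
tissues, a log-normal |β| with small per-tissue jitter, and a base sign.
A planted *opposite* gene designates one active tissue in which the
gene's regulation — every signal of the gene — flips sign. LD partners of
the causal SNP enter a tissue's table with β attenuated by the *signed*
haplotype correlation r and pass a logistic detection filter in scale·|β|
(the per-tissue scale emulates sample-size differences); the causal SNP
itself is always emitted in its active tissues, so the "no causal
censoring" recovery condition is structural rather than a switch. A
fraction of genes carries an independent *secondary* signal in a second
block, constant-signed across tissues, which sometimes outgrows the
primary in a tissue — reproducing the low-r² discordance (group 1b) that
the LD threshold exists to filter, and making the threshold-removal
sensitivity analysis non-vacuous.

p-values are a deterministic monotone map of |β| and the tissue scale
(p = 10^−(1.3 + 12·scale·|β|)). The pipeline only consumes ranks within a
tissue plus the significance cut, and monotonicity is the only property
top-SNP extraction needs; ties arise exactly for |r| = 1 partners and
exercise the lexicographic rule.

TSS distances are drawn per (gene, SNP) pair — once, shared across tissues
— from a mixture of a sharp Laplace peak at the TSS and a uniform
background over the ±1 Mbp cis window, with higher peak weight for
opposite genes. A mixture is essential: kurtosis is scale-invariant, so a
narrower peak alone would be invisible to the enrichment statistic;
raising the peak *weight* raises both the density at 0 and the kurtosis,
which is also how the real distance distributions behave (sharp TSS peak
over a broad background). Annotations are Bernoulli flags per (SNP, cell,
mark) with availability drawn per (cell, mark), boosted for SNPs in
opposite genes' causal blocks. The GWAS catalog receives, for a fraction ρ
of opposite causal SNPs, a same-block partner verified at r² > 0.8 (the
causal SNP itself when no partner qualifies), plus background
associations and sub-threshold rows that exercise the strict p-filter.
The background association count (6) is set so that the baseline overlap
proportion is a minority of SNPs, as in real catalogs, rather than
blanketing most LD blocks.

All randomness flows from one mandatory seed through four named
sub-streams (panel / eqtl / annotations / gwas); emitted files are
byte-identical across runs. Resampling tests spawn one child generator per
replicate from the user seed, so replicates are reproducible and
order-independent.

### What the generator does not emulate

No coalescent realism (fixed block sizes, two-ancestor blocks, frequencies
near 0.5), no covariate or population structure, one chromosome, no
multi-ancestry panels, no allele-frequency-dependent detection, no
correlated annotations across cell lines or marks. Passing tests therefore
demonstrate the *procedure's* correctness and calibration under the stated
generative assumptions — not robustness to the full messiness of real
eQTL releases.

## Test and acceptance problem sizes

The default cohort (200 genes × 6 tissues, 320-SNP panel) drives the
oracle-equivalence, recovery and sensitivity checks. Calibration uses 50
seeded null runs at 200 resampling replicates (kurtosis) and 100
replicates (annotation CI). Planted-enrichment detection uses a 400-gene ×
300-block cohort — roughly one block per gene, so per-SNP flags do not
leak between genes — with the TSS-peak and annotation-boost knobs turned
up (peak weight 0.4 vs 0.9, boost +0.5, ρ = 0.9), where all three matched
resampling tests report the bound p < 1/n_rep at n_rep = 1000. The
acceptance script runs the same cohorts with 10,000 replicates for the
headline tests.

## Known limitations

- At desk scale the TSS-matched null is partially contaminated by the opp
  pairs themselves (opp ⊆ multi, and near-TSS windows are opp-dominated
  when the cohort is small), which biases the adjusted null *toward* the
  opp set; the full-scale regime, with a ~12:1 multi:opp ratio, does not
  have this problem. The planted-detection configuration controls it by
  keeping block collisions rare.
- Group 1b/2b prevalence depends entirely on the secondary-signal rate;
  the generator plants secondaries as constant-signed, so 1b cases arise
  only from planted reversals topped by a secondary signal, a narrower
  mechanism than real secondary eQTLs.
- The Fisher odds ratio is the sample OR, not the conditional MLE;
  zero-margin tables return p = 1 with an undefined OR.
- Locus views require all-tested association tables to show
  non-significant SNPs; when given significant-only tables they render the
  significant subset.
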