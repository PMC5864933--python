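# Methods

`funcgwas` maps a quantitative trait in a structured panel of inbred
accessions by restricting association testing to *functional* SNP sets —
protein-altering variants, optionally extended with promoter variants —
and cross-checking every association signal against three independent
lines of evidence: pool allele-frequency contrasts, local LD/haplotype
structure, and selection statistics. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
validation does and does not establish.

## Genotype model and conventions

Accessions are inbred cultivars: genotypes are coded as alternate-allele
dosages 0/2 (with 1 reserved for residual heterozygosity and −1 for
missing calls). All association tests regress on dosage/2, so a reported
effect β is the phenotype difference in cm between alternate and
reference *homozygotes* — the natural contrast in a homozygous panel,
and the scale on which simulated effects are specified. Positions follow
the VCF convention (1-based); internal genome arithmetic is 0-based
half-open and converted at the file boundary.

## Synthetic studies

The generator emits a complete study — genome FASTA, GFF3 gene models,
VCF genotypes, phenotype TSV, truth JSON — from a single seed, which is
split into four independent streams (genome, population, missingness,
phenotype) via `numpy.random.SeedSequence.spawn`; outputs are
bit-identical across runs and platforms at the text-file level.

* **Genome.** Non-overlapping single-CDS genes (ATG … stop, no internal
  stop), roughly half on the reverse strand, packed with at least 200 bp
  spacing. Default: 2 chromosomes × 1 Mb, 100 genes of 300 bp.
* **Population.** Two subpopulations (defaults 390 and 231 accessions,
  the shape of a large cultivated-rice panel split into *indica*- and
  *japonica*-like groups). Per SNP an ancestral frequency is drawn
  uniformly from `ancestral_maf_range` (default 0.02–0.5, folded to
  either allele) and subpopulation frequencies follow the
  Balding–Nichols Beta distribution at the configured Fst (default 0.3).
  Dosages are independent across SNPs given the frequencies — there is
  **no linkage disequilibrium** in the base generator; LD structures
  needed for block-level validation are planted explicitly
  (`make_ld_block`, `simulate_block_panel`).
* **Causal variants.** Each entry of `causal_spec` names a gene and
  codon; the generator picks a substitution that is guaranteed
  non-synonymous and non-stop, at a controlled (optionally
  subpopulation-specific) frequency, with an effect in cm per
  alternate homozygote.
* **Phenotype.** `y = Σ (dosage/2)·effect + polygenic + noise`. The
  polygenic term uses 100 background SNPs (configurable);
  `heritability` is its variance share of the baseline
  (background + noise) variance, fixed at `baseline_variance_cm2`
  (default 1 cm²). Planted causal effects add on top on the absolute cm
  scale, so they remain recoverable as regression slopes. With
  `heritability = 0` the phenotype is pure noise. `phenotype_skew`
  applies a monotone convex transform (`max(1.1·e^{0.75z} − 0.35, 0)`)
  that reproduces the strongly right-skewed, zero-floored shape of
  mesocotyl-length panels; it preserves rankings (hence pool selection)
  but not cm-scale slopes, so effect-recovery experiments run with the
  skew off.
* **Neutral-SFS panel.** `simulate_neutral_panel` draws segregating-site
  allele counts with P(k) ∝ 1/k — the neutral infinite-sites sample
  spectrum, under which the pairwise (π) and Watterson (S/a₁) estimators
  agree in expectation. This, not the uniform-frequency Balding–Nichols
  panel, is the correct reference for Tajima's-D calibration: a uniform
  intermediate-frequency spectrum pushes D strongly positive by
  construction.

What passing on these panels does *not* show: robustness to real LD
(the base generator has none), to genotyping error beyond the planted
flip rates, to phenotype models with epistasis or GxE, or to
selection/demography beyond the planted constructions.

## Variant annotation and SNP sets

Consequences are called by strand-aware codon arithmetic against
single-representative gene models (longest CDS transcript; ties by
transcript id). Reverse-strand alleles are complemented before codon
substitution; the standard nuclear code classifies synonymous /
non-synonymous / stop-gained / stop-lost / start-lost. Promoter SNPs lie
within 1 kb upstream of the coding start (strand-aware) and outside
every CDS. SNPs in overlapping genes produce one record per gene; VCF
multiallelics are split into biallelic records (star alleles dropped).
Gene models flagged as transposons are excluded from functional
grouping. The three association sets are: group I (protein-altering;
stop/start changes included by default, excludable by flag), group II
(I ∪ promoter), group III (seeded uniform random sample of all SNPs).

## Structure, kinship, association

Variants are filtered at MAF > 0.05 and missingness < 0.5. PCA
mean-imputes missing dosages, centers at 2p and scales by √(2p(1−p));
component signs are fixed (largest-magnitude loading positive) for
reproducibility. Kinship is the VanRaden centered cross-product
K = ZZᵀ/Σ2p(1−p); under full homozygosity its diagonal averages
1 + f ≈ 2. Subpopulation labels come from PC1 by raw thresholds,
quantiles (scale-free default, 0.3/0.7), or seeded 2-means.

The GLM is OLS on [1, PCs, dosage/2] with a two-sided t-test. The mixed
model is y = Xβ + u + e, cov(u) = σ²g·K; REML profiles
δ = σ²e/σ²g through a single spectral decomposition of SKS
(S the covariate projection), on a log grid 1e−5…1e5 with
golden-section refinement to 1e−6. Variance components are estimated
once on the null model and reused for every SNP (the standard
population-parameters-previously-determined shortcut); each SNP is then
a generalized least-squares t-test with residual df = n − q − 1.
Compression (the CMLM idea) clusters accessions by average linkage on
max(K) − K, replaces K by the group-mean kinship, and under `"auto"`
picks the group count among n, n/2, …, 8 by REML likelihood;
compression with n groups reproduces the uncompressed model exactly.

Missing calls are handled by casewise deletion in both models. In the
mixed model this is computed exactly without per-SNP refactorization via
the principal-submatrix identity
(V_kk)⁻¹ = P_kk − P_km·P_mm⁻¹·P_mk with P = V⁻¹ computed once,
which agrees with a direct per-SNP factorization to numerical precision
while touching only a tiny m×m system per SNP.

Significance uses the scan-adaptive threshold −log₁₀(α/m), α = 0.01,
where m counts SNPs with p < α *in the same scan* (model-matched;
configurable), with a Bonferroni-over-all-tested fallback when m = 0.
Benjamini–Hochberg q-values accompany every scan. Significant SNPs
closer than 170 kb (an LD-decay-scale default) chain into QTLs; the peak
is the largest −log₁₀(p), ties to the smaller position. Scan comparison
pairs QTLs by span overlap or peak proximity.

## Bulked-segregant screen

High/low pools take the `pool_size` (default 20) phenotype extremes
among the *typical* members of a subpopulation (ties broken by
accession id). Each SNP gets a Pearson χ² (df 1, no continuity
correction) on the 2×2 pool-by-allele-count table; each inbred accession
contributes two alleles. Note the statistical consequence: with fully
homozygous accessions the two alleles per individual are identical, so
the allele-count χ² overstates significance relative to accession-level
resampling (roughly a doubled statistic). The SDS (p < 0.05) and ESDS
(p < 0.01) flags are therefore *screening* labels, exactly as used in
practice; genome-wide inference rests on the permutation thresholds,
which are calibrated regardless of the within-individual correlation
because they permute the realized flags. The null-calibration experiment
accordingly uses Hardy–Weinberg diploid genotypes, for which the test's
independent-allele sampling model holds and the nominal 5% rate is
recovered.

Flags are counted in 500 kb windows sliding by 50 kb (half-open,
trailing partial windows included). The permutation null permutes flag
labels across SNP positions genome-wide (preserving per-window SNP
occupancy); the threshold is the 99th percentile of the pooled permuted
window-count distribution, and windows strictly above it are enriched.
A per-iteration-maximum (family-wise) alternative is available via
`null="max"`. Default 10,000 iterations; validation runs use 1,000,
which moves the 99th-percentile estimate by well under one count at
these window occupancies.

## LD, haplotypes, conditional scan

r² is the squared Pearson correlation of dosages on pairwise-complete
accessions (composite r²; phase is trivial at homozygosity), with pairs
under 10 complete observations flagged unreliable. Blocks are
peak-anchored: members have r² > 0.6 with the peak (the all-pairs-clique
alternative is noted but not implemented). Haplotypes over a gene's
defining SNPs label every fully-called homozygous accession by its
allele string; labels A, B, C… descend by count (ties by string), and
haplotypes under `min_count` = 4 accessions are reported but excluded
from tests. Heterozygous calls exclude an accession from labeling — in
an inbred panel they are most plausibly errors.

Phenotype contrasts use one-way fixed-effects ANOVA (groups under 2
members excluded) and Duncan's multiple range test: critical ranges from
the studentized-range distribution at protection levels (1−α)^(k−1),
harmonic-mean group size for unbalanced data, and a compact letter
display in which letter sharing coincides exactly with the step-down
procedure's non-significance. Studentized-range quantiles are cached,
as their numerical inversion dominates the test's cost otherwise.

The conditional scan subsets to homozygous carriers of one allele of a
candidate SNP (≥30 carriers required) and re-tests the other block
members by GLM. Members monomorphic in the subset — or below the
pipeline's own 5% MAF filter there — are reported "untestable: no
allelic diversity" rather than tested at frequencies the pipeline's QC
would never admit. `identify_functional_snp` scores each member by (a)
whether conditioning on *each* of its alleles silences every other
member and (b) a haplotype-consistency term, the |correlation| across
retained block haplotypes between the member's allele and the haplotype
phenotype mean; score = 2·(a) + (b), ties by marginal signal. The
functional member is the unique one that silences the block from both
sides while its alleles separate long- from short-phenotype haplotypes.

## Selection statistics

Inbred accessions contribute one haploid sequence each (dosage 1 and
missing calls are masked per site). π is the mean over sequence pairs of
per-site differences divided by pairwise-comparable sites, counting the
region's invariant sites as comparable. Tajima's D uses the 1989
constants with π(total) and S computed over the same complete-case site
mask; D is reported missing when S = 0 or when its variance is
identically zero (n = 2). Gene regions take the CDS span ± 2 kb,
covering the promoter. The diversity ratio π_ref/π_focal flags an
infinite value when the focal region is monomorphic.

## Pipeline

Seven stages run in dependency order — annotation, structure, GWAS (per
SNP group, plus a complementary scan of group-I SNPs under group-III
covariates), BSA, blocks, haplotypes, selection — each writing plain
TSV/JSON/BED outputs and a manifest with a parameter-and-input hash.
The gene-level haplotype stage defines haplotypes over the gene's
*above-threshold* protein-altering SNPs when any exist (falling back to
all of them): with an LD-free generator, all-SNP haplotypes of a
~20-SNP synthetic gene are nearly all singletons, whereas the
significant-SNP haplotypes carry the planted contrast. The candidate
report scores each QTL by its count of supporting evidence lines (scan
threshold, ESDS, enriched window, block membership, haplotype ANOVA
p < 0.05), ties by peak −log₁₀(p), and names as candidate SNP the
top-ranked block member.

## Validation problem sizes

The validation experiments (`funcgwas.validation`, exercised by the
acceptance tests and `scripts/acceptance.py`) use panels of 400
accessions with 3,000–8,000 SNPs, 20–50 seeds per stochastic property,
and 1,000 permutation iterations — sizes at which each measured property
(nominal-rate calibration, ≥90% power, sub-unit provenance deltas,
exact oracle agreement) is clearly resolved on a single CPU. The
covariate-provenance experiment plants a 0.6 cm effect so the causal
peak sits in the −log₁₀(p) ≈ 3–14 range where sub-unit agreement is a
meaningful statement; kinship matrices estimated from a few thousand
SNPs are far noisier than the hundreds of thousands available at full
scale, so the desk-scale experiment is conservative.

## Known limitations

* No LD in the base population generator (planted blocks only); no
  recombination maps, coalescent genealogy, or selection during
  simulation.
* Single representative transcript per gene; no splice-site or InDel
  consequences.
* The mixed model fits variance components once (no per-SNP REML) and
  tests one SNP at a time; no multi-locus models, dominance, or
  epistasis.
* The allele-count χ² treats inbred alleles as independent (see above);
  use the permutation thresholds for genome-wide claims.
* Duncan's test inherits its well-known liberal protection levels; it is
  provided because it is the field's reporting convention, not as the
  most conservative choice.
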