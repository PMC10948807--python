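# coraligv

Detection and characterisation of **intra-colonial genetic variability
(IGV)** — the presence of more than one genotype within a single colonial
organism — from multi-sample SNP genotype data.

Colonial animals such as scleractinian corals acquire multiple genotypes in
two ways: **mosaicism** (somatic mutation within one genetic individual,
leaving a handful of mostly single-allele differences) and **chimerism**
(fusion of genetically distinct individuals, leaving lineage-scale allelic
divergence). Separating these signals from genotyping error is the central
difficulty: sequencing a colony fragment ("nubbin") at tens of thousands of
SNPs guarantees spurious allelic differences, so a single mismatch can never
evidence IGV. This package implements a threshold-based detection pipeline
for triplicate-sampled colony surveys, together with a synthetic-data
generator that reproduces the statistical structure of such a survey so
every stage is testable without sequencing data.

It is aimed at molecular ecologists working with multi-sample VCFs from
clonal or colonial organisms (corals, tunicates, bryozoans, clonal plants).

## Method

For nubbins *i*, *j* genotyped at diploid biallelic SNPs, the dissimilarity
is the percentage of different alleles over comparable sites (sites
genotyped in both):

```
d(i,j) = 100 · Σ_s |g_is − g_js| / (2 · n_comparable(i,j))
```

where *g* is the ALT-dosage (0/1/2). The pipeline then proceeds:

1. **Filtering** — sites: QUAL ≥ 20, biallelic only; genotypes: DP ≥ 12,
   SP ≤ 13 (failing genotypes set missing); optional %NA and MAF site
   filters. A filter grid reports N_SNP, T50 and Δrep (the mean replicate
   dissimilarity, an empirical error floor) per configuration.
2. **Clone calling** — the pairwise dissimilarity distribution is trimodal
   (errors+mutations ≪ chimeric ≪ inter-species-group); the first antimode
   separates clonal lineages, called as connected components below the
   threshold.
3. **Error threshold** — error and mutation modes overlap, so the low-value
   distribution is decomposed into a two-component Gaussian mixture
   `w₁·N(μ₁,σ₁²) + w₂·N(μ₂,σ₂²)` by EM; the IGV threshold `T_err` is the
   analytic intersection of the weighted component densities (the root of a
   quadratic in *x* between μ₁ and μ₂).
4. **Classification** — each colony's maximum intra-colonial dissimilarity
   is compared to `T_err` (invariable below) and to the next antimode gap
   (mosaic below the gap, chimeric above). T50, the threshold at which half
   the colonies show IGV, equals the median of the colony maxima.
5. **Characterisation** — within-colony differing SNPs are split into
   chimeric pairs (most-distant nubbin × each colony-mate) and
   mosaic-candidate pairs, located against a GFF3/FASTA annotation, and
   classified by codon position and effect (silent / missense / nonsense,
   transition / transversion); GO terms are weighted by non-silent allelic
   differences per gene. Category–site associations use an exact Fisher
   test for r×c tables.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
survey (93 colonies × 3 nubbins, 3 nubbins sequenced in triplicate, 30,000
candidate SNPs, two species groups, 15 clonal lineages):

```bash
python analysis/01_simulate_survey.py
python analysis/02_filter_grid.py
python analysis/03_dissimilarity_lineages.py
python analysis/04_detect_igv.py
python analysis/05_characterise_variants.py
```

Each writes its tables under `results/`. Script 02 prints the filter grid:

```
                        label  n_snp  t50  delta_rep
 QUAL>=20 & DP>=0 & SP<=1e+09  28513 1.89       1.81
QUAL>=20 & DP>=12 & SP<=1e+09  28513 0.84       0.76
   QUAL>=20 & DP>=12 & SP<=13  28513 0.85       0.76
```

— quality thresholds barely move the metrics while the genotype-level depth
filter removes over half the replicate error floor, because low-depth
genotypes carry most of the genotyping error. Script 04 then reports

```
GMM on 5249 low-value pairs: weights (0.944, 0.056), means (0.793, 1.309)%
density intersection -> error threshold T_err = 1.06%
called: {'invariable': 74, 'mosaic': 7, 'chimeric': 12}   truth: {...same...}
classification agrees with truth for 100.0% of colonies
```

i.e. the mixture separates the genotyping-error mode (≈0.8%) from the
somatic-mutation mode (≈1.3%), and thresholding at their density
intersection recovers every simulated colony category. Script 05
characterises the differing SNPs (≈19% coding, mosaic differences ≈99.8%
single-allele, transition:transversion ≈ 1.8).

The same stages are exposed as a CLI
(`coraligv simulate | filter | dissim | detect | characterise | run`) and as
a one-shot pipeline driven by a YAML config (`coraligv run --config run.yaml`).

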