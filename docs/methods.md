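# Methods

## The detection problem

A colony sampled at three nubbins and genotyped at ~10⁴–10⁵ SNPs will show
allelic differences between its nubbins even when it is genetically
homogeneous: genotype calls at moderate depth carry per-allele error, and
that error accumulates linearly with the number of compared sites. IGV
detection is therefore a thresholding problem on the pairwise
percent-different-alleles statistic

d(i,j) = 100 · (number of differing alleles) / (2 · number of comparable sites),

with three nested decision boundaries: error vs somatic mutation (mosaic),
mosaic vs chimeric, and intra- vs inter-species-group. The last two appear
as clear antimodes of the pairwise distribution; the first is encrypted by
the overlap of the error and mutation modes, and is estimated parametrically.

## Dissimilarity

Genotypes are unordered diploid allele pairs stored as ALT dosage; the
number of differing alleles between two genotypes is the dosage difference
|g₁−g₂| ∈ {0,1,2}, equivalently 2 minus the multiset intersection of the
allele pairs. Pairs with zero comparable sites are flagged, never reported
as 0. The implementation computes all pairs through one-hot indicator
matrix products and is tested for exact agreement with a nested-loop oracle.
Dividing by **2 ×** comparable sites (not 1 ×) makes the statistic a true
percentage of alleles with maximum 100; this convention is consistent with
the ~25% plateau observed between sympatric species groups and with the
percent scale of the common population-genetics implementations of the
count-of-differences distance.

## Filters

Order is fixed: site QUAL → biallelic → genotype DP/SP masking → site %NA →
site MAF. DP/SP act on genotypes (masked to missing, site retained), so the
%NA filter must see the missingness that masking creates — %NA is computed
*after* masking. %NA retention is strict (`< x`); MAF retention keeps ties
(`≥ x`) with allele counts of two per non-missing genotype. Mapping- and
base-quality filters act upstream of genotype calling and are outside this
package's inputs; in the simulator their effect is represented by the
error-rate knobs.

## Clone calling and the antimode

`detect_antimode` histograms the values (bins anchored at 0) and returns a
maximal run of empty interior bins; the clone threshold is the midpoint of
the **first** such gap. "First" rather than "widest" matters: above the
error+mutation mass the first gap separates same-lineage from
different-lineage pairs (and, above `T_err`, mosaic from chimeric pairs),
while the widest gap is usually the one below the inter-species-group
plateau. The default bin width for pipeline-level gap detection is 0.25
percentage points — coarse enough that the dense error mass never produces
a spurious empty bin, fine enough to separate the mutation mode from pairs
of doubly-mutated nubbins (see *Degenerate inputs*). Lineages are connected
components of the sub-threshold pair graph (single linkage); transitivity
violations inside a component are reported as warnings rather than split.

## The mixture threshold

The low-value mass (everything below the first antimode) is decomposed into
two univariate normal components by EM: tolerance 1e−8 on the
log-likelihood, at most 500 iterations, best of 10 seeded restarts
(quantile-based initialisation first, then random), restarts discarded when
a component's standard deviation collapses below 1e−6. The error threshold
`T_err` is the analytic intersection of the weighted component densities —
the root of a quadratic in x (linear when σ₁ = σ₂) taken between the two
means; a root outside the means is returned flagged.

The intersection is only meaningful when the fitted mixture actually
describes two modes. When a survey contains no (or almost no) mutation
signal, EM either splits the error mode into two heavily overlapping
components or buries one component under the other; in both cases the
fitted density has no interior dip. The pipeline therefore checks
bimodality of the fitted density between the means and, when it fails,
falls back to `T_err` = lower edge of the first antimode gap (the whole
low mass is error). This guard is what makes the seed-sweep recovery
criterion stable when a random survey draws zero mosaic colonies.

## Classification and pair enumeration

A colony's statistic is the maximum dissimilarity over its intra-colonial
nubbin pairs, after collapsing sequencing replicates to one representative
(first by sample id). Invariable ⇔ max ≤ `T_err`; among IGV colonies the
mosaic/chimera boundary is the first antimode gap above `T_err`, anchored
at `T_err` so that a survey with chimeras but no mosaics still finds the
gap immediately above the threshold. In-gap maxima are split at the gap
midpoint and flagged ambiguous. T50 — the threshold at which half the
colonies are IGV — is the median of the colony maxima (midpoint convention),
which is exactly where the non-increasing threshold-sweep curve crosses 50%.

For characterisation, each 3-nubbin chimeric colony contributes two
chimeric pairs (most-distant nubbin, by mean dissimilarity to its
colony-mates, against each of the other two) and one mosaic-candidate pair;
2-nubbin chimeras contribute one chimeric pair; every intra-colonial pair
of a non-chimeric colony is a mosaic candidate. This bookkeeping reproduces
the reference survey's 21 chimeric and 252 mosaic-candidate pairs exactly.

## Effects

A coding SNP is evaluated against its reference codon independently of any
other SNP in the same codon: the strand-corrected alternate base is
substituted at the CDS-phase-determined position and both codons are
translated with the standard genetic code. Silent = same amino acid;
nonsense = sense → stop; everything else missense, with reference-stop →
sense (stop-loss) counted missense and flagged. The implementation is
tested against an oracle that mutates the whole genome, re-splices and
re-translates the full protein, at every coding site on both strands.
Overlapping transcripts resolve to the longest CDS. Effects are defined
REF→ALT regardless of which nubbin carries which allele. GO terms are
weighted by the summed non-silent allelic differences of their genes and
filtered at a minimum weight (default 50); genes missing from the mapping
are tallied as unannotated. Semantic-similarity reduction of the GO table
is out of scope; the table is exported in a two-column format ready for
such tools.

## Fisher exact test for r×c tables

The two-sided p-value is the total conditional probability, given the
margins, of tables no more probable than the observed one. Tables are
enumerated exactly by recursion over row compositions (with the standard
log-gamma probability), falling back to a seeded Monte-Carlo sample of
tables with the observed margins (label permutation) when the lattice
exceeds the enumeration budget; the result records which method ran.
Checked against the 2×2 hypergeometric case and an independent
implementation of the r×c test.

## The synthetic survey

The generator emulates the study design end-to-end: clonal founder lineages
partitioned into sympatric species groups; per-site divergence classes
(fixed opposite homozygotes between groups at a fraction
`inter_group_divergence` of sites, independent lineage dosages at
`intra_group_divergence`, shared polymorphism elsewhere); colonies drawn
from a heavy-tailed lineage-size distribution; chimeric colonies with one
nubbin from a foreign lineage; mosaic colonies with Poisson-distributed
somatic changes (each altering exactly one allele of one genotype) in one
nubbin; per-allele genotyping error with optional inflation at low read
depth; negative-binomial depths, exponential strand-bias scores, gamma
site-quality scores and independent per-genotype missingness applied after
errors. The genome is one contig of non-overlapping genes (UTR + contiguous
CDS of sense codons + terminal stop + UTR, phase 0, alternating strands)
sized so site classes match `gene_fraction`/`coding_fraction`; everything is
driven by a single seeded generator, so one config is byte-reproducible.

Defaults are the survey conditions: 93 colonies × 3 nubbins on three sites,
3 nubbins sequenced in triplicate, 15 lineages in 2 groups, 60,000
candidate sites, per-allele error 0.004 (error mode ≈0.85%), 40% missing
data, mean depth 46×, mosaic probability 0.075, chimera probability 0.12.
Two defaults are the package's own calibration where no external value
exists: the somatic mutation count (600 per mosaic nubbin, placing the
mutation mode ≈0.5 percentage points above the error mode so that the three
pair classes keep disjoint supports while the distribution stays trimodal)
and the per-sample error-rate spread (cv 0.05, the noise budget under which
that disjointness holds across hundreds of pair comparisons per run).

What the generator does **not** emulate: read-level artefacts (mapping
error, allelic imbalance, index hopping), linkage between sites, indels and
multi-allelic sites, spatial structure of mosaic patches within a colony,
and biased missingness (missingness is independent of genotype). Passing
tests therefore show that the statistical pipeline is correct under its own
assumptions, not that those assumptions hold for any particular sequencing
protocol.

## Problem sizes and numerical choices

Tests and the analysis scripts run the survey at scaled site counts (8,000
to 40,000 sites; the analysis scripts use 30,000 with the mutation count
scaled to keep the 0.5-pp mosaic offset), chosen so the binomial noise of
the dissimilarity estimate stays close to the full-size survey where the
thresholds are well separated. The seed-sweep recovery suite (50 seeds,
25 colonies × 40,000 sites) recovers ≥99% of true colony categories; the
mixture-recovery check fits 10⁴ draws from the published component
parameters and recovers means within ±0.01 and weights within ±0.02. EM
cross-checks against scikit-learn's GaussianMixture agree to ~10⁻⁴;
scikit-learn is a test-only dependency. Degenerate inputs handled
explicitly: identical values (degenerate-fit error), non-crossing densities
(no-intersection error, with the pipeline fallback above), pairs of
doubly-mutated nubbins from different mosaic colonies (they sit one
mutation load above the mosaic mode and are excluded from the mixture fit
range by the finer antimode bin), zero-replicate metadata, empty pair sets,
colonies with one usable nubbin.

## Known limitations

The mixture threshold is exquisitely sensitive when error and mutation
modes genuinely overlap — a property of the problem, not the code; the
threshold-sensitivity curve is exposed so users can report how category
counts move with `T_err`. Clone calling by single linkage can chain through
intermediate samples (warned, not corrected). The GMM fit assumes the error
mode is adequately normal after filtering; heavy-tailed per-sample error
profiles would bias the intersection downwards. Surface-area correlations
use colony-level means and ignore within-colony pair dependence.
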