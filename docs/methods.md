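# Methods

This note records the models implemented in `rookery`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing its
output.

## The synthetic rookery

The generator is a forward simulation with four layers, each seeded
independently from one master seed (`numpy.random.SeedSequence.spawn`,
so no stage perturbs another's stream).

**Marker panel.** Each microhaplotype locus carries 2–7 alleles drawn
from the spectrum (0.546, 0.365, 0.05, 0.02, 0.01, 0.009) over counts
2…7. This spectrum has mean 2.61 alleles per locus and puts ~12 of 135
loci at four or more alleles, matching the empirical panel the package
targets. Base allele frequencies are symmetric Dirichlet(1) draws,
re-drawn until every allele reaches 0.01: a finalized amplicon panel has
already passed a MAF < 0.01 filter, so counted alleles cannot sit below
that floor. Without the floor, simulated panels contain near-private
alleles that no real filtered panel would report, and rare-homozygote
reference genotypes receive enormous Lynch–Ritland locus weights that
inflate estimator variance beyond anything the study system shows.

**Complex divergence.** Per-complex frequencies follow the
Balding–Nichols construction: a Dirichlet with concentration
p(1−F)/F per allele (marginally Beta), centred on the base vector.
F = 0 copies the base exactly; as F → 1 numerical underflow of the
gamma draws is resolved by its correct limit, fixation on a single
allele chosen with probability p. The default F = 0.04 reproduces
overall G′_ST in the few-percent range typical of weak east–west
differentiation between nesting complexes (G′_ST ≈ 0.036).

**Pedigree.** Defaults: 13 nesting females and 12 breeding males in
three complexes (5/7/1 females, 5/6/1 males), strictly assortative by
complex, exactly one polygynous male (two mates), no polyandry, 1–5
nests per female, clutches of 10–40 sampled offspring (≈ 1000 offspring
per season). Beaches sit on a one-dimensional coastline with a gap
between complexes; individual coordinates get ±10⁻⁴ degree jitter.

**Errors and sequencing.** Observed genotypes corrupt the truth
call-by-call: allelic dropout 3.5% (a heterozygote loses one allele,
chosen uniformly), other errors 0.4% (one allele replaced by a uniform
panel allele), missingness 0.5%. Read totals are negative-binomial
(dispersion 8) around a per-locus mean drawn uniformly on [300, 500];
heterozygote depth splits are Binomial(total, 0.5 + bias) with bias 0 by
default; every non-carried allele receives Poisson(1) noise reads,
which is what exercises the contamination rule. Three caller views are
independent corruptions of the observed table (a call is re-drawn from
Hardy–Weinberg with probability 2%). Replicate samples (12% of
individuals) are *re-genotyped* from truth with fresh error draws —
copies would make replicate-mismatch filtering vacuous.

What the generator does **not** emulate: read-level sequence (no FASTQ,
alignment or real variant callers), linkage disequilibrium between loci
(loci are simulated independently, so LD pruning is exercised only via
planted duplicates in tests), background/generational inbreeding,
genotyping batch effects, and locus-specific error heterogeneity.
Passing tests therefore certify the statistical machinery under the
nominal error structure above, not robustness to those real-data
phenomena.

## QC cascade conventions

Stage order: sample depth → depth-ratio calling → contamination →
ratio-acceptability → caller consensus → replicate mismatch → MAF →
iterative missingness → final consistency. Boundary conventions are
exact (with a 10⁻¹² float guard): samples with ≥ 10 000 reads are kept;
loci are removed when replicate mismatch > 7% or pooled caller mismatch
> 5.5%, when all minor alleles are < 1%, and kept when replicate
consistency ≥ 93%; calls need total depth ≥ 12, a second/top depth
ratio ≤ 0.09 for homozygotes or ≥ 0.20 for heterozygotes (between the
two: ambiguous, set missing), and ≥ 70% of depth-adequate calls per
locus must be ratio-acceptable. Choices the source thresholds left
open, fixed here: mismatch denominators count only replicate pairs with
both calls present; caller mismatch is pooled over caller pairs rather
than taken as a pairwise maximum; the missingness filter tightens in
0.10 steps dropping loci before individuals (preserving samples) and
iterates each level to a fixed point; a call with a third haplotype at
≥ 0.20 of the top depth is set missing, lower third alleles are masked,
and a locus is removed when > 5% of individuals are affected. All are
configurable.

## Relatedness

The Lynch & Ritland (1999) locus estimator and weight are implemented
exactly as published (see README for the formula); the multilocus value
is the weight-averaged estimate computed as ratio-of-sums, symmetrized
by averaging the x- and y-referenced forms (simple and pooled
symmetrization were both evaluated; they are statistically
indistinguishable here and the average-of-ratios form is kept).
Loci are used pairwise-complete; a locus is skipped for a pair when a
carried allele has zero reference frequency or the denominator
degenerates (e.g. a heterozygote reference at a biallelic locus with
p = ½ has weight 0 and drops out naturally). Estimates with fewer than
20 co-typed loci are flagged. Confidence intervals are percentile
bootstraps over loci (1000 replicates, 95%). A Queller–Goodnight
estimator is provided behind the same interface as an alternative;
estimator evaluation simulates 100 pairs per relationship class by
explicit gamete sharing and reports Pearson correlation against the
class expectations {0.5, 0.5, 0.25, 0}.

The reference-bias experiment measures E[r̂] among unrelated pairs when
the allele-frequency reference is estimated from the same N samples; the
expectation is ≈ −1/N. The default experiment uses N iid individuals
(the configuration under which the 1/N rule holds); a
`family_structure` variant instead fills the reference with offspring
of the 25 focal adults, which concentrates the reference on the
breeders' alleles and drags the bias back toward −1/25 regardless of
N — the reason "add more hatchlings" does not rescue self-referenced
estimates in rookery data.

## Kin likelihood

P(g_y | g_x, k) = k₀P_HW(g_y) + k₁P₁(g_y|g_x) + k₂·[g_y = g_x], with
P₁ placing one uniformly chosen allele of g_x into g_y and drawing the
other from the population. Observation error mixes toward
Hardy–Weinberg: P_obs = (1−e)P + e·P_HW with e = 0.02 per locus (the
standard default of pseudo-likelihood kin frameworks). The conditional
distribution sums to 1 exactly (enumeration-tested to 7 alleles).
Zero-probability configurations at e = 0 return a −10³⁰ sentinel with a
flag rather than −∞. The decision threshold is Λ = 0 and both error
rates are reported, so that no fixed design point is baked in; calibration simulates clean genotype
pairs per class and scores them with the error-mixed likelihood.

## Pedigree inference

Rather than a joint pedigree sampler, inference is compositional —
pairwise Λ statistics plus per-locus ML reconstruction plus explicit
merge rules — which is deterministic and unit-testable, and is justified
by the strong mutual agreement of moment, likelihood and full-pedigree
methods on data of this power (135 informative loci, large clutches).

*Maternity*: per orphan nest, Λ(PO vs U) summed over offspring for each
candidate (negative controls included); an "unsampled mother"
alternative scores 0 by construction; probabilities are softmax over
candidates + unsampled (uniform prior); support requires ≥ 0.95.
*Paternal reconstruction*: per locus, ML over all unordered genotypes of
the product over offspring of the error-mixed Mendelian probability
given the mother (population-marginalized where the mother is missing);
ties are ambiguity-masked; with exactly one informative offspring only
the unambiguous non-maternal allele is recorded (one offspring exposes
one paternal gamete — the ML homozygote would be an overclaim).
Offspring maternally incompatible at > 10% of co-typed loci are
excluded. *Polygyny*: sires reconstructed for different mothers merge
when genotype identity ≥ 0.90 over ≥ 50 jointly unmasked loci AND a
cross-nest half-sib-majority link corroborates; 0.90 (not higher)
because two independent reconstructions of the same male under 3.5%
dropout each run ≈ 97% accurate and agree at ≈ 94%, while distinct
males agree below ≈ 75% on these panels; identity without sib support
is reported unmerged with a warning.

*Sibship Nₑ*: random offspring pairs are classified FS/HS/U by Λ; with
Q_FS and Q_HS the sib-dyad frequencies, the random-mating estimator is
1/Nₑ = (2Q_FS + Q_HS)/4, the coancestry identity that reduces to
Wright's 1/Nₑ = (1/N_m + 1/N_f)/4 under independent parent sharing. The
non-random-mating variant multiplies the coalescence rate by (1+α),
α = corr(share-father, share-mother) estimated from the same
frequencies (α = 1 under monogamy, halving Nₑ; α = 0 recovers the
random model). This is this package's own derivation of a
sibship-frequency estimator, chosen for transparency; it matches the
qualitative behaviour expected of such estimators (non-random ≤ random,
factor ≈ 2 under near-monogamy) but is not a line-for-line port of any
published implementation. CIs bootstrap over offspring.

## Population structure

Ho/Hs/Ht use the Nei–Chesser small-sample corrections with the harmonic
mean of per-locus group sizes. Because the unbiased estimators can dip
below Hs = Ht on identical groups, differentiation statistics are
clipped at zero. Overall statistics apply the G′_ST / G″_ST / Jost's D
formulas to across-locus means of Hs and Ht over polymorphic loci
(multiallelic small-sample variants of G″_ST differ between programs;
numeric identity with any particular package is not claimed).
Permutation p-values shuffle individuals across groups and use
(b+1)/(m+1), so they are never exactly zero; 1000 permutations resolve
p < 0.005. G_IS = 1 − Ho/Hs per locus, per group, with Hs = 0 loci
excluded and a 1000-replicate locus bootstrap on the mean. HWE uses the
conditional exact-table probability with Monte-Carlo re-pairing of
allele copies; being an exact conditional test it is valid but
conservative on discrete tables (observed null rejection a few percent
at α = 5%). LD uses a permutation G-test on two-locus genotype
contingency tables; Benjamini–Hochberg step-up controls FDR in both;
significant LD pairs prune the member with more missing data (ties:
keep the lexicographically smaller id).

Multivariate analyses one-hot encode allele dosages, column-center
without scaling (mean-imputing missing calls so they carry no signal),
retain 20 PCs (reduced with a warning when fewer individuals), select K
for K-means by BIC(k) = n·log(WSS/n) + k·log(n), and ordinate with
linear discriminants on the retained PCs. sPCA eigen-decomposes
(1/2n)·Xᵀ(W+Wᵀ)X with W the row-normalized, symmetrized
5-nearest-neighbour network of the coordinates (computed via the n×n
reduction through X's SVD, so its eigenvalue sum equals the trace of
the decomposed matrix to 10⁻⁸). The global test statistic is the
largest positive eigenvalue — a simplification of multi-axis global
tests, documented as such — with p from coordinate permutations,
(b+1)/(m+1)-corrected. Coincident coordinates are jittered (seeded,
with a warning). Coordinates are decimal-degree WGS84 used only for
network adjacency; no projection or distance computation.

## Problem sizes and determinism

The test suite and the acceptance script run everything at the sizes a
desk reproduction needs: estimator evaluation uses the prescribed 100
pairs per class (averaged over 10–12 replicate panels), bias
experiments 25–1000 reference samples over 10–20 replicates,
calibration 300–2000 pairs per class where the distributional shape is
all that matters, permutation counts 20–199 in tests (1000 remains the
library default), and rookeries of ~300–1000 offspring. Every public
function takes a seed; the pipeline writes a manifest with per-stage
seeds and SHA-256 checksums of all outputs, and identical configuration
plus seed reproduces byte-identical files.

## Known limitations

Linked loci are handled only by pruning, never modelled in the
likelihoods. The compositional pedigree procedure does not propagate
uncertainty between stages (a misassigned mother would silently bias
her reconstructed mate). The sibship-Nₑ α correction is a two-moment
approximation. G″_ST's multiallelic small-sample behaviour differs
across published variants. sPCA's global test uses one axis. The HWE
exact test is conservative on loci with rare alleles. Maternity
probabilities are likelihood ratios under a uniform prior, not
calibrated posteriors; printed-table probabilities from full-pedigree
samplers are not expected to match numerically.
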