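# Methods

`nile` re-implements, as a tested library, the computational core of a
population-genetic analysis of an ancient-DNA time transect: read-level
genotyping and authentication of degraded samples, allele-frequency
(f-statistic) ancestry inference, mitochondrial sequence- and
frequency-based comparisons of populations sampled centuries apart, a
drift-based test of population continuity, admixture dating from the
decay of admixture linkage disequilibrium, and the arithmetic that turns
coalescent effective-size estimates into census-like numbers. Every
input class can be simulated with known ground truth, so each estimator
is validated by recovery of the quantity it claims to estimate.

## Read-level model

Ancient samples are low-coverage and damaged, so genotypes are called
**pseudo-haploid**: at each targeted SNP one read passing the quality
filters (default mapping and base quality ≥ 30) whose base matches the
ref or alt allele is sampled uniformly and recorded as a homozygote
(ref → 2, alt → 0); no eligible read yields missing (9), never a guess.
Pseudo-haploid individuals contribute one allele, not two, to every
downstream allele count.

**Damage.** Post-mortem cytosine deamination is read as C→T near the 5'
fragment end (G→A mirrored at 3'). The profile reports, per 0-based end
distance k, the fraction of reads covering a reference-C site that read
T; positions with empty denominators report NaN rather than 0. The
simulator uses a geometric decay d0·λ^k (amplitude d0, decay λ per
base); real damage curves are roughly exponential but not exactly
geometric, which does not matter for the estimators, only for the
realism of the fixture. A sample authenticates when its first-base rate
is at least 8% (inclusive bound).

**Sex.** From mean coverages: male iff X/autosome ≤ 0.75 and
Y/autosome ≥ 0.25; female iff X/autosome > 0.75 and Y/autosome < 0.25;
anything else undetermined.

**Contamination (male X).** A male is hemizygous on X, so any second
allele at a polymorphic site is sequencing error or contamination. With
the per-site mismatch rate mᵢ (fraction of reads differing from the
majority base), the error rate ε̂ estimated from monomorphic flanking
sites, and the population minor-allele frequency qᵢ (the probability a
contaminant read differs from the endogenous allele), the
method-of-moments estimate is ĉ = Σᵢ(mᵢ − ε̂) / Σᵢ qᵢ over sites covered
at least twice. Fewer than 150 qualifying sites is a refusal (a QC
rule), not a warning. Estimates are clipped to [0, 1] with the raw
value retained. Two known approximations: the (1 − 2ε) factor in
E[mᵢ] = ε + c·qᵢ(1 − 2ε) is ignored (negligible at ε ≈ 10⁻³), and the
majority-base consensus mis-identifies the endogenous allele with
probability ~(c·q)^⌈depth/2⌉, which biases ĉ downward by a few percent
of its value at coverage ≲ 3; the unbiasedness test therefore runs at
coverage where the consensus is reliable.

**QC cascades.** Mitochondrial: coverage > 10-fold AND contamination
< 3%, both strict, as the bounds are stated as strict inequalities.
Nuclear: male AND first-base damage ≥ 8% AND ≥ 150 X SNPs covered
twice, inclusive ("at least"). Missing metadata excludes a sample with
reason `missing_metadata`. Filters are idempotent and report one row
per input sample.

**Y haplogroups and phenotype SNPs.** The haplogroup caller takes a
table of defining SNPs (snp_id, haplogroup, tree depth,
ancestral/derived alleles) and calls the deepest haplogroup with an
observed derived allele whose ancestor chain — haplogroups whose names
are prefixes — is not contradicted by observed ancestral states; ties
break by count of supporting derived SNPs, then lexically. Only calls
with mapping quality strictly above 30 are used. Phenotype lookup
reports derived/ancestral/missing per locus.

## f-statistics

With alt-allele frequencies a, b, c, d estimated per population
(missing codes excluded, pseudo-haploid samples contributing one
allele) and the small-sample heterozygosity correction
h = x(1 − x)/(n − 1) (n = observed allele count):

    f2(A,B)     = (a − b)² − h_A − h_B
    f3(C; A,B)  = (c − a)(c − b) − h_C
    f4(A,B;C,D) = (a − b)(c − d)

averaged over SNPs with complete data for the populations involved
(complete case per statistic). When a population has a single observed
allele the correction is undefined; it is set to 0 and the result is
flagged. The identity f3(C;A,B) = [f2(A,C) + f2(B,C) − f2(A,B)]/2 holds
exactly including corrections, and is property-tested, as are f4
antisymmetry and exchange symmetry; on ≤10-SNP instances all statistics
equal a naive double-loop reference to 1e-12.

**Block jackknife.** Standard errors use a weighted delete-one-block
jackknife (Busing-style pseudovalues weighted by per-block SNP counts).
Blocks are 5 cM windows of the genetic map when that yields ≥ 20
blocks, otherwise ~50 equal contiguous index blocks — synthetic panels
have independent SNPs, so index blocks are exact there; real data needs
map-based blocks to absorb LD.

**Scans.** Outgroup-f3 ranks candidates by shared drift (descending
estimate, lexical ties); admixture-f3 ranks by Z ascending, the most
negative Z marking the most plausible source.

**Ancestry proportions.** The f4-ratio α = f4(A,O;X,C)/f4(A,O;B,C) is a
ratio of per-SNP sums, with the jackknife applied to the ratio; a
denominator under 10 of its own jackknife SEs flags `weak_denominator`.
The least-squares (qpAdm-style) estimator solves, for target T, sources
Sₖ, base right population r₀ and remaining rights r:

    min_w Σ_r v_r⁻¹ [f4(T,r₀;r,r₀) − Σ_k w_k f4(S_k,r₀;r,r₀)]²,  Σ w_k = 1

with v_r the jackknife variance of the target statistic. Under the
mixture model x = Σ w_k s_k the relation is exact for any right set.
Weight SEs come from re-solving with each block deleted; collinear
source columns raise an error naming the pair; a residual norm beyond
the χ² 99.9% quantile at R − (K−1) degrees of freedom flags `poor_fit`.
The rank/feasibility machinery of the original method is intentionally
out of scope; only the weight-estimation contract is reproduced.

**PCA with projection.** Components are computed from reference
individuals only, after centring each SNP at its reference mean and
scaling by √(p(1−p)); monomorphic and all-missing SNPs are dropped.
Low-coverage samples are projected by least squares restricted to their
non-missing SNPs, so a complete duplicate of a reference individual
lands exactly on its twin's coordinates.

## Mitochondrial analyses

**Haplogroup binning.** Twenty bins (H, HV, I, J, K, L0–L4, M1, N, R,
R0, T, T1, T2, U, W, X) by longest-prefix match on the uppercased
label; everything else is "other" (so M2 is "other" because M1 is a bin
but M is not, while HV1 is HV, not H). Frequency PCA column-centres the
per-population frequency vectors and reports the first two component
scores with explained-variance fractions (cross-checked against an
independent eigensolver).

**TN93 + gamma distances.** Base frequencies are estimated from each
sequence pair (pairwise deletion of sites with anything outside
A/C/G/T). With purine/pyrimidine transition proportions P1, P2 and
transversion proportion Q, the standard TN93 logarithmic terms −ln(w)
are replaced, under gamma rate heterogeneity with shape a, by
a(w^(−1/a) − 1). Shape 10⁶ reproduces plain TN93 to 1e-6, the
implementation matches an independent reference implementation to 1e-9
on a frozen fixture, and simulated pairs at 0.05 substitutions/site
(10 kb, shape 0.26) are recovered within the sampling CI. Saturated
pairs (non-positive log/power argument) return NaN rather than a
number.

**ΦST.** AMOVA on squared pairwise distances: ΦST = σ²ₐ/(σ²ₐ + σ²w)
from the among/within variance components; populations of size 1 are an
error (within-group variance undefined). The permutation test shuffles
individual labels (default 10,000 permutations) and uses the add-one
rule p = (1 + #{perm ≥ obs})/(n + 1), so p is never 0. The three
ancient period groups can be pooled into one meta-population before
pairwise comparisons via the `pool` mapping. p-values across pairs are
Benjamini–Hochberg adjusted; Slatkin linearization FST/(1−FST) (negative
estimates clamped to 0 first) prepares distances for MDS.

**Classical MDS.** Torgerson double-centring B = −½JD²J; coordinates
are the top-k eigenvectors scaled by √eigenvalue. Negative eigenvalues
simply mean the input is not Euclidean (ΦST matrices need not be) and
their axes are dropped; asking for more axes than there are positive
eigenvalues is an error.

## Test of population continuity

Given haplogroup counts for an earlier and a later sample: ancestral
frequencies are estimated with an Anscombe pseudocount (default 0.5);
frequencies evolve by per-generation multinomial resampling of Ne
maternal lineages (haploid effective size — mtDNA is maternally
inherited) for t = round(elapsed years / generation length) generations
(clamped to ≥ 1); a sample of the descendant's size is drawn; and the
χ² distance (or Euclidean, configurable) between the simulated sample
and the ancestral frequencies forms the null distribution for the
observed descendant's distance. p uses the add-one rule; continuity is
rejected below 0.05. Under the null the p distribution is uniform to KS
distance < 0.1 (500 replicates) and the rejection rate at α = 0.05
stays in [0.02, 0.09]. Sampling noise in the *ancestral* observed
sample is not modelled — its frequencies are taken as estimated — which
makes the test slightly anticonservative when the ancestral sample is
very small; the generation length (default 29 years) and Ne are priors,
and `sensitivity_sweep` re-runs the test over a grid of them (p is
expected non-increasing in Ne; violations are logged, not failed).

## Admixture dating from weighted LD

A single admixture pulse n generations ago leaves ancestry correlation
e^(−n·d) between loci at genetic distance d Morgans. For SNP pairs
binned by distance (default 0.05 cM bins from 0.5 cM — discarding
short-range background LD — to 30 cM; bins with < 100 pairs report
NaN), each pair contributes cov_target(i,j)·wᵢ·wⱼ with weights
w = f_ref1 − f_ref2, making the curve invariant under swapping the
references. The curve is fit with A·e^(−n·d) + c by nonlinear least
squares, started from a log-linear regression on the offset-corrected
positive bins; the affine offset c absorbs long-range background. A
constant or negative-amplitude curve raises `NoDecaySignalError`. The
simulation route generates ancestry-mosaic haplotypes: tract boundaries
follow a Poisson process of rate n per Morgan and each tract is
source 1 with probability α — a Markov (exponential-tract)
approximation to the pulse model, adequate for n ≥ 5 generations — with
alleles copied from finite source haplotype pools (default 100 per
source; source allele frequencies Uniform(0.05, 0.95) per SNP, a
generator parameter because no empirical profile is prescribed). On
2,000 haplotypes over 1 Morgan with 1,500 SNPs, a 10-generation pulse
is recovered within 25% (median over 10 seeds).

## Demographic rescaling

Coalescent analysis of maternally inherited genomes estimates female
effective size × generation time (years·individuals). Assuming equal
male and female effective sizes, the individual count is
2·x/generation_time = x/14.5 at a 29-year generation, rounded to the
nearest individual — the convention that reproduces all three published
values (1,625,187 → 112,082; 693,670 → 47,839; 4,490,725 → 309,705;
truncation would give 112,081 for the first). Year/generation
conversion multiplies or divides by the generation time, rounding
generations to the nearest integer (700 years → 24 generations).

## Synthetic data: what it does and does not show

The admixture-graph generator draws per-SNP ancestral frequencies
(default Uniform(0.05, 0.95)) and drifts each branch with the
Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) model — chosen for its
closed form and standard use; branches with F = 0 copy frequencies
exactly, and boundary frequencies stay fixed. The graph topology is
ancestral → {outgroup O, source C, internal}; internal → {A, B};
target X = αB + (1−α)C, so A is a sister of source B (what an f4-ratio
requires) and optional extra outgroups (O2, …) populate the right set
for the least-squares weights. Genotypes are Binomial(2, f) for
diploids, Bernoulli(f) encoded 0/2 for pseudo-haploids, with uniform
missingness; drift series use per-generation multinomial resampling.
All generators are bit-reproducible given their seed.

These fixtures have independent SNPs (no background LD), no population
structure within populations, uniform missingness, geometric damage and
a single contaminant profile. Passing tests therefore demonstrate
estimator correctness under the model each method assumes, not
robustness to the messiness of real data (reference bias, batch
effects, UDG treatment differences, non-uniform capture efficiency).

## Problem sizes in the test suite

Recovery tests use 100k-SNP panels with 20 samples per population
(ancestry proportions), 2,000 haplotypes × 1,500 SNPs × 10 seeds (LD
dating), 500 outer × 199 inner replicates (continuity calibration), 400
replicates × 99 permutations (ΦST uniformity) and 100 × 10 kb sequence
pairs (TN93) — sizes at which the verified tolerances (3 jackknife SE,
25% relative error, [0.02, 0.09] rejection band, ±0.01
substitutions/site) are comfortably resolvable.
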