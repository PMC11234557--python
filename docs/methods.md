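# Methods

This note documents what rohscan computes, the assumptions behind each
stage, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that a user
of the results should know about.

## Genotype representation and quality control

Genotypes are allele counts of a designated *counted allele* per SNP
(0/1/2), with a distinct missing sentinel that is never conflated with a
genotype code. The PED/MAP reader designates the first allele observed in
file order as the counted allele and records it; the BED/BIM/FAM reader uses
BIM allele 1, matching the binary format's 2-bit code semantics. Because the
designation is representation, not data, `align_counted_alleles` re-orients
one matrix onto another's designation; every downstream statistic (call
rates, HWE, ROH, GRM) is invariant to the choice.

QC applies four filters in a fixed, logged order:

1. remove SNPs on sex chromosomes (labels X, Y, XY, MT and PLINK's numeric
   aliases by default);
2. remove individuals with call rate ≤ 0.90;
3. remove SNPs with call rate < 0.95;
4. remove SNPs with Hardy-Weinberg exact-test p < 1e-6.

These defaults are the standard PLINK `--mind/--geno/--hwe` readings of
array QC. The order matters (it changes survivor sets) and is not an
intrinsic property of the filters, so the report records counts removed at
each step, and applying QC twice is a no-op. Monomorphic SNPs are retained
(no minor-allele-frequency filter); they are excluded from the GRM sums
instead. The HWE test is the two-sided exact test (sum of probabilities of
all heterozygote counts, conditional on allele counts, no more probable than
the observed one), without the mid-p adjustment — PLINK's default variant.

## ROH detection

Detection follows the PLINK sliding-window scheme. Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `window_snps` | 50 | SNPs per sliding window |
| `window_max_het` | 1 | heterozygous calls tolerated per window |
| `window_max_missing` | 1 | missing calls tolerated per window |
| `window_hit_threshold` | 0.05 | fraction of covering windows that must be homozygous for a SNP to be flagged |
| `min_length_kb` | 1000 | minimum physical span of a reported segment |
| `min_snps` | Lencz bound at `alpha` | minimum SNPs per segment |
| `max_density_kb_per_snp` | 50 | maximum kb per SNP inside a segment (boundary inclusive) |
| `max_gap_kb` | 1000 | maximum gap between adjacent flagged SNPs |
| `alpha` | 0.05 | tolerated expected count of chance ROH |

Only windows wholly inside a chromosome are enumerated, so SNPs near
chromosome ends are covered by fewer windows (PLINK behaviour); chromosomes
shorter than one window produce no calls. The per-window het/missing caps
are window-level limits, not per-segment caps. Segment length is
`end − start + 1` (1-based inclusive, the `.hom` convention). With
`min_snps=None` the bound is computed from the data as
`ceil(ln(α/(n_a·n_s)) / ln(1−het))`, where `het` is the proportion of
heterozygous calls among non-missing calls over the whole matrix. The bound
grows with panel size and shrinks as heterozygosity rises (chance
homozygous runs become rarer), and is undefined at het ∈ {0, 1}.

A consequence of the strict one-missing-per-window cap worth knowing: two
missing calls within one window distance of each other suppress the flags
between and around them, truncating or splitting an otherwise continuous
run. Individual segment endpoints therefore wobble by up to about one
window around the true autozygous boundaries, and consensus intervals
(intersections across carriers) are much shorter than the tracts that
generate them — which is exactly the regime in which consensus regions of a
few dozen kb arise from multi-Mb ROH.

Length classes for summaries are half-open bins [1,2), [2,4), [4,8),
[8,16), [16,∞) Mb; lengths below 1 Mb cannot arise from a valid scan and
are a domain error.

## Consensus regions and islands

Per chromosome, segments are pooled by single-linkage interval overlap; a
pool's consensus is `[max(member starts), min(member ends)]`. A linkage
component whose members do not all share an interval is split: the longest
member seeds a pool, members are added in (start, end) order while the
running intersection stays non-empty, and the remainder is processed
recursively. This reading keeps every reported pool's consensus non-empty
and makes consensus intervals on a chromosome pairwise disjoint, while
agreeing with "the interval common to all members" whenever that is
well-defined. No allelic-identity matching is attempted — pooling is purely
positional.

Carrier frequency divides distinct carriers by **all** QC-surviving
individuals, not by carriers of any ROH. The association set keeps pools
with frequency strictly above 5% and at least five SNPs (post-QC map,
endpoints inclusive); islands are the subset with frequency strictly above
80%. Both thresholds are strict: exactly 5% or exactly 80% is excluded.

Annotation intersects consensus intervals with gene records from GFF3
(1-based inclusive, `gene` features only) or BED (0-based half-open,
converted on load); one shared base pair counts as overlap and strand is
ignored, the bedtools-intersect defaults.

## Genomic relationships and the animal model

The GRM is VanRaden's first form: `G = WW′ / (2 Σ_k p_k(1−p_k))` with `W`
the genotype codes centred by twice the sample allele frequency, missing
cells imputed to the SNP mean (0 after centring), and monomorphic SNPs
contributing to neither numerator nor denominator. Row sums are exactly
zero when frequencies come from the sample, and the mean diagonal
approaches 1 for unrelated individuals in Hardy-Weinberg proportions. If
`G` is singular (duplicated genotypes, n below rank), `stabilize` blends it
with the identity, `G* = 0.98·G + 0.02·I`, only on demand and with the
eigenvalue change logged; blending to nearest-PD bending was rejected as
harder to reason about.

Association fits, per trait,

    y = μ + Xb + Zu + e,  u ~ N(0, G σ²u),  e ~ N(0, I σ²e)

with X = intercept, treatment-coded factors (first level alphabetically as
reference), the age covariate, and one 0/1 indicator per consensus ROH, all
fitted simultaneously. Columns linearly dependent on earlier ones are
detected by incremental orthogonalisation and dropped with a logged reason,
so the intercept and management factors take precedence over ROH indicators
when a set is collinear; aliased ROH are reported as untestable, never as
p = 1. Individuals missing a trait are dropped for that trait's model.

REML works in the eigenbasis of G: rotating y and X by the eigenvectors
makes the covariance diagonal, and the restricted likelihood is profiled
over the variance ratio on a 61-point log grid spanning
σ²e/σ²u ∈ [1e-4, 1e4] (plus the σ²u = 0 boundary), then refined by bounded
one-dimensional optimisation. Variances are floored at 1e-10 at the
boundary. When G is a multiple of the identity the split σ²u/σ²e is not
identifiable — the likelihood is flat in it — and the fit reports σ²u = 0
with the total variance in σ²e plus an explicit warning rather than an
arbitrary split. More generally, identifiability rests on the spread of G's
eigenvalues: panels of unrelated individuals with many SNPs give G ≈ I and
near-flat likelihoods, which is why the synthetic generator produces family
structure (below).

Wald tests use t = estimate/SE with the residual degrees of freedom n − p
(equivalently F(1, n−p) on the squared statistic) rather than the
asymptotic χ²(1). At thousands of records the two are indistinguishable; at
hundreds of records with ~200 indicator columns χ²(1) is measurably
anti-conservative, while the denominator-df form holds the nominal 0.01
level (verified by simulation in the test suite) and mirrors how REML
packages report conditional Wald tests. Significance is flagged at the
nominal P < 0.01 with no multiple-testing correction; a Benjamini-Hochberg
FDR column is emitted for reference but never drives the flag.

The univariate screen fits each factor/covariate alone (intercept + term)
with the same machinery and a joint Wald F over the term's coefficients.

## Synthetic data generator

The generator emulates a farmed-mink-style association study at desk scale.
Defaults: 300 individuals in full-sib families of 5, 14 autosomes × 500
SNPs at ~25 kb mean spacing (uniform jitter), background allele frequencies
Uniform(0.1, 0.9), missing rate 0.002. Each family draws two unrelated
parents from Hardy-Weinberg proportions; sibs inherit one whole parental
haplotype per chromosome from each parent (no recombination). The family
blocks give the GRM the eigenvalue spread that makes the variance split
identifiable, as in a real livestock population.

Planted tracts emulate autozygosity sweeps: inside a tract the counted
allele's background frequency is drawn high (Uniform(0.75, 0.90)) and the
carriers — sampled without replacement at the specified fraction — are
overwritten with the same fully homozygous haplotype. Planting against high
background frequencies is what a selection sweep looks like and keeps tract
SNPs compatible with the HWE QC filter; planting a haplotype against
arbitrary frequencies would produce gross heterozygote deficits that QC
would (correctly) strip, destroying the islands before detection.
Non-carriers still segregate inside tracts (per-SNP het rate 2q(1−q) ≈
0.15–0.38), so they are not called as ROH.

Phenotypes are drawn from the same animal model the association stage fits:
u with covariance σ²u·G computed from the simulated panel, iid residuals,
uniform factor-level assignment (farm, sex, colour, row-year), integer age
uniform on [184, 229] with a small linear effect, and tract effects added
to carriers in phenotypic-SD units (unit total variance: σ²u = h²,
σ²e = 1 − h²). All truth (carrier sets, effects, h², fixed-effect
coefficients) is recorded.

The default study preset plants five tracts — three islands at carrier
fractions 0.85/0.90/0.95 and two mid-frequency consensus tracts at
0.30/0.50 — and three traits (FBW, ADG, RFI) at h² = 0.4, each affected by
one island with a ±1 SD effect. A paper-scale preset (2,288 × ~49,268)
exists behind an explicit constructor.

What the generator does **not** emulate: linkage disequilibrium beyond the
planted tracts and family haplotype sharing, recombination within families,
genotyping error, chance background ROH (background windows essentially
never pass the 50-SNP homozygosity vote at these heterozygosities), allele
frequency spectra skewed toward rare variants, or selection acting on the
traits. Passing tests therefore demonstrate correctness of the machinery
and calibration under the stated model, not robustness to every property of
real array data.

## Problem sizes used in the test suite

The suite exercises oracle equivalence on 100 random 20×300 panels; HWE
against full enumeration on 500 random triples (n ≤ 200, tolerance 1e-12);
GRM identities on a 200×5,000 HWE panel; REML recovery at n = 500 over 20
replicates (h² = 0.4 ± 0.1) and the OLS limit to 1e-8; null calibration of
the Wald tests with 200 simultaneous indicators over 50 replicates at
n = 600 (one shared eigendecomposition, fresh phenotypes per replicate) and
power at a 30%-frequency 1-SD effect; and full-pipeline closure on the
default preset. These sizes keep each property statistically meaningful
while the whole suite runs in well under a minute of compute per heavy test.

## Known limitations

- The ROH caller is the sliding-window method only; no HMM/model-based
  calling, no F_ROH inbreeding coefficient against an assumed genome length.
- Pooling is positional; two overlapping ROH on different haplotypes pool
  together.
- Single random effect; no maternal/litter effects, no multi-trait models,
  no breeding-value prediction.
- The Wald denominator-df choice is an approximation; exact small-sample
  behaviour with estimated variance components is not guaranteed, only
  simulation-verified at the sizes above.
- BED (binary) output is written SNP-major v1.00 only; individual-major
  files are rejected rather than converted.
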