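# Methods notes

This note records the statistical models the package implements, the
conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and known limitations.

## Genotype representation and QC

Genotypes are alternate-allele dosages (0/1/2, −1 missing) over a map sorted
by chromosome and position. Array data carry no reference strand, so for
PED/MAP input the pooled minor allele is designated "alt" (ties broken
lexicographically — the smaller symbol becomes ref). All downstream
statistics are orientation-invariant; the fixed rule only makes outputs
reproducible. VCF input keeps REF/ALT as given, so write→read round-trips
are call-exact. Coordinates are 1-based inclusive internally; BED export is
0-based half-open.

QC runs in a fixed order: (1) drop non-autosomal (X/Y/XY/MT) and unplaced
(chromosome "0") variants, (2) drop samples with missing fraction above
`sample_missing_max` (default 0.30), (3) drop variants with pooled MAF below
`maf_min` (default 0.01), (4) drop variants with missing fraction above
`variant_missing_max` (default 1.0, i.e. inactive). MAF is computed on the
pooled post-sample-filter dataset, all populations together: filtering one
combined dataset is what leaves nonzero *per-population* monomorphic
fractions afterwards, which the diversity stage then reports. Whether the
MAF filter should precede sample removal is not fixed by convention; the
order above is the usual one and the thresholds are arguments, so the
alternative is one call away.

## Diversity and F_IS

Per population: allele frequency, MAF, observed heterozygosity Ho (fraction
of hets among non-missing calls) and expected heterozygosity per SNP. He
uses the small-sample correction He = 2pq · 2n/(2n−1) by default (the
PLINK `--hardy`/`--het` convention); `correct_he=False` gives plain 2pq.
Both are kept because published array studies rarely state which they used.

Individual F_IS is (O_i − E_i)/(nSNP_i − E_i), with O_i the observed
homozygote count over the SNPs genotyped in individual i and
E_i = Σ (1 − He) using the allele frequencies of i's *own population*
(computed over all its members, including i). SNPs monomorphic within the
population contribute 1 to both O_i's expectation and E_i and therefore
cancel in the numerator; when every SNP is monomorphic the statistic is
undefined and returned as NaN. Subpopulation summaries reuse the parent
population's frequencies (so He is constant across subpopulations while Ho
varies) — the convention that makes subpopulation F_IS comparable within a
population rather than re-estimated from small samples.

Mean MAF averages over all retained SNPs including monomorphic ones
(MAF 0); `include_monomorphic_in_maf=False` switches to polymorphic-only.

## LD, Ne and ΔF

r² is the squared Pearson correlation of genotype dosages (composite LD),
the estimator PLINK reports for unphased data; no phasing is attempted.
Missing data are handled by pairwise deletion, implemented with
indicator-matrix algebra so each pair uses exactly the samples genotyped at
both SNPs; pairs with zero variance after deletion are skipped and counted.
Pairs come only from within chromosomes, between `min_dist_bp` (default
1 kb) and `max_dist_bp` (default 33.3 Mb).

Pairs are binned by distance (default 0.1 Mb). The 50 %-decay point is the
first bin, ascending in distance, whose mean r² falls to half the *maximum
bin mean* or below — relative to the maximum, not to r² at zero distance,
because array data never sample zero distance. Each bin maps to a past
generation through the Sved relation: c = mean distance/(100 Mb per Morgan),
N_e = (1 − r²)/(4cr²), t = 1/(2c), ΔF = 1/(2N_e). The identities
ΔF·2N_e = 1 and t·2c = 1 hold to machine rounding by construction. Bins
with r² = 0 (infinite N_e) are flagged and excluded from any truncated
(t ≤ 100 generations) view; the full trajectory is always retained. No
sample-size correction (−1/n) is applied to r², so absolute N_e values are
biased downward at small n; comparisons between populations analysed at the
same n are unaffected. Confidence intervals and regression smoothing of the
N_e curve are out of scope.

## Runs of homozygosity

An ROH is a maximal run of consecutive SNPs with no heterozygous call, at
most `max_missing` missing calls, and homozygous first and last SNPs.
"Maximal" is under interval inclusion: every qualifying run not contained
in a longer one is emitted. This direct stretch definition (rather than a
window-hit-proportion heuristic) is exactly testable: the caller is verified
against an O(n²) brute-force enumeration. One consequence worth stating:
with a positive missing budget two maximal runs may overlap (hom–miss–hom–
miss–hom with budget 1 yields two overlapping maximal runs), so
non-overlap is only guaranteed at budget 0; non-nesting always holds.
The three standard tiers are (min 5 SNPs, 0 missing), (30, 3), (60, 5).
No minimum kb length or density filter is applied — on sparse maps the
5-SNP tier therefore includes short chance runs, which is the reason the
stricter tiers exist.

F_ROH = ΣL_ROH/L_AUTO with L_AUTO the per-chromosome span from first to
last SNP (inclusive) summed over chromosomes, segment lengths likewise
end − start + 1. Cut-offs at >1 Mb and >4 Mb separate older from recent
inbreeding.

Consensus ROH: per SNP, the carrier fraction is the share of a population's
individuals whose ROH covers the position; for each consensus level
(10…100 %), regions are maximal runs of consecutive SNPs at or above the
level. How overlapping per-individual ROHs should be reduced to discrete
consensus regions is genuinely underdetermined in the field; the per-SNP
coverage-run definition used here is one consistent reading, verified
against a brute-force coverage count, and region counts under other
readings may differ. Subpopulation sharing reports n_r/n_t per region and
assigns pool_i by the number of subpopulations with at least one carrier;
a pairwise matrix over pool_2 regions summarises two-region sharing.

## Weir–Cockerham F_ST and the d_i scan

Per SNP the two-population Weir & Cockerham (1984) variance components a,
b, c are computed with unequal sample sizes and observed heterozygosity;
θ = a/(a+b+c), undefined when both populations are fixed for the same
allele or either has fewer than two genotypes. Negative estimates are kept
— clipping would bias the track mean and SD used for standardisation.
Two genome-wide aggregates serve different purposes: the per-SNP mean M and
SD feed d_i (matching per-SNP standardisation over all scored SNPs), while
the weighted ratio-of-sums Σa/Σ(a+b+c) (`genome_fst`) is the unbiased
genome-wide estimate — the per-SNP average of ratios under-estimates the
generating parameter noticeably (≈0.08 for a true 0.10 at n = 100).

d_i sums (F_ST^ij − M)/sd over the comparisons j of a focal population i at
SNPs scored in every comparison; unscored SNPs are excluded, not imputed.
M and sd are per-track over all that track's scored SNPs. Windows tile each
chromosome in 1-Mb steps anchored at bp 1; windows with fewer than 4 scored
SNPs are discarded before the percentile; a window is an outlier when its
mean d_i is at or above the 99th percentile (linear-interpolation quantile)
of all retained windows of that scan. By construction ≈1 % of windows are
flagged under the null, up to ties and granularity (with W retained windows
the smallest non-zero fraction is 1/W — scans in the test-suite use ≥100
windows so the calibration is visible at its natural resolution).

Unique selective events: outlier windows present in every required-in
comparison scan and absent from every required-out scan are kept; adjacent
kept windows merge; the event region snaps to the first/last scored SNP
inside the merged windows (hence sub-Mb region lengths). The uniqueness
rule operates on windowed scans of single standardised pairwise tracks
(`z_track`), since it names pairwise comparisons individually; the
multi-comparison d_i is used for population-level and
subpopulation-specific scans. Subpopulation scans compare one
subpopulation against each of the others within the same population and
require at least three subpopulations. Gene annotation uses any-bp overlap
of 1-based inclusive intervals (an abutting gene with zero overlap is not
listed), implemented with an interval tree and tested against an all-pairs
check.

## Synthetic data: what it emulates, and what it does not

The generator emulates a medium-density array study: ~18 autosomes of tens
of Mb, uniform SNP placement at a configurable density (default
0.02241/kb), several populations with controllable differentiation and
inbreeding, and planted signals with recorded ground truth.

* **Balding–Nichols**: ancestral frequency p ~ U(0.05, 0.95) per SNP;
  population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so F is the expected
  Weir–Cockerham parameter; genotypes drawn with within-individual
  correlation f (P(het) = 2q(1−q)(1−f)); for f < 0 the genotype
  probabilities are clipped at zero and renormalised. Gives closed-form
  targets for the F_ST and F_IS estimators.
* **Planted ROH**: every call in the requested interval is set homozygous
  (one allele per SNP, shared across targeted samples so the interval is
  also a consensus region); truth intervals snap to the SNP grid and
  overlapping requests merge.
* **Planted sweeps**: the focal population's genotypes in the window are
  redrawn at the target frequency under Hardy–Weinberg; other populations
  untouched.
* **Wright–Fisher LD**: forward simulation of N diploids; initial
  haplotypes independent per SNP (generation 0 has no LD beyond the 1/n
  sampling floor); each offspring draws two parents uniformly; gametes
  recombine with Haldane inter-SNP crossover probabilities at
  100 Mb = 1 Morgan (0.5 across chromosome breaks); sampling without
  replacement at the end. Chosen over a coalescent because only
  qualitative N_e ordering and order-of-magnitude recovery are asserted —
  the Sved relation is itself approximate — and a forward model is
  dependency-free and exactly reproducible.

One RNG stream per dataset, seeded from the config, drawn in a documented
fixed order (map → ancestral frequencies → per-population frequencies →
genotypes → planted intervals), so composite datasets are bit-reproducible.

Not emulated: realistic recombination maps, mutation during the
Wright–Fisher phase, migration, phased output, ascertainment bias of array
SNP selection, genotyping error, and linkage disequilibrium in the
Balding–Nichols generator (its SNPs are independent given frequencies).
Passing tests on these data therefore demonstrate correctness of the
estimators under their own model assumptions, not robustness to array
artefacts or background LD.

## Problem sizes and tolerances

The test-suite and the acceptance script size their simulations for a
single CPU: estimator-recovery checks use ~10,000 SNPs with 100 samples per
population (F_ST within ±0.02 of 0.10; mean F_IS within ±0.03 of 0.2);
sweep recovery uses 20 replicates of 10,000 SNPs / 4 × 25 samples with a
1-Mb window fixed at frequency 0.99 (detection required in ≥18/20, null
calibration ≈1 %); N_e ordering uses 10 replicate pairs of a 500-SNP,
50-Mb chromosome at N = 100 vs 400 for 60 generations (larger simulated N
must give larger recent-generation estimates in ≥9/10); the ROH caller is
checked for exact set equality against the brute-force oracle on 1,000
random genotype strings. Oracle equivalence for θ is asserted to 1e−12
against an independently transcribed scalar implementation of the variance
components.

## Known limitations

* The PLINK window-heuristic ROH caller and the exact stretch definition
  agree on clean data but can differ around missing-call clusters; counts
  on real array data are therefore not guaranteed to match
  heuristic-based published counts.
* vcftools' per-site F_ST and this implementation agree on the estimator
  definition, but sites that vcftools drops for other reasons (e.g.
  filtered FORMAT fields) are not reproduced here.
* Absolute N_e values inherit the biases of the Sved relation and of
  uncorrected r² (no −1/n term); treat trajectories comparatively.
* The CLI exposes `simulate` and `run-all`; individual stages are library
  functions rather than separate subcommands, with per-stage outputs and
  parameter hashes in the manifest making isolated re-runs reproducible.
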