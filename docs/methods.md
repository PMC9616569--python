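# Methods

## Signal model

A SNP array reports two per-SNP quantities. The log R ratio (LRR) is a
normalized total-intensity measure: 0 at two copies, negative in losses,
positive in gains. The B allele frequency (BAF) is the allelic intensity
ratio in [0, 1]: diploid bands at 0, ½ and 1; a heterozygous deletion
removes the ½ band; a duplication shifts heterozygote bands to ⅓ and ⅔.

The generator renders LRR as

    LRR = μ(CN) + a·(gc − mean gc) + batch offset + ε,  ε ~ N(0, σ_LRR²)

with state means μ = (CN0 −3.0, CN1 −0.66, CN2 0, CN3 +0.40, CN4 +0.68).
These are the conventional six-state values for Illumina-style arrays; the
noise scale σ_LRR (default 0.15) and BAF component SD (default 0.03) are
typical of a well-behaved array and are free parameters of the config, not
estimates of any particular dataset. BAF is drawn from the binomial
allele-count bands implied by the copy number and the true per-SNP B-allele
frequency (Hardy–Weinberg), plus Gaussian noise clipped to [0, 1] — the
clipping produces the point-mass-plus-half-Gaussian behaviour at the 0/1
boundaries that the caller's emission model mirrors. CN0 carries no allelic
signal and emits uniform BAF.

The GC track is an Ornstein–Uhlenbeck (AR(1)-in-position) process with a
300-kb correlation length, mean 0.42, SD 0.05, so genomic waves are smooth
at the scale the waviness statistic and the 1-Mb binning operate on. The
wave couples into LRR with coefficient `wave_amplitude` (default 0.2 LRR
units per unit GC deviation).

## Cohort model

Carrier status at each configured locus is drawn per population group at
the configured *population* frequency; gout status then follows a logistic
model over age (centred at 50, per-decade coefficient), sex, batch, ten
principal components and ln(OR)·carrier terms. Exact case/control counts
are achieved by stratified selection from a simulated pool (enlarged up to
a bound, then an explicit error) rather than per-individual rejection, so a
fixed seed reproduces the cohort byte-for-byte. Under case-control
selection the logistic slope (hence the OR) remains consistently estimable;
only the intercept absorbs the sampling fractions. With OR = 1 the
configured frequency equals the control-stratum frequency, which is how the
generator's binomial sanity checks are posed.

WGS depth is Poisson per 1-kb bin with mean `background_depth`·CN/2
(default 30× at two copies). The serum-biomarker generator is log-normal
with genotype-dependent medians (defaults 55.7 / 172.9 / 219.9 pg/ml for
CN 0/1/2, log-SD 0.5), preserving the CN0 < CN1 < CN2 ordering in
expectation.

All randomness derives from the single config seed through fixed substream
tags plus a deterministic string hash of the sample id, so per-sample
tracks are reproducible independently of rendering order.

## Caller

Six states: CN0, CN1, CN2, CN2-LOH, CN3, CN4. The LOH state shares the
diploid LRR level but lacks the heterozygote BAF band; it is decoded (to
prevent long homozygous runs being mistaken for deletions) but never
emitted as a CNV call. Emissions multiply a Gaussian LRR term by a BAF
mixture whose components sit at the allelic ratios of the state weighted by
binomial genotype frequencies from the PFB; boundary components carry the
clipped point mass (½ at exactly 0/1), and missing BAF marginalises the
BAF factor. Per-SNP log emission terms are floored at −60 to keep single
outliers from dominating a segment.

Transitions interpolate between a sticky base matrix (diagonal 0.999 for
CN2, 0.95 otherwise; 80% of leaving mass returns to CN2) and its
stationary distribution with weight 1 − exp(−d/D), D = 100 kb, so SNPs far
apart are nearly independent. Viterbi ties are broken toward the smaller
|CN − 2|, then plain CN2 — implemented as a preference-ordered argmax, and
verified against exhaustive path enumeration on short tracks. The
confidence score of a call is the summed per-SNP log-likelihood ratio of
the called state against diploid, which makes it additive in supporting
evidence; the default filter threshold of 40 is kept as a configurable
default without claiming numerical equivalence to any other tool's score.

GC adjustment fits one OLS slope of LRR on local GC per sample and removes
slope·(gc − mean gc); removing a fitted linear term can only reduce track
variance. PFB compilation is the mean non-missing BAF over reference
(non-gout) samples, clipped to [0.01, 0.99]; SNPs with no data fall back
to 0.5 with a warning.

No Baum–Welch re-estimation, no split/merge post-processing of adjacent
calls (merging happens at region level), no sex chromosomes or mosaicism.

## QC, regions, association, meta-analysis

Call filters remove a call on *any* failing criterion (<10 SNPs, <5 kb,
confidence <40) — the disjunctive reading, which is the stricter and more
conventional one. Sample filters use strict inequalities (">" removes,
"=" keeps): LRR SD of the GC-adjusted track >0.28, |waviness factor|
>0.05, CNV count above the cohort's nearest-rank 85th percentile,
recomputed per cohort. The waviness factor is defined here (its published
form is not printed anywhere usable) as the SD of 1-Mb-bin median LRR on
the raw track, signed by the correlation of bin medians with bin GC.

Regions are transitive closures of ≥1-bp overlap (inclusive coordinates;
no reciprocal-overlap requirement — exposed as config), spanning the
outermost boundaries of the union; regions carried by <10 distinct
individuals are excluded from the reported set but retained. Genotype
assignment takes the member call covering ≥50% of the region or lying
wholly within it; with several calls the largest overlap wins and ties go
to the lower CN. Specificity is classified on control-stratum frequencies
(cases would bias toward disease-associated regions): rare unless >2% in
the target group, then specific (all comparators 0%), amplified (all
<1%) or shared.

Association uses carrier (CN ≠ 2) vs diploid coding by default — published
region tables print one OR per region despite three genotype columns — with
dose coding (total copies deviating from 2) available. Logistic fits are
maximum likelihood (statsmodels) with Wald CIs (±1.96·SE) and p-values;
complete separation or non-convergence is flagged on the result (infinite
CI semantics), never raised or hidden. Individuals missing a model's
covariates are dropped per fit with counts logged. Urate models are OLS in
controls only. Biomarker group comparisons use Kruskal–Wallis (tie
corrected) for >2 groups and Mann–Whitney otherwise (exact for small
tie-free samples, else normal approximation with continuity correction),
with Benjamini–Hochberg correction across pairwise tests; sidedness
defaults to two-sided with a one-sided option.

Meta-analysis: fixed-effects inverse-variance pooling and DerSimonian–
Laird random effects, with Q, I² = max(0,(Q−df)/Q) and a χ²
heterogeneity p. The automatic method rule uses random effects when
I² > 50%, which reproduces the published choice (random effects exactly for
the burden test, I² = 80%, and the most heterogeneous region; fixed
elsewhere) and can be overridden. When pooling printed ORs/CIs, SEs are
recovered as (ln hi − ln lo)/3.92 and agreement is asserted at two
decimals to absorb input rounding. One published pooled cell (an OR
printed below its own CI lower bound) is internally inconsistent and is
not used.

## WGS validation

Depth is binned at 1 kb (partial trailing bins averaged over their actual
width). Region CN = round(2·median(region bins)/background), clipped to
[0, 4], with exact .5 ratios rounded away from two; the background is the
per-sample median bin depth outside all called regions. Medians rather
than means throughout, for robustness to mapping spikes. Regions covered
by fewer than three whole bins are no-calls. Concordance is exact CN
match, reported per region and as the unweighted mean of per-region
percentages.

## Problem sizes and what the tests show

The acceptance measurements use a 200-sample, one-chromosome (10 Mb,
100 SNPs/Mb) cohort with three embedded loci of 25–35 SNPs at 18% carrier
frequency; coverage of the burden OR is measured over 200 replicates of
n = 4000 with all Model 2 covariates active in generation; WGS
concordance uses 40 samples at 30× background. These sizes were chosen as
the smallest at which the binomial/CLT tolerances in the checks are
meaningful.

Passing tests show that the pipeline's logic is correct under its own
generative model: the caller recovers events whose signal matches its
emission model, and concordance is measured against depth simulated from
the same truth. They do not show robustness to real-array pathologies the
generator deliberately omits: linkage disequilibrium between SNPs,
locus-specific probe biases, mosaicism, sex chromosomes, relatedness,
population stratification in the PFB, or waves that do not track GC
linearly. The published per-subset regression ORs from the source cohort
are treated as *inputs* to the meta-analysis layer, not as recomputable
targets — their exact exposure coding is not reconstructable from the
printed counts alone.

## Numerical conventions

Internal coordinates are 1-based inclusive; BED export is 0-based
half-open. Chromosome labels are stored without a "chr" prefix (both
accepted on read). PFB values are clipped to [0.01, 0.99] on write.
Writers use fixed column orders and numeric formats so outputs regenerate
byte-identically; the pipeline manifest records SHA-256 digests per stage
and resumes only when digests match, so a corrupted intermediate triggers
recomputation from that stage onward.
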