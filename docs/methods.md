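# Methods

## The measurement

The quantity of interest is how reliably a known single-nucleotide
variant is genotyped as a function of sequencing effort, compared between
a uniform-coverage platform (WGS-like) and a capture platform
(exome-like). Two statistics carry the analysis:

* **Per-site sensitivity** s(d): among gold-standard variant sites
  observed at downsampled per-site depth d, the fraction whose called
  genotype equals the gold genotype exactly. A missing call (zero depth
  or no-call) is always counted as incorrect; it sits in the denominator.
* **Overall estimated sensitivity** S = Σ_d P(d)·s(d), where P(d) is the
  per-base depth histogram over *all* targeted bases, zeros included, and
  s(0) = 0 is forced because an uncovered site can never be called. S is
  compared against the mean on-target depth d̄ (a per-targeted-base
  average, zeros included), which is what a lane of sequencing buys.

The gold standard for each sample is its own full-data call set,
restricted to the known-sites panel by position and alleles, non-missing,
with genotype quality GQ ≥ 60 (the `min_gq_gold` parameter). Sensitivity
scoring uses only the downsampled rungs (retention p < 1), never the rung
the gold was built from.

## Study conditions (the synthetic generator)

The generator reproduces the statistical structure the analyses consume —
per-site depth and per-site ref/alt read counts — not reads themselves.

**Coverage** is a tile-level gamma-Poisson field: each ≤ 100 bp tile
draws a rate multiplier from Gamma(k, 1/k) (mean 1), scaled by the target
mean depth and by exp(−g·|GC − 0.5|); a `failure_rate` fraction of tiles
captures nothing; per-base depth is Poisson around the tile rate. The
variance/mean ratio is 1 + d̄/k, so k ≈ 50 gives near-Poisson WGS-like
uniformity and k ≈ 2 the spiky profile of capture data. Tile-level
simulation was chosen over read placement deliberately: downstream code
only ever sees per-site depths, and the gamma-Poisson family reproduces
the relevant marginal and its downsampling behaviour at a fraction of the
cost.

**Allele counts** at a het site are Binomial(d, p_alt) with
p_alt = 0.5(1−β)(1−ε) + (1 − 0.5(1−β))ε: a fraction 0.5(1−β) of fragments
carries the alternate allele (β is the reference-capture bias), and each
read mis-reports its allele with error ε in both directions. Homozygous
sites are Binomial(d, ε) and Binomial(d, 1−ε).

**Downsampling** thins each site's ref and alt counts independently as
Binomial(count, p). The original experiment downsampled physical reads
pair-preservingly; site-level thinning is an approximation that preserves
exactly the per-site depth and allele-count distributions, which is all
the downstream statistics use. Thinning is consistent under composition
(p then q ≡ p·q), verified by a moment-matching test.

**Default platform settings** (one choice, held fixed): WGS-like
mean 40X, k = 50, β = 0, no GC penalty; exome-like mean 80X, k = 2,
GC-penalty strength 2, 1% tile failure, β = 0.1. Deep exomes genuinely
run ~2x the nominal depth of matched genomes; β has no published point
estimate, so 0.1 is a sensitivity-tested placeholder rather than a
measured value, and the β-monotonicity property (higher β strictly lowers
het s(d) for every d ≥ 2) is what the tests pin down. Cohorts are 6
individuals, ~100 kb of exon-scale targets (625 regions), ~2,000 panel
sites with truth drawn 40% het / 20% hom-alt / 40% hom-ref per
individual, ladder p = 0.1 … 1.0. These sizes keep the full workflow
around ten seconds while leaving hundreds of observations per depth bin;
they are the package's chosen desk-scale study conditions, not estimates
of any particular cohort.

Every stochastic stage derives its own substream seed by SHA-256 hashing
of (master seed, stage label, sample/fraction id), so one integer
reproduces the entire experiment byte-for-byte and no stage's draws
perturb another's.

**What the generator does not emulate.** Mapping ambiguity and
mapping-quality effects; indels and multi-allelic sites; linkage between
neighbouring sites (truths are independent draws); GC effects on the
*panel* (sites are scattered uniformly); read pairing; batch effects
between samples. Repeat presence and alignability are generated as
annotation covariates but do not drive coverage, so the difficulty
regression on synthetic cohorts is expected to be near-null — the
regression machinery is validated instead by planted-coefficient
recovery. Consequently, passing tests demonstrate the *mechanisms*
(bias lowers het sensitivity; overdispersion raises the required mean
depth; pooling rescues low-depth carriers), not the numerical thresholds
of any real data set, which depend on cohort-specific coverage shapes.

## The caller

Biallelic diploid likelihoods L(RR) = ε^a(1−ε)^r, L(RA) = 0.5^(r+a),
L(AA) = ε^r(1−ε)^a (shared binomial coefficient omitted), posterior ∝
likelihood × prior, genotype = argmax with ties broken in the fixed order
RR < RA < AA, GQ = round(−10·log10(1 − max posterior)) capped at 99.
Zero depth returns "missing" at GQ 0. The default prior is uniform, which
keeps every expected value exactly enumerable; a population-style prior
(P(RA) = θ, P(AA) = θ/2, θ = 0.001) is available.

A property worth knowing: under the uniform prior with ε = 0.01, the
hom-alt accuracy and the specificity are *sawtoothed* in depth, not
monotone. Up to d = 6 only the all-alternate (resp. all-reference)
outcome yields a homozygous call, so accuracy is (1−ε)^d and declines;
at d = 7 the likelihood first tolerates one discordant read and accuracy
jumps (0.941 → 0.998), repeating at each tolerance step. The het curve
inherits mirror-image dips (e.g. a lone alt read stops being called RA at
d = 7). These discrete steps are exact consequences of the likelihood
ratios and are asserted by enumeration tests; real callers smooth them
away with base qualities and non-uniform priors. They also create
isolated depths where the het curve momentarily exceeds the dipping hom
curve, which is why "hom dominates het" is enforced only outside those
enumerated dip depths.

**Grouped calling.** A site is polymorphic for the group when the pooled
alternate count exceeds the Binomial(pooled depth, ε) upper tail at
α = 1e-4; each sample is then genotyped freely at flagged sites and
forced to RR (or missing) elsewhere. Single-sample calling applies the
same discovery rule to one sample's own reads — this is what makes the
grouped-vs-single comparison meaningful, since it is the discovery step,
not the genotyping step, that pooling improves. α = 1e-4 is a design
choice balancing false discoveries against rescue power at desk scale.

## Curves, crossings and requirements

Depth bins run 0 … d_cap (default 50, the low-depth regime of interest)
plus an overflow bin excluded from threshold searches. Empty bins carry
NaN, never 0. Threshold crossings ("95% at 9X") use isotonic
(pool-adjacent-violators) smoothing over bins with at least
`min_bin_sites` = 100 observations — raw finite-bin noise would otherwise
make the crossing ill-defined — and the smallest depth whose smoothed
value meets the threshold is reported; raw curves are always written
alongside. In S = Σ P(d)s(d), undefined interior bins are imputed from
the isotonic fit of the defined ones (not zero-filled, avoiding
artefactual dips), and overflow mass takes s(d_cap).

Depth requirements interpolate linearly between ladder points after an
isotonic adjustment of S against d̄; extrapolation above the largest
ladder point returns "not reached" rather than a guess, and a bracketing
point with zero sensitivity/breadth contributes no interpolation
information (the crossing is reported at the first point actually meeting
the threshold — relevant only for step-like ladders). The matched-sample
analysis restricts to sites with identical alleles and genotypes in both
platforms' gold standards, records per site and platform the smallest
ladder depth with a correct call, and reports the 95th percentile with
never-correct sites kept in the denominator (the conservative convention;
dropping them is available by flag).

## Difficulty classification and regression

A tile is *difficult* when fewer than 50% of its bases reach 15X in the
full alignments of at least half the samples (ceiling for odd cohort
sizes), *easy* when every base reaches 15X in every sample, *neither*
otherwise; the two named classes are mutually exclusive by construction.
The regression is ordinary least squares — not a count GLM — of the
per-tile failing-sample count on GC, repeat flag and alignability with an
intercept and no interactions, restricted to tiles failing in at least
one sample; a constant response short-circuits to zero slopes, and
perfectly collinear predictors raise an error naming the offending
columns. Tiles (≤ 100 bp) are the default unit; whole regions can be
classified by tiling with a large tile size.

## Cost model

Mean on-target depth is exactly linear in lane share: d̄ = Y·lanes/G for
WGS and d̄ = (Y/samples-per-lane)·f_ot/T for exome capture, with target
size T = 65 Mb and on-target fraction f_ot = 0.60. Lane yield Y is
calibrated per method from published anchors (22X at 16 exome
samples/lane; 11X at 1 WGS lane) because the two anchors are mutually
inconsistent under a single Y — the published depths embed unstated
genome-size and duplicate-rate assumptions. Per-sample cost is library
prep + capture (exome only) + lane cost × lane share, normalised to the
cheapest exome configuration. Cost ratios at matched sensitivity tiers
are computed from the published normalised totals, which the package
ships as a reference table; a least-squares component fit to that table
(max |residual| ≈ 0.13 — the published totals are not exactly linear) is
used only for the parity scan, which scales lane cost by a multiplier m
for both methods, holds capture cost fixed, and reports the largest grid
m at which WGS is no more expensive. Under the fitted components parity
arrives only at m ≈ 0.06/0.03 for the two tiers; published estimates
using unpublished costing inputs put it higher, so the scan's value is
the mechanism, not the point estimate.

## Known limitations

* Site-level thinning cannot represent read-pair or fragment-level
  artefacts of physical downsampling.
* The caller has no base-quality model; ε is a single shared constant, so
  GQ values are systematically more optimistic than a BAQ-aware caller's.
* The GC penalty's exponential form in |GC − 0.5| is a modelling choice;
  only its direction, not its shape, is empirically constrained.
* Difficulty regression on synthetic cohorts has no planted
  repeat/alignability effect to find (see above).
* Chromosome names are matched exactly; no "chr" prefix normalisation is
  attempted, by design — mismatches raise an error naming both sets.
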