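# Methods

## The replica-set survival model

A replica-set assay scores each well once: at timepoint `t` a well
contributes counts `(n_alive, n_dead)` and is discarded. Conditional on the
well's timepoint, the number alive is modelled as
`Binomial(n, p(t))` with the two-parameter logit survival curve

    p(t) = 1 / (1 + exp(a·t − b)),

i.e. logistic regression of survival on time with linear predictor
`η = b − a·t`. The slope `a` (units: 1/time) controls how sharply survival
collapses; the intercept `b` (dimensionless) sets the location. Derived
summaries are closed forms on the fitted curve:

* LD50 `= b/a` (survival crosses 1/2 there, exactly);
* maximum life `= (b + ln((1−θ)/θ))/a` for threshold `θ` (default 5%,
  giving `(b + ln 19)/a`). This is a property of the **fitted curve**, not
  of the observed extreme animals.

Signs are fixed so that `a > 0` means declining survival and a positive
LD50; a dataset implying `a ≤ 0` fits fine but its summaries should be
interpreted with care (the curve is non-decreasing).

### Fitting

Maximum likelihood by iteratively reweighted least squares (Newton/Fisher
scoring), with the 2×2 weighted normal equations solved in closed form.
Starting values come from a weighted least-squares fit of the empirical
logits `log((alive + 0.5)/(dead + 0.5))` against time — the standard GLM
start. It is robust when pooled survival never crosses 0.5 within the
observation window and, unlike crossing-point heuristics, vectorises: the
kernel (`irls_batch`) fits thousands of datasets simultaneously as (R, n)
arrays, which is what makes K = 10,000 resampling runs cheap.

Convergence: maximum absolute parameter change < 1e−8 within 100
iterations; non-convergence sets a flag rather than raising, so resampling
replicates never abort a run. The linear predictor is clipped at |η| = 30
before the logistic transform (beyond that the probabilities are saturated
to double precision).

### Perfect separation

The binomial likelihood is unbounded when deaths are perfectly separated in
time: every well pure (fully alive or fully dead) and all fully-alive wells
strictly preceding all fully-dead wells, or all wells on one side. A single
mixed well guarantees a finite optimum. At top level this raises
`SeparationError`. Inside resampling — where at K = 10,000 some replicates
will separate by chance — a separated replicate is assigned the midpoint of
the separating interval as a surrogate LD50 (the crossing is only known to
lie in that interval), flagged, and kept countable; one-sided degeneracies
fall back on the extreme observed timepoint, a bound on the crossing. A
replicate that draws a single distinct timepoint is likewise flagged and
assigned that timepoint. `K_effective` reports how many replicates produced
a genuine refit.

## Resampling

The resampling unit is the **well**: wells are the independent unit of the
replica-set design, so the bootstrap draws wells with replacement (same
number of wells) and refits; 95% intervals are the 2.5/97.5 percentiles of
the replicate LD50 distribution (percentile bootstrap — simple,
monotone-invariant, and adequate at 24 wells per the coverage simulations
below).

The two-sample test pools wells, randomly reassigns condition labels
preserving group sizes, refits both groups, and compares `|Δ*|` with the
observed `|Δ|`; `p = (#{|Δ*| ≥ |Δ_obs|} + 1)/(K + 1)` (add-one, so p is
never 0 and never below `1/(K+1)`). An optional stratified mode permutes
labels only within trials.

The ratio comparison asks whether a treatment's **relative** LD50 effect
differs between two genetic backgrounds. The statistic is
`(LD50_treat_A/LD50_ctrl_A) − (LD50_treat_B/LD50_ctrl_B)`; each of the four
conditions is bootstrapped independently (streams split from one seed via
`SeedSequence`), giving a replicate distribution of the difference. The
two-sided p counts replicates at least as far from the observed statistic
as zero is — the bootstrap test of whether zero lies inside the difference
distribution — which reduces exactly to p = 1 when the four inputs are
identical.

All routines are bit-reproducible given a seed.

## Traditional assays

Kaplan–Meier product-limit curves are computed with exact rational
arithmetic on the integer death/at-risk counts, so on uncensored data the
curve equals the empirical survivor function bit-for-bit (a float running
product does not). The reported median is the first time survival reaches
≤ 0.5 (infinite when it never does). The Mantel–Cox log-rank test
(unweighted, no continuity correction, 1 df) is delegated to `lifelines`;
the test suite checks it against a per-event-time hypergeometric
enumeration written from scratch.

Percent changes — the uniform effect-size report for medians and LD50s —
are `100·(comparison − reference)/reference`, rounded half-away-from-zero
at the reported precision. This rounding convention reproduces all the
published worked examples at their printed precision.

## Regulatory overlap

Coordinates are 0-based half-open (BED dialect); a TSS is one 0-based
coordinate; peak midpoint is `floor((start+end−1)/2)` (left-of-centre for
even lengths). Offsets are strand-aware (upstream negative). Target
assignment requires a peak **midpoint** within `[−700, +100]` of the TSS,
inclusive at both ends; the window bounds follow the empirical enrichment
of binding around worm TSSs, and inclusivity is this package's convention
since only the bounds are conventionally stated. A peak may target several
flanking genes (all-in-window is the default; a nearest-only mode exists
because either convention appears in practice).

E-boxes are counted as occurrences of `CANNTG` (the Myc-family consensus;
the class is closed under reverse complement, so one strand is scanned),
overlapping matches included. GO enrichment uses the Pearson chi-squared
test on the 2×2 of (in target set vs not) × (has term vs not), 1 df, no
continuity correction; tables with a zero margin are emitted flagged with
p = 1 rather than dropped. Fold enrichment is the term frequency among
bound genes over its genome-wide frequency. Raw p-values are reported (no
multiple-testing correction), matching the reporting convention for such
screens; Benjamini–Hochberg can be applied downstream.

## Synthetic data

The generators define the conditions everything is tested under.

**Replica sets**: 24 wells × 25 animals (the bench protocol's 24-well
plates, ~25 animals per well), timepoints assigned round-robin over an
every-other-day schedule (default days 2–24) so each timepoint is covered
evenly; deaths binomial under the true curve. The default true curve is
`a = 0.4/day, b = 7.2` (LD50 = 18 days), a wild-type-like median lifespan.
`exact=True` replaces draws with expectations (the infinite-animal limit)
for noise-free checks. Traditional lifespans use inverse-CDF draws from
the logistic survival curve with optional independent censoring.

**Genomes**: genes on a regular TSS grid (3 chromosomes × 2 Mb, 1000
genes, random strands), one planted peak per chosen target gene with its
midpoint placed strand-aware inside the promoter window, decoy peaks kept
≥ 1.5 kb from every TSS so planted-target recovery is exact by
construction. Peak sequences are i.i.d. uniform ACGT **scrubbed free of
E-boxes**, after which one E-box is planted into the stated fraction — so
the realised E-box fraction equals the planted fraction exactly, including
the 0% case. GO annotation is i.i.d. per term (background frequency 8%)
with the first term enriched at 3× among the first factor's planted
targets. The genome size and term frequency are chosen so that a 3-fold
planted enrichment is comfortably detectable above the fluctuation of the
19 null terms — a self-validating generator must carry enough statistical
power for its own planted signal to be recoverable.

What the toy genome does **not** emulate: real gene density and operons,
nucleotide composition bias, peak-width and signal-strength distributions,
correlated binding between factors, and the dependency structure of real
GO annotations. Passing the planted-recovery tests therefore demonstrates
correctness of the assignment/scanning/enrichment logic, not performance
on real ChIP-seq data.

## Numerical choices and degenerate inputs

* IRLS tolerance 1e−8, cap 100 iterations; η clipped at ±30.
* Log-likelihoods omit the binomial coefficient (constant in the
  parameters).
* Percentile CIs use linear-interpolation percentiles (numpy default).
* `percent_change` and the E-box percent use decimal half-away-from-zero
  rounding, not banker's rounding.
* Chromosomes holding peaks but no genes are skipped with a warning in the
  TSS profile; degenerate 2×2 margins yield flagged p = 1 rows; zero logit
  slope raises rather than returning ±inf summaries.
* A mortality table whose wells are all at one timepoint is unfittable and
  raises `InsufficientDataError`, including at the top of a bootstrap.

## Problem sizes

The calibration suite runs 200 simulated experiments for LD50 recovery,
200 × K = 500 bootstraps for coverage, 200 × K = 200 permutation tests for
type-I error, and 100 × K = 1000 four-condition ratio tests for power —
sizes at which the Monte-Carlo error of each calibration quantity is small
relative to its acceptance band, while the vectorised IRLS kernel keeps
the whole suite in the tens of seconds.

## Known limitations

* The logit model assumes a shared curve across wells and trials; pooling
  across trials is the default (a per-trial option exists at the data
  layer) and inter-trial heterogeneity is not modelled.
* Percentile bootstrap slightly undercovers at 24 wells (~92% empirical
  coverage for nominal 95%); BCa intervals were deliberately not used to
  keep the interval definition simple and monotone-invariant.
* No Cox models, frailty terms, or husbandry covariates; no peak calling
  or signal processing (called peaks are the input); no operon-aware
  promoter modelling.
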