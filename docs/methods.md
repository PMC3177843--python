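# Methods

This note records the statistical model, the synthetic-data assumptions,
and the numerical choices behind the package, in the spirit of a methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Design and scored quantities

The design is a two-group split-plot: a between-subjects affiliation factor
at two levels (left/right, default 15/13 participants) and a
within-subjects character factor at four levels. Each participant completes
one 48-trial block per character: 2 cue directions × 2 congruency levels ×
12 repetitions, SOA 75 ms between the distractor's gaze shift and the
imperative cue.

A trial is scored by the first post-cue horizontal saccade with amplitude
larger than 2°. Trials without a detected saccade are *excluded*; detected
saccades with latency < 100 ms are rejected as anticipations and > 500 ms
as delays. Both bounds are inclusive on the kept side (kept iff
100 ≤ RT ≤ 500 ms): the verbal rule speaks of "less than" and "greater
than", which leaves the boundary samples in. The anticipation/delay rate is
reported under both denominators (all trials, and trials with a detected
saccade) because the conventions coexist in the literature and differ by
about half a point at typical exclusion rates.

### Saccade detection

Velocity is estimated by a 5-point moving-average differentiator
(`(x[i+2]+x[i+1]−x[i−1]−x[i−2])/(6Δ)`), and a candidate movement is a run of
at least two consecutive samples whose |velocity| exceeds the larger of the
user threshold (default 30°/s) and `λ = 3` times the robust (MAD-based) SD
of the pre-cue velocity. One-sample dropouts inside a run are bridged.
Amplitude is the displacement from the median position over the 100 ms
before the run to the median over the 50 ms after it; runs that do not
carry at least 25% of that displacement themselves (noise runs adjacent to
a later movement) are skipped and the scan continues. The reported onset is
refined by a broken-stick least-squares fit — flat at the pre-movement
median, then a free-slope ramp truncated below 85% of the step — over
candidate break points within ±6–8 samples of the run start.

The plain "centered difference over threshold, sustained two samples" rule
was evaluated first and discarded: at 240 Hz with 0.1–0.3° sample noise its
velocity estimate has an SD of 17–51°/s, so a fixed 30°/s threshold either
false-triggers next to the true movement (biasing onsets early by 10–25 ms)
or misses small saccades entirely. With the refined detector, the
generator→detector round trip recovers direction exactly and onset within
one sample period (4.17 ms) at the generator's default noise (0.1°) for
amplitudes ≥ 2.5°. At the extreme corner — 3° amplitude with 0.3° noise —
the per-sample onset evidence is only ≈1.4 SD (slope·Δ/σ), so *no* detector
can guarantee sample-exact recovery there; empirically ~99% of onsets fall
within two sample periods, and that is what the high-noise test asserts.

## Interference indices

Accuracy interference is `100·(p̂_cong − p̂_incong)` over kept trials;
latency interference is `mean RT(incongruent) − mean RT(congruent)` over
kept *correct* trials. Signs follow the gaze-cueing convention that
positive = stronger capture (congruent more accurate, incongruent slower);
the incongruent-minus-congruent order for RT makes a typical cueing cost a
positive number. Cells with no qualifying trials are missing (NaN), never
zero, and participants with missing cells are dropped listwise before the
ANOVA.

The outlier rule removes a participant whose index in *any* character
condition lies beyond `k = 3` SDs (n−1 denominator) of their own group's
mean for that condition, evaluated in a single pass on the original table.
Note the arithmetic consequence: since the participant's own value enters
the group statistics, the largest attainable |z| in a group of n is
(n−1)/√n, so the rule can only ever fire for groups of at least 12 — a
property the tests exercise. A whole-sample variant is available via
`within_group=False`.

## Split-plot ANOVA

Strata: group (df 1) against subjects-within-groups (df N−2); character
(df 3) and group×character (df 3) against the character×subject residual
(df 3(N−2)). Partial η² uses each effect's own error stratum.

With unequal group sizes the sums of squares use frequency-weighted
(proportional-frequency) marginal means. For this design — complete
within-subject data, cell counts proportional to group sizes — the factors
remain orthogonal, the five strata decompose the total SS *exactly* (an
invariant asserted to 10⁻¹⁰ relative tolerance), and the results agree to
machine precision with both an independent OLS projection oracle and
`pingouin.mixed_anova`. A harmonic-mean-n "unweighted means" variant was
considered and rejected because it sacrifices exact SS additivity for
unequal groups while differing negligibly at 14-vs-13 sized designs; the
harmonic mean is retained where it belongs, in Duncan's critical ranges.

## Bootstrap F-null

The default resampling unit is the single observation: each iteration pools
all N×4 values, draws N×4 with replacement, arranges them into the original
design shape, and records all three F statistics. This is a full-null,
structure-breaking scheme — group, condition *and* subject structure are
destroyed — matching the described "randomly assign each datum to each
condition" procedure. `p_boot` is the plain proportion k/B of null draws at
or above the observed F ((k+1)/(B+1) available by option). A
participant-level resampling mode (rows within group, condition labels
shuffled within row) is provided behind a flag for designs with strong
subject covariance, but is not the default.

Calibration, computed by the acceptance script at B = 500 on null
i.i.d. normal data at the study's shape (28×4, 15/13): the type-I error of
the interaction test at α = .05 is within about half a point of nominal.

## Duncan's multiple range test

A pair of means spanning p ordered means is significant when its difference
exceeds `r_p = q(α_p, p, df)·√(MS_err/n)` with protection level
`α_p = 1−(1−α)^(p−1)`; quantiles come from `scipy.stats.studentized_range`
(numerical accuracy validated against published 5% tables to within table
rounding, |Δ| ≤ 0.015). A pair contained in a wider pair already declared
non-significant is never declared significant. Unequal cell sizes enter via
the harmonic mean of the two n's. Within-subject comparisons use the
character×subject residual MS; a zero error MS with unequal means yields an
all-significant table with an explicit degenerate-variance warning.

## Bootstrap confidence intervals

Mean and Pearson-r CIs are plain percentile intervals over B = 2000
resamples (paired resampling for r); BCa was not used because the pipeline
reports plain upper/lower percentile bounds throughout. Percentile
intervals for r under-cover slightly at small n — at n = 30, ρ = 0 the
measured coverage of the nominal 95% interval is ≈ 0.92–0.93 — the known
small-sample behavior of the method, not an implementation artifact; the
acceptance script measures it directly. Degenerate resamples (constant x or
y) are dropped from the bootstrap distribution.

## Assumption checks and routing

Shapiro–Wilk per group×character cell, Levene (absolute deviations from
group means) per character across the two groups. The bootstrap branch of
the pipeline runs when any cell or condition rejects at α (policy
`on-assumption-failure`, the default; `always` and `never` available).
One-sample tests of each cell against zero use the t-test for cells passing
normality and the percentile-bootstrap mean CI otherwise. With
`b_iterations = 0` every resampling stage is disabled and the report is
seed-free and fully parametric.

## Synthetic cohort generator

The generator emulates the study conditions: 28 participants (15 left / 13
right), 4 characters × 48 balanced trials, 13.5% no-saccade trials, 2.0%
anticipations and 1.4% delays (3.4% rejections in total), saccadic RTs from
a shifted lognormal (shift 150 ms, median ≈ 90 ms, σ_log = 0.4, ≈ 247 ms
mean) with a +35 ms incongruency cost, clipped into the 100–500 ms window
so the exclusion fractions converge exactly to their configured rates;
anticipations/delays are drawn outside the window so they exercise the
latency filter as defined. Directional-error probabilities per
(group, character, congruency) default to a congruent base of 0.04 with
incongruent increments encoding the reference group×character accuracy
interference pattern the generator is parameterized around (right-wing:
18.3/17.4/8.7/4.0 points for Berlusconi/Vespa/Di Pietro/Prodi; left-wing:
2.1/5.2/10/9). Traces, when
requested, are fixation noise (SD 0.1°) plus a 30 ms linear ramp to the
target amplitude at the trial's RT, sampled at 240 Hz.

Rating profiles: the self profile is a discretized normal on {1..5} per
item; each character profile is constructed from the self profile by
distributing an exact city-block distance `round((1−s)·100)` over items
within the 1–5 bounds, so the perceived-similarity score hits its target
`s` to within 0.01. Targets default to reference group×character means
(ingroup ≈ 0.72–0.77, outgroup ≈ 0.56–0.62) with SD 0.08. Emotion ratings
are integer (positive, negative) pairs whose difference follows the
reference group×character differential-emotion means and SDs (an ingroup
bias of roughly 2–4.5 rating points between ingroup and outgroup
characters).

**Similarity–interference coupling.** A per-participant-per-character
latent deviate first sets the similarity target; the interference deviate
is then `v = ρ·z + √(1−ρ²)·w`, where `z` is the *realized* similarity
standardized within character across the cohort and `ρ` is
`similarity_coupling`. Anchoring on the realized, standardized similarity
(rather than the raw latent) keeps the cohort-level correlation between
similarity score and injected interference at ≈ ρ even when group-level
base similarities differ by character — which they do by default. The
injected interference shifts the incongruent error probability by
`interference_sd/100 · v` (default SD 13 points, in the range implied by
group-level interference SDs typical of this design), clipped to [0, 0.5].

What the generator does *not* emulate: sequential/practice effects, block
order, speed–accuracy trade-offs at the trial level, subject-level
correlations between RT and accuracy interference, vertical eye position,
blinks, drift, or calibration error. Passing tests therefore validate the
pipeline's statistical machinery and its sensitivity under the configured
effect structure — not the detector's robustness to real recording
artifacts.

Canned conditions used by the tests and the acceptance script (all chosen
at design time): `null_config` (flat 10% errors, no heterogeneity, no
coupling), `planted_interaction_config` (two ingroup characters of one
group at +15 points, no heterogeneity — a clean interaction at roughly the
scale of the default interference matrix), and `coupled_similarity_config`
(uniform
2%/20% error rates, heterogeneity SD 15 points, coupling as given). In the
coupled condition the recovered correlation at n = 28 is attenuated from
the injected 0.5 to ≈ 0.4 by binomial measurement noise (~20 kept trials
per condition implies ≈ 9 points of SE on a cell's interference estimate);
the acceptance script reports the attenuated value it actually measures.

## Problem sizes

The calibration and recovery runs use 1500 null replications (B = 500) for
the type-I rate, 12000 replications (B = 2000) for CI coverage — the
coverage sits within a point of its band edge, so its Monte-Carlo SE must
be pushed below 0.3 points — 30 seeds for interaction recovery and 40 for
coupling recovery. The whole acceptance script completes in about a minute
on one CPU.

## Known limitations

- The bootstrap F-null breaks subject covariance; with strong
  subject-level correlations across conditions its null can diverge from
  the permutation-appropriate one (the participant-resampling mode
  mitigates this but is nonstandard).
- Duncan's test controls error per comparison-span, not familywise; it is
  implemented for fidelity to the target procedure, not as a recommended
  modern post-hoc.
- Percentile bootstrap CIs under-cover by 1–2 points at n ≈ 30 (see above).
- The detector assumes a single dominant horizontal movement per trial;
  overlapping saccade sequences within a velocity run are scored as one.
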