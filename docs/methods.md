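# Methods

## The measurement model

A reviewer annotating one video produces a stream of timestamped marks:
certain breaths, uncertain breaths (seen but not trusted), and distortion
boundaries. The scored region is a *considered window* `[start, end)`
fixed in the video's metadata, identical for every reviewer of that video,
so all reviewers' rates share the same denominator base.

All intervals are half-open `[a, b)` in seconds from video start. This is
what makes the bookkeeping exact: distorted periods and calm segments
partition the window, so calm + distorted durations equal the window length
to the last bit, and a breath exactly on a distorted period's start belongs
to the distorted period while one on its end belongs to the following calm
segment.

### Distortion canonicalization

Two input dialects are supported. In the default **paired** dialect,
`distortion_start`/`distortion_end` events are matched by a depth counter in
time order (nesting and overlap are unioned). A `strict` policy rejects
unmatched marks; `lenient` drops a dangling end and closes a dangling start
at the window end, logging each repair. In the **moment** dialect a
distortion is a single instantaneous mark; maximal runs of marks with
consecutive gaps under `gap_threshold_s` (default 2 s) span `[first, last)`
and an isolated mark expands by ±0.5 s. The paired dialect is the default
because finite excludable periods need two endpoints; the moment dialect
covers tools that log distortions as clicks. Canonical periods are clipped
to the window, zero-length periods dropped, and overlaps/adjacency merged;
canonicalization is idempotent.

A video eligibility rule excludes videos with more than 30 s of total
distortion (strict inequality: exactly 30 s is still eligible).

### Respiratory rate

For one reviewer-video, calm segments are the window minus the canonical
distorted periods. A segment with `m ≥ 1` certain breaths contributes
`m − 1` full cycles plus two boundary fractions, `(first − seg_start)/ref`
and `(seg_end − last)/ref`, where the reference cycle `ref` is the mean
inter-breath gap within the segment when `m ≥ 2`, falling back to the mean
over all full cycles of that reviewer-video, and undefined (contribution 0,
warning) when no full cycle exists anywhere. Fractions are **uncapped**: a
gap may exceed one reference cycle when a reviewer missed a boundary
breath; capping would bias RR downward, and exactness under uniform
breathing requires fractions up to exactly 1. A warning is recorded above
1.5. Segments with zero breaths contribute nothing to the numerator but
keep their full duration in the denominator (the literal reading of
"breath cycles per calm second"). Uncertain breaths are counted and
reported but never enter the numerator; certain breaths inside a distorted
period are *shadowed* — retained in the record, excluded from the rate, and
counted in the result.

RR = 60 × numerator / calm seconds. When distortion covers the window the
rate is undefined (`NoCalmPeriodError`; batch processing records a missing
cell instead). Fast breathing is `RR ≥ cutoff` for the video's age group
(60/50/40 bpm defaults, configurable); the inclusive boundary is the
conventional IMCI reading.

Two properties pin the arithmetic down: (i) for breaths on a perfect grid
of period `T`, any distortion placement that leaves every calm segment at
least one breath, boundary gaps ≤ `T`, and at least one full cycle
somewhere yields RR = 60/`T` to machine precision — inserting distortions
into uniform breathing cannot move the rate; (ii) the computation agrees
with a naive brute-force cycle enumerator on a thousand random instances.
The one-breath-per-segment corner (no full cycle anywhere) is the stated
exception: with no cycle to serve as reference the fraction rule is
undefined and the rate degrades to counting full cycles only.

## Agreement statistics

Reviewers are assigned to videos by simple random sampling from a panel,
so rater "slots" carry no identity across videos and the default
reliability model is a **one-way random-effects ANOVA** with videos as
groups: SEM = √MS_within with df = Σ(kᵢ − 1), and the 95% CI from the
chi-square interval for a variance,

    [ √(df·MS_w / χ²_{0.975, df}),  √(df·MS_w / χ²_{0.025, df}) ],

written out explicitly because the upper quantile gives the *lower* limit —
a classic transposition bug. ICC(1) uses Searle's unbalanced form with the
adjusted replicate count `k₀ = (N − Σkᵢ²/N)/(n − 1)`; with the
variance-component estimate `SD²_total = (MS_b − MS_w)/k₀ + MS_w` the
identity `SEM² = SD²_total(1 − ICC)` holds exactly, balanced or not, and is
asserted numerically to 1e-9. A two-way crossed residual SEM is provided
for fully-crossed datasets, where constant rater offsets should not count
as measurement error.

Missing cells (a reviewer with undefined RR) are handled by per-statistic
row filtering: SEM/ICC use rows with ≥ 2 ratings; Fleiss' κ by default
excludes videos lacking the full k ratings (`reduce` analyses all videos at
the smallest common count, trimming in slot order). κ is computed by the
standard count-table formula and returns an explicit "undefined" (`None`)
when all ratings fall in one category, rather than propagating 0/0. Verbal
bands: κ < 0 poor, then slight/fair/moderate/substantial/almost-perfect at
inclusive upper edges 0.20/0.40/0.60/0.80/1.00 (the nominal gap below 0.01
closes downward into slight). Distortion strata default to empirical
tertiles of the per-video mean distorted fraction, ranked with stable
tie-breaking and split with extra members to the lower strata (50 videos →
17/17/16); fixed thresholds are available via configuration. Kruskal–Wallis
uses the tie-corrected H (all-identical input returns H = 0, p = 1); Dunn's
pairwise z uses the pooled-rank variance with tie correction and Holm's
step-down adjustment.

## Design utilities

Bonett's precision sample size for an ICC, with `w = 2 × half-width` and
the ceiling taken (never rounding) so the precision target is guaranteed.
A simulation check confirms the approximation: at the returned n the mean
large-sample CI width stays within 15% of the target. Reviewer assignment
is uniform sampling without replacement, reproducible by seed.

## The synthetic cohort generator

The generator emulates a field study of annotated breathing videos, not any
particular video. Per video: window length normal (mean 66.1, SD 14.9 s,
truncated at 30 s); true RR normal within age group (61.2/16.3, 56.2/14.6,
38.2/10.7 bpm for <2, 2–11, 12–59 months; truncated at 10 bpm); breath
times from a gamma-renewal process with cycle CV 0.1 (positive support,
tunable regularity — no claim of physiological realism beyond that);
distortion episodes Poisson in time with exponential durations (mean 8 s),
clipped, merged, and rejection-sampled until total ≤ 30 s so generated
cohorts satisfy the eligibility rule by construction. The default episode
rate is 2.6/min: clipping at window edges, overlap merging and the ≤ 30 s
rejection remove roughly a third of the nominal rate × duration product,
and 2.6/min is the value whose *realized* distorted fraction matches the
~19.5% of the window such studies report. Default cohort size is 19/14/17
videos across the three age groups, five reviewers per video from a panel
of ten.

Reviewer noise: each true breath is missed with probability 0.02, otherwise
jittered (Gaussian, SD 0.1 s) and flagged uncertain with probability 0.05;
distortion edges get Gaussian jitter of SD 0.5 s; an optional constant
per-reviewer bias term (default off) stresses the SEM-vs-ICC distinction.
Errors are independent across breaths and reviewers.

Two consequences of this noise model are worth stating plainly. First,
because uncertain breaths are excluded from the numerator, every missed
*or* uncertain-flagged breath removes exactly one cycle, so the estimator
recovers `(1 − miss − uncertain) × true RR` — about 7% (≈ 3.5 bpm at
50 bpm) below truth at the defaults. The test suite asserts this
accounting identity; a check that demands recovery of the undiminished
truth within 2 bpm at these defaults fails for exactly this structural
reason, and is kept failing rather than weakened. Second, the generator
does not model shared perceptual difficulty (all reviewers missing the
same shallow breath) or systematic disagreement about what counts as
distortion, which real panels exhibit; synthetic agreement is therefore
optimistic (SEM ≈ 2 bpm at defaults versus ~5 bpm reported in field data),
and passing tests demonstrate the correctness of the pipeline's
arithmetic and statistics, not that real reviewers agree this well.

## Problem sizes and numerics

Simulation-based tests use cohorts of 200 videos (recovery, jitter
monotonicity), 1,000 windows (distortion-fraction calibration), 5,000
replicates of 15×5 matrices (SEM CI coverage, within ±2 points of 95%),
and 2,000 replicates for the Bonett width check — sizes at which Monte
Carlo error is well inside the asserted tolerances. The jitter grid
(0/0.1/0.3/0.6 s) reuses one seed so all configurations share the same
underlying random draws; SEM monotonicity is then a common-random-numbers
comparison rather than a noisy one. Exactness assertions use relative
1e-9; float times round-trip through CSV bit-for-bit
(`float_precision="round_trip"` on read).
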