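# Methods

## Task and schedule generation

A dot-probe run consists of 280 trials: 80 per CS-containing condition
(CS+/CSn, CS−/CSn, CS+/CS−) and 40 neutral-only trials. Within each CS
condition the design is fully counterbalanced over target side × probe side ×
stimulus duration (100, 500 ms), giving 10 trials per cell; neutral trials
balance probe side × duration. Per-trial timing constants are fixation
500 ms, cue pair 100/500 ms, blank 50 ms, response window 2,000 ms, ITI
750 ms. "Pseudo-randomized" order is implemented as a seeded permutation with
runs of at most 2 consecutive trials of the same condition (the conventional
reading; the bound is configurable). For the CS+/CS− condition the designated
target side is the side holding the CS+; the CS− side is derived.

The conditioning schedule presents 16 CS+ and 16 CS− (run length ≤ 2), with
exactly `round(16 × 0.75) = 12` reinforced CS+; US onset is drawn uniformly
on 6–12 s after CS+ onset (16 s distension, co-terminating), ITI 20 s. A
reinforcement rate whose product with the CS+ count is non-integral is
rejected rather than silently rounded.

The printed run durations of the original protocol are not derivable from
the stated per-trial constants; the package therefore reports durations
computed from its own constants (`dotprobe_run_duration_min`) and makes no
claim about the published figures.

## Synthetic cohort

Subject covariates (BMI, trait anxiety, positive/negative affect, pain
catastrophizing/coping, pain threshold) are drawn per sex from truncated
normals. Defaults reproduce the study sample's per-sex means, with SD
recovered from the printed SEM at n = 32; truncation bounds are the BMI
inclusion window (18–30) and instrument score ranges. The truncated normal's
location is solved (Brent) so the *truncated* mean equals the configured
mean; sample means therefore converge to the configured values. Trait
z-scores used for effect injection are taken against the truncated
distribution's actual moments, so "per SD of trait" refers to the SD
actually realized — without this, strongly floor-bounded scores such as
negative affect would dilute injected effects.

Reaction times are ex-Gaussian: RT = N(μ, σ) + Exp(τ) with defaults
μ = 350 ms, σ = 40 ms, τ = 60 ms (plausible dot-probe range; the RT noise
family and magnitudes are scenario parameters, not estimates from any
dataset) plus a subject-level offset N(0, 30 ms). Attentional effects are
injected on population cell means: for a design cell with engagement shift E
and disengagement shift D, congruent-trial means are lowered by E and
incongruent-trial means by D relative to neutral, so the scored indices
equal E, D and E − D in expectation — parameter recovery is exact by
construction rather than mediated by a latent attention process. Shifts can
be constant or linear in a trait z-score, per phase/condition/duration/sex.

Premature (< 100 ms, uniform), missing and false responses occur as mutually
exclusive per-trial events with default rates 2% / 1% / 2% (rates must sum
below 1), reproducing the categories the cleaning stage removes.

For moderation scenarios two helpers pin the effect scale analytically:
`index_change_noise_sd` gives the trial-sampling SD of a baseline→test index
change score (≈ 22.8 ms for avoidance at 80 trials/condition under default
noise), and `trait_slope_for_interaction_beta` converts a target
*standardized sex × trait interaction coefficient* (the scale on which such
regressions are conventionally reported) into the required ms-per-SD slope,
via b = s·β·√(2/(1−β²)) for sex coded 0/1 with balanced groups.

What the generator does **not** emulate: sequential effects and practice or
fatigue drifts, RT autocorrelation, non-stationary attention, speed–accuracy
trade-offs, or subject-level variance heterogeneity of the indices beyond
trial sampling. Passing recovery and calibration tests therefore shows the
analysis chain is correct and calibrated under these idealized conditions,
not that real dot-probe data satisfy them.

Valence ratings use the −100 (very pleasant) … +100 (very unpleasant) scale:
all cues center at 0 at baseline; from post-conditioning the CS+ shifts
positive (default +40) and the CS− negative (default −30), persisting
through the post-test rating. Contingency ratings draw around the study's
per-sex means (CS+ ≈ 77/82%, CS− ≈ 16/11%), clipped to [0, 100]. Raw VAS
marks on the physical 0–200 mm scale map linearly via `raw − 100`, with the
0 mm end fixed as "very pleasant" (the orientation is a documented
convention; the instrument leaves it open).

## RT preprocessing

Cleaning removes, in order of precedence: missing responses, premature
responses (RT < 100 ms, strict), and false responses (response side ≠ probe
side). RTs above the 2,000 ms response cap are a schema violation. The
exclusion log is additive (categories always sum to the input count) and the
filter is idempotent.

Cell means use the side-cell formulas
RT_congruent = (RT_tldl + RT_trdr)/2, RT_incongruent = (RT_tldr + RT_trdl)/2,
RT_neutral = four-cell average — i.e. the unweighted mean of per-side cell
means, which equals the plain trial mean when cells are balanced; a
trial-weighted variant is available. The CS+/CS− condition is aggregated
twice, once per designated target. Congruency is undefined for neutral
trials, which feed only RT_neutral — except for the response-slowing control
analysis, where neutral trials are split by pseudo-congruency (probe at the
left-placed vs right-placed cue), mirroring the two averaging arms.

Outlier screening operates on subject-level cell means *across subjects*
within each phase × condition × duration × congruency cell (screening after
mean calculation; a trial-level switch is not provided because indices are
defined on means): values strictly outside Tukey fences Q1 − 1.5·IQR /
Q3 + 1.5·IQR are flagged in exactly one pass (no re-fencing on the retained
values). Quartiles interpolate linearly between order statistics; the method
is pinned and configurable for reproducibility. Flagging is cellwise by
default — a flagged mean propagates missingness only into the indices that
use it — with a listwise option that drops the whole subject.

## Bias indices and change scores

avoidance = RT_inc − RT_con (negative = avoidance), engagement = RT_neu −
RT_con (positive = capture), disengagement = RT_neu − RT_inc (negative =
difficulty disengaging). The identity avoidance = engagement − disengagement
holds exactly on every cell. Change scores are test − baseline per subject ×
condition, averaged over the two durations by default (regression outcomes
are reported per condition without a duration factor; a per-duration option
exists). Report tables give mean ± SEM per condition × phase × sex, both
duration-collapsed and per duration.

## Mixed-design repeated-measures ANCOVA

The univariate (contrast) decomposition: subject × within-cell responses are
projected onto orthonormal within-subject contrasts (Kronecker products over
factors; the unit vector for factors not in the effect). Each projected
column is regressed on the between-subjects design — intercept, grand-mean
centered covariate, sum-coded between factor — and sums of squares are
pooled across columns; the covariate enters every stratum with a homogeneous
slope (no covariate × sex term), which is what makes within effects
covariate-adjusted. Per within-effect stratum with q columns,
Greenhouse–Geisser ε = tr(S)²/(q·tr(S²)) from the residual covariance S
(clipped to [1/q, 1]); ε = 1 exactly for two-level factors. GG-corrected
p-values multiply both dfs by ε; effect sizes are partial η² =
SS_effect/(SS_effect + SS_error). Subjects with incomplete within-cells are
removed listwise with a warning; a constant covariate is dropped with a
warning, reducing the model to a plain ANOVA.

The decomposition is verified in the test suite against a brute-force
cell-means oracle (machine precision on a 4-subject 2 × 2 × 2 design) and
cross-checked against an independent implementation (pingouin) for F, p and
partial η²; the ε estimate pools the *residual* covariance after removing
the between design (the SPSS-style convention), which can differ in the
third decimal from implementations that pool marginally.

Post-hoc pairwise contrasts decompose an interaction into two-sample t-tests
(between factor, on covariate-adjusted values) or paired t-tests (within
factor) with Bonferroni correction over the explicit contrast family;
family definitions are whatever set of contrasts is requested, and are
logged in the output rather than implied.

The response-slowing control is a cue (CS+/CSn vs CSn/CSn) × congruency
ANCOVA on raw cell-mean RTs per stimulus duration, with sex and BMI handled
as above.

Degenerate paired comparisons are reported, not masked: constant nonzero
differences give signed-infinite t with p = 0; all-zero differences give
t = 0, p = 1.

## Moderation regression ladder

Per candidate predictor of a change score: fit outcome ~ sex + predictor +
sex×predictor; if the overall model F is not significant at α = .05, remove
the interaction; if still not significant, remove the main effect, keeping
sex. Model-level significance (not coefficient significance) drives the
transitions; coefficient p-values only trigger the per-sex follow-up fits.
Sex is coded 0 = female / 1 = male, uncentered, the interaction is the raw
product, and standardized betas are b·SD(x)/SD(y) with the interaction
standardized as the z-score of the product — so betas can exceed 1 under
the collinearity this coding induces, which is accepted as the reporting
convention. Several candidates may enter one ladder (all interactions are
removed before all main effects). Collinear or zero-variance terms raise an
error naming the term. No correction is applied across candidate ladders by
default; a Bonferroni flag exists at the family level of the post-hoc
machinery for users who want one.

## Power analysis

For the between-groups effect of a g-group, m-measurement repeated-measures
design, power uses the noncentral F with df = (g−1, N−g) and noncentrality
λ = f²·N·m·ε/(1 + (m−1)ρ). The repeated-measures correlation ρ defaults to
0.5 — the conventional assumption, which jointly reproduces a critical
F ≈ 3.99 at df (1, 64), a required balanced N of 66 and achieved power 0.95
at f = 0.338 (f = d/2 = 0.676/2 under the two-group convention). Required N
is the smallest multiple of g meeting the target power, found by upward
scan (power is monotone in N).

## Problem sizes and numerical conventions

Simulation-based checks use the design's own sizes: 32 subjects per sex,
280 trials per run, both phases. The type-I calibration runs 500 replicate
cohorts of the full pipeline (rejection rate of the phase × sex interaction
judged against a 99% binomial interval around .05); moderation recovery runs
300 replicates at a standardized interaction coefficient of 0.5; parameter
recovery judges group means against ±3 SEM of the estimate. All randomness
flows from single integer seeds through one generator per entry point in a
fixed call order, so identical seeds give byte-identical outputs, including
the pipeline's CSV artifacts (provenance JSON records seed, config and
content hashes). Orthonormal contrasts fix signs deterministically; quartile
interpolation, IQR multiplier (1.5), the premature cutoff (100 ms), response
cap (2,000 ms) and α (.05) are config values with the defaults above.

## Known limitations

- The ANCOVA covers balanced crossed within designs with one between factor
  and one covariate; no mixed-effects/multilevel alternative is provided.
- Cell exclusion after outlier flagging can unbalance within-cells, which is
  resolved by listwise deletion in the ANCOVA (logged), not imputation.
- The generator's independence assumptions (above) make calibration results
  idealized; real dot-probe data may show heavier tails and drift.
- The printed protocol durations and the original study's Tables 2–4 F
  statistics are not reproducible without the raw data and are not targets
  of this package.
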