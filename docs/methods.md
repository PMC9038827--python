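# Methods

## Data model and filtering

A trial table has one row per naming trial (`study, participant, item,
condition, rt, correct`), condition ∈ {related, unrelated}, RT in ms.
Filtering follows standard PWI practice: correct responses only, then
exclusion of any unit (participant or item) with fewer than
`min_per_condition` correct trials in either condition. The default
threshold is 5 — one trial per quintile is the logical minimum for a
five-bin analysis — and is configurable; real studies have used both
stricter and looser rules.

No RT trimming is applied by default at the data-loading layer; an
optional `[lo, hi]` window (`trim_rt`) is available. The *simulation
study* (below) does apply a 400–2000 ms window by default — see
"Simulation study".

Correctness is never assumed: a table without a `correct` column
cannot pass `filter_correct` and the caller must decide.

## Delta plots

Per unit and condition, RTs are stably sorted and rank j (0-based, n
values) is assigned to bin ⌊j·k/n⌋, k = 5 by default. This rule is
deterministic, keeps every bin non-empty for n ≥ k, and makes bin
sizes differ by at most one. Ties retain input order (stable sort), so
re-running on a permuted table gives identical quintile means.

The per-quintile delta is related minus unrelated quintile mean; the
combined mean is their average. The segment slope is
(Δ_b − Δ_a)/(combined_b − combined_a) with (a, b) = (1, 2) for the
fastest and (4, 5) for the slowest segment; the across-condition
average in the denominator follows standard delta-plot practice. A
zero denominator raises a degenerate-profile error and the unit is
dropped pairwise from any correlation (with n reflecting the drop)
rather than propagating a non-finite slope.

A unit's mean interference effect is the raw mean RT difference over
all of its correct trials, not the average of quintile deltas; the two
coincide only when both conditions have trial counts divisible by k.
The raw difference is the quantity a mixed-model fixed effect
estimates, so it is the default.

## Per-study estimates

Per-quintile study effects are the participant-summary estimator: the
mean over participants of the per-participant quintile delta, with
SE = sd/√n (sample sd, ddof = 1). Under a balanced design this is an
unbiased estimator of the condition contrast at each quintile. It is
*not* the nested mixed-effects estimator some analyses use; its SEs
will generally differ from model-based ones, which is why per-study
SEs feed a random-effects meta-analysis rather than being interpreted
alone.

Slope–effect correlations are plain Pearson correlations across units,
carried to the meta-analysis as Fisher z = atanh(r) with the
large-sample SE 1/√(n − 3); n < 4 units is an error, and |r| = 1
(infinite z) is reported but refused as a meta-analysis input.

## Random-effects meta-analysis

Model: y_i | θ_i ~ N(θ_i, σ_i²), θ_i ~ N(θ, τ²), θ ~ N(0, A²),
τ ~ half-N(0, B²), with σ_i fixed at the supplied SEs. Defaults
A = B = 100 for millisecond-scale effects and A = B = 10 for Fisher-z
correlations — weakly informative on either scale (a 100 ms pooled
effect or a z of 10 are far outside plausibility).

The sampler collapses θ_i analytically (marginally y_i ~ N(θ, σ_i² +
τ²)) and alternates a conjugate normal draw for θ with a stepping-out/
shrinkage slice-sampling update for τ ≥ 0. Collapsing removes the
funnel that afflicts samplers of the full hierarchy as τ → 0, so the
fixed-effect limit mixes as well as the heterogeneous case. The slice
width is max(B, sd(y), median σ_i)/2: oversized widths only cost a few
extra shrinkage steps, undersized ones cripple traversal. Four chains
by default, seeds spawned deterministically from one root seed via
`numpy.random.SeedSequence`; summaries are only emitted when
split-R̂ < 1.01 and bulk ESS ≥ 400 (computed with arviz), with one
automatic retry at doubled draw counts before a loud convergence
error. Credible intervals are equal-tailed (2.5/97.5 percentiles).

Shrinkage note: with few studies and a weakly identified τ the pooled
mean is pulled toward the prior mean. A single study, however precise,
does not pin θ unless τ is constrained — the fixed-effect behaviour is
recovered as B → 0 and is verified against the conjugate closed form
in the tests.

Bayes factors for θ = 0 use the Savage–Dickey density ratio:
prior density at zero over a Gaussian-KDE estimate of the posterior
density at zero. KDE tail estimates are unreliable, so any ratio whose
posterior density at zero falls below 1/1000 of the prior density is
reported as the bound "> 1000" instead of an unstable point value.
Very large BFs should be read as "overwhelming", not quoted to
precision.

The prior-sensitivity sweep refits under a list of prior specs with a
common seed policy and flags stability when pooled means agree within
0.1 × the smallest study SE. Note the flag concerns the pooled mean
only: τ estimates can differ substantially between specs while the
pooled mean stays put (with homogeneous SEs the weighting is unchanged).

## Simulator

`simulate_experiment` emulates a well-powered PWI experiment: 100
participants × 50 items × 2 within-unit conditions, fully crossed,
every cell once, all trials correct. A trial RT is
Normal(μ_cond + b_p + b_i + e, σ_cond) + Exp(τ_cond) with b_p ~
N(0, 100), b_i ~ N(0, 70) shared across conditions, and per-trial
residual e ~ N(0, 100) — i.e. all adjustments enter through the normal
component's mean. Condition parameters (related 578/68/219, unrelated
570/53/202 ms) are method-of-moments estimates from pooled empirical
PWI data; the related condition is slower *and* more variable, which
is the entire mechanism. Non-positive draws are resampled (probability
< 10⁻⁶ at defaults). Identical seeds give byte-identical tables.

What the generator does not emulate: error trials and their removal,
RT-trimming artifacts of voice keys, item repetitions, SOA
manipulations, attention lapses, and any inhibition process. Passing
tests on this synthetic data therefore show that the analysis chain is
correct and that the slope–effect correlation needs no inhibition —
they do not validate distributional assumptions of real data sets.

The method-of-moments ex-Gaussian estimator uses τ̂ = (m₃/2)^{1/3}
(clamped to 0 when the sample is left-skewed), σ̂ = √(var − τ̂²)
(clamped to 0.01·sd, flagged, when the shape is incompatible), μ̂ =
mean − τ̂. σ̂ is the noisiest of the three: sampling error in m₃ and
the variance propagates into σ̂ amplified by var/σ² (≈ 11 at the
default parameters), so σ̂ needs ~10⁵ observations for ~3% precision
where μ̂ needs far fewer.

## Simulation study

`replicate_table5` runs the whole chain — simulate, profile by
participant and by item, correlate segment slopes with mean effects —
over 100 independent replications (seeds spawned from one root seed)
and reports replication means ± SEs of the four correlations, plus the
replication-mean interference effect with a near-zero flag (|effect| <
2·SE) for symmetric configurations.

The analysis applies a 400–2000 ms response-time window by default.
Empirical PWI analyses operate on RTs in essentially that range
(voice-key artifacts below, timeouts above), and the reference
correlations this study reproduces were obtained under it; without the
window the simulated ex-Gaussian tail extends far beyond anything an
experiment would retain (≈ 4% of trials fall outside the window at the
default parameters) and the fastest-segment correlations drop by
about 0.15 while the slowest-segment ones barely move. The window is a
parameter (`rt_window`, disable with `None` or `--rt-window 0 0`).

Reference values for the four correlations come from a single
simulated data set; their single-run sampling SD at this design size
is ≈ 0.08–0.14, which replication means ± SE make explicit.

## Pipeline

`run_pipeline` executes filter → exclusion → profiles → study effects
per study, then one meta-analysis per distinct quantity (five quintile
effects by participant; slowest/fastest correlations by participant
and item — nine analyses in the full layout). All randomness flows
from one root seed recorded in a JSON manifest along with input/output
SHA-256 digests, per-stage row counts and exclusion counts; rerunning
with the same seed and inputs reproduces the output files
byte-for-byte. Per-study failures abort by default (naming the study)
or are skipped under `keep_going`.

## Problem sizes in the test suite

The suite runs the simulation study at its full design size (100
replications of 100 × 50 × 2), the parameter-recovery calibration at
200 synthetic meta-analyses (θ = 20, τ = 10, K = 50, SE = 2) with
reduced draw counts (4 × 350 after 250 warmup, ESS gate 300 — the
collapsed sampler's autocorrelation is near zero, so this retains
stable summaries), and moment checks at 10⁵–10⁶ draws. These sizes
give Monte-Carlo error comfortably below every asserted tolerance.

## Known limitations

- The per-study quintile-effect SEs ignore item-level clustering; a
  crossed mixed model would give different (usually wider) SEs.
- The Savage–Dickey estimator shares the KDE's boundary and tail
  limitations; BFs are bounded rather than extrapolated.
- The τ posterior is weakly identified for K ≲ 5 studies; summaries
  are honest but prior-dominated there.
- Fisher-z SEs assume bivariate normality of (slope, effect) pairs;
  heavy-tailed slope distributions (possible with near-degenerate
  segment denominators) inflate the true sampling variance.
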