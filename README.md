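# pwimeta

Distributional analysis of semantic interference in picture naming:
delta-plot (Vincentile) statistics, Bayesian random-effects
meta-analysis, and an ex-Gaussian simulator that shows the
"inhibition" correlation arising with no inhibition mechanism at all.

## The scientific problem

In the picture-word-interference (PWI) task, naming a pictured object
takes longer when a superimposed distractor word is semantically
*related* to the picture than when it is *unrelated*. The difference
(related − unrelated RT) is the **semantic interference effect**.

Delta-plot analyses ask how this effect evolves over the RT
distribution: per participant (or item) and condition, RTs are sorted
into five quintiles, the per-quintile condition difference
delta(q) is computed, and the slope of a delta segment between
quintiles *a* and *b* is

```
slope(a, b) = (delta(b) − delta(a)) / (mean(b) − mean(a))
```

with mean(q) the across-condition average quintile mean. Under the
activation-suppression hypothesis, selective inhibition builds up
within a trial, so a *flatter* slowest-segment slope (quintiles 4–5)
has been read as *more* inhibition, and the positive correlation
between that slope and a unit's mean interference effect as an
inhibition signature.

`pwimeta` implements that full analysis chain, plus two inferential
layers:

- **Random-effects meta-analysis** of study-level effects
  y_i ~ N(θ_i, σ_i²), θ_i ~ N(θ, τ²), with weakly informative priors
  θ ~ N(0, 100²) and τ ~ half-N(0, 100²) on the millisecond scale
  (N(0, 10²) / half-N(0, 10²) for Fisher-z correlations, entered with
  SE 1/√(n−3)). Sampling is by a collapsed Gibbs sampler (θ_i
  marginalised; conjugate update for θ, slice sampling for τ) gated on
  split-R̂ < 1.01 and bulk ESS ≥ 400; Bayes factors against θ = 0 use
  the Savage–Dickey density ratio.
- **A no-inhibition simulator**: ex-Gaussian RTs (related μ=578, σ=68,
  τ=219; unrelated μ=570, σ=53, τ=202, in ms) with crossed random
  intercepts for 100 participants (SD 100), 50 items (SD 70) and
  per-trial residual error (SD 100). Because the slower condition has
  larger σ and τ, the interference effect grows over the distribution
  — and the slope–effect correlation appears even though nothing in
  the generator inhibits anything.

## Worked example

```python
from pwimeta import (SimulationConfig, simulate_experiment, unit_profiles,
                     segment_slope, slope_effect_correlation, replicate_table5)

table = simulate_experiment(SimulationConfig(seed=1))   # 10,000 trials
profiles = unit_profiles(table, unit_kind="participant")
print(len(profiles), "participants")
print(tuple(round(float(d), 1) for d in profiles[0].deltas))  # per-quintile effect, ms
res = slope_effect_correlation(profiles, "slowest")
print(round(res.r, 3), round(res.z, 3))
```

prints

```
100 participants
(53.4, 43.4, 66.5, 103.2, 148.1)
0.5 0.55
```

— one simulated participant's interference effect per quintile (rising
toward the slow tail), and a positive slope–effect correlation
(r = .50, Fisher z = .55) across participants in a single synthetic
experiment in which no inhibition was simulated.

The replication-level result (the simulator's headline output):

```python
result = replicate_table5(SimulationConfig(seed=0), n_replications=100)
print({k: round(v, 3) for k, v in result.as_dict().items()})
# {'r_slowest_participants': 0.406, 'r_fastest_participants': 0.306,
#  'r_slowest_items': 0.405, 'r_fastest_items': 0.337}
```

All four correlations are reliably positive: the putative inhibition
signature is reproduced by distributional properties alone.

The same steps are available from the shell:

```sh
pwimeta simulate --seed 1 --out trials.csv
pwimeta profiles trials.csv --out profiles.csv
pwimeta effects trials.csv --out effects.csv
pwimeta meta effects.csv --out summaries.csv --seed 1
pwimeta table5 --seed 0 --replications 100 --out table5_out
pwimeta run-all --studies 3 --seed 1 --out full_run
```

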