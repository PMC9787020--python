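# herdlab

Headless simulation and measurement pipeline for a collaborative
search-and-corral task: three players roam a 500 × 500 m arena to locate,
corral, and contain a set of autonomous target agents (TAs) inside a
10 m containment disc. Teams succeed by keeping every TA contained for
5 continuous seconds within a 300 s trial.

The package is aimed at researchers studying division of labor and
behavioral structure in collaborative search. It provides:

* **Simulator** — TA physics (1 Hz Brownian forcing up to 60 N,
  inverse-distance avatar repulsion capped at 450 N within 10 m, linear
  drag, 10 m/s speed caps) at 90 Hz, with scripted player policies whose
  sensing emulates the task manipulations: fog vs clear visibility
  (sensing radius), HUD vs compass (global vs local information), and
  9 vs 18 targets.
* **Fluctuation series** — per-player 5 Hz displacement-angle and
  head-orientation-change series, built by decimation with the first
  second removed.
* **DFA** — detrended fluctuation analysis with windows growing by a
  factor 1.2 from 5 samples up to 10% of the series length, 50% overlap,
  linear detrending. The slope α of log fluctuation vs log window size
  is ≈0.5 for white noise, ≈1.0 for 1/f noise, ≈1.5 for Brownian noise.
* **Search overlap** — per-player alpha-shape search polygons (convex
  hull fallback) and the proportion of the team's total search area
  covered by two or more players: 0 = cleanly partitioned, 1 = everyone
  searched the same ground.
* **Survival model** — log-logistic accelerated failure time (AFT)
  regression of trial duration, `log T = x'β + σW` with logistic `W`,
  with failed trials right-censored at the 300 s ceiling, maximum
  likelihood fitting, cluster-robust errors, and survival-curve
  prediction `S(t|x) = 1/(1 + (t/e^{x'β})^{1/σ})`.
* **Experiment pipeline** — seeded, fully reproducible batches over the
  2×2×2 emulated design with per-trial metrics, bootstrap summaries, and
  qualitative direction checks.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from herdlab import WorldConfig, PolicyConfig, run_trial, trial_metrics

world = WorldConfig()                       # 9 TAs, 300 s cap, 90 Hz
policy = PolicyConfig(strategy="partitioned_sweep", global_info=True)
log, outcome = run_trial(world, [policy] * 3, seed=0)
m = trial_metrics(log)
print(f"outcome={outcome} duration={log.duration:.1f}")
print(f"overlap={m['proportion_overlap']:.3f}")
print(f"dfa_disp={m['dfa_disp_mean']:.3f} dfa_head={m['dfa_head_mean']:.3f}")
```

```
outcome=success duration=225.5
overlap=0.133
dfa_disp=1.109 dfa_head=0.552
```

Three fully informed players sweeping disjoint 120° sectors contained
all nine targets after 225.5 s. They overlapped on only 13% of their
joint search area (labor well divided). Mean displacement-angle
DFA α ≈ 1.11 indicates strongly persistent, directed movement —
between 1/f structure and Brownian drift — and head-orientation
DFA α ≈ 0.55 sits just above uncorrelated scanning. Under fog with
compass-only information the same policies fail at the 300 s ceiling,
and shared-route search overlaps above 0.8.

The same stages are scriptable from the shell:

```sh
herdlab simulate --config config.yaml --trials 5 --seed 1 --out runs/
herdlab overlap  --in runs/trial_000.csv --out overlap.csv
herdlab dfa      --in series.csv --out dfa.csv
herdlab experiment --plan plan.yaml --out exp/
```

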