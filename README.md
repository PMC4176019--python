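# cardiofit

Fitting the parameters of a cardiac ionic model to an action potential (AP)
alone is ill-posed: very different combinations of channel conductances
produce near-identical isolated-cell APs, because only the *net* membrane
current shapes the voltage — a large influx cancelling a large efflux looks
exactly like a small influx cancelling a small efflux. The degeneracy
matters in tissue, where the membrane resistance R\_m sets how a cell
responds to gap-junctional source–sink currents. `cardiofit` implements a
multi-objective genetic algorithm that fits AP morphology *together with*
R\_m measured at a few voltages during the AP, for researchers who calibrate
ventricular myocyte models against patch-clamp data.

## What's inside

* **`cardiofit.ionic_model`** — the ten Tusscher–Noble–Noble–Panfilov (2004)
  epicardial human ventricular cell model (17 states, 12 currents, 16
  scalable parameters), numba-jitted Rush–Larsen integration (20 µs) with an
  LSODA cross-check path, plus an ohmic linear-leak membrane used as an
  analytic oracle.
* **`cardiofit.protocols`** — pacing, APD90, and the paired voltage-clamp
  R\_m protocol: from the same saved state, V\_m is stepped ±10 mV and held
  5 ms; R\_m = 20 mV / (I₊ − I₋), reported in mV/(pA/pF) (numerically
  GΩ·pF).
* **`cardiofit.objectives`** — the two normalized objectives
  f\_ap = mean[(V\_t − V\_f)²]/APA² and f\_rm = Σ|R\_t − R\_f|/R\_base
  (an mV-scale RMSE is carried alongside f\_ap).
* **`cardiofit.moga`** — NSGA-II-style elitist GA (crossover 0.8, mutation
  0.01, bounded genes, non-dominated sorting + crowding, chained restarts),
  fully deterministic given a seed.
* **`cardiofit.tissue`** — 1D monodomain cable (and a coarse 2D sheet mode)
  for electrotonic-coupling experiments.
* **`cardiofit.fixtures`** — packaged search bounds and published parameter
  sets, and a synthetic target generator (the original experimental rabbit
  recordings are unpublished, so targets are simulated from known
  parameters, optionally with multiplicative noise).

See `docs/methods.md` for the model equations' provenance, numerical
choices, and an honest account of which published numbers reproduce.

## Worked example

Pace the control model (3 s pre-pacing, cycle length 1 s) and summarize the
fourth beat:

```bash
$ cardiofit --seed 1 --outdir out simulate
{"resting_V_mV": -86.39, "peak_V_mV": 32.76, "apd90_ms": 275.11}
```

A diastolic potential of −86.4 mV and APD90 of 275 ms are the expected
epicardial values at this cycle length. Measure R\_m at three instants of
that beat (t = 3050 ms is mid-plateau, 3170 ms late plateau, 3320 ms
diastole), at both 5 and 10 ms delays:

```bash
$ cardiofit --outdir out measure-rm --times 3050,3170,3320
 time_ms  voltage_mV    rm_5ms   rm_10ms  percent_error
  3050.0   22.129482  7.963496  8.188742       2.828482
  3170.0    7.478087 26.302112 26.633660       1.260539
  3320.0  -86.109817  0.477871  0.478857       0.206395
```

R\_m (units mV/(pA/pF)) is small at rest where I\_K1 clamps the membrane,
and rises through the plateau as channels shut; the 5-vs-10 ms agreement
shows the fast gating transients have settled. Finally, a self-fit: build a
noiseless target from the control parameters (AP + R\_m at 22.57, 8.084,
−59.87 mV) and recover the eight bounded parameters with the GA
(population 30, three chained restarts of 10 generations):

```bash
$ cardiofit --seed 1 --outdir out fit --restarts 3 --generations 10
best RMSE = 0.1844 mV, f_rm = 1.154
```

The selected individual (least AP error on the final Pareto front)
reproduces the target AP to ~0.2 mV root-mean-square — visually
indistinguishable — with the recovered conductances written to
`out/result.json` and the per-generation history to `out/history.csv`.
Running with `--objectives ap` instead converges measurably more slowly and
returns far more variable parameters across seeds; that comparison is the
package's central property and is exercised statistically in
`tests/test_acceptance.py`.

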