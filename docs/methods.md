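# Methods

## The problem

Ionic models of the cardiac action potential (AP) are fit to recordings by
adjusting maximum channel conductances and Ca²⁺-handling rates until the
simulated AP matches a target. The fit is ill-posed: very different
parameter combinations produce near-identical isolated-cell APs, because a
large inward flux cancelling a large outward flux is indistinguishable — at
the level of net membrane current — from a small inward flux cancelling a
small outward flux. Those degenerate solutions are *not* equivalent in
coupled tissue, where the membrane's input resistance R_m governs how the
cell responds to gap-junctional source–sink currents. This package
implements a multi-objective genetic algorithm that fits AP morphology *and*
R_m sampled at a few voltages, which collapses much of the degeneracy.

## Cell model

The base model is the ten Tusscher–Noble–Noble–Panfilov (2004) epicardial
human ventricular myocyte: 17 states (V_m, 12 Hodgkin-Huxley-type gates,
Ca_i, Ca_SR, Na_i, K_i), 12 membrane currents, currents as densities in
pA/pF, dV_m/dt = −(I_ion + I_stim). Sixteen parameters are scalable
(`ParameterVector`): nine conductances (g_Na, g_bNa, g_CaL, g_bCa, g_to,
g_Kr, g_Ks, g_K1, g_pK), the Na/K-pump and Na/Ca-exchanger turnover rates
(k_NaK, k_NaCa), the sarcolemmal Ca-pump rate (k_pCa), and four SR fluxes
(a_rel, c_rel, V_leak, V_max_up). Control values are the published ones.
Two transcription quirks worth knowing: the published resting state is only
quasi-steady (V_m drifts < 1 mV over a quiescent second), and the fCa gate's
steady state legitimately exceeds 1 (max ≈ 1.048 at low Ca_i), so the
"gates in [0,1]" invariant is enforced for the other eleven gates only.

A single-state linear-leak membrane (I_m = g·(V_m − E)) is included as an
analytic oracle: every protocol run against it must return R_m = 1/g
exactly, independent of onset, delay and step size.

### Integration

Two interchangeable integrators sit behind the model interface:

* `rl` (default): Rush–Larsen exponential updates for the twelve gates and
  forward Euler for V_m and concentrations, fixed step 20 µs — the scheme
  published with the model itself, numba-jitted. The m-gate time constant
  falls below 1 µs near rest, which the exponential update absorbs exactly;
  explicit Euler on the gates would not be usable at this step.
* `adaptive`: LSODA with rtol 1e-6, atol 1e-8 and segment splitting at
  stimulus edges.

The two agree to better than 0.15 mV over a full paced beat (and 20 µs vs
5 µs Rush–Larsen agree to < 0.05 mV), so the fixed-step path — roughly two
orders of magnitude faster, ~0.1 s per 4-second paced run — is the default
for optimization work, with the adaptive path retained as the numerical
cross-check.

## Protocols

**Pacing.** Stimuli of −52 pA/pF for 1 ms at cycle length 1000 ms, starting
at t = 0; 3 s of pre-pacing ("run to approximate steady state") and the
following full beat is the analysis window, resampled at 1 ms. The pacing
protocol, including the timing that puts the analysed beat at 3000–4000 ms,
is a package convention chosen so clamp-onset times in the 3020–3320 ms
range fall inside the fourth beat.

**R_m measurement.** At the chosen instant the state is saved; two branches
are launched from that identical state with V_m stepped to ±10 mV around the
instantaneous voltage and held for 5 ms (V_m fixed ⇒ no capacitive current;
all other states keep evolving). The total ionic current is read a fixed
delay (default 5 ms) after onset, and

    R_m = (V₊ − V₋) / (I₊ − I₋) = 20 mV / (I₊ − I₋),

reported in mV/(pA/pF) (numerically GΩ·pF; on a 150 pF cell, 1 mV/(pA/pF)
is 6.7 MΩ). Published compilations of such measurements are inconsistent about
units, so this convention is stated wherever values are printed. Voltage-specified onsets
resolve on the baseline trace to the *last* downward crossing after the AP
peak: the epicardial spike-notch transient crosses plateau-level voltages
once on the way down to the notch, and the last crossing is the one on the
dome/repolarization limb. An upstroke phase selector exists for
completeness. Onsets the AP never reaches raise a no-crossing error (and
count as worst-case during optimization, see below).

**APD90** is measured from maximum dV/dt to the interpolated crossing of
peak − 0.9·(peak − rest), with rest taken at the trace start.

## Objectives

For a target trace V_t and candidate trace V_f on a common 1-ms grid over
one cycle, with APA the AP amplitude of the *control* parameterization:

    f_ap = mean[ (V_t − V_f)² ] / APA²        (dimensionless)

The mV-scale RMSE of the same residual is carried alongside every
evaluation, because fit quality is usually quoted in mV; the algebra of the
dimensionless form was chosen (mean of squared normalized residuals) so
that both numbers describe one residual. For the n target R_m points,
normalized by the base-model R_m at the same voltage:

    f_rm = Σᵢ |R_t,i − R_f,i| / |R_base,i|    (dimensionless)

Failed simulations (no AP, diverged integration) receive the penalty pair
f_ap = f_rm = 10⁶, dominated by any viable individual, so the optimizer
never crashes on a bad parameter set. A target R_m voltage the candidate AP
never reaches contributes as if the fitted R_m were zero.

## The genetic algorithm

NSGA-II-style elitist multi-objective GA over a fitted subset of the
parameters, each gene bounded by its physiological range. Defaults follow
the published protocol: population 100 (30 in the desk-scale experiments),
crossover rate 0.8, mutation rate 0.01 per gene, termination at a
generation cap (100 default) or wall-time limit (86 400 s). Ranking is
Deb's fast non-dominated sort, diversity is crowding distance, parents are
chosen by binary tournament on (rank, crowding), and survivors are the best
N of parents ∪ children. The selected solution is the first-front member
with least f_ap (ties by f_rm, then index). With AP-only objectives the
same machinery runs on the single objective.

Operator details (not fixed by the published protocol; chosen here after
measuring convergence on the self-fit problem):

* **Crossover** is a per-parameter arithmetic blend α·a + (1−α)·b with
  α ~ U(−0.5, 1.5), clipped to bounds. A purely interpolating blend
  (α ∈ [0,1]) shrinks the population hull every generation and measurably
  stalls on the correlated-conductance ridge of this problem
  (best RMSE ~0.7 mV at population 30 × 30 generations vs ~0.4 mV with the
  extended blend, same budget).
* **Mutation** adds zero-mean Gaussian steps with σ annealed geometrically
  from 5% to 0.1% of each bound's width across the run and clips to bounds
  — coarse exploration early, fine refinement late, the fixed-step analogue
  of the adaptive-step mutation used by common GA toolboxes.
* **Restarts** chain runs, each later run's initial population containing
  the previous best verbatim plus fresh uniform random individuals; the σ
  annealing restarts with each run. Fresh full-range diversity measurably
  outperforms a local Gaussian cloud around the seed here (0.18 vs
  0.36 mV at an equal 30-generation budget), because the blend crossover
  feeds on population spread. The desk-scale self-fit protocol is 3
  restarts × 10 generations at population 30.

Determinism: one seeded `numpy` generator drives initialization and all
operators; evaluation is deterministic; the evaluation backend (pluggable
`map_fn`, e.g. joblib) must preserve submission order, so concurrency never
changes results. Identical (seed, config, target) reproduce a run exactly.

## Synthetic targets

The experimental recordings the method was originally applied to are
unpublished, so targets are generated from known parameters: pace, take the
final beat at 1 kHz, measure R_m at the requested voltages through the same
clamp protocol, and optionally apply multiplicative Gaussian noise
(relative SD per voltage sample and per R_m point). The generating
parameters are stored for recovery scoring. The default self-fit voltages
are 22.57, 8.084 and −59.87 mV; "experiment-like" bundles use 4–5 points
spanning plateau to rest (24, −1, −23, −28, −81 mV and 32, 28, −21,
−78 mV). What this generator does *not* emulate: measurement hardware
artifacts (switch-clamp chopping, capacitive transients, junction
potentials), beat-to-beat variability, and model-form error (the target
comes from the same model family being fitted). Passing self-fit tests
therefore demonstrates algorithmic correctness and identifiability gains,
not robustness to model mismatch.

## Tissue

A 1D monodomain cable demonstrates coupling effects: explicit operator
splitting (forward-Euler diffusion on V_m, then the jitted ionic step per
node), 100 µm nodes, 25 µs steps, longitudinal intracellular conductivity
0.174 S/m. The surface-to-volume ratio (1400 cm⁻¹) and specific capacitance
(1 µF/cm²) are not cell-model parameters and are exposed in the config;
they give an effective diffusivity D = σ/(χC_m) ≈ 1.24·10⁻³ cm²/ms and a
conduction velocity of ~65 cm/s. The construction-time stability check
enforces D·Δt/Δx² ≤ ½. Boundaries are zero-flux in conservative
finite-volume form (the discrete diffusion operator conserves total
voltage). Nodes start from the single-cell pre-paced state; one edge (or
center) stimulus launches a wave; APD90 is read at an interior node and
conduction velocity from two interior activation times. A coarse 2D sheet
mode (≥ 200 µm, center stimulus, anisotropic σ_l/σ_t = 0.174/0.019 S/m)
exists for sheet-level questions; it is a plain-Python loop intended for
qualitative checks only.

Grid refinement (100 µm/25 µs → 50 µm/6.25 µs) changes interior APD90 by
< 2%. Note that the refined step obeys the stability bound; halving dx at
fixed dt does not.

## Reproduction notes and honest discrepancies

Desk-scale problem sizes used throughout (package choices): pacing runs of
4 s; GA experiments at population 30 with a total budget of 30 generations;
the identifiability comparison at population 16 × 10 generations over 10
seeds; tissue on a 1 cm (tests: 0.3 cm) cable.

Reproducing the originally reported experiments with this faithful transcription of the
2004 epicardial model succeeds in part and fails honestly in part:

* The R_m-protocol table reproduces at rest and through the early/mid
  plateau (values within ~3–9%), and the mean 5-vs-10-ms delay difference
  excluding the first two plateau points matches (≈1.2% vs the printed
  1.1%). But the originally reported single-cell trace has a deeper notch, a ~10 ms
  longer plateau, and large *positive* R_m through phase 3, whereas the
  published 2004 model — verified here against an independent adaptive
  integrator and its own published APD — exhibits an ICaL-window
  negative-slope region there (our R_m peak has the same magnitude, ~147
  vs ~149, at a different voltage). Longer pre-pacing, step refinement,
  stimulus variants and voltage-matched onsets do not reconcile this; the
  original single-cell implementation appears to differ
  in late-plateau conductance.
* Consistently with that, the two published "same AP, different parameters"
  sets reproduce their near-identical single-cell APs (APD90 within ~2%)
  but show similar — not ten-fold different — R_m profiles here, and
  correspondingly the dramatic tissue-coupling divergence (−45% APD for one
  set) does not occur in our cable or coarse sheet (both sets stay within
  ~2% of their single-cell APD at normal and 10×-reduced coupling). The
  coupling *machinery* (decoupled-limit equivalence, CV scaling with
  conductivity) is verified by its own oracle tests.

These are findings about the reproducibility of the original report from its published
ingredients, not about the fitting method, and the corresponding checks are
left failing rather than loosened.

## Known limitations

* Only the 2004 epicardial variant ships; the model interface is pluggable
  but no second biophysical model is included.
* The GA evaluates serially by default; the pluggable backend parallelizes
  but numba-jitted workers pay a per-process compile cost.
* The cable integrator is implemented for the TNNP kernel only.
* Bounds for the eight parameters outside the packaged search table default
  to nothing — callers must supply bounds to fit them.
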