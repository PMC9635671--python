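# aletrack

Analysis of high-throughput adaptive laboratory evolution (ALE) experiments
on solid-agar colony arrays, together with a synthetic serial-transfer
evolution simulator that provides ground truth for every analysis stage.

## The scientific problem

In colony-array ALE, thousands of microbial populations (for example, the
strains of a yeast single-gene deletion collection) are evolved in parallel
under a selection pressure: each population repeatedly expands from a
~5 × 10⁴-cell bottleneck to 2–4 × 10⁶ cells over a 72 h batch cycle, is
robotically subsampled onto a fresh plate, and is imaged throughout so that
a population-size growth curve is available for every colony in every
cycle.  Over ~19 cycles (~100 generations), each population's doubling time
*D* under stress falls as beneficial mutations sweep.  The analysis
questions are:

* how fast does each population adapt (its **adaptation trajectory**,
  doubling time vs cumulative generations)?
* does a strain's **preadaptation fitness** (its doubling time under stress
  before adaptive mutations accumulate) predict how much it adapts — and
  which strains deviate significantly from that prediction?
* can the prediction be explained by **diminishing-return (global)
  epistasis** — the same beneficial mutation conferring a smaller absolute
  benefit in fitter genetic backgrounds?

## The model

Per colony and cycle, the maximum specific growth rate is the steepest
5-point ordinary-least-squares slope of log₂ cells vs time,

&nbsp;&nbsp;&nbsp;&nbsp;µ_max = max over windows of slope(log₂ N, t),&nbsp;&nbsp;&nbsp;&nbsp;D = 1/µ_max (hours per doubling),

after median-filter despiking and Gaussian smoothing; generations per cycle
are G = log₂(N_last/N_first).  Doubling times are spatially normalized
against nonevolving wild-type reference colonies placed at every fourth
plate position (bilinear interpolation of log₂ D over the reference grid).
Each population's (cumulative generations, D) points are smoothed with a
LOESS fit *f*, and the adaptation milestones are

&nbsp;&nbsp;&nbsp;&nbsp;A_g = f(0) − f(g)&nbsp;&nbsp;for g = 25, 50, 75 generations

(hours of doubling-time reduction; positive = faster growth).  The
statistical layer fits the regression **A_g ~ preadaptation D** across
strains (slope, R²), screens for strains adapting significantly
better/worse than predicted (one-sample t-tests on replicate residuals,
Benjamini–Hochberg FDR at q = 0.05), and quantifies global epistasis from
reconstruction experiments: the stress-specific benefit of a mutation in
background *b*,

&nbsp;&nbsp;&nbsp;&nbsp;Δ_b = (D_stress − D_basal)_background − (D_stress − D_basal)_reconstructed,

regressed on the background's stress doubling time.  In the simulator each
mutation class removes a fraction φ (its *rescue fraction*) of the
*remaining* stress-specific deficit, so the fitted diminishing-return slope
estimates φ.

## Worked example

Simulate a small experiment (24 strains × 3 replicates on one 96-position
plate, 19 cycles) and analyse it end to end:

```sh
$ cat > sim.yaml <<'YAML'
n_strains: 24
replicates_per_strain: 3
plate_rows: 8
plate_cols: 12
n_cycles: 19
seed: 11
YAML
$ aletrack simulate --config sim.yaml --out data/ --seed 11
$ aletrack run --curves data/curves.csv --layout data/layout.csv --out results/ --seed 1
milestone  n_strains    slope  intercept  rsquared  replicate_repeatability_r2  n_significant_outliers
      A25         24 1.204908  -3.312898  0.951714                    0.697043                       0
      A50         24 0.874531  -1.856577  0.972243                    0.635266                       0
      A75         24 0.898774  -1.936319  0.945317                    0.447826                       0
```

Reading: across 24 strains, preadaptation doubling time explains ~95% of
the variance in adaptation at every milestone; the A75 slope ≈ 0.90 h of
doubling-time reduction per hour of preadaptation D, matching the dominant
mutation class's rescue fraction (φ = 0.9) — adaptation rescues a fixed
fraction of each strain's deficit, the signature of diminishing-return
epistasis.  No strain deviates significantly from the prediction, as
expected when the generative model contains no dedicated evolvability
effects.

The same analysis from Python, plus an epistasis reconstruction panel:

```python
import aletrack as at

cfg = at.SimulationConfig(n_strains=120, replicates_per_strain=6, seed=5)
strains, meas = at.simulate_adaptation_dataset(cfg)   # trajectory-level data
table = at.milestone_table(meas)                      # per-replicate A25/50/75

res = at.regress_adaptation(table, "A75")
print(res.summary())
# Fitness -> adaptation regression (A75 on preadaptation_D)
#   strains: 120
#   slope:     +0.8997 h/h
#   intercept: -2.0466 h
#   R^2:       0.9991

calls = res.call_outliers(q_threshold=0.05)           # BH-FDR outlier screen

mc = at.MutationClass("arr3-dup", 5e-6, rescue_fraction=0.6)
recon = at.simulate_reconstruction(strains, mc, noise_sd_h=0.15, seed=5)
fit = at.fit_diminishing_return(at.mutation_effects(recon))
print(fit.summary())
# Diminishing-return fit for arr3-dup (effect on background stress_D)
#   backgrounds: 120
#   slope:       +0.6493     <- recovers the rescue fraction 0.6
#   intercept:   -1.5794 h
#   R^2:         0.8646
#   mean effect: 1.394 h
```

`res.plot()`, `fit.plot()` and `AdaptationTrajectory.plot()` draw the
corresponding scatter-plus-regression figures.

Real curve tables (CSV columns `plate_id,row,col,cycle,time_h,cells`, with
a matching layout table) are ingested with the same `aletrack run` command;
an adapter for other deposited table layouts is a documented extension
point in `aletrack.io`.

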