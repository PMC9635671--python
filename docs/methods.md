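# Methods

This note documents the models, estimators, defaults and numerical choices
behind aletrack, and what the synthetic data do and do not establish about
real experiments.

## 1. Serial-transfer evolution model

Each population is a set of lineages (genotype, cell count, doubling time
*D*).  One batch cycle consists of:

1. **Deterministic exponential growth.**  Lineage *i* grows as
   *n_i(t) = n_i(0)·2^(t/D_i)* until the colony total reaches a final size
   drawn uniformly from 2–4 × 10⁶ cells (or the 72 h growth window, minus
   the lag, runs out).  The growth time for a mixture is solved with Brent's
   method on the monotone total-size function (closed form when a single
   lineage is present).
2. **Mutant seeding.**  For each lineage and each accessible mutation
   class, the number of new mutant cells is Poisson(rate per division ×
   number of divisions).  Mutants are appended at the end of the cycle;
   their own within-cycle growth is neglected (they are rare when they
   arise, so the error is second-order).
3. **Multinomial bottleneck.**  The next cycle's inoculum of 5 × 10⁴ cells
   is a multinomial sample of the end-of-cycle lineage frequencies — the
   only place drift matters at these population sizes, which is why a full
   division-by-division agent simulation is not used.

Per cycle the model records realized generations
*G = log₂(final/inoculum)* (which therefore falls in
[log₂ 40, log₂ 80] = [5.32, 6.32] under the default sizes) and the
effective mixture doubling time *D_eff = t_growth / G*.

**Mutation effects.**  A strain's doubling time under stress is
*D = D_basal + deficit*, with the stress-specific deficit drawn uniformly
from [0.5, 4.0] h across strains.  Acquiring a mutation of class *c*
removes the fraction φ_c (its rescue fraction) of the *remaining* deficit:

    D(genotype) = D_basal + deficit · Π_{c ∈ genotype} (1 − φ_c)

This is the minimal parameterization of diminishing-return (global)
epistasis: the absolute benefit of a mutation is proportional to how unfit
the background still is, the composed effect is independent of acquisition
order, and *D* can never undershoot the basal level.  A class can be
structurally inaccessible in a background that already lacks its target
gene (a fps1-like loss cannot arise in an fps1Δ background); such cases are
modeled as structural zeros.

**Default classes and rates.**  Three classes mirror the known
arsenite-exclusion routes in budding yeast: a strong importer-loss class
(φ = 0.9), a weak regulator-loss class (φ = 0.3) and an intermediate
exporter-duplication class (φ = 0.6), at 2 × 10⁻⁵, 1 × 10⁻⁵ and 5 × 10⁻⁶
per division.  The φ ratio puts the two loss classes' mean simulated
benefits in roughly a 3:1 ratio.  Because the experimental protocol
precedes selection with a recovery plate and stress-free precultures
(~25 generations of expansion), mutants arising there are near-neutral and
enter cycle 1 as standing variation at expected frequency rate ×
preculture generations (`preculture_generations = 25`, configurable).  The
rates were fixed once so that wild-type-like populations (deficit 1.34 h,
i.e. a wild type slowed from 2.27 h to 3.61 h) complete about half of
their final adaptation within 25 generations, the kinetic regime this kind
of experiment operates in; with strong selection and this mutation supply
the sweep is essentially complete by generation 50–60.

**Known kinetic limitation.**  Real wild-type populations keep accruing a
substantial minority (~19%) of their adaptation after generation 75; the
simulator's single dominant sweep finishes earlier and leaves almost no
slow tail.  The model contains no weak-effect mutational continuum, clonal
interference between plates, or media adaptation — analyses that depend on
late-tail behaviour should not be validated against it.

**Curve forward model.**  A rendered growth curve is the lineage-sum
exponential delayed by a lag (default 2 h), hard-capped at the cycle's
carrying capacity, sampled every 20 min for 72 h, with multiplicative
log-normal measurement noise (ln-scale sd 0.02) and isolated spikes
(probability 0.01/point, factor 2^U(1,3)).  The hard cap keeps the
exponential phase exactly log-linear, which the estimator oracles rely on;
real curves round off near saturation.  Injected spike indices are recorded
so QC bookkeeping can be audited.  Plates carry a smooth spatial field on
log₂ D (random plane plus low-frequency sinusoid, peak amplitude
0.07 log₂ h ≈ ±5%, configurable); nonevolving reference colonies occupy
the (even row, even col) member of every 2×2 quartet.

## 2. Growth-parameter estimation

Processing chain per curve: rolling-median despiking (window 5, shrinking
symmetrically at edges) → Gaussian smoothing of log₂ counts (σ = 1.5
points, kernel truncated at ±4σ and renormalized at edges) → µ_max as the
maximum 5-point OLS slope of log₂ cells vs time (ties broken by the
earliest window), D = 1/µ_max.  Generations use the despiked (not
Gaussian-smoothed) endpoints so a spiked endpoint cannot inflate G.  All
smoothing operates in log₂ space, where exponential growth is linear and
the slope is directly doublings per hour.

The maximum-over-windows estimator is noise-biased fast: under 2%
multiplicative noise it overestimates µ_max by the expected extreme of
~200 correlated window slopes, worth roughly −0.15 h at D = 2.5 h and
−0.5 h at D = 4.5 h with the default smoothing.  Stronger smoothing would
shrink this but smear the short exponential phase of fast growers into lag
and plateau.  Downstream analyses operate on doubling-time differences and
LOESS-smoothed trajectories, which absorb most of this bias; absolute
doubling times carry it.

QC thresholds are package choices (the upstream platform does not publish
its criteria): ≥ 10 points, ≥ 1 doubling of dynamic range (else
`no_growth`), ≤ 20% of points altered by the median filter by more than
0.5 log₂ units, endpoints not dropping more than 0.25 log₂ units (else
`flagged`).

## 3. Spatial normalization

Reference-colony log₂ doubling times are bilinearly interpolated over the
reference grid; positions beyond the outermost references are clamped to
the grid edge (nearest-reference extrapolation), and missing references
are imputed from their 4 nearest usable neighbours.  The correction
subtracts the interpolated surface minus the log₂ plate-set reference
median, so corrections are multiplicative on D and every usable reference
maps exactly onto the common median.  All plates of a cycle share one
pooled reference median, harmonizing between-plate offsets.  Bilinear
interpolation was chosen over 2-D LOESS for determinism and testability;
the normalization is idempotent (re-fitting a normalized plate yields
offsets < 10⁻⁶ log₂ h) and on gradient-free plates perturbs strain
estimates only by the interpolated reference noise.

## 4. Adaptation trajectories and milestones

One trajectory per population: each QC-passing cycle contributes the point
(cumulative generations, normalized D), where cumulative generations is
the running sum of every cycle's G — excluded cycles contribute no point
but still advance the axis, since evolutionary time passes even when a
measurement fails.  Trajectories with fewer than 4 usable cycles are
dropped (and counted).

The trajectory is smoothed with an in-house LOESS (tricube-weighted local
polynomial, evaluable at arbitrary generations): defaults span 0.25,
degree 2, no robustness iterations.  These defaults were calibrated on
simulated ground truth: serial-transfer adaptation curves are sigmoidal,
and (a) wide degree-1 windows cannot track the sweep transition, (b)
bisquare robustness reweighting treats the sweep's own points as outliers;
either choice inflates milestone bias from < 0.05 h to 0.1–0.4 h.
Robustness iterations remain available for data with genuine outliers that
survive QC.  Evaluation outside the observed generation range is clamped
to the boundary value (constant extension): local polynomials are not
trusted to extrapolate, so the preadaptation estimate f(0) equals the
fitted value at the first usable cycle (~generation 6) rather than an
extrapolation.  A first-cycle raw-D estimator of preadaptation fitness is
exposed as an alternative.

Milestones: A_g = f(0) − f(g), hours of doubling-time reduction, positive
= improvement; a milestone beyond the trajectory's support is undefined
(absent), never zero.  A25 ≤ A50 ≤ A75 is not enforced — non-monotone fits
are legitimate under noise.

## 5. Statistics

* **Fitness → adaptation**: OLS of strain-mean milestone on strain-mean
  preadaptation D (statsmodels).  Replicate trajectories are fitted
  individually and milestone values averaged per strain.
* **Outlier screen**: per strain with ≥ 2 replicates, a two-sided
  one-sample t-test of replicate-level residuals (replicate milestone
  minus the regression prediction at the strain's mean preadaptation D)
  against zero, Benjamini–Hochberg FDR across strains at q = 0.05.  The
  regression is not refit excluding the tested strain; with hundreds of
  strains the leave-one-out difference is negligible.  Zero-variance
  replicate sets are handled explicitly (significant only if genuinely
  offset beyond numerical tolerance).  Strains with one replicate are
  skipped with a log notice.
* **Replicate repeatability**: replicates split per strain into two
  disjoint random halves (seeded), R² between half-means across strains;
  an averaged-over-splits variant approximates the full pairwise mean.
* **Set overlaps**: expected overlap |A||B|/N under independence; p-value
  from Fisher's exact test on the 2×2 table, two-sided with the standard
  hypergeometric-tail definition (sidedness is a package choice).
* Cross-condition comparisons are performed by running the pipeline per
  condition and comparing outlier sets via the overlap test; no joint
  cross-condition model is fitted.

## 6. Epistasis reconstruction

The stress-specific resistance deficit of a strain is D_stress − D_basal
(hours).  A reconstructed mutation's effect in a background is the deficit
reduction Δ = (D_stress − D_basal)_bg − (D_stress − D_basal)_mut, which
cancels any basal growth cost of the mutation exactly — the reason the
difference (not the ratio, which is available as an option) is the default
comparison.  The diminishing-return fit is OLS of Δ on the background's
stress doubling time (the deficit is an equivalent predictor up to the
shared basal offset, and is also reported).  Under the simulator's
generative model the slope estimates φ; with measurement noise on the
predictor the slope carries a small (<0.02) attenuation-plus-correlation
bias, well inside the ±0.05 recovery tolerance verified in the tests.

## 7. What the synthetic data establish

The generator reproduces the statistical structure the pipeline assumes:
exponential-phase curves with spikes and noise, plate gradients with
interleaved references, per-cycle generations in the log₂ size-ratio
bounds, replicate populations with stochastic sweep timing, and adaptation
that is by construction a diminishing-return function of the deficit.
Passing tests therefore demonstrate estimator correctness, normalization
recovery, milestone calibration, outlier operating characteristics and
parameter recovery *under these assumptions*.  They do not demonstrate
robustness to real-data pathologies outside the model: non-exponential
growth phases, pixel-calibration error, spatially correlated QC failures,
clonal interference between mutation classes of similar strength, or the
slow late-adaptation tail noted in §1.

## 8. Problem sizes and determinism

Default analysis-scale runs use 300 strains × 12 replicates at the
trajectory level (per-cycle doubling times observed with 0.08 h Gaussian
error) and smaller strain counts when full curve rendering is exercised;
these sizes give stable estimates of every reported quantity while keeping
a complete run in minutes on one core.  All randomness flows from explicit
integer seeds through numpy Generators (component streams keyed as
`[seed, component, ...]`); equal seeds give byte-identical output tables,
which the test suite asserts end to end.
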