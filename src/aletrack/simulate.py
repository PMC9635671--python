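"""Synthetic serial-transfer evolution experiments.

The simulator produces data with the statistical structure the analysis
pipeline assumes, together with ground truth for parameter-recovery tests:

* a strain collection with per-strain stress-specific doubling-time deficits;
* lineage dynamics over repeated growth--bottleneck cycles, with mutant
  classes whose benefit is a fixed fraction of the *remaining* deficit
  (diminishing-return epistasis by construction);
* rendered noisy colony growth curves on plates with spatial gradients and
  interleaved nonevolving reference colonies at every fourth position;
* a reconstruction experiment measuring the stress-specific benefit of one
  mutation class across many genetic backgrounds.

Within-colony dynamics use discrete per-cycle steps: deterministic
exponential growth of lineages, Poisson seeding of new mutant lineages
proportional to the number of divisions, and a multinomial bottleneck at
transfer.  At colony sizes of 5e4 cells and above, drift matters only at
seeding and transfer, which the Poisson and multinomial steps capture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import CurveNoiseConfig, MutationClass, SimulationConfig
from .errors import LayoutError
from .growth import GrowthCurve

Genotype = frozenset  # of mutation-class names


# ---------------------------------------------------------------------------
# strain collection


def build_strain_collection(config: SimulationConfig,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the ground-truth strain table.

    Returns a DataFrame with one row per strain: ``strain_id``,
    ``basal_D_h``, ``deficit_h`` (uniform over ``config.deficit_range_h``),
    ``stress_D_h``, ``background`` (deleted-gene label, blocking the matching
    mutation class, or empty), and ``extinct`` (non-grower injected to
    exercise QC paths).  Deterministic given ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    n = config.n_strains
    lo, hi = config.deficit_range_h
    deficits = rng.uniform(lo, hi, size=n)
    backgrounds = np.array([""] * n, dtype=object)
    n_blocked = int(round(config.blocked_background_fraction * n))
    targets = [mc.target for mc in config.mutation_classes if mc.target]
    if n_blocked and targets:
        blocked_idx = rng.choice(n, size=n_blocked, replace=False)
        for j, i in enumerate(blocked_idx):
            backgrounds[i] = targets[j % len(targets)]
    extinct = np.zeros(n, dtype=bool)
    n_extinct = int(round(config.extinct_fraction * n))
    if n_extinct:
        # the slowest strains go extinct, mirroring loss of the least fit
        extinct[np.argsort(deficits)[-n_extinct:]] = True
    width = max(4, len(str(n)))
    return pd.DataFrame({
        "strain_id": [f"strain_{i:0{width}d}" for i in range(n)],
        "basal_D_h": config.basal_doubling_time_h,
        "deficit_h": deficits,
        "stress_D_h": config.basal_doubling_time_h + deficits,
        "background": backgrounds,
        "extinct": extinct,
    })


# ---------------------------------------------------------------------------
# lineage dynamics


def genotype_doubling_time(basal_D: float, deficit: float, genotype: Genotype,
                           classes: dict[str, MutationClass]) -> float:
    """Doubling time of a genotype under stress.

    Each acquired mutation removes its rescue fraction of the *remaining*
    deficit, so the composed effect is order-invariant and D never falls
    below the basal doubling time:

        D = D_basal + deficit * prod_c (1 - phi_c)
    """
    remaining = deficit
    for name in genotype:
        remaining *= (1.0 - classes[name].rescue_fraction)
    return basal_D + remaining


@dataclass
class CycleState:
    """Lineage composition and realized growth of one cycle."""

    genotypes: tuple          # tuple of Genotype, one per lineage
    start_cells: np.ndarray   # cells per lineage at the bottleneck inoculum
    final_cells: np.ndarray   # cells per lineage at the end of growth
    doubling_times: np.ndarray
    final_size: float
    generations: float        # log2(final / inoculum)
    effective_D: float        # elapsed growth time / generations (mixture D)

    @property
    def frequencies(self) -> np.ndarray:
        return self.final_cells / self.final_cells.sum()


@dataclass
class LineageTrajectory:
    """Per-cycle lineage states for one evolving population."""

    strain_id: str
    basal_D: float
    deficit: float
    cycles: list[CycleState] = field(default_factory=list)

    @property
    def effective_D(self) -> np.ndarray:
        return np.array([c.effective_D for c in self.cycles])

    @property
    def generations(self) -> np.ndarray:
        return np.array([c.generations for c in self.cycles])

    @property
    def cumulative_generations(self) -> np.ndarray:
        return np.cumsum(self.generations)

    @property
    def adaptation(self) -> np.ndarray:
        """Hours of doubling-time reduction relative to the first cycle."""
        d = self.effective_D
        return d[0] - d


def _solve_growth_time(start: np.ndarray, rates: np.ndarray, target: float,
                       t_max: float) -> float:
    """Time for a lineage mixture to reach `target` total cells.

    ``rates`` are doublings per hour; growth is deterministic exponential.
    Returns ``t_max`` if the target is not reached within it.
    """
    if len(start) == 1:
        t = math.log2(target / start[0]) / rates[0]
        return min(t, t_max)

    def excess(t: float) -> float:
        return float(np.sum(start * np.exp2(t * rates))) - target

    if excess(t_max) <= 0:
        return t_max
    return brentq(excess, 0.0, t_max, xtol=1e-9)


def simulate_serial_transfer(strain: pd.Series | dict, config: SimulationConfig,
                             rng: np.random.Generator | int | None = None
                             ) -> LineageTrajectory:
    """Evolve one population over ``config.n_cycles`` growth--bottleneck cycles.

    ``strain`` needs keys ``strain_id``, ``basal_D_h``, ``deficit_h`` and
    optionally ``background``.  Each cycle: lineages grow exponentially at
    1/D doublings per hour until the colony reaches a final size drawn from
    ``final_size_range`` (or growth time runs out); new mutant lineages are
    seeded Poisson(rate_per_division x divisions); a multinomial sample of
    ``bottleneck_size`` cells seeds the next cycle.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng([config.seed if rng is None else int(rng), 2])
    basal = float(strain["basal_D_h"])
    deficit = float(strain["deficit_h"])
    background = strain.get("background", "") or None
    classes = {mc.name: mc for mc in config.mutation_classes}
    accessible = [mc for mc in config.mutation_classes
                  if mc.accessible_in(background)]

    t_grow = config.cycle_duration_h - config.curve_noise.lag_h
    bottleneck = int(config.bottleneck_size)
    traj = LineageTrajectory(str(strain["strain_id"]), basal, deficit)

    # lineage state: parallel lists (genotype, cells at inoculum).  The
    # recovery and preculture expansions precede selection; mutants arising
    # there are near-neutral and enter the first stress cycle as standing
    # variation at expected frequency rate x preculture generations.
    genotypes: list[Genotype] = [frozenset()]
    cells = np.array([float(bottleneck)])
    if config.preculture_generations > 0:
        standing = []
        for mc in accessible:
            k = rng.poisson(mc.rate_per_division
                            * config.preculture_generations * bottleneck)
            if k > 0:
                standing.append((frozenset({mc.name}), float(k)))
        if standing:
            genotypes = genotypes + [g for g, _ in standing]
            extra = np.array([c for _, c in standing])
            cells = np.concatenate([[float(bottleneck) - extra.sum()], extra])

    for _ in range(config.n_cycles):
        ds = np.array([genotype_doubling_time(basal, deficit, g, classes)
                       for g in genotypes])
        rates = 1.0 / ds
        target = rng.uniform(*config.final_size_range)
        t = _solve_growth_time(cells, rates, target, t_grow)
        final = cells * np.exp2(t * rates)
        divisions = final - cells

        # seed new mutant lineages (appear at end of cycle; their own growth
        # within the founding cycle is neglected)
        new_genotypes = list(genotypes)
        new_final = list(final)
        for i, g in enumerate(genotypes):
            for mc in accessible:
                if mc.name in g:
                    continue
                k = rng.poisson(mc.rate_per_division * divisions[i])
                if k > 0:
                    new_genotypes.append(g | {mc.name})
                    new_final.append(float(k))
        final_all = np.array(new_final)
        ds_all = np.array([genotype_doubling_time(basal, deficit, g, classes)
                           for g in new_genotypes])
        total = final_all.sum()
        gens = math.log2(total / cells.sum())
        traj.cycles.append(CycleState(
            genotypes=tuple(new_genotypes),
            start_cells=cells.copy(),
            final_cells=final_all,
            doubling_times=ds_all,
            final_size=total,
            generations=gens,
            effective_D=t / gens,
        ))

        counts = rng.multinomial(bottleneck, final_all / total)
        keep = counts > 0
        # merge lineages that converged on the same genotype
        merged: dict[Genotype, float] = {}
        for g, c in zip([gt for gt, k in zip(new_genotypes, keep) if k],
                        counts[keep]):
            merged[g] = merged.get(g, 0.0) + float(c)
        genotypes = list(merged.keys())
        cells = np.array(list(merged.values()))

    return traj


# ---------------------------------------------------------------------------
# growth-curve forward model


def render_growth_curve(start_cells: np.ndarray, doubling_times: np.ndarray,
                        carrying_capacity: float,
                        noise: CurveNoiseConfig,
                        rng: np.random.Generator,
                        meta: dict | None = None) -> GrowthCurve:
    """Render a noisy colony growth curve for a lineage mixture.

    The noiseless signal is the sum of exponential expansions of each
    lineage from its inoculum share, delayed by the lag, and hard-capped at
    the carrying capacity.  Multiplicative log-normal measurement noise is
    applied everywhere; isolated spikes multiply single points by
    ``2**U(0.5m, 1.5m)`` with m = ``spike_log2_magnitude``.  Injected spike
    indices are recorded on the returned curve for bookkeeping tests.
    """
    times = np.arange(noise.n_points) * noise.sampling_interval_h
    tau = np.clip(times - noise.lag_h, 0.0, None)
    start = np.asarray(start_cells, dtype=float)
    ds = np.asarray(doubling_times, dtype=float)
    finite = np.isfinite(ds)
    signal = np.full_like(times, start[~finite].sum() if (~finite).any() else 0.0)
    if finite.any():
        signal = signal + (
            start[finite][None, :] * np.exp2(tau[:, None] / ds[finite][None, :])
        ).sum(axis=1)
    signal = np.minimum(signal, carrying_capacity)

    cells = signal.copy()
    if noise.multiplicative_noise_sd > 0:
        cells = cells * np.exp(rng.normal(0.0, noise.multiplicative_noise_sd,
                                          size=len(cells)))
    spike_idx = np.empty(0, dtype=int)
    if noise.spike_probability > 0:
        mask = rng.random(len(cells)) < noise.spike_probability
        spike_idx = np.flatnonzero(mask)
        if len(spike_idx):
            m = noise.spike_log2_magnitude
            factors = np.exp2(rng.uniform(0.5 * m, 1.5 * m, size=len(spike_idx)))
            cells[spike_idx] = cells[spike_idx] * factors

    meta = meta or {}
    return GrowthCurve(times=times, cells=cells, spike_indices=spike_idx, **meta)


# ---------------------------------------------------------------------------
# plate layout


def make_plate_layout(n_rows: int, n_cols: int, populations: list[tuple[str, int]],
                      plate_id: str = "P00") -> pd.DataFrame:
    """Assign populations to the non-reference positions of one plate.

    Reference (nonevolving spatial control) colonies occupy the (even row,
    even col) member of every 2x2 quartet -- one quarter of all positions.
    Populations fill the remaining positions in row-major order; leftovers
    are marked ``empty``.
    """
    if n_rows % 2 or n_cols % 2:
        raise LayoutError("plate dimensions must be even")
    capacity = n_rows * n_cols * 3 // 4
    if len(populations) > capacity:
        raise LayoutError(
            f"{len(populations)} populations exceed plate capacity {capacity}")
    rows, cols, roles, sids, reps = [], [], [], [], []
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            rows.append(r)
            cols.append(c)
            if r % 2 == 0 and c % 2 == 0:
                roles.append("reference")
                sids.append("")
                reps.append(-1)
            elif k < len(populations):
                roles.append("strain")
                sids.append(populations[k][0])
                reps.append(populations[k][1])
                k += 1
            else:
                roles.append("empty")
                sids.append("")
                reps.append(-1)
    return pd.DataFrame({
        "plate_id": plate_id, "row": rows, "col": cols, "role": roles,
        "strain_id": sids, "replicate": reps,
    })


def make_gradient_field(n_rows: int, n_cols: int, amplitude_log2: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Smooth spatial field of log2 doubling-time offsets for one plate.

    A random plane plus a low-frequency sinusoid, rescaled so the maximum
    absolute offset equals ``amplitude_log2``.  Amplitude 0 gives an exactly
    flat (noise-free) plate.
    """
    # draw shape coefficients even when amplitude is zero so that the rng
    # stream does not depend on the amplitude
    a_r, a_c, a_s = rng.uniform(-1.0, 1.0, size=3)
    ph_r, ph_c = rng.uniform(0.0, 2.0 * np.pi, size=2)
    if amplitude_log2 == 0:
        return np.zeros((n_rows, n_cols))
    r = np.arange(n_rows)[:, None] / max(n_rows - 1, 1) - 0.5
    c = np.arange(n_cols)[None, :] / max(n_cols - 1, 1) - 0.5
    field_ = (a_r * r + a_c * c
              + 0.5 * a_s * np.sin(2 * np.pi * r + ph_r) * np.sin(2 * np.pi * c + ph_c))
    peak = np.abs(field_).max()
    if peak == 0:
        return np.zeros((n_rows, n_cols))
    return field_ * (amplitude_log2 / peak)


# ---------------------------------------------------------------------------
# full experiment


@dataclass
class ExperimentBundle:
    """Everything one synthetic experiment produces."""

    config: SimulationConfig
    strains: pd.DataFrame       # ground-truth strain table
    layout: pd.DataFrame        # long layout over all plates
    curves: pd.DataFrame        # long curve table
    truth: pd.DataFrame         # per population x cycle ground truth
    gradients: dict             # plate_id -> 2-D log2-offset array


def simulate_experiment(config: SimulationConfig) -> ExperimentBundle:
    """Simulate a complete plate-based evolution experiment.

    Produces rendered growth curves for every strain replicate and every
    reference colony across all cycles (cycle 0 is the stress-free
    preculture; cycles 1..n are under selection), plus the ground-truth
    table with each population's true mixture doubling time and adaptation
    at every cycle.  Fully deterministic given ``config.seed``.
    """
    strains = build_strain_collection(config)
    populations = [(sid, rep)
                   for sid in strains["strain_id"]
                   for rep in range(config.replicates_per_strain)]
    capacity = config.plate_rows * config.plate_cols * 3 // 4
    n_plates = max(1, math.ceil(len(populations) / capacity))
    layouts = []
    for p in range(n_plates):
        chunk = populations[p * capacity:(p + 1) * capacity]
        layouts.append(make_plate_layout(config.plate_rows, config.plate_cols,
                                         chunk, plate_id=f"P{p:02d}"))
    layout = pd.concat(layouts, ignore_index=True)

    gradients = {
        f"P{p:02d}": make_gradient_field(
            config.plate_rows, config.plate_cols, config.gradient_amplitude_log2,
            np.random.default_rng([config.seed, 3, p]))
        for p in range(n_plates)
    }
    strain_rows = strains.set_index("strain_id")
    ref_D_stress = config.basal_doubling_time_h + config.reference_deficit_h
    bottleneck = float(int(config.bottleneck_size))

    curve_frames = []
    truth_rows = []

    for pos in layout.itertuples(index=False):
        if pos.role == "empty":
            continue
        g_off = gradients[pos.plate_id][pos.row, pos.col]
        distort = 2.0 ** g_off
        meta = {"plate_id": pos.plate_id, "row": pos.row, "col": pos.col}
        if pos.role == "reference":
            plate_idx = int(pos.plate_id.lstrip("P"))
            rng = np.random.default_rng([config.seed, 5, plate_idx,
                                         pos.row, pos.col])
            for cycle in range(0, config.n_cycles + 1):
                d_true = (config.basal_doubling_time_h if cycle == 0
                          else ref_D_stress)
                k = rng.uniform(*config.final_size_range)
                curve = render_growth_curve(
                    np.array([bottleneck]), np.array([d_true * distort]), k,
                    config.curve_noise, rng, meta={**meta, "cycle": cycle})
                curve_frames.append(_curve_frame(curve))
            continue

        srow = strain_rows.loc[pos.strain_id]
        strain_idx = int(pos.strain_id.rsplit("_", 1)[1])
        rng = np.random.default_rng([config.seed, 2, strain_idx, pos.replicate])
        if bool(srow["extinct"]):
            for cycle in range(0, config.n_cycles + 1):
                d0 = srow["basal_D_h"] * distort
                k = rng.uniform(*config.final_size_range)
                if cycle == 0:
                    curve = render_growth_curve(
                        np.array([bottleneck]), np.array([d0]), k,
                        config.curve_noise, rng, meta={**meta, "cycle": 0})
                else:
                    curve = render_growth_curve(
                        np.array([bottleneck]), np.array([np.inf]), k,
                        config.curve_noise, rng, meta={**meta, "cycle": cycle})
                curve_frames.append(_curve_frame(curve))
                truth_rows.append((pos.strain_id, pos.replicate, pos.plate_id,
                                   pos.row, pos.col, cycle, np.nan, 0.0, np.nan))
            continue

        traj = simulate_serial_transfer(srow.to_dict() | {"strain_id": pos.strain_id},
                                        config, rng=rng)
        # cycle 0: stress-free preculture at basal D
        k0 = rng.uniform(*config.final_size_range)
        curve0 = render_growth_curve(
            np.array([bottleneck]), np.array([srow["basal_D_h"] * distort]), k0,
            config.curve_noise, rng, meta={**meta, "cycle": 0})
        curve_frames.append(_curve_frame(curve0))
        truth_rows.append((pos.strain_id, pos.replicate, pos.plate_id,
                           pos.row, pos.col, 0, srow["basal_D_h"], np.nan, np.nan))
        d1 = traj.cycles[0].effective_D
        for cycle, state in enumerate(traj.cycles, start=1):
            # first len(start_cells) entries of doubling_times describe the
            # lineages present at the inoculum; later entries are mutants
            # seeded during the cycle, whose growth the forward model folds
            # into the capacity
            n_start = len(state.start_cells)
            curve = render_growth_curve(
                state.start_cells, state.doubling_times[:n_start] * distort,
                state.final_size, config.curve_noise, rng,
                meta={**meta, "cycle": cycle})
            curve_frames.append(_curve_frame(curve))
            truth_rows.append((pos.strain_id, pos.replicate, pos.plate_id,
                               pos.row, pos.col, cycle, state.effective_D,
                               state.generations, d1 - state.effective_D))

    curves = pd.concat(curve_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=[
        "strain_id", "replicate", "plate_id", "row", "col", "cycle",
        "true_D_h", "generations", "true_adaptation_h"])
    return ExperimentBundle(config=config, strains=strains, layout=layout,
                            curves=curves, truth=truth, gradients=gradients)


def _curve_frame(curve: GrowthCurve) -> pd.DataFrame:
    return pd.DataFrame({
        "plate_id": curve.plate_id, "row": curve.row, "col": curve.col,
        "cycle": curve.cycle, "time_h": curve.times, "cells": curve.cells,
    })


# ---------------------------------------------------------------------------
# trajectory-level dataset (no curve rendering)


def simulate_adaptation_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate evolution and return per-cycle doubling-time measurements.

    Skips the growth-curve forward model: per-cycle mixture doubling times
    from the lineage dynamics are observed directly with additive Gaussian
    measurement noise (``config.d_measurement_sd_h``).  This is the fast
    route for studying the statistical layers of the pipeline at full scale.

    Returns ``(strains, measurements)`` where measurements has columns
    ``strain_id, replicate, cycle, generations, true_D_h, measured_D_h``.
    """
    strains = build_strain_collection(config)
    rows = []
    for strain_idx, srow in strains.iterrows():
        if bool(srow["extinct"]):
            continue
        for rep in range(config.replicates_per_strain):
            rng = np.random.default_rng([config.seed, 2, int(strain_idx), rep])
            traj = simulate_serial_transfer(srow, config, rng=rng)
            noise = rng.normal(0.0, config.d_measurement_sd_h,
                               size=config.n_cycles)
            d_true = traj.effective_D
            for cyc in range(config.n_cycles):
                rows.append((srow["strain_id"], rep, cyc + 1,
                             traj.cycles[cyc].generations, d_true[cyc],
                             d_true[cyc] + noise[cyc]))
    measurements = pd.DataFrame(rows, columns=[
        "strain_id", "replicate", "cycle", "generations", "true_D_h",
        "measured_D_h"])
    return strains, measurements


# ---------------------------------------------------------------------------
# reconstruction experiment (mutation effects across backgrounds)


def simulate_reconstruction(strains: pd.DataFrame, mutation_class: MutationClass,
                            noise_sd_h: float = 0.15,
                            basal_cost_range_h: tuple[float, float] = (0.0, 0.4),
                            seed: int = 0) -> pd.DataFrame:
    """Measure one mutation class reconstructed in many backgrounds.

    For each background strain the four doubling times (basal/stress x
    background/reconstructed) are observed with independent Gaussian noise.
    The reconstruction may carry a background-dependent basal growth cost,
    drawn uniformly from ``basal_cost_range_h``; the cost adds to both the
    basal and stress doubling time of the reconstructed strain, so the
    stress-specific effect is unaffected.  Backgrounds in which the class is
    inaccessible (gene already absent) are marked inapplicable.
    """
    rng = np.random.default_rng([seed, 7])
    phi = mutation_class.rescue_fraction
    rows = []
    for srow in strains.itertuples(index=False):
        accessible = mutation_class.accessible_in(srow.background or None)
        cost = rng.uniform(*basal_cost_range_h)
        basal, deficit = srow.basal_D_h, srow.deficit_h
        if accessible:
            mut_basal = basal + cost
            mut_stress = mut_basal + (1.0 - phi) * deficit
        else:
            mut_basal, mut_stress = basal, basal + deficit  # unchanged strain
        eps = rng.normal(0.0, noise_sd_h, size=4)
        rows.append((srow.strain_id, mutation_class.name, accessible,
                     deficit, cost,
                     basal + eps[0], basal + deficit + eps[1],
                     mut_basal + eps[2], mut_stress + eps[3]))
    return pd.DataFrame(rows, columns=[
        "strain_id", "mutation_class", "applicable", "deficit_true_h",
        "basal_cost_true_h", "D_basal_bg", "D_stress_bg", "D_basal_mut",
        "D_stress_mut"])
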