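"""Adaptation trajectories: doubling time vs cumulative generations.

One trajectory per evolving population: each quality-passing cycle
contributes a point (cumulative generations, normalized doubling time).
Cycles excluded by QC contribute no point but their generations still
accumulate -- evolutionary time passes even when a measurement fails.  A
LOESS curve smooths technical and environmental variation; the adaptation
milestone A_g is the doubling-time reduction (hours, positive = faster
growth) achieved by generation g, read from the fit:

    A_g = fit(0) - fit(g)

``fit(0)`` also serves as the default estimator of preadaptation fitness
(the doubling time under stress before adaptive mutations accumulate); the
first measured cycle's raw D is exposed as an alternative estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import LoessConfig
from .errors import ParameterError
from .loess import LoessFit, loess_fit

__all__ = [
    "AdaptationTrajectory", "assemble_trajectory", "fit_trajectory",
    "extract_milestones", "milestone_table",
]


@dataclass
class AdaptationTrajectory:
    """Per-population adaptation data and (optionally) its LOESS fit."""

    population_id: str
    generations: np.ndarray     # cumulative generations at each usable cycle
    doubling_times: np.ndarray  # normalized D (hours) at each usable cycle
    n_cycles_total: int         # cycles elapsed, including QC-excluded ones
    first_cycle_D: float        # raw D of the first usable cycle
    fit: LoessFit | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.generations, dtype=float)
        if len(g) >= 2 and not np.all(np.diff(g) > 0):
            raise ParameterError("cumulative generations must be strictly increasing")

    @property
    def max_generations(self) -> float:
        return float(self.generations[-1])

    def plot(self, ax=None, milestones: tuple[float, ...] = (25.0, 50.0, 75.0)):
        """Scatter the per-cycle points with the LOESS curve overlaid."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.generations, self.doubling_times, "o", ms=4, alpha=0.7)
        if self.fit is not None:
            gs = np.linspace(0.0, self.max_generations, 120)
            ax.plot(gs, self.fit(gs), "-", color="k", lw=1.5)
            for g in milestones:
                if g <= self.max_generations:
                    ax.axvline(g, color="grey", ls=":", lw=0.8)
        ax.set_xlabel("cumulative generations")
        ax.set_ylabel("doubling time (h)")
        ax.set_title(self.population_id)
        return ax


MIN_TRAJECTORY_POINTS = 4


def assemble_trajectory(population_id: str, generations_per_cycle: np.ndarray,
                        doubling_times: np.ndarray,
                        qc_ok: np.ndarray | None = None) -> AdaptationTrajectory | None:
    """Build a trajectory from per-cycle records of one population.

    Parameters
    ----------
    generations_per_cycle
        Realized generations G of every cycle in order, including cycles
        whose D measurement failed QC (their G still advances the axis; a
        non-finite G is replaced by the mean of the finite ones).
    doubling_times
        Per-cycle D in hours, aligned with ``generations_per_cycle``.
    qc_ok
        Boolean mask of usable cycles; defaults to finite D.

    Returns ``None`` (trajectory excluded) if fewer than
    ``MIN_TRAJECTORY_POINTS`` cycles are usable.
    """
    g = np.asarray(generations_per_cycle, dtype=float)
    d = np.asarray(doubling_times, dtype=float)
    if qc_ok is None:
        qc_ok = np.isfinite(d)
    qc_ok = np.asarray(qc_ok, dtype=bool) & np.isfinite(d)
    if g.shape != d.shape:
        raise ParameterError("generations and doubling times must align")
    g_filled = g.copy()
    bad_g = ~np.isfinite(g_filled)
    if bad_g.all():
        return None
    if bad_g.any():
        g_filled[bad_g] = np.nanmean(g_filled[~bad_g])
    cumg = np.cumsum(g_filled)
    if qc_ok.sum() < MIN_TRAJECTORY_POINTS:
        return None
    return AdaptationTrajectory(
        population_id=population_id,
        generations=cumg[qc_ok],
        doubling_times=d[qc_ok],
        n_cycles_total=len(g),
        first_cycle_D=float(d[qc_ok][0]),
    )


def fit_trajectory(traj: AdaptationTrajectory,
                   loess: LoessConfig | None = None) -> AdaptationTrajectory:
    """Attach a LOESS fit of D on cumulative generations (in place).

    The fit's domain is anchored at generation 0: the trajectory's support
    for milestone extraction is [0, max cumulative generations].
    """
    cfg = loess or LoessConfig()
    traj.fit = loess_fit(traj.generations, traj.doubling_times,
                         span=cfg.span, degree=cfg.degree,
                         robustness_iterations=cfg.robustness_iterations)
    return traj


def extract_milestones(traj: AdaptationTrajectory,
                       milestones: tuple[float, ...] = (25.0, 50.0, 75.0),
                       preadaptation: str = "fit0") -> dict:
    """Preadaptation D and adaptation milestones from a fitted trajectory.

    Returns a dict with ``preadaptation_D`` (hours) and one entry ``A{g}``
    per milestone generation g: hours of doubling-time reduction, positive =
    improvement.  A milestone beyond the trajectory's support is absent from
    the dict (undefined, not zero).

    ``preadaptation`` selects the estimator: ``"fit0"`` (LOESS fit at
    generation 0, the default) or ``"first_cycle"`` (raw D of the first
    usable cycle).
    """
    if traj.fit is None:
        raise ParameterError("trajectory has no fit; call fit_trajectory first")
    d0 = float(traj.fit(0.0))
    pre = d0 if preadaptation == "fit0" else traj.first_cycle_D
    out = {"preadaptation_D": pre}
    for g in milestones:
        if g <= traj.max_generations:
            out[f"A{g:g}"] = d0 - float(traj.fit(g))
    return out


def milestone_table(measurements, loess: LoessConfig | None = None,
                    milestones: tuple[float, ...] = (25.0, 50.0, 75.0),
                    d_column: str = "measured_D_h"):
    """Per-replicate milestone table from per-cycle D measurements.

    ``measurements`` is a long DataFrame with columns ``strain_id,
    replicate, cycle, generations`` and ``d_column`` (as produced by
    :func:`aletrack.simulate.simulate_adaptation_dataset` or by the curve
    pipeline).  One trajectory is assembled and LOESS-fitted per (strain,
    replicate); excluded trajectories are dropped.
    """
    import pandas as pd
    rows = []
    for (sid, rep), grp in measurements.groupby(["strain_id", "replicate"],
                                                sort=True):
        grp = grp.sort_values("cycle", kind="stable")
        traj = assemble_trajectory(f"{sid}/r{rep}",
                                   grp["generations"].to_numpy(),
                                   grp[d_column].to_numpy())
        if traj is None:
            continue
        fit_trajectory(traj, loess)
        ms = extract_milestones(traj, milestones)
        rows.append({"strain_id": sid, "replicate": rep, **ms})
    return pd.DataFrame(rows)
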