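"""Configuration objects for the simulator and the analysis pipeline.

The simulator models a serial-transfer (batch-cycle) evolution experiment on
solid-agar colony arrays: populations are bottlenecked to ~5e4 cells, expand
to 2-4e6 cells over a 72 h cycle, and are robotically subsampled to seed the
next cycle, for 19 cycles.  Adaptation is driven by a small set of mutation
classes whose benefit is a fixed fraction (the rescue fraction, phi) of the
strain's *remaining* stress-specific doubling-time deficit -- the minimal
parameterization of diminishing-return (global) epistasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class MutationClass:
    """One class of adaptive mutation available during evolution.

    Parameters
    ----------
    name
        Label for the class (e.g. ``fps1-loss``).  Purely symbolic; no
        sequence-level representation is modeled.
    rate_per_division
        Probability that one cell division spawns a mutant of this class.
    rescue_fraction
        Fraction phi in [0, 1] of the strain's *remaining* stress-specific
        doubling-time deficit removed when the mutation is acquired.  Because
        each acquisition removes a fraction of what is left, the doubling
        time can never undershoot the basal (unstressed) level, and the
        composed effect of several classes is independent of the order of
        acquisition.
    target
        Optional gene label this class inactivates/duplicates.  A strain
        whose deleted-gene background equals ``target`` has no access to the
        class (you cannot lose a gene that is already gone).
    """

    name: str
    rate_per_division: float
    rescue_fraction: float
    target: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate_per_division <= 1.0:
            raise ConfigError(
                f"mutation class {self.name!r}: rate_per_division must be in "
                f"[0, 1], got {self.rate_per_division}"
            )
        if not 0.0 <= self.rescue_fraction <= 1.0:
            raise ConfigError(
                f"mutation class {self.name!r}: rescue_fraction must be in "
                f"[0, 1], got {self.rescue_fraction}"
            )

    def accessible_in(self, background: str | None) -> bool:
        """Whether this class can arise in a strain with the given background."""
        return self.target is None or background != self.target


def default_mutation_classes() -> tuple[MutationClass, ...]:
    """Three mutation classes mirroring the known arsenite-exclusion routes.

    A high-rate, high-rescue loss-of-function class (aquaglyceroporin-channel
    loss), a lower-rescue regulator-loss class, and an intermediate
    duplication class.  Rescue fractions 0.9 / 0.3 / 0.6 put the mean
    simulated benefits of the first two classes in a ~3:1 ratio.
    """
    return (
        MutationClass("fps1-loss", rate_per_division=2e-5, rescue_fraction=0.9,
                      target="FPS1"),
        MutationClass("ask10-loss", rate_per_division=1e-5, rescue_fraction=0.3,
                      target="ASK10"),
        MutationClass("arr3-dup", rate_per_division=5e-6, rescue_fraction=0.6,
                      target=None),
    )


@dataclass(frozen=True)
class CurveNoiseConfig:
    """Forward-model parameters for rendering a noisy colony growth curve.

    Defaults follow the measurement regime of transmissive-scanner colony
    phenomics: one density estimate every 20 min for 72 h.
    """

    sampling_interval_h: float = 1.0 / 3.0
    duration_h: float = 72.0
    spike_probability: float = 0.01
    spike_log2_magnitude: float = 2.0   # spikes multiply counts by ~2**mag
    multiplicative_noise_sd: float = 0.02  # sd of ln-scale measurement noise
    lag_h: float = 2.0

    def __post_init__(self) -> None:
        if self.sampling_interval_h <= 0:
            raise ConfigError("sampling_interval_h must be > 0")
        if self.duration_h < 10 * self.sampling_interval_h:
            raise ConfigError(
                "duration_h must be at least 10 sampling intervals "
                f"({10 * self.sampling_interval_h:g} h)"
            )
        if not 0.0 <= self.spike_probability <= 1.0:
            raise ConfigError("spike_probability must be in [0, 1]")
        if self.multiplicative_noise_sd < 0:
            raise ConfigError("multiplicative_noise_sd must be >= 0")
        if self.lag_h < 0:
            raise ConfigError("lag_h must be >= 0")

    @property
    def n_points(self) -> int:
        import math
        return int(math.floor(self.duration_h / self.sampling_interval_h)) + 1


@dataclass(frozen=True)
class SimulationConfig:
    """Full design of one synthetic serial-transfer evolution experiment.

    ``deficit_range_h`` is the interval from which each strain's
    stress-specific doubling-time deficit (stress D minus basal D, in hours)
    is drawn uniformly.  ``reference_deficit_h`` is the fixed deficit of the
    nonevolving wild-type spatial-control colonies; the default 1.34 h
    corresponds to a wild type slowed from 2.27 h to 3.61 h by the stressor.
    """

    n_strains: int = 300
    replicates_per_strain: int = 12
    basal_doubling_time_h: float = 2.27
    deficit_range_h: tuple[float, float] = (0.5, 4.0)
    n_cycles: int = 19
    bottleneck_size: float = 5e4
    final_size_range: tuple[float, float] = (2e6, 4e6)
    cycle_duration_h: float = 72.0
    # Generations of stress-free expansion (recovery plate plus precultures)
    # before selection starts; mutants arising there are near-neutral and
    # enter cycle 1 as standing variation at frequency ~ rate x generations.
    preculture_generations: float = 25.0
    mutation_classes: tuple[MutationClass, ...] = field(
        default_factory=default_mutation_classes)
    curve_noise: CurveNoiseConfig = field(default_factory=CurveNoiseConfig)
    reference_deficit_h: float = 1.34
    # Fraction of strains assigned a background that blocks one mutation
    # class (deleted-gene background equals the class target), and fraction
    # injected as non-growers to exercise QC paths.
    blocked_background_fraction: float = 0.0
    extinct_fraction: float = 0.0
    # Spatial gradient on log2 doubling time: plane + low-frequency sinusoid.
    gradient_amplitude_log2: float = 0.07
    # Measurement noise on per-cycle doubling-time estimates when curves are
    # not rendered (trajectory-level simulation), sd in hours.
    d_measurement_sd_h: float = 0.08
    plate_rows: int = 16
    plate_cols: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.deficit_range_h
        if lo < 0 or hi < lo:
            raise ConfigError(
                f"deficit_range_h must satisfy 0 <= lo <= hi, got {self.deficit_range_h}")
        if self.bottleneck_size >= min(self.final_size_range):
            raise ConfigError(
                "bottleneck_size must be smaller than the smallest final size")
        f_lo, f_hi = self.final_size_range
        if f_lo <= 0 or f_hi < f_lo:
            raise ConfigError("final_size_range must satisfy 0 < lo <= hi")
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        if self.n_strains < 1 or self.replicates_per_strain < 1:
            raise ConfigError("n_strains and replicates_per_strain must be >= 1")
        if self.basal_doubling_time_h <= 0:
            raise ConfigError("basal_doubling_time_h must be > 0")
        if not 0.0 <= self.blocked_background_fraction <= 1.0:
            raise ConfigError("blocked_background_fraction must be in [0, 1]")
        if not 0.0 <= self.extinct_fraction <= 1.0:
            raise ConfigError("extinct_fraction must be in [0, 1]")
        if self.plate_rows % 2 or self.plate_cols % 2:
            raise ConfigError("plate_rows and plate_cols must be even "
                              "(reference positions occupy one member of each "
                              "2x2 quartet)")


@dataclass(frozen=True)
class LoessConfig:
    """LOESS smoothing parameters for adaptation trajectories.

    Defaults (span 0.25, local quadratics, no robustness reweighting) are
    tuned for serial-transfer adaptation curves, which are sigmoidal: wide
    linear windows cannot track the selective-sweep transition and bisquare
    reweighting mistakes the sweep itself for outliers; both inflate
    milestone bias by an order of magnitude on simulated ground truth.
    """

    span: float = 0.25
    degree: int = 2
    robustness_iterations: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.span <= 1.0:
            raise ConfigError("span must be in (0, 1]")
        if self.degree not in (0, 1, 2):
            raise ConfigError("degree must be 0, 1 or 2")
        if self.robustness_iterations < 0:
            raise ConfigError("robustness_iterations must be >= 0")


@dataclass(frozen=True)
class QCThresholds:
    """Quality-control thresholds for growth curves.

    The thresholds themselves are implementation choices (the upstream
    phenomics platform flags poor curves without publishing its criteria):
    a curve must span at least ``min_doublings`` of dynamic range to count
    as growth, carry at least ``min_points`` samples, not end below its
    start by more than ``endpoint_drop_tol_log2`` doublings after despiking,
    and have at most ``max_spike_fraction`` of its points altered by the
    median filter by more than ``spike_detect_log2`` doublings.
    """

    min_points: int = 10
    min_doublings: float = 1.0
    max_spike_fraction: float = 0.2
    spike_detect_log2: float = 0.5
    endpoint_drop_tol_log2: float = 0.25


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full analysis run over curve and layout tables."""

    curve_table: str = "curves.csv"
    layout_table: str = "layout.csv"
    median_window: int = 5
    gaussian_sigma: float = 1.5
    mu_max_window: int = 5
    loess: LoessConfig = field(default_factory=LoessConfig)
    milestones: tuple[float, ...] = (25.0, 50.0, 75.0)
    q_threshold: float = 0.05
    normalization: str = "bilinear"  # or "none"
    qc: QCThresholds = field(default_factory=QCThresholds)
    seed: int = 0

    def __post_init__(self) -> None:
        ms = self.milestones
        if any(m <= 0 for m in ms) or any(b <= a for a, b in zip(ms, ms[1:])) is True:
            raise ConfigError("milestones must be positive and increasing")
        if list(ms) != sorted(ms) or len(set(ms)) != len(ms):
            raise ConfigError("milestones must be positive and increasing")
        if not 0.0 < self.q_threshold < 1.0:
            raise ConfigError("q_threshold must be in (0, 1)")
        if self.normalization not in ("bilinear", "none"):
            raise ConfigError("normalization must be 'bilinear' or 'none'")
        if self.median_window % 2 == 0 or self.median_window < 3:
            raise ConfigError("median_window must be odd and >= 3")
        if self.gaussian_sigma <= 0:
            raise ConfigError("gaussian_sigma must be > 0")


def _as_plain_dict(obj) -> dict:
    d = asdict(obj)
    return d


def load_simulation_config(path: str) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a YAML file.

    Nested blocks ``mutation_classes`` (list of mappings) and ``curve_noise``
    (mapping) are converted to their dataclasses; all other keys map directly
    to :class:`SimulationConfig` fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    kwargs = dict(raw)
    if "mutation_classes" in kwargs:
        kwargs["mutation_classes"] = tuple(
            MutationClass(**mc) for mc in kwargs["mutation_classes"])
    if "curve_noise" in kwargs:
        kwargs["curve_noise"] = CurveNoiseConfig(**kwargs["curve_noise"])
    for tup_key in ("deficit_range_h", "final_size_range"):
        if tup_key in kwargs:
            kwargs[tup_key] = tuple(kwargs[tup_key])
    try:
        return SimulationConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_run_config(path: str) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    kwargs = dict(raw)
    if "loess" in kwargs:
        kwargs["loess"] = LoessConfig(**kwargs["loess"])
    if "qc" in kwargs:
        kwargs["qc"] = QCThresholds(**kwargs["qc"])
    if "milestones" in kwargs:
        kwargs["milestones"] = tuple(kwargs["milestones"])
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
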