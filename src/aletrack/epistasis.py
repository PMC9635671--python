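"""Diminishing-return epistasis from reconstructed mutations.

A candidate adaptive mutation (gene loss or duplication) is reconstructed in
many genetic backgrounds; each strain's doubling time is measured with and
without the stressor.  The stress-specific resistance deficit of a strain is

    resistance deficit = D_stress - D_basal          (hours)

and the stress-specific effect of the mutation in a background is the
deficit reduction

    delta = (D_stress_bg - D_basal_bg) - (D_stress_mut - D_basal_mut)

which cancels any basal growth cost of the mutation exactly.  Regressing
delta on the background's stress doubling time quantifies global
(diminishing-return) epistasis: under the simulator's generative model the
slope estimates the mutation class's rescue fraction phi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ParameterError

log = logging.getLogger(__name__)


def stress_specific_resistance(d_basal: float, d_stress: float,
                               mode: str = "difference") -> float:
    """Stress-specific doubling-time excess of a strain (hours).

    Larger values mean more sensitive.  ``mode="difference"`` (default)
    returns ``D_stress - D_basal`` in hours, which makes basal growth costs
    cancel exactly in mutation effects; ``mode="ratio"`` returns
    ``D_stress / D_basal``.
    """
    if not (np.isfinite(d_basal) and np.isfinite(d_stress)) or d_basal <= 0 \
            or d_stress <= 0:
        raise ParameterError("both doubling times must be positive and finite")
    if mode == "difference":
        return float(d_stress - d_basal)
    if mode == "ratio":
        return float(d_stress / d_basal)
    raise ParameterError(f"unknown mode {mode!r}")


def mutation_effects(measurements: pd.DataFrame,
                     mode: str = "difference") -> pd.DataFrame:
    """Per-background stress-specific mutation effects.

    Parameters
    ----------
    measurements
        One row per (background, reconstruction) pair with columns
        ``strain_id, mutation_class, D_basal_bg, D_stress_bg, D_basal_mut,
        D_stress_mut`` and optionally ``applicable`` (False marks structural
        inaccessibility, e.g. deleting a gene the background already lacks:
        the effect is a structural zero and the record is excluded from
        fits).  Rows with missing basal measurements are excluded and
        logged.

    Returns the input annotated with ``resistance_bg``, ``resistance_mut``
    and ``effect_h`` (delta; positive = the mutation confers resistance).
    """
    df = measurements.copy()
    needed = ["D_basal_bg", "D_stress_bg", "D_basal_mut", "D_stress_mut"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParameterError(f"measurement table lacks columns {missing}")
    ok = df[needed].notna().all(axis=1)
    if (~ok).any():
        log.info("excluding %d records with missing measurements", int((~ok).sum()))
        df = df[ok].copy()
    if "applicable" not in df.columns:
        df["applicable"] = True
    if mode == "difference":
        df["resistance_bg"] = df["D_stress_bg"] - df["D_basal_bg"]
        df["resistance_mut"] = df["D_stress_mut"] - df["D_basal_mut"]
    elif mode == "ratio":
        df["resistance_bg"] = df["D_stress_bg"] / df["D_basal_bg"]
        df["resistance_mut"] = df["D_stress_mut"] / df["D_basal_mut"]
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    df["effect_h"] = df["resistance_bg"] - df["resistance_mut"]
    return df


class DiminishingReturnModel:
    """OLS model of mutation effect size on background stress fitness.

    Parameters
    ----------
    records
        Output of :func:`mutation_effects` for one mutation class.
    predictor
        ``"stress_D"`` (default; the background's doubling time under
        stress, matching how reconstruction panels are usually plotted) or
        ``"deficit"`` (the background's stress-specific resistance deficit).
        The two differ only by the basal-D offset when basal doubling times
        are shared across backgrounds.
    """

    def __init__(self, records: pd.DataFrame, predictor: str = "stress_D"):
        if predictor not in ("stress_D", "deficit"):
            raise ParameterError("predictor must be 'stress_D' or 'deficit'")
        usable = records[records.get("applicable", True) == True]  # noqa: E712
        if len(usable) < 3:
            raise ParameterError(
                f"need >= 3 applicable records, got {len(usable)}")
        self.records = usable
        self.predictor = predictor
        self._x = (usable["D_stress_bg"] if predictor == "stress_D"
                   else usable["resistance_bg"]).to_numpy(dtype=float)
        self._y = usable["effect_h"].to_numpy(dtype=float)
        classes = usable.get("mutation_class")
        self.mutation_class = (str(classes.iloc[0])
                               if classes is not None and classes.nunique() == 1
                               else "")

    def fit(self) -> "DiminishingReturnResults":
        if np.ptp(self._x) == 0:
            raise ParameterError("all backgrounds share one predictor value; "
                                 "slope undefined")
        ols = sm.OLS(self._y, sm.add_constant(self._x)).fit()
        return DiminishingReturnResults(self, ols)


class DiminishingReturnResults:
    """Fitted diminishing-return (global epistasis) line for one class.

    ``slope`` is the empirical global-epistasis coefficient (hours of
    stress-specific benefit per hour of background stress doubling time);
    under the remaining-deficit generative model it estimates the rescue
    fraction phi of the mutation class.
    """

    def __init__(self, model: DiminishingReturnModel, ols):
        self.model = model
        self._ols = ols
        self.intercept, self.slope = (float(ols.params[0]), float(ols.params[1]))
        self.rsquared = float(ols.rsquared)
        self.nobs = int(ols.nobs)
        self.mean_effect_h = float(np.mean(model._y))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        return self._ols.conf_int(alpha)

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def summary(self) -> str:
        name = self.model.mutation_class or "mutation"
        return "\n".join([
            f"Diminishing-return fit for {name} "
            f"(effect on background {self.model.predictor})",
            f"  backgrounds: {self.nobs}",
            f"  slope:       {self.slope:+.4f}",
            f"  intercept:   {self.intercept:+.4f} h",
            f"  R^2:         {self.rsquared:.4f}",
            f"  mean effect: {self.mean_effect_h:.3f} h",
        ])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model._x, self.model._y, s=12, alpha=0.6)
        xs = np.linspace(self.model._x.min(), self.model._x.max(), 50)
        ax.plot(xs, self.predict(xs), "k-", label=f"$R^2$ = {self.rsquared:.2f}")
        xlab = ("background doubling time under stress (h)"
                if self.model.predictor == "stress_D"
                else "background resistance deficit (h)")
        ax.set_xlabel(xlab)
        ax.set_ylabel("stress-specific benefit (h)")
        ax.legend()
        return ax


def fit_diminishing_return(records: pd.DataFrame,
                           predictor: str = "stress_D") -> DiminishingReturnResults:
    """Fit the diminishing-return line for one mutation class's records."""
    return DiminishingReturnModel(records, predictor=predictor).fit()
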