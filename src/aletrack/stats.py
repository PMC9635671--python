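"""Fitness-predicts-adaptation statistics.

The central claim being quantified: across a strain collection, the
preadaptation doubling time under stress (fitness proxy) linearly predicts
the adaptation milestone A_g, because beneficial mutations rescue a fraction
of the stress-specific deficit -- diminishing-return epistasis.  This module
fits that regression, screens for strains adapting significantly faster or
slower than their fitness predicts (one-sample t-tests on replicate-level
residuals, Benjamini-Hochberg FDR), measures replicate repeatability, and
tests gene-set overlaps with Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# model / results


class FitnessAdaptationModel:
    """OLS model of strain-mean adaptation on strain-mean preadaptation D.

    Parameters
    ----------
    replicate_milestones
        Long table with one row per (strain, replicate): columns
        ``strain_id``, ``replicate``, the predictor column (default
        ``preadaptation_D``, hours) and one column per adaptation milestone
        (e.g. ``A75``, hours of doubling-time reduction).
    milestone
        Which milestone column to model.
    predictor
        Predictor column name.

    Examples
    --------
    >>> model = FitnessAdaptationModel(reps, milestone="A75")
    >>> res = model.fit()
    >>> res.rsquared, res.slope
    >>> outliers = res.call_outliers(q_threshold=0.05)
    """

    def __init__(self, replicate_milestones: pd.DataFrame, milestone: str = "A75",
                 predictor: str = "preadaptation_D"):
        required = {"strain_id", predictor, milestone}
        missing = required - set(replicate_milestones.columns)
        if missing:
            raise ParameterError(f"replicate table lacks columns {sorted(missing)}")
        df = replicate_milestones.dropna(subset=[predictor, milestone])
        self.replicates = df
        self.milestone = milestone
        self.predictor = predictor
        self.strain_means = (df.groupby("strain_id", sort=True)
                             .agg(n=("strain_id", "size"),
                                  pre=(predictor, "mean"),
                                  adapt=(milestone, "mean"))
                             .reset_index())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, milestone: str = "A75",
                       predictor: str = "preadaptation_D") -> "FitnessAdaptationModel":
        return cls(df, milestone=milestone, predictor=predictor)

    def fit(self) -> "FitnessAdaptationResults":
        means = self.strain_means
        if len(means) < 3:
            raise ParameterError("need at least 3 strains with defined milestone")
        x = means["pre"].to_numpy()
        if np.ptp(x) == 0:
            raise ParameterError("zero variance in predictor; regression undefined")
        X = sm.add_constant(x)
        ols = sm.OLS(means["adapt"].to_numpy(), X).fit()
        return FitnessAdaptationResults(self, ols)


class FitnessAdaptationResults:
    """Fitted fitness-to-adaptation regression.

    Attributes
    ----------
    slope : hours of adaptation per hour of preadaptation doubling time
    intercept : hours
    rsquared : squared coefficient of the linear regression
    nobs : number of strains
    """

    def __init__(self, model: FitnessAdaptationModel, ols):
        self.model = model
        self._ols = ols
        self.intercept, self.slope = (float(ols.params[0]), float(ols.params[1]))
        self.rsquared = float(ols.rsquared)
        self.nobs = int(ols.nobs)

    @property
    def params(self) -> np.ndarray:
        return self._ols.params

    def predict(self, preadaptation_D) -> np.ndarray:
        x = np.asarray(preadaptation_D, dtype=float)
        return self.intercept + self.slope * x

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        return self._ols.conf_int(alpha)

    def summary(self) -> str:
        lines = [
            f"Fitness -> adaptation regression ({self.model.milestone} on "
            f"{self.model.predictor})",
            f"  strains: {self.nobs}",
            f"  slope:     {self.slope:+.4f} h/h",
            f"  intercept: {self.intercept:+.4f} h",
            f"  R^2:       {self.rsquared:.4f}",
        ]
        return "\n".join(lines)

    def call_outliers(self, q_threshold: float = 0.05) -> pd.DataFrame:
        """Strains adapting significantly better/worse than fitness predicts.

        Per strain with >= 2 replicates, a two-sided one-sample t-test of
        the replicate-level residuals (replicate adaptation minus the
        regression prediction at the strain's mean preadaptation D) against
        zero; Benjamini-Hochberg FDR across strains at ``q_threshold``.
        The regression is not refit excluding the tested strain; with
        hundreds of strains the leave-one-out difference is negligible.
        """
        return call_outliers(self.model.replicates, self,
                             milestone=self.model.milestone,
                             predictor=self.model.predictor,
                             q_threshold=q_threshold)

    def plot(self, ax=None):
        """Scatter of strain means with the regression line."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        m = self.model.strain_means
        ax.scatter(m["pre"], m["adapt"], s=10, alpha=0.6)
        xs = np.linspace(m["pre"].min(), m["pre"].max(), 50)
        ax.plot(xs, self.predict(xs), "k-",
                label=f"$R^2$ = {self.rsquared:.2f}")
        ax.set_xlabel(f"preadaptation doubling time (h)")
        ax.set_ylabel(f"{self.model.milestone} (h reduction)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# functional surface


def regress_adaptation(replicate_milestones: pd.DataFrame, milestone: str = "A75",
                       predictor: str = "preadaptation_D") -> FitnessAdaptationResults:
    """Fit the fitness-to-adaptation OLS regression (strain means)."""
    return FitnessAdaptationModel(replicate_milestones, milestone, predictor).fit()


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def call_outliers(replicate_milestones: pd.DataFrame,
                  regression: FitnessAdaptationResults,
                  milestone: str = "A75", predictor: str = "preadaptation_D",
                  q_threshold: float = 0.05) -> pd.DataFrame:
    """Outlier screen; see :meth:`FitnessAdaptationResults.call_outliers`.

    Returns one row per tested strain: ``strain_id, n, mean_residual_h,
    t, pvalue, qvalue, significant, direction`` (direction ``better`` for a
    positive residual, i.e. more adaptation than predicted).  The returned
    frame carries ``median_better_h`` / ``median_worse_h`` (median absolute
    deviation magnitude among significant calls per direction) in ``attrs``.
    """
    rows = []
    for sid, grp in replicate_milestones.groupby("strain_id", sort=True):
        vals = grp[milestone].dropna().to_numpy()
        if len(vals) < 2:
            log.info("strain %s has %d replicate(s); outlier test skipped",
                     sid, len(vals))
            continue
        pred = float(regression.predict(grp[predictor].mean()))
        resid = vals - pred
        scale = max(1.0, float(np.abs(vals).max()))
        if np.ptp(resid) <= 1e-9 * scale:
            # zero-variance replicates: significant only if genuinely offset
            off = abs(resid.mean()) > 1e-9 * scale
            t, p = (np.inf, 0.0) if off else (0.0, 1.0)
        else:
            t, p = sps.ttest_1samp(resid, 0.0)
        rows.append((sid, len(vals), float(resid.mean()), float(t), float(p)))
    out = pd.DataFrame(rows, columns=["strain_id", "n", "mean_residual_h",
                                      "t", "pvalue"])
    if len(out) == 0:
        out["qvalue"] = out["significant"] = out["direction"] = []
        return out
    out["qvalue"] = benjamini_hochberg(out["pvalue"].to_numpy())
    out["significant"] = out["qvalue"] <= q_threshold
    out["direction"] = np.where(out["mean_residual_h"] > 0, "better", "worse")
    sig = out[out["significant"]]
    out.attrs["median_better_h"] = float(
        sig.loc[sig["direction"] == "better", "mean_residual_h"].median())
    out.attrs["median_worse_h"] = float(
        sig.loc[sig["direction"] == "worse", "mean_residual_h"].abs().median())
    return out


def replicate_repeatability(replicate_milestones: pd.DataFrame,
                            milestone: str = "A75", seed: int = 0,
                            method: str = "half_split") -> float:
    """R-squared between replicate measures of adaptation across strains.

    ``half_split`` (default): replicates of each strain are split into two
    disjoint random halves (seeded); the OLS R^2 between the half-means
    across strains is returned.  ``pairwise``: mean R^2 over many random
    replicate pairings is approximated by the same half-split averaged over
    25 seeds.
    """
    if method == "pairwise":
        return float(np.mean([
            replicate_repeatability(replicate_milestones, milestone,
                                    seed=seed * 1000 + k, method="half_split")
            for k in range(25)]))
    rng = np.random.default_rng([seed, 11])
    a_means, b_means = [], []
    for _, grp in replicate_milestones.groupby("strain_id", sort=True):
        vals = grp[milestone].dropna().to_numpy()
        if len(vals) < 2:
            continue
        perm = rng.permutation(len(vals))
        half = len(vals) // 2
        a_means.append(vals[perm[:half]].mean())
        b_means.append(vals[perm[half:]].mean())
    if len(a_means) < 3:
        raise ParameterError("need >= 3 strains with >= 2 replicates")
    a = np.asarray(a_means)
    b = np.asarray(b_means)
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class OverlapResult:
    observed: int
    expected: float
    pvalue: float


def overlap_test(set_a, set_b, universe_size: int) -> OverlapResult:
    """Two-sided Fisher's exact test for the overlap of two gene sets.

    ``expected = |A| * |B| / N`` under independence; the p-value comes from
    the 2x2 table (in both, A only, B only, neither) with the standard
    two-sided hypergeometric-tail definition.
    """
    a, b = set(set_a), set(set_b)
    n_a, n_b = len(a), len(b)
    k = len(a & b)
    if n_a > universe_size or n_b > universe_size:
        raise ParameterError("set larger than universe")
    if len(a | b) > universe_size:
        raise ParameterError("union of sets exceeds universe size")
    table = [[k, n_a - k], [n_b - k, universe_size - n_a - n_b + k]]
    if min(min(row) for row in table) < 0:
        raise ParameterError("overlap exceeds set sizes")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return OverlapResult(observed=k, expected=n_a * n_b / universe_size,
                         pvalue=float(p))
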