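"""Linking management scores to ecological outcomes.

Three estimators:

- :func:`fit_score_outcome` — ordinary least squares of a farm-level outcome
  on a single score, with the two-sided p-value from the t distribution on
  n − 2 degrees of freedom;
- :func:`compare_principles` — one univariate fit per principle plus one on
  the combined score, the comparison used to ask which principles best
  predict an outcome (principle-level fits are typically more informative
  than the combined score, whose wider 0–P range dilutes any single signal);
- :func:`baci_did` — a difference-in-differences estimate for a
  before–after control–impact panel, with a farm-level block bootstrap
  standard error.

The farm is the unit of analysis throughout: multiple within-farm outcome
measurements are averaged before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import FitError

__all__ = [
    "RegressionResult",
    "PrincipleComparison",
    "BaciResult",
    "fit_score_outcome",
    "compare_principles",
    "baci_did",
]

SIGNIFICANCE_LEVEL = 0.05
TREND_LEVEL = 0.10


@dataclass(frozen=True)
class RegressionResult:
    """Univariate OLS summary for one predictor."""

    predictor: str
    slope: float
    intercept: float
    stderr: float
    tvalue: float
    pvalue: float
    r2: float
    n: int

    @property
    def significant(self) -> bool:
        return self.pvalue < SIGNIFICANCE_LEVEL

    @property
    def trend(self) -> bool:
        return SIGNIFICANCE_LEVEL <= self.pvalue < TREND_LEVEL

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "beta": self.slope,
            "intercept": self.intercept,
            "se": self.stderr,
            "t": self.tvalue,
            "p": self.pvalue,
            "r2": self.r2,
            "n": self.n,
            "significant": self.significant,
            "trend": self.trend,
        }


@dataclass
class PrincipleComparison:
    """Per-principle regressions plus the combined-score regression."""

    results: list[RegressionResult]
    errors: dict[str, str]
    holm_adjusted: Mapping[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.to_dict() for r in self.results])
        if self.holm_adjusted is not None:
            df["p_holm"] = df["predictor"].map(self.holm_adjusted)
        return df

    def result(self, predictor: str) -> RegressionResult:
        for r in self.results:
            if r.predictor == predictor:
                return r
        raise KeyError(predictor)


@dataclass(frozen=True)
class BaciResult:
    """Difference-in-differences estimate with bootstrap uncertainty."""

    estimate: float
    stderr: float
    pvalue: float
    n_impact: int
    n_control: int
    n_boot: int


def fit_score_outcome(x: Sequence[float], y: Sequence[float],
                      predictor: str = "score") -> RegressionResult:
    """OLS of outcome ``y`` on score ``x`` at the farm level."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise FitError(f"need at least 3 paired observations, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise FitError("non-finite values in inputs")
    if np.ptp(x) == 0:
        raise FitError(f"degenerate predictor {predictor!r}: x is constant")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = float(fit.rsquared)
    if not np.isfinite(r2):  # constant outcome: no variance to explain
        r2 = 0.0
    return RegressionResult(
        predictor=predictor,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        stderr=float(fit.bse[1]),
        tvalue=float(fit.tvalues[1]),
        pvalue=float(fit.pvalues[1]),
        r2=r2,
        n=int(fit.nobs),
    )


def _holm(pvals: Mapping[str, float]) -> dict[str, float]:
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted, running = {}, 0.0
    for rank, (name, p) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * p))
        adjusted[name] = running
    return adjusted


def compare_principles(scores: pd.DataFrame, outcomes: pd.DataFrame,
                       principle_ids: Sequence[str] | None = None,
                       combined_col: str = "combined",
                       holm: bool = False) -> PrincipleComparison:
    """Fit outcome on each principle score and on the combined score.

    ``scores`` is one row per farm (as from
    :func:`regenscore.scoring.weighted_scores_table`); ``outcomes`` has
    columns farm_id and value, averaged per farm before fitting.  Fits that
    fail (e.g. a constant predictor) are recorded in ``errors`` and the rest
    proceed.  No multiple-testing correction is applied unless ``holm=True``:
    raw p-values are reported so borderline results remain visible as trends.
    """
    if principle_ids is None:
        meta = {"farm_id", "group", "landscape", combined_col, "normalized", "coverage"}
        principle_ids = [c for c in scores.columns if c not in meta]
    per_farm = outcomes.groupby("farm_id", sort=False)["value"].mean()
    merged = scores.merge(
        per_farm.rename("outcome"), left_on="farm_id", right_index=True
    )
    if len(merged) < 3:
        raise FitError("need at least 3 farms with both scores and outcomes")

    results, errors = [], {}
    for col in [*principle_ids, combined_col]:
        try:
            results.append(
                fit_score_outcome(merged[col], merged["outcome"], predictor=col)
            )
        except FitError as exc:
            errors[col] = str(exc)
    adjusted = _holm({r.predictor: r.pvalue for r in results}) if holm else None
    return PrincipleComparison(results, errors, adjusted)


def baci_did(panel: pd.DataFrame,
             impact_group: str = "transition",
             control_group: str = "control",
             n_boot: int = 1000,
             seed: int = 0) -> BaciResult:
    """Difference-in-differences for a before–after control–impact panel.

    ``panel`` needs columns farm_id, group, period (before/after), value.
    The estimate is the mean after-minus-before change on impact farms minus
    the same change on control farms; the standard error comes from a
    farm-level block bootstrap (farms resampled with replacement within each
    group), and the p-value from a normal approximation on the bootstrap SE.
    """
    need = {"farm_id", "group", "period", "value"}
    if missing := need - set(panel.columns):
        raise FitError(f"panel missing columns {sorted(missing)}")
    bad = set(panel["period"]) - {"before", "after"}
    if bad:
        raise FitError(f"unknown period labels {sorted(bad)}")

    def farm_changes(group: str) -> np.ndarray:
        sub = panel[panel["group"] == group]
        cell = sub.pivot_table(index="farm_id", columns="period", values="value",
                               aggfunc="mean")
        for period in ("before", "after"):
            if period not in cell.columns or cell[period].isna().any():
                raise FitError(f"missing cell: group {group!r} × period {period!r}")
        return (cell["after"] - cell["before"]).to_numpy()

    impact = farm_changes(impact_group)
    control = farm_changes(control_group)
    estimate = float(impact.mean() - control.mean())

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bi = rng.integers(0, len(impact), len(impact))
        bc = rng.integers(0, len(control), len(control))
        boots[b] = impact[bi].mean() - control[bc].mean()
    stderr = float(boots.std(ddof=1))
    if stderr == 0.0:
        pvalue = 1.0 if estimate == 0.0 else 0.0
    else:
        pvalue = float(2.0 * stats.norm.sf(abs(estimate) / stderr))
    return BaciResult(estimate, stderr, pvalue, len(impact), len(control), n_boot)
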