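"""Air-water thermal sensitivity and future stream-temperature projection.

The coupling slope beta is the OLS slope of maximum daily stream water
temperature (MDST) on maximum daily air temperature (MDAT) over the June 1
to August 31 summer window: the unit change in MDST per 1 degree C change
in MDAT.  Sites with beta >= 0.275 are "high sensitivity"; below that,
stream temperature is treated as decoupled from air temperature and is
assumed not to warm.  A logistic model extends the high/low classification
from gauged sites to ungauged reaches; a linear model fitted on
high-sensitivity sites supplies a continuous beta estimate for reaches the
logistic gate classifies as high.  Future July mean daily maximum stream
temperature is the contemporary estimate plus beta times the air-warming
scenario delta (zero for low-sensitivity reaches).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .thermal import LinearModelSpec, fit_ols

#: Observed-slope boundary between low and high thermal sensitivity
#: (boundary inclusive: beta == 0.275 is high).
BETA_THRESHOLD = 0.275

HIGH, LOW = "high", "low"


@dataclass
class DailyTemperatureSeries:
    """Paired daily maximum air/stream temperatures for one site."""

    site_id: int
    dates: pd.DatetimeIndex
    mdat_c: np.ndarray
    mdst_c: np.ndarray

    def __post_init__(self) -> None:
        self.mdat_c = np.asarray(self.mdat_c, dtype=float)
        self.mdst_c = np.asarray(self.mdst_c, dtype=float)
        if not (len(self.dates) == len(self.mdat_c) == len(self.mdst_c)):
            raise ValueError(f"site {self.site_id}: unequal series lengths")

    def july_mean_mdst(self) -> float:
        """July mean of daily maximum stream temperature (JMMST, deg C)."""
        mask = pd.DatetimeIndex(self.dates).month == 7
        if not mask.any():
            raise ValueError(f"site {self.site_id}: no July observations")
        return float(self.mdst_c[mask].mean())


@dataclass
class SensitivityResult:
    site_or_reach_id: int
    beta_observed: float | None
    beta_predicted: float | None
    sensitivity_class: str
    p_high: float = float("nan")


@dataclass
class LogisticModelSpec:
    """Logistic classifier over reach covariates.

    ``orientation`` states which sensitivity class the linear predictor
    points toward: ``"high"`` means the fitted outcome was high=1 (the
    probability returned by :meth:`predict_p` is that of the high class
    directly); ``"low"`` means the coefficients were fitted with low=1 and
    the probability is complemented.
    """

    intercept: float
    coefficients: dict[str, float]
    cutoff: float = 0.50
    orientation: str = HIGH
    p_values: dict[str, float] = field(default_factory=dict)
    std_errors: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    separation_flag: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must be in (0, 1)")
        if self.orientation not in (HIGH, LOW):
            raise ValueError("orientation must be 'high' or 'low'")

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        missing = [t for t in self.coefficients if t not in covariates.columns]
        if missing:
            raise KeyError(f"covariates missing model terms: {missing}")
        eta = np.full(len(covariates), self.intercept, dtype=float)
        for term, coef in self.coefficients.items():
            eta += coef * covariates[term].to_numpy(dtype=float)
        return eta

    def predict_p(self, covariates: pd.DataFrame) -> np.ndarray:
        """Probability of the *high* sensitivity class per reach."""
        from scipy.special import expit

        p = expit(self.linear_predictor(covariates))
        return p if self.orientation == HIGH else 1.0 - p


def estimate_beta(series: DailyTemperatureSeries) -> float:
    """OLS slope of MDST on MDAT: cov(MDAT, MDST) / var(MDAT)."""
    x, y = series.mdat_c, series.mdst_c
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError(
            f"site {series.site_id}: slope undefined (need >= 2 distinct MDAT)"
        )
    x_c = x - x.mean()
    return float(np.dot(x_c, y) / np.dot(x_c, x_c))


def classify_observed(beta: float, threshold: float = BETA_THRESHOLD) -> str:
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return HIGH if beta >= threshold else LOW


def fit_logistic(
    labels: Sequence[int] | np.ndarray,
    design: pd.DataFrame,
    terms: Sequence[str],
    cutoff: float = 0.50,
    orientation: str = HIGH,
) -> LogisticModelSpec:
    """Maximum-likelihood logistic regression of 0/1 labels on covariates.

    ``labels`` are coded 1 for the ``orientation`` class.  Complete or
    quasi-complete separation is flagged (warning + ``separation_flag``)
    rather than fatal; coefficients are still reported.
    """
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("labels must contain both classes, coded 0/1")
    terms = list(terms)
    X = sm.add_constant(design[terms].astype(float), has_constant="add")

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except np.linalg.LinAlgError:
            # singular Hessian under (quasi-)complete separation; IRLS
            # still yields a finite-iteration fit to report
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
            separation = True
            converged = False
        separation = separation or any(
            "separat" in str(w.message).lower() for w in caught
        )
    if not converged or np.abs(res.params.to_numpy()).max() > 1e3:
        separation = True
    if separation:
        warnings.warn(
            "possible complete separation; logistic coefficients unstable",
            stacklevel=2,
        )
    return LogisticModelSpec(
        intercept=float(res.params["const"]),
        coefficients={t: float(res.params[t]) for t in terms},
        cutoff=cutoff,
        orientation=orientation,
        p_values={t: float(res.pvalues[t]) for t in terms},
        std_errors={t: float(res.bse[t]) for t in terms},
        converged=converged,
        separation_flag=separation,
    )


def classify_predicted(
    model: LogisticModelSpec, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Per-reach p(high) and class (high iff p >= cutoff, boundary inclusive).

    ``covariates`` must be indexed by reach id; returns a DataFrame with
    columns ``p_high`` and ``sensitivity_class``.
    """
    p = model.predict_p(covariates)
    cls = np.where(p >= model.cutoff, HIGH, LOW)
    return pd.DataFrame(
        {"p_high": p, "sensitivity_class": cls}, index=covariates.index
    )


@dataclass
class ConfusionSummary:
    per_class_pct: dict[str, float]
    per_class_counts: dict[str, tuple[int, int]]  # (correct, total)
    overall_pct: float
    n: int


def confusion_summary(true_labels, predicted_labels) -> ConfusionSummary:
    """Per-class and overall percent correctly classified."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"label length mismatch: {len(t)} vs {len(p)}")
    per_pct: dict[str, float] = {}
    per_counts: dict[str, tuple[int, int]] = {}
    for cls in np.unique(t):
        mask = t == cls
        correct = int((p[mask] == cls).sum())
        per_counts[str(cls)] = (correct, int(mask.sum()))
        per_pct[str(cls)] = 100.0 * correct / mask.sum()
    overall = 100.0 * float((t == p).sum()) / len(t)
    return ConfusionSummary(per_pct, per_counts, overall, len(t))


def fit_beta_model(
    beta_observed: Sequence[float] | np.ndarray,
    design: pd.DataFrame,
    terms: Sequence[str],
    threshold: float = BETA_THRESHOLD,
) -> LinearModelSpec:
    """Linear model for the coupling slope, fitted on high-sensitivity
    sites only.  Including a site with observed beta below the threshold
    is an error: the continuous model is defined only over the
    high-sensitivity stratum."""
    beta = np.asarray(beta_observed, dtype=float)
    low = np.flatnonzero(beta < threshold)
    if low.size:
        raise ValueError(
            f"{low.size} low-sensitivity site(s) in beta-model input "
            f"(first at position {low[0]}); fit on observed beta >= "
            f"{threshold} only"
        )
    return fit_ols(beta, design, terms)


@dataclass
class Scenario:
    """Uniform July mean MDAT increase (degrees C) above contemporary."""

    delta_mdat_c: float

    def __post_init__(self) -> None:
        if self.delta_mdat_c < 0:
            raise ValueError("air-warming delta must be >= 0")


def project_future(
    jmmst_now,
    sensitivity_class,
    beta_predicted,
    scenario: Scenario,
) -> np.ndarray:
    """Future JMMST per reach: contemporary + beta * delta for
    high-sensitivity reaches; unchanged for low-sensitivity reaches.

    Predicted betas below zero are clipped to zero so warming air can
    never cool a stream.  Vectorized over aligned per-reach arrays.
    """
    now = np.asarray(jmmst_now, dtype=float)
    cls = np.asarray(sensitivity_class)
    beta = np.asarray(beta_predicted, dtype=float)
    if not (len(now) == len(cls) == len(beta)):
        raise ValueError("inputs must be aligned per reach")
    high = cls == HIGH
    if high.any() and np.isnan(beta[high]).any():
        raise ValueError("high-sensitivity reach without predicted beta")
    increase = np.where(high, np.clip(beta, 0.0, None) * scenario.delta_mdat_c, 0.0)
    return now + increase
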