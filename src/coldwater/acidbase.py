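"""Two-step acid neutralizing capacity (ANC) estimation with monotone
bias recalibration.

Step one is a binomial gate at 300 ueq/L: reaches with predicted
probability of exceeding 300 at or above the cutoff are "high ANC" and are
safely above any biologically relevant acidity threshold, so they receive
no continuous estimate.  Step two is a linear model that predicts a
reach-specific ANC value (possibly negative, for acidified streams) for
the low-ANC reaches only.  Raw linear predictions carry a sign-flipping
bias around a pivot (under-prediction above ~75 ueq/L, over-prediction
below), which is corrected with a monotone nondecreasing recalibration
mapping fitted by isotonic regression; monotonicity guarantees the
correction never reorders reaches by ANC, so threshold crossings move
coherently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .sensitivity import LogisticModelSpec
from .thermal import LinearModelSpec

ANC_GATE_UEQ_L = 300.0
RECAL_PIVOT_UEQ_L = 75.0

HIGH, LOW = "high", "low"


@dataclass
class ANCEstimate:
    reach_id: int
    anc_class: str
    anc_raw: float | None = None
    anc_corrected: float | None = None

    def __post_init__(self) -> None:
        if self.anc_class not in (HIGH, LOW):
            raise ValueError("anc_class must be 'high' or 'low'")
        if (self.anc_class == LOW) != (self.anc_raw is not None):
            raise ValueError("anc_raw present iff class is low")
        if (self.anc_corrected is not None) and (self.anc_raw is None):
            raise ValueError("corrected value requires a raw value")


def classify_anc(model: LogisticModelSpec, covariates: pd.DataFrame) -> pd.Series:
    """Gate reaches into high (> 300 ueq/L) vs low ANC classes.

    The logistic model's positive class is "exceeds the gate"; a reach is
    high iff that probability is at or above the model cutoff.
    """
    p = model.predict_p(covariates)
    cls = np.where(p >= model.cutoff, HIGH, LOW)
    return pd.Series(cls, index=covariates.index, name="anc_class")


def estimate_anc_low(
    model: LinearModelSpec,
    covariates: pd.DataFrame,
    anc_class: pd.Series | None = None,
) -> pd.Series:
    """Linear ANC prediction (ueq/L) for low-class reaches.

    If ``anc_class`` is given it must mark every row low; applying the
    low-ANC model to a high-class reach is an error because those reaches
    are outside the model's fitting stratum.
    """
    if anc_class is not None:
        bad = covariates.index[np.asarray(anc_class) == HIGH]
        if len(bad):
            raise ValueError(
                f"low-ANC linear model applied to high-class reach(es) "
                f"{list(bad[:5])}"
            )
    return pd.Series(
        model.predict(covariates), index=covariates.index, name="anc_raw"
    )


@dataclass
class RecalibrationSpec:
    """Monotone nondecreasing raw -> corrected mapping (piecewise linear).

    ``knots_x`` / ``knots_y`` are the breakpoints; outside the fitted raw
    range the mapping is clamped to the end values, which keeps it
    nondecreasing everywhere.  A knot is placed at the pivot where the
    bias changes sign.
    """

    pivot: float
    knots_x: np.ndarray
    knots_y: np.ndarray
    identity: bool = False

    def __post_init__(self) -> None:
        self.knots_x = np.asarray(self.knots_x, dtype=float)
        self.knots_y = np.asarray(self.knots_y, dtype=float)
        if np.any(np.diff(self.knots_x) < 0) or np.any(np.diff(self.knots_y) < -1e-9):
            raise ValueError("recalibration knots must be nondecreasing")

    def __call__(self, raw):
        return apply_recalibration(self, raw)


def fit_recalibration(
    predicted,
    observed,
    pivot: float = RECAL_PIVOT_UEQ_L,
) -> RecalibrationSpec:
    """Fit the monotone bias-correction mapping on (predicted, observed)
    pairs by isotonic least squares.

    Requires at least 10 pairs.  If the predictions do not span the pivot
    there is nothing to correct on one side; a warning is issued and the
    identity mapping returned.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if len(x) != len(y):
        raise ValueError("predicted/observed length mismatch")
    if len(x) < 10:
        raise ValueError(f"need >= 10 calibration pairs, got {len(x)}")
    if x.min() >= pivot or x.max() <= pivot:
        warnings.warn(
            f"calibration pairs do not span the {pivot} ueq/L pivot; "
            "returning identity mapping",
            stacklevel=2,
        )
        span = np.array([x.min(), x.max()])
        return RecalibrationSpec(pivot, span, span.copy(), identity=True)

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(x, y)
    kx = np.asarray(iso.X_thresholds_, dtype=float)
    ky = np.asarray(iso.y_thresholds_, dtype=float)
    if pivot not in kx:
        ky = np.insert(ky, np.searchsorted(kx, pivot), np.interp(pivot, kx, ky))
        kx = np.insert(kx, np.searchsorted(kx, pivot), pivot)
    return RecalibrationSpec(pivot, kx, ky)


def apply_recalibration(spec: RecalibrationSpec, anc_raw):
    """Map raw ANC predictions through the monotone correction.

    Nondecreasing by construction, so reach order by ANC is preserved.
    Accepts scalars or arrays.
    """
    raw = np.asarray(anc_raw, dtype=float)
    out = np.interp(raw, spec.knots_x, spec.knots_y)
    return float(out) if out.ndim == 0 else out


def rmse(observed, predicted) -> float:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((o - p) ** 2)))


def stratified_rmse(
    observed, predicted, cut_ueq_l: float = 150.0
) -> dict[str, float]:
    """Overall RMSE plus RMSE over predictions below ``cut_ueq_l``, where
    accuracy matters most for biological-impairment mapping."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    out = {"rmse_all": rmse(o, p)}
    mask = p < cut_ueq_l
    out[f"rmse_below_{cut_ueq_l:g}"] = (
        rmse(o[mask], p[mask]) if mask.any() else float("nan")
    )
    return out
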