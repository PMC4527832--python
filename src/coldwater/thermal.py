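"""Contemporary stream-temperature regression.

Fits multiple linear regressions of July mean daily maximum stream water
temperature (JMMST, degrees C) on landscape covariates, selects among
candidate covariate subsets by AIC subject to a per-term significance
constraint, and predicts JMMST across a stream network.

AIC convention: computed from the Gaussian log-likelihood with the maximum
likelihood variance estimate, dropping additive constants,

    AIC = n * ln(SSR / n) + 2 * (k + 1)

where k counts the intercept and slope parameters and the extra 1 counts
the residual variance.  Only AIC differences within a candidate set matter,
so the dropped constants are immaterial.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor


@dataclass
class LinearModelSpec:
    """A fitted (or externally supplied) linear model with diagnostics.

    ``coefficients`` maps covariate ids to slopes.  Diagnostics are empty
    for models built from published coefficient tables, which carry no
    intercept and support only prediction *contrasts*.
    """

    intercept: float
    coefficients: dict[str, float]
    r2: float = float("nan")
    rmse: float = float("nan")
    p_values: dict[str, float] = field(default_factory=dict)
    std_errors: dict[str, float] = field(default_factory=dict)
    vif: dict[str, float] = field(default_factory=dict)
    aic: float = float("nan")
    n_obs: int = 0
    selection_note: str = ""

    @property
    def terms(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, covariates: pd.DataFrame | Mapping[str, float]):
        """Linear prediction intercept + sum(coef * covariate).

        ``covariates`` is a DataFrame (one row per reach) or a mapping for
        a single reach.  Raises ``KeyError`` naming any missing term.
        """
        if isinstance(covariates, pd.DataFrame):
            missing = [t for t in self.coefficients if t not in covariates.columns]
            if missing:
                raise KeyError(f"covariates missing model terms: {missing}")
            out = np.full(len(covariates), self.intercept, dtype=float)
            for term, coef in self.coefficients.items():
                out += coef * covariates[term].to_numpy(dtype=float)
            return out
        missing = [t for t in self.coefficients if t not in covariates]
        if missing:
            raise KeyError(f"covariates missing model terms: {missing}")
        return self.intercept + sum(
            c * float(covariates[t]) for t, c in self.coefficients.items()
        )

    # flat key-value serialization so published coefficient tables can be
    # loaded verbatim
    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"intercept\t{float(self.intercept)!r}\n")
            fh.write(f"r2\t{float(self.r2)!r}\n")
            fh.write(f"rmse\t{float(self.rmse)!r}\n")
            fh.write(f"aic\t{float(self.aic)!r}\n")
            fh.write(f"n_obs\t{self.n_obs}\n")
            fh.write(f"selection_note\t{self.selection_note}\n")
            for term, coef in self.coefficients.items():
                p = float(self.p_values.get(term, float("nan")))
                v = float(self.vif.get(term, float("nan")))
                fh.write(f"term\t{term}\t{float(coef)!r}\t{p!r}\t{v!r}\n")

    @classmethod
    def from_text(cls, path) -> "LinearModelSpec":
        scalars: dict[str, str] = {}
        coefficients: dict[str, float] = {}
        p_values: dict[str, float] = {}
        vif: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "term":
                    _, term, coef, p, v = parts
                    coefficients[term] = float(coef)
                    p_values[term] = float(p)
                    vif[term] = float(v)
                else:
                    scalars[parts[0]] = parts[1] if len(parts) > 1 else ""
        return cls(
            intercept=float(scalars["intercept"]),
            coefficients=coefficients,
            r2=float(scalars["r2"]),
            rmse=float(scalars["rmse"]),
            p_values=p_values,
            vif=vif,
            aic=float(scalars["aic"]),
            n_obs=int(scalars["n_obs"]),
            selection_note=scalars.get("selection_note", ""),
        )


class RankDeficientDesignError(ValueError):
    pass


def _check_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the terms involved in the deficiency via near-zero singular
        # directions
        _, s, vt = np.linalg.svd(mat, full_matrices=False)
        tol = s.max() * max(mat.shape) * np.finfo(float).eps
        bad = np.abs(vt[s < tol]).sum(axis=0)[1:]  # skip the constant
        names = [t for t, w in zip(X.columns, bad) if w > 1e-8]
        raise RankDeficientDesignError(
            f"design is rank deficient; collinear terms: {names}"
        )


def gaussian_aic(ssr: float, n: int, k: int) -> float:
    """n*ln(SSR/n) + 2*(k+1); k = intercept + slopes, +1 for sigma^2."""
    if ssr <= 0:
        ssr = np.finfo(float).tiny
    return float(n * np.log(ssr / n) + 2 * (k + 1))


def fit_ols(
    response: Sequence[float] | np.ndarray,
    design: pd.DataFrame,
    terms: Iterable[str],
    compute_vif: bool = True,
) -> LinearModelSpec:
    """Ordinary least squares of ``response`` on ``design[terms]`` plus an
    intercept, with r2, RMSE (root mean squared residual), per-term
    p-values, and variance inflation factors (``compute_vif=False`` skips
    the VIFs, which cost one auxiliary regression per term)."""
    terms = list(terms)
    y = np.asarray(response, dtype=float)
    if np.isnan(y).any() or design[terms].isna().any().any():
        raise ValueError("missing values in response or design")
    n = len(y)
    if n <= len(terms) + 1:
        raise ValueError(
            f"need more than {len(terms) + 1} observations, got {n}"
        )
    X = design[terms].astype(float)
    _check_rank(X)
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()

    if compute_vif and len(terms) >= 2:
        Xc = sm.add_constant(X, has_constant="add").to_numpy()
        vif = {
            t: float(variance_inflation_factor(Xc, i + 1))
            for i, t in enumerate(terms)
        }
    elif compute_vif:
        vif = {t: 1.0 for t in terms}
    else:
        vif = {}

    ssr = float(res.ssr)
    return LinearModelSpec(
        intercept=float(res.params["const"]),
        coefficients={t: float(res.params[t]) for t in terms},
        r2=float(res.rsquared) if len(terms) else 0.0,
        rmse=float(np.sqrt(ssr / n)),
        p_values={t: float(res.pvalues[t]) for t in terms},
        std_errors={t: float(res.bse[t]) for t in terms},
        vif=vif,
        aic=gaussian_aic(ssr, n, len(terms) + 1),
        n_obs=n,
    )


def _intercept_only(y: np.ndarray, note: str) -> LinearModelSpec:
    n = len(y)
    ssr = float(np.sum((y - y.mean()) ** 2))
    return LinearModelSpec(
        intercept=float(y.mean()),
        coefficients={},
        r2=0.0,
        rmse=float(np.sqrt(ssr / n)),
        aic=gaussian_aic(ssr, n, 1),
        n_obs=n,
        selection_note=note,
    )


def select_model(
    response,
    design: pd.DataFrame,
    candidate_terms: Sequence[str],
    max_terms: int | None = None,
    alpha: float = 0.05,
    exhaustive_limit: int = 16,
) -> LinearModelSpec:
    """Best-subset selection by AIC over admissible covariate subsets.

    A subset is admissible when every included term is significant at
    ``alpha`` in its own fit; the admissible subset with the lowest AIC
    wins.  The search enumerates all subsets when there are at most
    ``exhaustive_limit`` candidates; beyond that it falls back to greedy
    forward expansion over admissible additions (flagged in
    ``selection_note``).  With no admissible subset, the intercept-only
    model is returned with a warning.
    """
    candidate_terms = list(candidate_terms)
    if not candidate_terms:
        raise ValueError("candidate_terms must be nonempty")
    y = np.asarray(response, dtype=float)
    if max_terms is None:
        max_terms = len(candidate_terms)

    best: LinearModelSpec | None = None

    def consider(terms: tuple[str, ...]) -> LinearModelSpec | None:
        try:
            spec = fit_ols(y, design, terms, compute_vif=False)
        except RankDeficientDesignError:
            return None
        if any(p >= alpha for p in spec.p_values.values()):
            return None
        return spec

    if len(candidate_terms) <= exhaustive_limit:
        note = "exhaustive"
        for size in range(1, max_terms + 1):
            for terms in itertools.combinations(candidate_terms, size):
                spec = consider(terms)
                if spec is not None and (best is None or spec.aic < best.aic):
                    best = spec
    else:
        note = "greedy-forward"
        current: tuple[str, ...] = ()
        current_aic = np.inf
        while len(current) < max_terms:
            step_best: LinearModelSpec | None = None
            for t in candidate_terms:
                if t in current:
                    continue
                spec = consider(current + (t,))
                if spec is not None and (step_best is None or spec.aic < step_best.aic):
                    step_best = spec
            if step_best is None or step_best.aic >= current_aic:
                break
            best = step_best
            current = tuple(step_best.coefficients)
            current_aic = step_best.aic

    if best is None:
        warnings.warn(
            "no admissible subset (every candidate model has a term with "
            f"p >= {alpha}); returning intercept-only model",
            stacklevel=2,
        )
        return _intercept_only(y, note="intercept-only (no admissible subset)")
    best = fit_ols(y, design, best.terms)  # refit winner with VIFs
    best.selection_note = note
    return best


def predict_jmmst(model: LinearModelSpec, covariates: pd.DataFrame) -> np.ndarray:
    """Predict JMMST (degrees C) for every row of a reach covariate table."""
    return model.predict(covariates)
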