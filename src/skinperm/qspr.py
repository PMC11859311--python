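"""Linear QSPR-style correlation models for enhancement ratios.

Fits the small multilinear models that relate enhancement ratios to each
other and to molecular descriptors — e.g. QER on (KER, PER), KER on
(polar surface area, hydrogen-bond-donor count), PER on the
solubility-parameter gap Δδ — and reports the multiple correlation
coefficient r = sqrt(1 − SSE/SST), an overall-fit F-test p-value, and
rectangular prediction grids for response-surface plots.

Predictors are used on their raw scales (no standardization) and no
multiple-testing correction is applied across models.  Panels of only a
handful of drugs leave very few residual degrees of freedom; the fit
warns rather than refuses in that regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionResult",
    "DegenerateFitError",
    "CollinearityError",
    "fit_linear_model",
    "pearson_correlation",
    "response_surface",
]


class DegenerateFitError(ValueError):
    """Raised for inputs with no usable variation (constant vectors)."""


class CollinearityError(ValueError):
    """Raised when the design matrix is rank-deficient to machine precision."""


@dataclass(frozen=True)
class RegressionResult:
    """An ordinary-least-squares fit of a response on named predictors.

    ``multiple_r`` is sqrt(1 − SSE/SST); ``p_value`` comes from the overall
    F statistic of the fit.  ``low_df`` flags fewer than 3 residual degrees
    of freedom, where the p-value is fragile.
    """

    predictor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    multiple_r: float
    p_value: float
    n: int
    residual_sd: float
    low_df: bool = False

    def predict(self, predictors: np.ndarray) -> np.ndarray:
        """Linear-model prediction for rows of predictor values."""
        x = np.atleast_2d(np.asarray(predictors, dtype=float))
        if x.shape[1] != len(self.coefficients):
            raise ValueError(
                f"expected {len(self.coefficients)} predictor columns, got {x.shape[1]}"
            )
        return self.intercept + x @ np.asarray(self.coefficients)


def fit_linear_model(
    predictors: pd.DataFrame | np.ndarray,
    response: np.ndarray,
    names: tuple[str, ...] | None = None,
) -> RegressionResult:
    """Fit response = β₀ + Σ βⱼ·xⱼ by OLS with overall-fit diagnostics.

    Raises
    ------
    ValueError
        If there are fewer rows than predictors + 2.
    CollinearityError
        If the design matrix (with constant) is rank-deficient.
    DegenerateFitError
        If the response is constant (r is undefined).
    """
    if isinstance(predictors, pd.DataFrame):
        if names is None:
            names = tuple(str(c) for c in predictors.columns)
        x = predictors.to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(predictors, dtype=float))
        if x.ndim == 2 and x.shape[0] == 1 and x.shape[1] > 1 and len(response) > 1:
            x = x.T
        if names is None:
            names = tuple(f"x{i + 1}" for i in range(x.shape[1]))
    y = np.asarray(response, dtype=float)
    n, p = x.shape
    if y.shape != (n,):
        raise ValueError("response length must match predictor rows")
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows for {p} predictors, got {n}")

    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("predictors are collinear to machine precision")
    if np.ptp(y) == 0:
        raise DegenerateFitError("constant response: correlation undefined")

    with warnings.catch_warnings():
        # tiny panels trigger kurtosis-test warnings irrelevant to the fit
        warnings.simplefilter("ignore")
        fit = sm.OLS(y, design).fit()
    r2 = max(0.0, min(1.0, float(fit.rsquared)))
    dof = n - p - 1
    p_value = float(fit.f_pvalue) if dof > 0 and np.isfinite(fit.f_pvalue) else 1.0
    if dof < 3:
        warnings.warn(
            f"only {dof} residual degree(s) of freedom: p-value is fragile",
            stacklevel=2,
        )
    return RegressionResult(
        predictor_names=tuple(names),
        coefficients=tuple(float(b) for b in fit.params[1:]),
        intercept=float(fit.params[0]),
        multiple_r=float(np.sqrt(r2)),
        p_value=p_value,
        n=n,
        residual_sd=float(np.sqrt(fit.mse_resid)) if dof > 0 else 0.0,
        low_df=dof < 3,
    )


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation coefficient in [−1, 1].

    Requires at least 3 paired observations and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("at least 3 observations required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateFitError("constant input: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def response_surface(
    result: RegressionResult,
    ranges: dict[str, tuple[float, float]],
    resolution: int = 25,
) -> pd.DataFrame:
    """Rectangular prediction grid for a two-predictor model.

    ``ranges`` maps each predictor name to its (min, max); the returned
    long-format DataFrame has one row per grid node with the two predictor
    values and the predicted response, suitable for surface plotting.
    """
    if len(result.coefficients) != 2:
        raise ValueError("response surfaces require exactly 2 predictors")
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    try:
        (lo1, hi1), (lo2, hi2) = (ranges[n] for n in result.predictor_names)
    except KeyError as exc:
        raise ValueError(f"missing range for predictor {exc.args[0]!r}") from exc
    g1 = np.linspace(lo1, hi1, resolution)
    g2 = np.linspace(lo2, hi2, resolution)
    xx, yy = np.meshgrid(g1, g2, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    pred = result.predict(pts)
    n1, n2 = result.predictor_names
    return pd.DataFrame({n1: pts[:, 0], n2: pts[:, 1], "predicted": pred})
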