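"""Extended Bland-Altman assay comparison and linear cross-platform calibration.

Two assays that are each linearly related to an unknown true value (with
independent errors) are themselves linearly related, and so are the
differences and averages of their paired measurements. Regressing the
difference D = y - x on the average A = (x + y)/2 therefore identifies the
between-assay conversion: if D = a + b*A then

    y = a / (1 - b/2)  +  (1 + b/2) / (1 - b/2) * x

which is the conversion (calibration) equation used to transfer values —
and prognostic cutpoints — from one platform's log scale to the other's.
Limits of agreement are the fitted difference line offset by a normal
quantile times the residual sd.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DifferenceMeanFit",
    "CalibrationModel",
    "log_transform",
    "pair_cases",
    "ba_regression",
    "conversion_from_ba",
    "invert_calibration",
    "apply_calibration",
    "limits_of_agreement",
]


@dataclass(frozen=True)
class DifferenceMeanFit:
    """OLS fit of between-assay differences on within-pair averages."""

    intercept_a: float
    slope_b: float
    resid_sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("difference-vs-mean fit needs at least 3 pairs")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be nonnegative")


@dataclass(frozen=True)
class CalibrationModel:
    """Linear conversion ``to = alpha + beta * from`` on the log scale."""

    from_platform: str
    to_platform: str
    alpha: float
    beta: float
    pred_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def equation(self, decimals: int = 2) -> str:
        a = round(self.alpha, decimals)
        b = round(self.beta, decimals)
        return f"{self.to_platform} = {a:+.{decimals}f} {b:+.{decimals}f} x {self.from_platform}"


def log_transform(records: pd.DataFrame) -> pd.DataFrame:
    """Populate ``log_score`` with the natural log of ``score``.

    Nonpositive scores are a domain violation for the log-linear model and
    are rejected, naming the offending cases, rather than offset-corrected.
    """
    scores = records["score"].to_numpy(dtype=float)
    bad = ~(scores > 0)
    if bad.any():
        cases = ", ".join(map(str, records.loc[bad, "case_id"].tolist()[:10]))
        raise ValueError(f"nonpositive score for case(s): {cases}")
    out = records.copy()
    out["log_score"] = np.log(scores)
    return out


def pair_cases(
    records_x: pd.DataFrame, records_y: pd.DataFrame, value: str = "log_score"
) -> pd.DataFrame:
    """Inner-join two platforms' records on case_id.

    Cases present on only one platform are dropped (counts logged).
    Duplicate case_ids within a platform make the pairing ambiguous and are
    an error. Returns a frame with columns ``case_id``, ``x``, ``y``.
    """
    if len(records_x) == 0 or len(records_y) == 0:
        raise ValueError("both record collections must be nonempty")
    for name, rec in (("x", records_x), ("y", records_y)):
        dup = rec["case_id"][rec["case_id"].duplicated()]
        if len(dup):
            raise ValueError(
                f"duplicate case_id on platform {name}: {dup.iloc[0]!r}"
            )
    merged = pd.merge(
        records_x[["case_id", value]].rename(columns={value: "x"}),
        records_y[["case_id", value]].rename(columns={value: "y"}),
        on="case_id",
        how="inner",
    )
    if len(merged) == 0:
        raise ValueError("no overlapping cases between the two platforms")
    drop_x = len(records_x) - len(merged)
    drop_y = len(records_y) - len(merged)
    if drop_x or drop_y:
        logger.info(
            "pair_cases: %d pairs; dropped %d x-only and %d y-only cases",
            len(merged), drop_x, drop_y,
        )
    return merged


def ba_regression(x: np.ndarray, y: np.ndarray) -> DifferenceMeanFit:
    """Regress paired differences on paired averages (ordinary least squares)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    a_vals = (x + y) / 2.0
    d_vals = y - x
    if np.ptp(a_vals) == 0:
        raise ValueError("averages are constant; difference-vs-mean slope undefined")
    slope, intercept = np.polyfit(a_vals, d_vals, 1)
    resid = d_vals - (intercept + slope * a_vals)
    resid_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return DifferenceMeanFit(
        intercept_a=float(intercept), slope_b=float(slope), resid_sd=resid_sd, n=n
    )


def conversion_from_ba(
    fit: DifferenceMeanFit, from_platform: str = "x", to_platform: str = "y"
) -> CalibrationModel:
    """Turn the difference-vs-mean fit into the x -> y conversion equation.

    With D = a + b*A the implied relation y = alpha + beta*x has
    alpha = a/(1 - b/2) and beta = (1 + b/2)/(1 - b/2); the prediction-band
    sd scales by the same 1/(1 - b/2) factor.
    """
    denom = 1.0 - fit.slope_b / 2.0
    if denom == 0:
        raise ValueError("slope_b = 2 is degenerate: conversion undefined")
    return CalibrationModel(
        from_platform=from_platform,
        to_platform=to_platform,
        alpha=fit.intercept_a / denom,
        beta=(1.0 + fit.slope_b / 2.0) / denom,
        pred_sd=abs(fit.resid_sd / denom),
    )


def invert_calibration(model: CalibrationModel) -> CalibrationModel:
    """Algebraic inverse conversion (platforms swapped)."""
    return replace(
        model,
        from_platform=model.to_platform,
        to_platform=model.from_platform,
        alpha=-model.alpha / model.beta,
        beta=1.0 / model.beta,
        pred_sd=model.pred_sd / model.beta,
    )


def apply_calibration(model: CalibrationModel, values: np.ndarray) -> np.ndarray:
    """Map log-scale values through ``alpha + beta * value``."""
    return model.alpha + model.beta * np.asarray(values, dtype=float)


def limits_of_agreement(
    fit: DifferenceMeanFit, level: float = 0.95
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Limit-of-agreement lines in difference-vs-mean coordinates.

    Returns ((lower_intercept, slope), (upper_intercept, slope)): the fitted
    difference line shifted by ±z * resid_sd where z is the standard normal
    quantile of (1 + level)/2.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = float(stats.norm.ppf((1.0 + level) / 2.0))
    half = z * fit.resid_sd
    return (
        (fit.intercept_a - half, fit.slope_b),
        (fit.intercept_a + half, fit.slope_b),
    )
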