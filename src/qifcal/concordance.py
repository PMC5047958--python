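"""Agreement statistics: Lin's CCC, coefficient of variation, 2x2 agreement.

Continuous agreement between platforms is summarised by the concordance
correlation coefficient (Pearson correlation penalised for location and
scale shift — 1 only when paired values lie on the identity line), replicate
reproducibility by the coefficient of variation, and dichotomised agreement
by percent agreement and Cohen's kappa on the 2x2 cross-classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from statsmodels.stats import inter_rater

__all__ = [
    "ConcordanceResult",
    "AgreementTable",
    "KappaResult",
    "ccc",
    "coefficient_of_variation",
    "cross_tabulate",
    "percent_agreement",
    "cohens_kappa",
]

LABELS = ("low", "high")


@dataclass(frozen=True)
class ConcordanceResult:
    rho_c: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not (-1 - 1e-12 <= self.ci_low <= self.rho_c + 1e-12):
            raise ValueError("inconsistent CCC confidence bounds")
        if not (self.rho_c - 1e-12 <= self.ci_high <= 1 + 1e-12):
            raise ValueError("inconsistent CCC confidence bounds")


def ccc(x: np.ndarray, y: np.ndarray, level: float = 0.95) -> ConcordanceResult:
    """Lin's concordance correlation coefficient with an asymptotic CI.

    Moments use the n-denominator (population) form of the original
    estimator; the confidence interval applies the Fisher z-transform with
    Lin's asymptotic variance and back-transforms.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need at least 3 paired observations")
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    if sx2 == 0 or sy2 == 0:
        raise ValueError("zero variance in one of the vectors")
    sxy = np.mean((x - mx) * (y - my))
    rho_c = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    r = sxy / math.sqrt(sx2 * sy2)
    if abs(rho_c) >= 1.0 - 1e-12:
        # perfect (anti)concordance: degenerate CI at the boundary
        return ConcordanceResult(rho_c=float(np.sign(rho_c)),
                                 ci_low=float(np.sign(rho_c)),
                                 ci_high=float(np.sign(rho_c)), n=n)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    one_m = 1.0 - rho_c**2
    var_z = (
        (1.0 - r**2) * rho_c**2 / (one_m * r**2)
        + 4.0 * rho_c**3 * (1.0 - rho_c) * u**2 / (r * one_m**2)
        - 2.0 * rho_c**4 * u**4 / (r**2 * one_m**2)
    ) / (n - 2)
    z = math.atanh(rho_c)
    from scipy.stats import norm

    half = norm.ppf((1 + level) / 2) * math.sqrt(max(var_z, 0.0))
    return ConcordanceResult(
        rho_c=float(rho_c),
        ci_low=float(math.tanh(z - half)),
        ci_high=float(math.tanh(z + half)),
        n=n,
    )


def coefficient_of_variation(replicates: np.ndarray | pd.DataFrame) -> float:
    """Replicate coefficient of variation, in percent.

    ``replicates`` is an (n_cases, k>=2) array (or a frame of replicate
    columns). The per-case CV is sd/mean (sd with the n-1 denominator); the
    reported CoV is the root-mean-square of per-case CVs, times 100 — the
    conventional aggregation for assay reproducibility.
    """
    arr = np.asarray(replicates, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need at least 2 replicates per case")
    if not np.all(arr > 0):
        raise ValueError("replicate values must be positive")
    cv = arr.std(axis=1, ddof=1) / arr.mean(axis=1)
    return float(np.sqrt(np.mean(cv**2)) * 100.0)


@dataclass(frozen=True)
class AgreementTable:
    """2x2 cross-classification of low/high calls by two platforms.

    Cell ``n_lh`` counts cases called low by platform 1 and high by
    platform 2, and so on.
    """

    n_ll: int
    n_lh: int
    n_hl: int
    n_hh: int

    def __post_init__(self) -> None:
        if min(self.n_ll, self.n_lh, self.n_hl, self.n_hh) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total < 1:
            raise ValueError("table must contain at least one pair")

    @property
    def total(self) -> int:
        return self.n_ll + self.n_lh + self.n_hl + self.n_hh

    @property
    def row_marginals(self) -> tuple[int, int]:
        return (self.n_ll + self.n_lh, self.n_hl + self.n_hh)

    @property
    def col_marginals(self) -> tuple[int, int]:
        return (self.n_ll + self.n_hl, self.n_lh + self.n_hh)

    def as_array(self) -> np.ndarray:
        return np.array([[self.n_ll, self.n_lh], [self.n_hl, self.n_hh]])

    def to_frame(self) -> pd.DataFrame:
        rm = self.row_marginals
        cm = self.col_marginals
        return pd.DataFrame(
            {
                "low": [self.n_ll, self.n_hl, cm[0]],
                "high": [self.n_lh, self.n_hh, cm[1]],
                "total": [rm[0], rm[1], self.total],
            },
            index=["low", "high", "total"],
        )


class Agreement(NamedTuple):
    fraction: float
    percent: float


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if self.kappa > 1 + 1e-12:
            raise ValueError("kappa cannot exceed 1")


def cross_tabulate(class_x, class_y) -> AgreementTable:
    """Cross-classify paired low/high labels into an AgreementTable."""
    cx = np.asarray(class_x)
    cy = np.asarray(class_y)
    if cx.shape != cy.shape:
        raise ValueError("label vectors must be paired")
    for v in np.unique(np.concatenate([cx, cy])):
        if v not in LABELS:
            raise ValueError(f"unknown class label {v!r}; expected 'low'/'high'")
    return AgreementTable(
        n_ll=int(np.sum((cx == "low") & (cy == "low"))),
        n_lh=int(np.sum((cx == "low") & (cy == "high"))),
        n_hl=int(np.sum((cx == "high") & (cy == "low"))),
        n_hh=int(np.sum((cx == "high") & (cy == "high"))),
    )


def percent_agreement(table: AgreementTable) -> Agreement:
    """Observed agreement: diagonal fraction and the same as a percentage."""
    frac = (table.n_ll + table.n_hh) / table.total
    return Agreement(fraction=frac, percent=frac * 100.0)


def cohens_kappa(table: AgreementTable) -> KappaResult:
    """Cohen's kappa for the 2x2 table.

    The confidence interval uses the large-sample standard error under the
    alternative; the two-sided p-value tests kappa = 0 with the standard
    error under the null — the conventional pairing.
    """
    arr = table.as_array()
    p_e = float(
        (table.row_marginals[0] * table.col_marginals[0]
         + table.row_marginals[1] * table.col_marginals[1])
    ) / table.total**2
    if p_e >= 1.0 - 1e-12:
        raise ValueError("degenerate marginals: chance agreement is 1, kappa undefined")
    res = inter_rater.cohens_kappa(arr)
    ci_low, ci_high = float(res.kappa_low), float(res.kappa_upp)
    if 0 in table.row_marginals or 0 in table.col_marginals:
        # one rater never used one category: the SE is not interpretable
        ci_low = ci_high = float("nan")
    return KappaResult(
        kappa=float(res.kappa),
        ci_low=ci_low,
        ci_high=min(ci_high, 1.0) if math.isfinite(ci_high) else ci_high,
        p_value=float(res.pvalue_two_sided),
    )
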