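"""Recurrence-free survival: KM estimation, log-rank tests, Cox models.

Recurrence-free survival (RFS) runs from diagnosis to first recurrence;
death without recurrence and loss to follow-up are censoring. Estimation
and testing are delegated to lifelines (product-limit estimator,
multivariate log-rank, Cox partial likelihood with Efron tie handling);
this module provides the validated domain surface and the separation
(monotone-likelihood) flagging that raw Cox output lacks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KMCurve",
    "CoxTerm",
    "CoxResult",
    "build_rfs",
    "km_fit",
    "logrank_test",
    "cox_fit",
]

# |coef| beyond this on the log-HR scale is treated as monotone likelihood
_SEPARATION_COEF = 10.0


def build_rfs(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table into recurrence-free survival records.

    Requires columns ``case_id``, ``time_months`` (months from diagnosis to
    first recurrence, or to last contact/death without recurrence) and
    ``event`` (1 = recurrence, 0 = censored). Covariate columns pass
    through unchanged.
    """
    for col in ("case_id", "time_months", "event"):
        if col not in clinical.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    out = clinical.copy()
    out["time_months"] = pd.to_numeric(out["time_months"])
    if (out["time_months"] < 0).any():
        bad = out.loc[out["time_months"] < 0, "case_id"].iloc[0]
        raise ValueError(f"negative follow-up time for case {bad!r}")
    ev = pd.to_numeric(out["event"])
    if not ev.isin([0, 1]).all():
        raise ValueError("event flag must be 0 or 1")
    out["event"] = ev.astype(int)
    return out


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate for one group."""

    group_label: str
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival estimate must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "group": self.group_label,
            }
        )


def km_fit(records: pd.DataFrame, labels) -> dict[str, KMCurve]:
    """Kaplan-Meier curve per group label."""
    labels = np.asarray(labels)
    if len(labels) != len(records):
        raise ValueError("labels must be paired with records")
    curves: dict[str, KMCurve] = {}
    for grp in pd.unique(labels):
        mask = labels == grp
        if mask.sum() == 0:
            raise ValueError(f"empty group {grp!r}")
        t = records.loc[mask, "time_months"].to_numpy(dtype=float)
        e = records.loc[mask, "event"].to_numpy(dtype=int)
        kmf = KaplanMeierFitter()
        kmf.fit(t, e)
        tbl = kmf.event_table
        ev_rows = tbl[tbl["observed"] > 0]
        times = ev_rows.index.to_numpy(dtype=float)
        surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
        curves[str(grp)] = KMCurve(
            group_label=str(grp),
            event_times=times,
            survival=surv,
            at_risk=ev_rows["at_risk"].to_numpy(dtype=int),
            n=int(mask.sum()),
            n_events=int(e.sum()),
        )
    return curves


def logrank_test(records: pd.DataFrame, labels) -> tuple[float, float]:
    """Log-rank chi-square and two-sided p-value across >= 2 groups."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(
        records["time_months"].to_numpy(dtype=float),
        labels,
        records["event"].to_numpy(dtype=int),
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxTerm:
    covariate: str
    level: str
    reference: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_level: int
    n_reference: int
    separation: bool = False


@dataclass(frozen=True)
class CoxResult:
    terms: tuple[CoxTerm, ...]
    n: int
    n_events: int
    separation: bool = False
    log_likelihood: float = field(default=float("nan"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.terms])

    def term(self, covariate: str) -> CoxTerm:
        for t in self.terms:
            if t.covariate == covariate:
                return t
        raise KeyError(covariate)


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    reference: dict[str, str] | None = None,
) -> CoxResult:
    """Cox proportional-hazards fit for categorical covariates.

    Each covariate is dummy-coded against a declared reference level (by
    default the lexicographically last level; pass ``reference`` explicitly
    to report, e.g., low-vs-high marker hazard ratios with ``high`` as the
    reference). Tied event times are handled by
    Efron's method. Monotone partial likelihood (complete separation) is
    flagged and the affected hazard ratio reported as infinite rather than
    as a spurious finite number.
    """
    reference = reference or {}
    records = build_rfs(records)
    if records["event"].sum() < 1:
        raise ValueError("Cox model needs at least one event")
    design = pd.DataFrame(
        {
            "time_months": records["time_months"].to_numpy(dtype=float),
            "event": records["event"].to_numpy(dtype=int),
        }
    )
    meta: list[tuple[str, str, str, int, int]] = []  # column, covariate, level...
    for cov in covariates:
        levels = sorted(map(str, pd.unique(records[cov].astype(str))))
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} has a single level")
        ref = str(reference.get(cov, levels[-1]))
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not found for {cov!r}")
        vals = records[cov].astype(str).to_numpy()
        for lev in levels:
            if lev == ref:
                continue
            col = f"{cov}[{lev}]"
            design[col] = (vals == lev).astype(float)
            meta.append(
                (col, cov, lev, ref, int((vals == lev).sum()), int((vals == ref).sum()))
            )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(design, duration_col="time_months", event_col="event")
    summary = cph.summary
    terms = []
    any_sep = False
    for col, cov, lev, ref, n_lev, n_ref in meta:
        row = summary.loc[col]
        coef = float(row["coef"])
        sep = abs(coef) > _SEPARATION_COEF
        any_sep = any_sep or sep
        hr = float(np.inf * np.sign(coef)) if sep else float(np.exp(coef))
        terms.append(
            CoxTerm(
                covariate=cov,
                level=lev,
                reference=ref,
                hr=hr,
                ci_low=float("nan") if sep else float(row["exp(coef) lower 95%"]),
                ci_high=float("nan") if sep else float(row["exp(coef) upper 95%"]),
                p_value=float("nan") if sep else float(row["p"]),
                n_level=n_lev,
                n_reference=n_ref,
                separation=sep,
            )
        )
    return CoxResult(
        terms=tuple(terms),
        n=len(records),
        n_events=int(records["event"].sum()),
        separation=any_sep,
        log_likelihood=float(cph.log_likelihood_),
    )
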