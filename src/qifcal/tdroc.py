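"""Time-dependent ROC curves and AUC(t) under right censoring.

The cumulative-case / dynamic-control construction is used: at horizon t,
cases are subjects with an observed event by t and controls are subjects
event-free beyond t. Subjects censored before t are neither, and their
missingness is corrected by inverse-probability-of-censoring weights (IPCW)
from a reverse Kaplan-Meier estimate of the censoring distribution. With no
censoring every weight is 1 and the AUC reduces exactly to the empirical
two-sample rank statistic between cases and controls.

The study's marker is protective (low values carry the risk), so by default
the negated marker is used as the risk score; both the curve and the AUC
are invariant to strictly increasing transformations of the marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TdRocResult", "td_roc", "auc_series"]


@dataclass(frozen=True)
class TdRocResult:
    horizon_months: float
    thresholds: np.ndarray  # descending risk-score values
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def _censor_survival_before(time: np.ndarray, event: np.ndarray, at: np.ndarray):
    """Reverse-KM censoring survival G(t-) evaluated at each ``at`` time.

    The censoring distribution is estimated with the roles of event and
    censoring swapped; at tied times, events precede censorings, so a
    subject failing at t contributes a full risk-set member to the censoring
    estimate at t. G(t-) is the product over censoring times strictly
    below t.
    """
    order = np.argsort(time, kind="stable")
    t_s = time[order]
    c_s = 1 - event[order]  # censoring indicator
    n = len(t_s)
    uniq, starts = np.unique(t_s, return_index=True)
    n_risk = (n - starts).astype(float)
    d_c = np.add.reduceat(c_s.astype(float), starts)
    factors = 1.0 - d_c / n_risk
    surv = np.cumprod(factors)  # G right-continuous at uniq
    # G(t-) = value at the last unique time strictly below t
    idx = np.searchsorted(uniq, at, side="left") - 1
    g_minus = np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)
    return g_minus


def td_roc(
    marker: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon_months: float,
    low_is_risk: bool = True,
) -> TdRocResult:
    """IPCW cumulative/dynamic ROC for the marker at one horizon.

    Cases (event by the horizon) are weighted by 1/G(T-) where G is the
    reverse-KM censoring survival; controls (followed beyond the horizon)
    are unweighted. Ties in the risk score contribute 0.5 to concordance.
    """
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if horizon_months > time.max():
        raise ValueError("horizon lies beyond the observed follow-up")
    risk = -marker if low_is_risk else marker.copy()
    is_case = (time <= horizon_months) & (event == 1)
    is_control = time > horizon_months
    n_cases = int(is_case.sum())
    n_controls = int(is_control.sum())
    if n_cases == 0:
        raise ValueError("no events observed before the horizon")
    if n_controls == 0:
        raise ValueError("no subjects followed beyond the horizon")
    g_minus = _censor_survival_before(time, event, time[is_case])
    w = 1.0 / np.clip(g_minus, 1e-12, None)
    r_case = risk[is_case]
    r_ctrl = np.sort(risk[is_control])

    # ROC coordinates over descending risk thresholds
    thresholds = np.unique(np.concatenate([r_case, risk[is_control]]))[::-1]
    w_total = w.sum()
    sens = np.array([w[r_case >= c].sum() / w_total for c in thresholds])
    spec = np.array(
        [(len(r_ctrl) - np.searchsorted(r_ctrl, c, side="left")) / n_controls
         for c in thresholds]
    )
    spec = 1.0 - spec  # fraction of controls strictly below threshold... see below
    # specificity = P(risk < c | control); computed as 1 - P(risk >= c | control)
    thresholds = np.concatenate([[np.inf], thresholds])
    sens = np.concatenate([[0.0], sens])
    spec = np.concatenate([[1.0], spec])

    # weighted rank AUC with 0.5 for ties
    less = np.searchsorted(r_ctrl, r_case, side="left")
    leq = np.searchsorted(r_ctrl, r_case, side="right")
    conc = less + 0.5 * (leq - less)
    auc = float(np.sum(w * conc) / (w_total * n_controls))
    return TdRocResult(
        horizon_months=float(horizon_months),
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=min(max(auc, 0.0), 1.0),
        n_cases=n_cases,
        n_controls=n_controls,
    )


def auc_series(
    marker: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizons,
    low_is_risk: bool = True,
) -> pd.DataFrame:
    """AUC(t) across horizons; failed horizons become gaps, not errors."""
    rows = []
    for h in horizons:
        try:
            r = td_roc(marker, time, event, h, low_is_risk=low_is_risk)
            rows.append(
                {
                    "horizon_months": float(h),
                    "auc": r.auc,
                    "n_cases": r.n_cases,
                    "n_controls": r.n_controls,
                    "note": "",
                }
            )
        except ValueError as ex:
            rows.append(
                {
                    "horizon_months": float(h),
                    "auc": float("nan"),
                    "n_cases": 0,
                    "n_controls": 0,
                    "note": str(ex),
                }
            )
    return pd.DataFrame(rows)
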