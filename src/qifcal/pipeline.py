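"""End-to-end orchestration: calibration -> agreement -> outcome -> ROC.

``run_pipeline`` reproduces the full analysis sequence on a pair of
platforms: log-transform and pair the measurements, fit the extended
Bland-Altman calibration in both directions, compute concordance before and
after calibration, find a data-driven survival cutpoint on each platform,
transfer each cutpoint to the other platform through the conversion
equations, cross-tabulate native against transferred classifications
(percent agreement, kappa), run KM / log-rank / Cox for every
classification, compute the time-dependent AUC series per platform, and —
when chromogen scores are available — the three-group chromogen/fluorescence
stratification. Every number in the report is produced by one upstream
module operation; the report layer only rounds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import concordance as conc
from . import cutpoints as cp
from . import io as qio
from . import survival as surv
from . import synthetic as syn
from . import tdroc

__version__ = "0.1.0"
logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "chromogen_stratify"]

DEFAULT_HORIZONS = tuple(12.0 * k for k in range(1, 13))  # years 1..12 in months


@dataclass
class PipelineConfig:
    """Everything needed to run (and re-run) one analysis."""

    measurements_path: str | None = None
    clinical_path: str | None = None
    synthetic_n: int | None = None
    platforms: tuple[str, str] = ("AQUA", "TissueStudio")
    folds: int = 10
    min_frac: float = 0.10
    percentile: float | None = None
    horizons: tuple[float, ...] = DEFAULT_HORIZONS
    seed: int | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if len(self.platforms) != 2 or self.platforms[0] == self.platforms[1]:
            raise ValueError("exactly two distinct platforms must be selected")
        if self.seed is None and (self.synthetic_n is not None or self.folds >= 2):
            raise ValueError(
                "a seed is mandatory when synthetic data or cross-validation is used"
            )
        if self.measurements_path is None and self.synthetic_n is None:
            raise ValueError("either input paths or a synthetic cohort size is required")

    def echo(self) -> dict:
        return {
            "measurements_path": self.measurements_path,
            "clinical_path": self.clinical_path,
            "synthetic_n": self.synthetic_n,
            "platforms": list(self.platforms),
            "folds": self.folds,
            "min_frac": self.min_frac,
            "percentile": self.percentile,
            "horizons": list(self.horizons),
            "seed": self.seed,
            "version": __version__,
        }


@dataclass
class ReportBundle:
    calibration: dict = field(default_factory=dict)
    agreement: dict = field(default_factory=dict)
    outcome: dict = field(default_factory=dict)
    roc: dict = field(default_factory=dict)
    chromogen: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "calibration": self.calibration,
            "agreement": self.agreement,
            "outcome": self.outcome,
            "roc": self.roc,
            "chromogen": self.chromogen,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_jsonify)

    def to_text(self) -> str:
        lines = ["# qifcal analysis report", ""]
        lines += ["## Calibration"]
        for k in ("equation_forward", "equation_reverse"):
            if k in self.calibration:
                lines.append(f"  {self.calibration[k]}")
        for k in ("ccc_before", "ccc_after_forward", "ccc_after_reverse"):
            if k in self.calibration:
                c = self.calibration[k]
                lines.append(
                    f"  {k}: {c['rho_c']:.3f} (95% CI {c['ci_low']:.3f}, {c['ci_high']:.3f})"
                )
        lines += ["", "## Agreement"]
        for name, sec in sorted(self.agreement.items()):
            lines.append(
                f"  {name}: agreement {sec['percent_agreement']:.1f}%, "
                f"kappa {sec['kappa']:.3f} "
                f"({sec['kappa_ci_low']:.3f}-{sec['kappa_ci_high']:.3f}), "
                f"P={sec['kappa_p']:.3g}"
            )
        lines += ["", "## Outcome"]
        for name, sec in sorted(self.outcome.items()):
            if "hr_low" in sec:
                lines.append(
                    f"  {name}: frac_low {sec['frac_low']:.2f}, HR "
                    f"{sec['hr_low']:.2f} ({sec['hr_ci_low']:.2f}-{sec['hr_ci_high']:.2f}), "
                    f"log-rank P={sec['logrank_p']:.3g}"
                )
        lines += ["", "## Time-dependent AUC"]
        for name, sec in sorted(self.roc.items()):
            series = ", ".join(
                f"{int(h)}m:{a:.3f}" for h, a in zip(sec["horizons"], sec["auc"])
                if np.isfinite(a)
            )
            lines.append(f"  {name}: {series}")
        if self.chromogen:
            lines += ["", "## Chromogen stratification"]
            for g, n in sorted(self.chromogen.get("group_sizes", {}).items()):
                lines.append(f"  {g}: n={n}")
            if "logrank_p" in self.chromogen:
                lines.append(
                    f"  log-rank chi2={self.chromogen['logrank_chi2']:.2f}, "
                    f"P={self.chromogen['logrank_p']:.3g}"
                )
        lines += ["", "## Provenance", f"  {json.dumps(self.provenance, sort_keys=True)}"]
        return "\n".join(lines) + "\n"


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def _ccc_dict(r: conc.ConcordanceResult) -> dict:
    return {"rho_c": r.rho_c, "ci_low": r.ci_low, "ci_high": r.ci_high, "n": r.n}


def chromogen_stratify(
    if_labels, dab_percent, records: pd.DataFrame
) -> dict:
    """Three-group chromogen/fluorescence stratification with KM + log-rank.

    DAB-positive means percent-positive >= 1 (the 1% detection floor of
    pathologist review). Groups: IF-low & DAB-low, IF-high & DAB-low,
    IF-high & DAB-high; the usually-empty IF-low & DAB-high combination is
    reported with its count and enters the comparison only if occupied.
    """
    if_labels = np.asarray(if_labels)
    dab = np.asarray(dab_percent, dtype=float)
    if len(if_labels) != len(records) or len(dab) != len(records):
        raise ValueError("labels, scores and records must be paired")
    dab_pos = dab >= 1.0
    group = np.where(
        if_labels == "low",
        np.where(dab_pos, "IF-low/DAB-high", "IF-low/DAB-low"),
        np.where(dab_pos, "IF-high/DAB-high", "IF-high/DAB-low"),
    )
    sizes = {g: int((group == g).sum()) for g in np.unique(group)}
    sizes.setdefault("IF-low/DAB-high", 0)
    occupied = group[np.isin(group, [g for g, n in sizes.items() if n > 0])]
    out: dict = {"group_sizes": sizes}
    curves = surv.km_fit(records, group)
    out["km"] = {g: c.to_frame().to_dict(orient="list") for g, c in curves.items()}
    if len(np.unique(occupied)) >= 2:
        chi2, p = surv.logrank_test(records, group)
        out["logrank_chi2"] = chi2
        out["logrank_p"] = p
    return out


def _outcome_section(
    marker: np.ndarray, threshold: float, records: pd.DataFrame, name: str
) -> tuple[dict, np.ndarray]:
    labels = cp.dichotomize(marker, threshold)
    sec: dict = {"threshold": float(threshold), "frac_low": float(np.mean(labels == "low"))}
    if len(np.unique(labels)) < 2:
        sec["note"] = "degenerate dichotomization: single class"
        return sec, labels
    chi2, p = surv.logrank_test(records, labels)
    sec["logrank_chi2"], sec["logrank_p"] = chi2, p
    covs = ["marker"]
    rec = records.copy()
    rec["marker"] = labels
    ref = {"marker": "high"}
    if "pr_status" in rec.columns and rec["pr_status"].nunique() > 1:
        covs.append("pr_status")
        ref["pr_status"] = "pos"
    fit = surv.cox_fit(rec, covs, reference=ref)
    t = fit.term("marker")
    sec.update(
        hr_low=t.hr, hr_ci_low=t.ci_low, hr_ci_high=t.ci_high, hr_p=t.p_value,
        n=fit.n, n_events=fit.n_events, separation=fit.separation,
    )
    if "pr_status" in covs:
        tp = fit.term("pr_status")
        sec["hr_pr_neg"], sec["hr_pr_p"] = tp.hr, tp.p_value
    curves = surv.km_fit(records, labels)
    sec["km"] = {g: c.to_frame().to_dict(orient="list") for g, c in curves.items()}
    return sec, labels


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and (optionally) write the report bundle."""
    bundle = ReportBundle(provenance=config.echo())
    p1, p2 = config.platforms

    stage = "inputs"
    try:
        if config.measurements_path is not None:
            meas = qio.read_measurements(config.measurements_path)
            clinical = qio.read_clinical(config.clinical_path)
        else:
            study = syn.simulate_study(n=config.synthetic_n, seed=config.seed)
            meas = study.measurements[["case_id", "platform_id", "score"]]
            clinical = study.clinical.drop(columns=["latent_low"])
        clinical = surv.build_rfs(clinical)

        stage = "log_transform"
        meas = cal.log_transform(meas)
        rec1 = meas[meas["platform_id"] == p1]
        rec2 = meas[meas["platform_id"] == p2]
        if len(rec1) == 0 or len(rec2) == 0:
            raise ValueError(f"platform(s) missing from measurements: {p1}/{p2}")

        stage = "pairing"
        pairs = cal.pair_cases(rec1, rec2)
        n_pairs = len(pairs)
        logger.info("paired %d cases on both platforms", n_pairs)
        if n_pairs < 3:
            raise ValueError("need at least 3 cases measured on both platforms")
        x = pairs["x"].to_numpy()
        y = pairs["y"].to_numpy()

        stage = "calibration"
        fit = cal.ba_regression(x, y)
        model_fwd = cal.conversion_from_ba(fit, from_platform=p1, to_platform=p2)
        model_rev = cal.invert_calibration(model_fwd)
        loa = cal.limits_of_agreement(fit, level=0.95)
        bundle.calibration = {
            "n_pairs": n_pairs,
            "difference_mean_fit": {
                "intercept_a": fit.intercept_a,
                "slope_b": fit.slope_b,
                "resid_sd": fit.resid_sd,
            },
            "alpha_forward": model_fwd.alpha,
            "beta_forward": model_fwd.beta,
            "alpha_reverse": model_rev.alpha,
            "beta_reverse": model_rev.beta,
            "equation_forward": model_fwd.equation(),
            "equation_reverse": model_rev.equation(),
            "limits_of_agreement": {
                "lower": list(loa[0]), "upper": list(loa[1]), "level": 0.95,
            },
        }

        stage = "concordance"
        bundle.calibration["ccc_before"] = _ccc_dict(conc.ccc(x, y))
        # platform-2 values calibrated onto platform-1's scale, and vice versa
        y_on_1 = cal.apply_calibration(model_rev, y)
        x_on_2 = cal.apply_calibration(model_fwd, x)
        bundle.calibration["ccc_after_forward"] = _ccc_dict(conc.ccc(x, y_on_1))
        bundle.calibration["ccc_after_reverse"] = _ccc_dict(conc.ccc(y, x_on_2))

        stage = "outcome_join"
        data = pairs.merge(clinical, on="case_id", how="inner")
        n_dropped = n_pairs - len(data)
        if n_dropped:
            logger.info("dropped %d paired cases without clinical data", n_dropped)
        if len(data) == 0 or data["event"].sum() == 0:
            raise ValueError("no cases with outcome data and an observed event")
        mx = data["x"].to_numpy()
        my = data["y"].to_numpy()

        stage = "cutpoints"
        if config.percentile is not None:
            thr1 = cp.percentile_cutpoint(mx, config.percentile)
            thr2 = cp.percentile_cutpoint(my, config.percentile)
            cut1 = cut2 = None
        else:
            cut1 = cp.datadriven_cutpoint(
                mx, data["time_months"], data["event"],
                folds=config.folds, min_frac=config.min_frac,
                seed=config.seed, platform=p1,
            )
            cut2 = cp.datadriven_cutpoint(
                my, data["time_months"], data["event"],
                folds=config.folds, min_frac=config.min_frac,
                seed=config.seed, platform=p2,
            )
            thr1, thr2 = cut1.threshold, cut2.threshold
        thr1_on_2 = cp.transfer_cutpoint(thr1, model_fwd, platform=p1)
        thr2_on_1 = cp.transfer_cutpoint(thr2, model_rev, platform=p2)

        stage = "outcome"
        analyses = {
            f"{p1}_native": (mx, thr1),
            f"{p2}_transferred_from_{p1}": (my, thr1_on_2),
            f"{p2}_native": (my, thr2),
            f"{p1}_transferred_from_{p2}": (mx, thr2_on_1),
        }
        labels_by_name = {}
        for name, (marker, thr) in analyses.items():
            sec, labels = _outcome_section(marker, thr, data, name)
            if cut1 is not None and name.endswith("_native"):
                cut = cut1 if name.startswith(p1) else cut2
                sec["cv_supported"] = cut.cv_supported
                sec["split_statistic"] = cut.split_statistic
            bundle.outcome[name] = sec
            labels_by_name[name] = labels

        stage = "agreement"
        comparisons = {
            f"{p1}_native_vs_{p2}_transferred": (
                f"{p1}_native", f"{p2}_transferred_from_{p1}"
            ),
            f"{p1}_transferred_vs_{p2}_native": (
                f"{p1}_transferred_from_{p2}", f"{p2}_native"
            ),
        }
        for name, (a, b) in comparisons.items():
            table = conc.cross_tabulate(labels_by_name[a], labels_by_name[b])
            agr = conc.percent_agreement(table)
            sec = {
                "counts": {
                    "n_ll": table.n_ll, "n_lh": table.n_lh,
                    "n_hl": table.n_hl, "n_hh": table.n_hh,
                },
                "total": table.total,
                "percent_agreement": agr.percent,
            }
            try:
                kap = conc.cohens_kappa(table)
                sec.update(
                    kappa=kap.kappa, kappa_ci_low=kap.ci_low,
                    kappa_ci_high=kap.ci_high, kappa_p=kap.p_value,
                )
            except ValueError as ex:
                sec["kappa_note"] = str(ex)
                sec.update(kappa=float("nan"), kappa_ci_low=float("nan"),
                           kappa_ci_high=float("nan"), kappa_p=float("nan"))
            bundle.agreement[name] = sec

        stage = "roc"
        for pname, marker in ((p1, mx), (p2, my)):
            series = tdroc.auc_series(
                marker, data["time_months"].to_numpy(), data["event"].to_numpy(),
                config.horizons,
            )
            bundle.roc[pname] = {
                "horizons": series["horizon_months"].tolist(),
                "auc": series["auc"].tolist(),
                "n_cases": series["n_cases"].tolist(),
                "note": [n for n in series["note"] if n],
            }

        stage = "chromogen"
        if "chromogen_percent" in data.columns and data["chromogen_percent"].notna().all():
            bundle.chromogen = chromogen_stratify(
                labels_by_name[f"{p2}_native"],
                data["chromogen_percent"].to_numpy(),
                data,
            )
    except Exception as ex:
        if config.out_dir is not None:
            _write_bundle(bundle, config.out_dir)  # retain partial outputs
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {ex}") from ex

    if config.out_dir is not None:
        _write_bundle(bundle, config.out_dir)
    return bundle


def _write_bundle(bundle: ReportBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(bundle.to_json())
    (out / "report.txt").write_text(bundle.to_text())
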