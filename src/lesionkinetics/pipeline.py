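"""End-to-end orchestration: validate -> classify -> features -> models -> survival.

Every stage is also importable on its own; this module wires them together
with a YAML-backed :class:`RunConfig`, structured per-stage logging and
deterministic outputs (the config hash and seed are embedded in the run
log so re-runs are auditable).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import response, stats
from .response import HPDvCriteria

logger = logging.getLogger("lesionkinetics")

__all__ = ["RunConfig", "ValidationReport", "validate_inputs", "run_pipeline"]


@dataclass
class RunConfig:
    lesions_csv: str
    patients_csv: str
    patch_dir: Optional[str] = None
    features_csv: Optional[str] = None
    out_dir: str = "run_output"
    ttf_max_months: float = 2.0
    ratio_min: float = 2.0
    increase_min_pct: float = 50.0
    nelson_threshold_pct: float = 25.0
    require_different_organs: bool = True
    bin_width: float = 25.0
    screen_alpha: float = 0.1
    elimination_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for path in (self.lesions_csv, self.patients_csv):
            if not os.path.exists(path):
                raise FileNotFoundError(path)
        if self.patch_dir is not None and not os.path.isdir(self.patch_dir):
            raise FileNotFoundError(self.patch_dir)
        for name in ("screen_alpha", "elimination_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def criteria(self) -> HPDvCriteria:
        return HPDvCriteria(
            ttf_max_months=self.ttf_max_months,
            ratio_min=self.ratio_min,
            increase_min_pct=self.increase_min_pct,
        )

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ValidationReport:
    problems: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems

    def add(self, msg: str) -> None:
        self.problems.append(msg)


def validate_inputs(lesions_csv: str, patients_csv: str) -> ValidationReport:
    """Column/type/range checks plus duplicate and orphan detection."""
    report = ValidationReport()
    try:
        lesions = pd.read_csv(lesions_csv)
    except Exception as exc:
        report.add(f"{lesions_csv}: unreadable ({exc})")
        return report
    try:
        patients = pd.read_csv(patients_csv)
    except Exception as exc:
        report.add(f"{patients_csv}: unreadable ({exc})")
        return report
    for col in ("patient_id", "lesion_id", "organ", "timepoint", "scan_date", "volume_mm3"):
        if col not in lesions.columns:
            report.add(f"{lesions_csv}: missing column '{col}'")
    for col in ("patient_id", "ttf_days", "os_days", "os_event"):
        if col not in patients.columns:
            report.add(f"{patients_csv}: missing column '{col}'")
    if not report.ok:
        return report
    bad_tp = ~lesions.timepoint.isin(response.TIMEPOINTS)
    for i in lesions.index[bad_tp]:
        report.add(f"{lesions_csv} row {i}: unknown timepoint '{lesions.loc[i, 'timepoint']}'")
    bad_org = ~lesions.organ.isin(response.ORGANS)
    for i in lesions.index[bad_org]:
        report.add(f"{lesions_csv} row {i}: unknown organ '{lesions.loc[i, 'organ']}'")
    neg = lesions.volume_mm3.notna() & (lesions.volume_mm3 < 0)
    for i in lesions.index[neg]:
        report.add(f"{lesions_csv} row {i}: negative volume {lesions.loc[i, 'volume_mm3']}")
    dup = lesions.duplicated(subset=["lesion_id", "timepoint"], keep=False)
    for (lid, tp), grp in lesions[dup].groupby(["lesion_id", "timepoint"]):
        report.add(f"{lesions_csv}: duplicate ({lid}, {tp}) rows {list(grp.index)}")
    orphans = set(lesions.patient_id) - set(patients.patient_id)
    for pid in sorted(orphans):
        report.add(f"{lesions_csv}: patient '{pid}' not present in {patients_csv}")
    for col, lo in (("ttf_days", 0), ("os_days", 0)):
        bad = patients[col] <= lo
        for i in patients.index[bad]:
            report.add(f"{patients_csv} row {i}: {col} must be > {lo}")
    bad_ev = ~patients.os_event.isin([0, 1])
    for i in patients.index[bad_ev]:
        report.add(f"{patients_csv} row {i}: os_event must be 0 or 1")
    return report


def _extract_patch_features(patch_dir: str, bin_width: float) -> pd.DataFrame:
    from .features import extract_features
    from .io import read_patch

    rows = []
    for fname in sorted(os.listdir(patch_dir)):
        if not fname.endswith(("_image.nii.gz", "_image.nii", "_image.nrrd")):
            continue
        lid = fname.split("_image")[0]
        mask_name = fname.replace("_image", "_mask")
        mask_path = os.path.join(patch_dir, mask_name)
        if not os.path.exists(mask_path):
            logger.warning("patch %s has no mask file; skipped", fname)
            continue
        patch = read_patch(os.path.join(patch_dir, fname), mask_path)
        fv = extract_features(patch, bin_width=bin_width)
        rows.append({"lesion_id": lid, **fv.values})
    return pd.DataFrame(rows)


def _fit_stratum(feats, y, cluster, screen_alpha, elim_alpha):
    selected = stats.univariate_screen(feats, y, cluster, alpha=screen_alpha)
    if not selected:
        return None
    fit, roc = stats.multivariable_model(
        feats[selected], y, cluster, alpha_stay=elim_alpha
    )
    terms = [t for t in fit.params.index if t != "intercept"]
    return {
        "selected_by_screen": selected,
        "final_terms": terms,
        "p_values": {t: float(fit.p_values[t]) for t in terms},
        "odds_ratios": {t: float(fit.odds_ratios[t]) for t in terms},
        "or_ci": {
            t: [float(fit.or_ci.loc[t, "lower"]), float(fit.or_ci.loc[t, "upper"])]
            for t in terms
        },
        "auc": roc.auc,
        "auc_ci": list(roc.ci_95),
        "n_clusters": fit.n_clusters,
        "converged": fit.converged,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the artifact dict and writes
    CSV/JSON outputs plus a run log under ``config.out_dir``."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    log_records = [f"config_hash={config.digest()}", f"seed={config.seed}"]

    report = validate_inputs(config.lesions_csv, config.patients_csv)
    if not report.ok:
        raise ValueError("input validation failed:\n" + "\n".join(report.problems))
    lesions_df = pd.read_csv(config.lesions_csv)
    patients_df = pd.read_csv(config.patients_csv)
    lesions = response.lesions_from_frame(lesions_df)
    patients = response.patients_from_frame(patients_df)
    log_records.append(f"loaded lesions={len(lesions)} patients={len(patients)}")

    criteria = config.criteria()
    classifications, patients_out = response.classify_cohort(
        lesions,
        patients,
        criteria=criteria,
        nelson_threshold_pct=config.nelson_threshold_pct,
        require_different_organs=config.require_different_organs,
    )
    summary = response.summarize_cohort(
        lesions,
        patients,
        criteria=criteria,
        nelson_threshold_pct=config.nelson_threshold_pct,
        require_different_organs=config.require_different_organs,
    )
    classifications.to_csv(os.path.join(config.out_dir, "classifications.csv"), index=False)
    patients_out.to_csv(os.path.join(config.out_dir, "patients_out.csv"), index=False)
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
    log_records.append(
        "classified: hpdv=%d non_hpdv=%d excluded=%d dr=%d non_dr=%d"
        % (summary.n_hpdv, summary.n_non_hpdv, summary.n_excluded, summary.n_dr, summary.n_non_dr)
    )

    # --- feature stage (optional) ---
    features_df = None
    if config.features_csv is not None:
        features_df = pd.read_csv(config.features_csv)
        log_records.append(f"features loaded from CSV: {len(features_df)} rows")
    elif config.patch_dir is not None:
        features_df = _extract_patch_features(config.patch_dir, config.bin_width)
        if len(features_df):
            features_df.to_csv(os.path.join(config.out_dir, "features.csv"), index=False)
            log_records.append(f"features extracted from patches: {len(features_df)} rows")
        else:
            features_df = None
            log_records.append("feature stage skipped: no readable patches")
    else:
        log_records.append("feature stage skipped: no patches or feature table supplied")

    # --- model stage (needs features + both outcome classes) ---
    models = None
    if features_df is not None and "lesion_id" in features_df.columns:
        merged = classifications.merge(features_df, on="lesion_id", how="inner", suffixes=("", "_f"))
        merged = merged[merged.hpdv_status != response.HPDvStatus.NOT_EVALUABLE.value]
        feat_cols = [
            c
            for c in features_df.columns
            if c not in ("lesion_id", "patient_id", "organ") and merged[c].dtype.kind in "fi"
        ]
        if len(merged) and merged.hpdv_status.nunique() == 2 and feat_cols:
            y = (merged.hpdv_status == response.HPDvStatus.HPDV.value).astype(int).to_numpy()
            pool, provenance = stats.build_transform_pool(merged[feat_cols])
            log_records.append(
                f"transform pool: {len(feat_cols)} original + {len(provenance)} transformed"
            )
            models = {}
            strata = {"all": np.ones(len(merged), dtype=bool)}
            for org in response.ORGANS:
                strata[org] = (merged.organ == org).to_numpy()
            for name, sel in strata.items():
                sub_y = y[sel]
                if sel.sum() < 10 or len(np.unique(sub_y)) < 2:
                    log_records.append(f"model stratum '{name}' skipped: insufficient data")
                    continue
                res = _fit_stratum(
                    pool[sel],
                    sub_y,
                    merged.patient_id.to_numpy()[sel],
                    config.screen_alpha,
                    config.elimination_alpha,
                )
                if res is None:
                    log_records.append(f"model stratum '{name}': no feature passed the screen")
                else:
                    models[name] = res
            with open(os.path.join(config.out_dir, "models.json"), "w") as fh:
                json.dump(models, fh, indent=2, sort_keys=True)
            model_rows = [
                {
                    "stratum": strat,
                    "variable": t,
                    "p_value": m["p_values"][t],
                    "odds_ratio": m["odds_ratios"][t],
                    "or_ci_lower": m["or_ci"][t][0],
                    "or_ci_upper": m["or_ci"][t][1],
                    "auc": m["auc"],
                    "auc_ci_lower": m["auc_ci"][0],
                    "auc_ci_upper": m["auc_ci"][1],
                }
                for strat, m in models.items()
                for t in m["final_terms"]
            ]
            pd.DataFrame(model_rows).to_csv(
                os.path.join(config.out_dir, "models.csv"), index=False
            )
        else:
            log_records.append("model stage skipped: need both outcome classes and features")

    # --- survival stage ---
    survival = None
    merged_pat = patients_df.merge(patients_out, on="patient_id", how="inner")
    if merged_pat.dr_status.nunique() == 2 and merged_pat.os_event.sum() > 0:
        curves, logrank = stats.km_logrank(
            merged_pat.os_days, merged_pat.os_event, merged_pat.dr_status
        )
        survival = {"chi_square": logrank.chi_square, "p_value": logrank.p_value}
        km_rows = []
        for lab, curve in curves.items():
            for t, s, r in zip(curve.times, curve.survival, curve.at_risk):
                km_rows.append({"group": lab, "time": t, "survival": s, "at_risk": r})
        pd.DataFrame(km_rows).to_csv(os.path.join(config.out_dir, "km_curves.csv"), index=False)
        with open(os.path.join(config.out_dir, "logrank.json"), "w") as fh:
            json.dump(survival, fh, indent=2)
        log_records.append(
            f"survival: logrank chi2={logrank.chi_square:.4f} p={logrank.p_value:.4f}"
        )
    else:
        log_records.append("survival stage skipped: need 2 DR groups and >=1 event")

    with open(os.path.join(config.out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(log_records) + "\n")
    for rec in log_records:
        logger.info(rec)
    return {
        "classifications": classifications,
        "patients_out": patients_out,
        "summary": summary,
        "features": features_df,
        "models": models,
        "survival": survival,
        "log": log_records,
    }
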