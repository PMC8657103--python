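"""Synthetic lesion-level cohorts with the structure the analysis assumes.

Two generators live here:

* :func:`generate_cohort` — a configurable stochastic simulator.  Each
  lesion's hyperprogression (HPDv) label is drawn first from a logistic
  model with organ-specific intercepts/feature effects and a patient-level
  random intercept (exchangeable within-patient correlation); the
  three-timepoint volume series is then back-solved so the deterministic
  rule engine reproduces the drawn label exactly.  Overall survival is
  exponential with a hazard ratio applied to dissociated-response patients.
* :func:`fixture_paper_marginals` — a fixed, seedless cohort of 196
  patients / 621 lesions constructed so that re-running the rule engine
  yields the reference accounting: 147 HPDv, 349 non-HPDv, 125 excluded
  lesions, per-organ splits 80/15/24/21 (HPDv) and 154/50/90/26
  (non-HPDv), and 54 DR / 142 non-DR patients.

All randomness flows from one ``numpy.random.default_rng(seed)``; identical
configs produce bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .features import VoxelPatch
from .response import (
    DAYS_PER_MONTH,
    ORGANS,
    TIMEPOINTS,
    DRStatus,
    HPDvCriteria,
    LesionRecord,
    NelsonResponse,
    PatientRecord,
    classify_dissociated,
    classify_nelson,
)

__all__ = [
    "ConfigError",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_patch",
    "fixture_paper_marginals",
]

#: Latent standardized features attached to every complete lesion.
LATENT_FEATURES = ("uniformity", "volume", "root_mean_square", "percentile_2_5")


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class CohortConfig:
    n_patients: int = 200
    #: mapping lesion-count -> probability; support must be >= 1
    lesions_per_patient_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.2, 2: 0.25, 3: 0.25, 4: 0.2, 5: 0.1}
    )
    organ_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "lung": 0.40,
            "bone": 0.12,
            "lymph_node": 0.20,
            "liver": 0.08,
            "other": 0.20,
        }
    )
    #: (pre-baseline -> baseline, baseline -> follow-up) gaps in days
    scan_interval_days: tuple = (60, 60)
    #: per-organ (mean, sd) of the log pre-treatment relative growth rate /day
    growth_model: Mapping[str, tuple] = field(
        default_factory=lambda: {org: (-5.0, 0.5) for org in ORGANS}
    )
    #: per-organ HPDv log-odds intercept
    hpdv_intercept: Mapping[str, float] = field(
        default_factory=lambda: {org: _logit(0.25) for org in ORGANS}
    )
    #: per-organ {latent feature -> log-odds coefficient}
    hpdv_effect: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {org: {} for org in ORGANS}
    )
    within_patient_sd: float = 0.5
    missing_prebaseline_prob: float = 0.0
    disappear_at_fu_prob: float = 0.0
    #: (baseline hazard per day, hazard ratio applied to DR patients)
    survival: tuple = (1.0 / 300.0, 2.0)
    censor_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        dist = dict(self.lesions_per_patient_dist)
        if not dist or any((not isinstance(k, int)) or k < 1 for k in dist):
            raise ConfigError("lesions_per_patient_dist support must be integers >= 1")
        if any(p < 0 for p in dist.values()) or abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ConfigError("lesions_per_patient_dist probabilities must be >=0 and sum to 1")
        probs = dict(self.organ_probs)
        if set(probs) != set(ORGANS):
            raise ConfigError(f"organ_probs must cover exactly {ORGANS}")
        if any(not (0 <= p <= 1) for p in probs.values()):
            raise ConfigError("organ_probs entries must be in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-12:
            raise ConfigError("organ_probs must sum to 1 within 1e-12")
        if len(self.scan_interval_days) != 2 or any(d <= 0 for d in self.scan_interval_days):
            raise ConfigError("scan_interval_days must be two positive day counts")
        for name in ("missing_prebaseline_prob", "disappear_at_fu_prob", "censor_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.within_patient_sd < 0:
            raise ConfigError("within_patient_sd must be >= 0")
        hazard, hr = self.survival
        if hazard <= 0 or hr <= 0:
            raise ConfigError("survival baseline hazard and hazard ratio must be > 0")
        for org in ORGANS:
            if org not in self.growth_model:
                raise ConfigError(f"growth_model missing organ {org!r}")
            for feat in self.hpdv_effect.get(org, {}):
                if feat not in LATENT_FEATURES:
                    raise ConfigError(
                        f"hpdv_effect[{org!r}] references unknown feature {feat!r}"
                    )

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "lesions_per_patient_dist" in d:
            d["lesions_per_patient_dist"] = {
                int(k): float(v) for k, v in dict(d["lesions_per_patient_dist"]).items()
            }
        if "scan_interval_days" in d:
            d["scan_interval_days"] = tuple(d["scan_interval_days"])
        if "survival" in d:
            d["survival"] = tuple(d["survival"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class SyntheticCohort:
    patients: list
    lesions: list
    truth: dict  # lesion_id -> {"label", "propensity", "features"}
    patches: Optional[dict] = None

    def __post_init__(self) -> None:
        pids = {p.patient_id for p in self.patients}
        for les in self.lesions:
            if les.patient_id not in pids:
                raise ValueError(f"lesion {les.lesion_id} has unknown patient")
        if set(self.truth) != {l.lesion_id for l in self.lesions}:
            raise ValueError("truth must cover exactly the lesion ids")

    def lesions_frame(self) -> pd.DataFrame:
        rows = []
        for les in self.lesions:
            for tp in TIMEPOINTS:
                if tp not in les.dates:
                    continue
                rows.append(
                    {
                        "patient_id": les.patient_id,
                        "lesion_id": les.lesion_id,
                        "organ": les.organ,
                        "timepoint": tp,
                        "scan_date": les.dates[tp],
                        "volume_mm3": les.volumes.get(tp),
                    }
                )
        return pd.DataFrame(rows)

    def patients_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in self.patients],
                "ttf_days": [p.ttf_days for p in self.patients],
                "os_days": [p.os_days for p in self.patients],
                "os_event": [p.os_event for p in self.patients],
            }
        )

    def features_frame(self) -> pd.DataFrame:
        """Latent standardized lesion features (complete lesions only)."""
        rows = []
        for les in self.lesions:
            feats = self.truth[les.lesion_id].get("features")
            if feats is None:
                continue
            rows.append(
                {"lesion_id": les.lesion_id, "patient_id": les.patient_id, "organ": les.organ, **feats}
            )
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.lesions_frame().to_csv(os.path.join(outdir, "lesions.csv"), index=False)
        self.patients_frame().to_csv(os.path.join(outdir, "patients.csv"), index=False)
        feats = self.features_frame()
        if len(feats):
            feats.to_csv(os.path.join(outdir, "features.csv"), index=False)
        if self.patches:
            from .io import write_patch

            for lid, patch in self.patches.items():
                write_patch(
                    patch,
                    os.path.join(outdir, "patches", f"{lid}_image.nii.gz"),
                    os.path.join(outdir, "patches", f"{lid}_mask.nii.gz"),
                )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate a cohort; the rule engine reproduces every stored truth label."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    gap1, gap2 = (int(d) for d in config.scan_interval_days)
    dates = {"pre_baseline": -gap1, "baseline": 0, "follow_up": gap2}
    dist_items = sorted(config.lesions_per_patient_dist.items())
    dist_vals = np.array([k for k, _ in dist_items])
    dist_probs = np.array([p for _, p in dist_items], dtype=float)
    dist_probs = dist_probs / dist_probs.sum()
    organ_names = list(ORGANS)
    organ_p = np.array([config.organ_probs[o] for o in organ_names], dtype=float)
    organ_p = organ_p / organ_p.sum()

    patients, lesions, truth = [], [], {}
    per_patient: list[list] = []
    lesion_counter = 0
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        u_pat = rng.normal(0.0, config.within_patient_sd)
        n_les = int(rng.choice(dist_vals, p=dist_probs))
        pat_lesions = []
        any_hpdv = False
        for _ in range(n_les):
            lesion_counter += 1
            lid = f"L{lesion_counter:05d}"
            organ = organ_names[int(rng.choice(len(organ_names), p=organ_p))]
            missing_pre = rng.random() < config.missing_prebaseline_prob
            disappear_fu = (not missing_pre) and rng.random() < config.disappear_at_fu_prob
            v0 = float(np.exp(rng.normal(np.log(1500.0), 0.6)))
            mu_g, sd_g = config.growth_model[organ]
            g_pre = float(np.exp(rng.normal(mu_g, sd_g)))  # relative growth /day
            v_pre = v0 / math.exp(g_pre * gap1)
            tgk_pre = (v0 - v_pre) / gap1  # > 0 by construction

            if missing_pre or disappear_fu:
                # incomplete lesion: stays out of the HPDv denominator split
                vols = {"baseline": v0}
                dts = {"baseline": 0}
                if not missing_pre:
                    vols["pre_baseline"] = v_pre
                    dts["pre_baseline"] = -gap1
                if not disappear_fu:
                    vols["follow_up"] = v0 * (1 + rng.uniform(-0.2, 0.2))
                    dts["follow_up"] = gap2
                les = LesionRecord(lid, pid, organ, dts, vols)
                truth[lid] = {"label": "NOT_EVALUABLE", "propensity": None, "features": None}
                pat_lesions.append(les)
                continue

            z = {f: float(rng.standard_normal()) for f in LATENT_FEATURES}
            eta = config.hpdv_intercept[organ] + u_pat
            for feat, coef in config.hpdv_effect.get(organ, {}).items():
                eta += coef * z[feat]
            prop = _expit(eta)
            label = bool(rng.random() < prop)
            if label:
                any_hpdv = True
                ratio = 2.5 + 2.0 * rng.random()
                v_fu = v0 + max(ratio * tgk_pre * gap2, 0.8 * v0)
            else:
                v_fu = v0 * (1 + rng.uniform(-0.55, 0.45))
            les = LesionRecord(
                lid,
                pid,
                organ,
                dict(dates),
                {"pre_baseline": v_pre, "baseline": v0, "follow_up": v_fu},
            )
            truth[lid] = {
                "label": "HPDV" if label else "NON_HPDV",
                "propensity": prop,
                "features": z,
            }
            pat_lesions.append(les)
        # TTF consistent with the drawn labels: HPDv needs TTF < 2 months
        if any_hpdv:
            ttf = float(rng.uniform(15.0, 0.98 * 2 * DAYS_PER_MONTH))
        else:
            ttf = float(rng.uniform(75.0, 400.0))
        per_patient.append((pid, ttf, pat_lesions))
        lesions.extend(pat_lesions)

    hazard, hr = config.survival
    for pid, ttf, pat_lesions in per_patient:
        pairs = []
        for les in pat_lesions:
            vb, vf = les.volumes.get("baseline"), les.volumes.get("follow_up")
            resp = classify_nelson(vb, vf) if (vb is not None and vf is not None) else None
            pairs.append((les, resp))
        dr = classify_dissociated(pairs)
        h = hazard * (hr if dr is DRStatus.DR else 1.0)
        os_raw = float(rng.exponential(1.0 / h)) + 1e-6
        if rng.random() < config.censor_rate:
            os_days = float(rng.uniform(0.0, os_raw)) + 1e-6
            event = 0
        else:
            os_days, event = os_raw, 1
        patients.append(PatientRecord(pid, ttf, os_days, event))
    return SyntheticCohort(patients=patients, lesions=lesions, truth=truth)


def generate_patch(
    target_features: Mapping[str, object],
    shape: tuple = (12, 24, 24),
    spacing: tuple = (2.0, 1.0, 1.0),
    seed: int = 0,
) -> VoxelPatch:
    """An HU-valued patch + ellipsoidal mask steering extracted features.

    Supported targets: ``mean`` (HU), ``sd`` (HU), ``uniformity`` ("low" or
    "high") and ``percentile_2_5_shift`` (HU subtracted from the lower
    tail).  Attainment is monotone, not exact: a wider spread yields lower
    extracted uniformity.
    """
    allowed = {"mean", "sd", "uniformity", "percentile_2_5_shift"}
    unknown = set(target_features) - allowed
    if unknown:
        raise ValueError(f"unsupported target features: {sorted(unknown)}")
    if any(s <= 0 for s in shape) or len(shape) != 3:
        raise ValueError("shape must be 3 positive integers")
    mean = float(target_features.get("mean", 40.0))
    sd = float(target_features.get("sd", 20.0))
    if sd < 0:
        raise ValueError("sd must be >= 0")
    uniformity = target_features.get("uniformity")
    if uniformity not in (None, "low", "high"):
        raise ValueError("uniformity target must be 'low' or 'high'")
    if uniformity == "low" and sd == 0:
        raise ValueError("cannot request low uniformity with sd=0 (constant patch)")
    rng = np.random.default_rng(seed)
    grid = np.indices(shape, dtype=float)
    center = (np.asarray(shape, dtype=float) - 1) / 2
    semi = np.maximum(np.asarray(shape, dtype=float) / 2 - 0.5, 0.5)
    dist = sum(((grid[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    mask = dist <= 1.0
    if uniformity == "low":
        sd = max(sd, 60.0)  # force spread across many 25-HU bins
    intensities = mean + sd * rng.standard_normal(shape)
    shift = float(target_features.get("percentile_2_5_shift", 0.0))
    if shift:
        flat_idx = np.flatnonzero(mask.ravel())
        n_tail = max(1, int(0.04 * flat_idx.size))
        chosen = rng.choice(flat_idx, size=n_tail, replace=False)
        flat = intensities.ravel()
        flat[chosen] = mean - abs(shift) + sd * 0.1 * rng.standard_normal(n_tail)
        intensities = flat.reshape(shape)
    return VoxelPatch(intensities=intensities, mask=mask, spacing=spacing)


# ---------------------------------------------------------------------------
# Deterministic fixture reproducing the reference cohort accounting
# ---------------------------------------------------------------------------

_HPDV_ORGAN_COUNTS = {"lung": 80, "bone": 15, "lymph_node": 24, "liver": 21, "other": 7}
_NON_HPDV_ORGAN_COUNTS = {"lung": 154, "bone": 50, "lymph_node": 90, "liver": 26, "other": 29}
_EXCLUDED_ORGAN_COUNTS = {"lung": 55, "bone": 15, "lymph_node": 25, "liver": 10, "other": 20}
_N_DR = 54
_N_PATIENTS = 196


def _organ_pool(counts: Mapping[str, int]) -> list:
    """Interleaved organ list realizing the given counts, deterministic."""
    pool, remaining = [], dict(counts)
    while any(remaining.values()):
        for org in ORGANS:
            if remaining.get(org, 0) > 0:
                pool.append(org)
                remaining[org] -= 1
    return pool


def fixture_paper_marginals() -> SyntheticCohort:
    """Fixed cohort of 196 patients / 621 lesions matching the reference
    lesion accounting and DR split when re-classified by the rule engine."""
    rng = np.random.default_rng(20211201)  # volume jitter only (scale-invariant)
    hpdv_pool = _organ_pool(_HPDV_ORGAN_COUNTS)
    non_hpdv_pool = _organ_pool(_NON_HPDV_ORGAN_COUNTS)
    excluded_pool = _organ_pool(_EXCLUDED_ORGAN_COUNTS)

    lesions, patients, truth = [], [], {}
    lesion_counter = 0

    def add_lesion(pid, organ, vols, dts, label):
        nonlocal lesion_counter
        lesion_counter += 1
        lid = f"L{lesion_counter:05d}"
        k = float(np.exp(rng.normal(0.0, 0.4)))  # per-lesion scale, rule-invariant
        vols = {tp: v * k for tp, v in vols.items()}
        lesions.append(LesionRecord(lid, pid, organ, dict(dts), vols))
        truth[lid] = {"label": label, "propensity": None, "features": None}

    full_dates = {"pre_baseline": -60, "baseline": 0, "follow_up": 60}
    hpdv_vols = {"pre_baseline": 800.0, "baseline": 1000.0, "follow_up": 1800.0}
    pr_vols = {"pre_baseline": 1000.0, "baseline": 1000.0, "follow_up": 700.0}
    stable_vols = {"pre_baseline": 900.0, "baseline": 1000.0, "follow_up": 1100.0}

    pat_counter = 0

    def next_pid():
        nonlocal pat_counter
        pat_counter += 1
        return f"P{pat_counter:04d}"

    # 54 DR patients: one HPDv (progressing) lesion + one partial-response
    # lesion in a different organ.  TTF < 2 months enables the HPDv call.
    for _ in range(_N_DR):
        pid = next_pid()
        hpdv_organ = hpdv_pool.pop(0)
        pr_idx = next(i for i, o in enumerate(non_hpdv_pool) if o != hpdv_organ)
        pr_organ = non_hpdv_pool.pop(pr_idx)
        add_lesion(pid, hpdv_organ, hpdv_vols, full_dates, "HPDV")
        add_lesion(pid, pr_organ, pr_vols, full_dates, "NON_HPDV")
        patients.append(PatientRecord(pid, ttf_days=45.0, os_days=1.0, os_event=1))

    # 47 non-DR patients carrying the remaining 93 HPDv lesions (progression
    # only => never DR): 46 patients with 2, one with a single lesion.
    for n_les in [2] * 46 + [1]:
        pid = next_pid()
        for _ in range(n_les):
            add_lesion(pid, hpdv_pool.pop(0), hpdv_vols, full_dates, "HPDV")
        patients.append(PatientRecord(pid, ttf_days=45.0, os_days=1.0, os_event=1))
    assert not hpdv_pool

    # 95 non-DR patients sharing the remaining 295 stable non-HPDv lesions
    # and the 125 excluded lesions.  Long TTF; no partial responses => non-DR.
    n_group_b = _N_PATIENTS - pat_counter
    group_b = []
    for _ in range(n_group_b):
        pid = next_pid()
        group_b.append(pid)
        patients.append(PatientRecord(pid, ttf_days=120.0, os_days=1.0, os_event=1))
    for j, organ in enumerate(non_hpdv_pool):
        add_lesion(group_b[j % n_group_b], organ, stable_vols, full_dates, "NON_HPDV")
    for j, organ in enumerate(excluded_pool):
        pid = group_b[(j + 40) % n_group_b]
        if j % 2 == 0:  # missing pre-baseline
            vols = {"baseline": 1000.0, "follow_up": 1100.0}
            dts = {"baseline": 0, "follow_up": 60}
        else:  # disappeared at first follow-up
            vols = {"pre_baseline": 900.0, "baseline": 1000.0}
            dts = {"pre_baseline": -60, "baseline": 0}
        add_lesion(pid, organ, vols, dts, "NOT_EVALUABLE")

    # Deterministic survival: DR patients die earlier on average.
    for i, pat in enumerate(patients):
        is_dr = i < _N_DR
        if is_dr:
            pat.os_days = 120.0 + 9.0 * i
        else:
            pat.os_days = 260.0 + 7.0 * (i - _N_DR)
        pat.os_event = 0 if i % 9 == 0 else 1

    cohort = SyntheticCohort(patients=patients, lesions=lesions, truth=truth)
    assert len(cohort.lesions) == 621 and len(cohort.patients) == _N_PATIENTS
    return cohort
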