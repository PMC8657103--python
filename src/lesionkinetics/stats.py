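"""Clustered statistics: feature transforms, GEE models, ROC/AUC, survival.

Lesions are clustered within patients, so binary-outcome models use
generalized estimating equations (logistic link, exchangeable working
correlation by default) with the Liang–Zeger robust sandwich covariance.
Model fitting is delegated to statsmodels; ROC/AUC (with the DeLong
variance estimator) is implemented here, and Kaplan–Meier / log-rank is
delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TransformSpec",
    "GEEFit",
    "ROCResult",
    "SurvivalCurve",
    "LogRankResult",
    "apply_transform",
    "choose_transform",
    "build_transform_pool",
    "gee_logistic",
    "univariate_screen",
    "multivariable_model",
    "roc_auc",
    "km_logrank",
]

_TRANSFORM_ORDER = ("identity", "log", "sqrt", "cbrt")


@dataclass(frozen=True)
class TransformSpec:
    """A distribution-compressing transform for one feature.

    ``pre_scale`` multiplies the raw values before the transform is applied
    (e.g. 1000 for features bounded in (0, 1] ahead of a log).
    """

    feature_name: str
    transform: str  # identity | log | sqrt | cbrt | cube
    pre_scale: float = 1.0

    @property
    def label(self) -> str:
        if self.transform == "identity":
            return self.feature_name
        inner = self.feature_name
        if self.pre_scale != 1.0:
            inner = f"{inner}*{self.pre_scale:g}"
        return f"{self.transform}({inner})"


def apply_transform(values: Sequence[float], spec: TransformSpec) -> np.ndarray:
    v = np.asarray(values, dtype=float) * spec.pre_scale
    if spec.transform == "identity":
        return v
    if spec.transform == "log":
        if np.any(v[np.isfinite(v)] <= 0):
            raise ValueError(f"log transform requires positive values ({spec.feature_name})")
        return np.log(v)
    if spec.transform == "sqrt":
        if np.any(v[np.isfinite(v)] < 0):
            raise ValueError(f"sqrt transform requires non-negative values ({spec.feature_name})")
        return np.sqrt(v)
    if spec.transform == "cbrt":
        return np.cbrt(v)
    if spec.transform == "cube":
        return v**3
    raise ValueError(f"unknown transform {spec.transform!r}")


def choose_transform(values: Sequence[float], feature_name: str = "") -> TransformSpec:
    """Pick the admissible transform minimizing absolute sample skewness.

    Features containing any negative value get the cube transform.  For
    positive features bounded in (0, 1], a pre-scale of 1000 is applied
    before the log.  Constant features return identity with a warning.
    Ties break in the order identity, log, sqrt, cbrt.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError(f"need >=3 finite values to choose a transform ({feature_name})")
    if np.ptp(v) == 0:
        warnings.warn(f"constant feature {feature_name!r}: using identity", stacklevel=2)
        return TransformSpec(feature_name, "identity")
    if np.any(v < 0):
        return TransformSpec(feature_name, "cube")
    candidates = [TransformSpec(feature_name, "identity")]
    if np.all(v > 0):
        pre = 1000.0 if v.max() <= 1.0 else 1.0
        candidates.append(TransformSpec(feature_name, "log", pre_scale=pre))
    candidates.append(TransformSpec(feature_name, "sqrt"))
    candidates.append(TransformSpec(feature_name, "cbrt"))
    best, best_skew = None, np.inf
    for spec in candidates:
        skew = abs(float(sps.skew(apply_transform(v, spec))))
        if skew < best_skew:
            best, best_skew = spec, skew
    return best


def build_transform_pool(features: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Original columns plus the chosen non-identity transformed variants.

    Returns the widened table and a map of new column label -> TransformSpec.
    Mirrors the analyzed pool of original + transformed features.
    """
    out = features.copy()
    provenance: dict[str, TransformSpec] = {}
    for name in features.columns:
        vals = features[name].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size < 3 or np.ptp(finite) == 0:
            continue
        spec = choose_transform(finite, name)
        if spec.transform == "identity":
            continue
        out[spec.label] = apply_transform(vals, spec)
        provenance[spec.label] = spec
    return out, provenance


@dataclass
class GEEFit:
    """Clustered logistic fit: coefficients, robust covariance, ORs, p-values."""

    params: pd.Series
    robust_cov: pd.DataFrame
    se: pd.Series
    odds_ratios: pd.Series
    or_ci: pd.DataFrame  # columns lower/upper
    p_values: pd.Series
    working_correlation: float
    n_clusters: int
    converged: bool
    diagnostics: str = ""

    def term_p(self, name: str) -> float:
        return float(self.p_values[name])


def _as_design(X, names: Optional[Sequence[str]]) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(names))


def gee_logistic(
    y: Sequence[int],
    X,
    cluster: Sequence,
    names: Optional[Sequence[str]] = None,
    add_intercept: bool = True,
    cov_struct: str = "exchangeable",
    maxiter: int = 100,
    ctol: float = 1e-6,
) -> GEEFit:
    """Logistic GEE with robust sandwich covariance and Wald tests.

    Non-convergence or a singular/separated fit is reported through the
    ``converged`` flag and ``diagnostics``, not raised.
    """
    import statsmodels.api as sm

    Xd = _as_design(X, names)
    if add_intercept:
        Xd = Xd.copy()
        Xd.insert(0, "intercept", 1.0)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(cluster)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 clusters")
    for col in Xd.columns:
        if col != "intercept" and np.ptp(Xd[col].to_numpy()) == 0:
            raise ValueError(f"constant non-intercept column {col!r}")
    structs = {
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
        "ar1": sm.cov_struct.Autoregressive,
    }
    cs = structs[cov_struct]()
    model = sm.GEE(y, Xd, groups=groups, family=sm.families.Binomial(), cov_struct=cs)
    converged, diagnostics = True, ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=maxiter, ctol=ctol)
        params = pd.Series(res.params, index=Xd.columns)
        cov = pd.DataFrame(res.cov_params(), index=Xd.columns, columns=Xd.columns)
        if not np.all(np.isfinite(params)) or not np.all(np.isfinite(cov)):
            raise ValueError("non-finite estimates")
        converged = bool(getattr(res, "converged", True))
        if not converged:
            diagnostics = "estimating equations did not converge"
        dep = cs.dep_params
        if dep is None or np.size(dep) == 0:
            working = 0.0
        else:
            working = float(np.asarray(dep).ravel()[0])
    except Exception as exc:  # separation, singular design, ...
        params = pd.Series(np.nan, index=Xd.columns)
        cov = pd.DataFrame(np.nan, index=Xd.columns, columns=Xd.columns)
        converged, diagnostics, working = False, f"{type(exc).__name__}: {exc}", float("nan")
    se = pd.Series(np.sqrt(np.diag(cov)), index=Xd.columns)
    z = params / se
    pvals = pd.Series(2 * sps.norm.sf(np.abs(z)), index=Xd.columns)
    or_ = np.exp(params)
    ci = pd.DataFrame(
        {
            "lower": np.exp(params - 1.96 * se),
            "upper": np.exp(params + 1.96 * se),
        },
        index=Xd.columns,
    )
    return GEEFit(
        params=params,
        robust_cov=cov,
        se=se,
        odds_ratios=or_,
        or_ci=ci,
        p_values=pvals,
        working_correlation=working,
        n_clusters=len(np.unique(groups)),
        converged=converged,
        diagnostics=diagnostics,
    )


def univariate_screen(
    features: pd.DataFrame,
    y: Sequence[int],
    cluster: Sequence,
    alpha: float = 0.1,
    cov_struct: str = "exchangeable",
) -> list[str]:
    """One single-feature GEE per candidate; keep features with Wald p < alpha.

    The threshold is strict: p exactly equal to alpha is not selected.
    Features with no finite values are skipped with a warning.
    """
    y = np.asarray(y, dtype=float)
    cluster = np.asarray(cluster)
    selected = []
    for name in features.columns:
        vals = features[name].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if not ok.any():
            warnings.warn(f"feature {name!r} has no finite values: skipped", stacklevel=2)
            continue
        if np.ptp(vals[ok]) == 0:
            warnings.warn(f"feature {name!r} is constant: skipped", stacklevel=2)
            continue
        fit = gee_logistic(
            y[ok], vals[ok, None], cluster[ok], names=[name], cov_struct=cov_struct
        )
        if fit.converged and fit.term_p(name) < alpha:
            selected.append(name)
    return selected


@dataclass
class ROCResult:
    auc: float
    ci_95: tuple
    n_pos: int
    n_neg: int


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Mann–Whitney AUC (0.5 credit for ties) with the DeLong 95% CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present for ROC analysis")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    # DeLong structural components
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = 1.96 * np.sqrt(max(var, 0.0))
    ci = (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))
    return ROCResult(auc=float(auc), ci_95=ci, n_pos=m, n_neg=n)


def multivariable_model(
    features: pd.DataFrame,
    y: Sequence[int],
    cluster: Sequence,
    alpha_stay: float = 0.05,
    cov_struct: str = "exchangeable",
) -> tuple[GEEFit, ROCResult]:
    """Joint GEE with backward elimination, scored in-sample by AUC.

    Starting from all supplied features, the largest-p term is dropped while
    any non-intercept Wald p >= ``alpha_stay``.  If every term is eliminated
    (or the fit degenerates) an intercept-only model with AUC 0.5 is
    returned.
    """
    if features.shape[1] < 1:
        raise ValueError("need at least one candidate feature")
    y = np.asarray(y, dtype=float)
    cluster = np.asarray(cluster)
    current = list(features.columns)
    fit = None
    while current:
        fit = gee_logistic(y, features[current], cluster, cov_struct=cov_struct)
        if not fit.converged:
            # drop the last term and retry; degenerate designs shrink
            current = current[:-1]
            fit = None
            continue
        pvals = fit.p_values.drop("intercept")
        worst = pvals.idxmax()
        if pvals[worst] >= alpha_stay:
            current.remove(worst)
            fit = None
        else:
            break
    if not current or fit is None:
        intercept_fit = gee_logistic(
            y, pd.DataFrame(index=features.index), cluster, cov_struct=cov_struct
        )
        return intercept_fit, ROCResult(
            auc=0.5, ci_95=(0.5, 0.5), n_pos=int(y.sum()), n_neg=int((1 - y).sum())
        )
    lin_pred = features[current].to_numpy(dtype=float) @ fit.params[current].to_numpy()
    roc = roc_auc(lin_pred, y.astype(int))
    return fit, roc


@dataclass
class SurvivalCurve:
    """Kaplan–Meier step function for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    label: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float


def km_logrank(
    os_days: Sequence[float],
    os_event: Sequence[int],
    group: Sequence,
) -> tuple[dict, LogRankResult]:
    """Per-group product-limit curves and the two-group log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    os_days = np.asarray(os_days, dtype=float)
    os_event = np.asarray(os_event).astype(int)
    group = np.asarray([str(g) for g in group])
    labels = sorted(set(group))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    if os_event.sum() == 0:
        raise ValueError("need at least one event overall")
    curves = {}
    for lab in labels:
        sel = group == lab
        if not sel.any():
            raise ValueError(f"group {lab!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(os_days[sel], os_event[sel])
        sf = kmf.survival_function_
        tab = kmf.event_table
        curves[lab] = SurvivalCurve(
            times=sf.index.to_numpy(dtype=float),
            survival=sf.iloc[:, 0].to_numpy(dtype=float),
            at_risk=tab["at_risk"].reindex(sf.index).to_numpy(dtype=float),
            label=lab,
        )
    a = group == labels[0]
    res = logrank_test(os_days[a], os_days[~a], os_event[a], os_event[~a])
    return curves, LogRankResult(
        chi_square=float(res.test_statistic), p_value=float(res.p_value)
    )
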