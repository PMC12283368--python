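"""Per-feature standardized-mean-difference meta-analysis across cohorts.

Pipeline: arcsine-square-root transform per-sample relative abundances,
compute Hedges' g (small-sample-corrected Cohen's d) per cohort for a binary
contrast, pool across cohorts with a random-effects model (REML or
Paule–Mandel tau^2, Hartung–Knapp confidence intervals and p-values from a
t distribution with k-1 degrees of freedom), then control the false
discovery rate across features with Benjamini–Hochberg.

Direction convention: positive g means higher abundance in group 1 (the
case/late/right group of the contrast).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CohortProfile, CrcMetaError

logger = logging.getLogger(__name__)


class DegenerateError(CrcMetaError):
    pass


@dataclass
class StudyEffect:
    """One cohort's standardized mean difference for one feature."""

    cohort_id: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    g: float
    var_g: float
    degenerate: bool = False


@dataclass
class MetaAnalysisRecord:
    feature_id: str
    studies: list[StudyEffect]
    g_pooled: float
    ci_low: float
    ci_high: float
    tau2: float
    i2: float
    p: float
    q: float = math.nan
    k: int = 0
    pooled: bool = True  # False when k == 1 (single study passthrough)
    direction_convention: str = "positive = higher in group 1"


def asin_sqrt_transform(p):
    """Arcsine-square-root transform of a fraction (variance stabilizing).

    Inputs within 1e-12 of the [0, 1] bounds are clipped; values further out
    raise a domain error.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
        raise ValueError("asin_sqrt_transform: input outside [0, 1]")
    out = np.arcsin(np.sqrt(np.clip(arr, 0.0, 1.0)))
    return out if out.ndim else float(out)


def hedges_g(x1, x2, cohort_id: str = "") -> StudyEffect:
    """Hedges' g with its sampling variance for two groups of observations.

    d = (mean1 - mean2) / s_pooled,  s_pooled^2 = ((n1-1)s1^2 + (n2-1)s2^2)/df,
    J = 1 - 3/(4 df - 1) with df = n1 + n2 - 2,  g = J d,
    Var(g) = J^2 ((n1+n2)/(n1 n2) + d^2/(2 df)).

    If both groups are constant and equal (s_pooled = 0), g is 0 with the
    variance from the mean term only and the effect is flagged degenerate.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("hedges_g needs at least 2 observations per group")
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("hedges_g: non-finite values")
    m1, m2 = x1.mean(), x2.mean()
    s1, s2 = x1.std(ddof=1), x2.std(ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    degenerate = sp2 <= 0.0
    if degenerate:
        d = 0.0
    else:
        d = (m1 - m2) / math.sqrt(sp2)
    var_g = J**2 * ((n1 + n2) / (n1 * n2) + d**2 / (2.0 * df))
    return StudyEffect(
        cohort_id=cohort_id, n1=n1, n2=n2,
        mean1=float(m1), mean2=float(m2), sd1=float(s1), sd2=float(s2),
        g=float(J * d), var_g=float(var_g), degenerate=degenerate,
    )


def feature_eligible(presence_counts, class_sizes, min_prevalence: float = 0.10,
                     min_positive: int = 5, min_class_n: int = 10,
                     min_studies: int = 3) -> bool:
    """Eligibility filter for meta-analysis of one feature.

    ``presence_counts``: mapping (cohort, class) -> number of samples with the
    feature detected; ``class_sizes``: mapping (cohort, class) -> class size.
    True iff some class-set within some cohort has prevalence >= 10% and >= 5
    positive samples, and at least ``min_studies`` cohorts have at least
    ``min_class_n`` samples in each class.
    """
    cohorts = {c for (c, _k) in class_sizes}
    big_enough = 0
    for c in cohorts:
        sizes = [n for (cc, _k), n in class_sizes.items() if cc == c]
        if len(sizes) >= 2 and all(n >= min_class_n for n in sizes):
            big_enough += 1
    if big_enough < min_studies:
        return False
    for key, pos in presence_counts.items():
        n = class_sizes.get(key, 0)
        if n and pos / n >= min_prevalence and pos >= min_positive:
            return True
    return False


def _reml_tau2(g: np.ndarray, v: np.ndarray, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Restricted maximum likelihood between-study variance (fixed point)."""
    k = len(g)
    tau2 = max(0.0, np.var(g, ddof=1) - v.mean()) if k > 1 else 0.0
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * g) / np.sum(w)
        num = np.sum(w**2 * ((g - mu) ** 2 - v))
        new = num / np.sum(w**2) + 1.0 / np.sum(w)
        new = max(0.0, new)
        if abs(new - tau2) < tol:
            tau2 = new
            break
        tau2 = new
    return float(tau2)


def _paule_mandel_tau2(g: np.ndarray, v: np.ndarray, tol: float = 1e-10) -> float:
    """Paule–Mandel tau^2: root of Q(tau2) = k - 1 (monotone; bisection)."""
    k = len(g)

    def q_of(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = np.sum(w * g) / np.sum(w)
        return float(np.sum(w * (g - mu) ** 2))

    if q_of(0.0) <= k - 1:
        return 0.0
    lo, hi = 0.0, 1.0
    while q_of(hi) > k - 1 and hi < 1e8:
        hi *= 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if q_of(mid) > k - 1:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return float(0.5 * (lo + hi))


def pool_random_effects(effects: list[StudyEffect], feature_id: str = "",
                        tau2_method: str = "REML",
                        hartung_knapp: bool = True) -> MetaAnalysisRecord:
    """Random-effects pooling of per-cohort standardized mean differences.

    Weights w_i = 1/(v_i + tau^2); pooled g = sum(w g)/sum(w).  With the
    Hartung–Knapp adjustment the pooled variance is
    sum(w (g - pooled)^2) / ((k-1) sum(w)) and CI/p come from t(k-1);
    otherwise the normal approximation with variance 1/sum(w) is used.
    Heterogeneity: Cochran's Q with fixed-effect weights, I^2 in percent.
    """
    k = len(effects)
    if k == 0:
        raise ValueError("no studies to pool")
    if k == 1:
        e = effects[0]
        se = math.sqrt(e.var_g)
        z = stats.norm.ppf(0.975)
        p = 2.0 * stats.norm.sf(abs(e.g) / se) if se > 0 else 1.0
        return MetaAnalysisRecord(
            feature_id=feature_id, studies=list(effects), g_pooled=e.g,
            ci_low=e.g - z * se, ci_high=e.g + z * se,
            tau2=0.0, i2=0.0, p=float(p), k=1, pooled=False,
        )
    g = np.array([e.g for e in effects])
    v = np.array([e.var_g for e in effects])
    if np.all(v <= 0):
        raise DegenerateError("all studies have zero sampling variance")
    v = np.maximum(v, 1e-12)

    if tau2_method.upper() == "REML":
        tau2 = _reml_tau2(g, v)
    elif tau2_method.upper() in ("PM", "PAULEMANDEL", "PAULE-MANDEL"):
        tau2 = _paule_mandel_tau2(g, v)
    else:
        raise ValueError(f"unknown tau2 method: {tau2_method}")

    w = 1.0 / (v + tau2)
    sw = np.sum(w)
    g_pooled = float(np.sum(w * g) / sw)

    # Cochran's Q with fixed-effect weights for I^2
    wfe = 1.0 / v
    mu_fe = np.sum(wfe * g) / np.sum(wfe)
    Q = float(np.sum(wfe * (g - mu_fe) ** 2))
    i2 = max(0.0, 100.0 * (Q - (k - 1)) / Q) if Q > 0 else 0.0

    if hartung_knapp:
        var_hk = float(np.sum(w * (g - g_pooled) ** 2) / ((k - 1) * sw))
        se = math.sqrt(var_hk)
        dfree = k - 1
    else:
        se = math.sqrt(1.0 / sw)
        dfree = math.inf
    if se == 0.0:
        p = 0.0 if g_pooled != 0 else 1.0
        ci_low = ci_high = g_pooled
    elif math.isinf(dfree):
        z = stats.norm.ppf(0.975)
        ci_low, ci_high = g_pooled - z * se, g_pooled + z * se
        p = float(2.0 * stats.norm.sf(abs(g_pooled) / se))
    else:
        tcrit = stats.t.ppf(0.975, dfree)
        ci_low, ci_high = g_pooled - tcrit * se, g_pooled + tcrit * se
        p = float(2.0 * stats.t.sf(abs(g_pooled) / se, dfree))
    return MetaAnalysisRecord(
        feature_id=feature_id, studies=list(effects), g_pooled=g_pooled,
        ci_low=float(ci_low), ci_high=float(ci_high),
        tau2=tau2, i2=float(i2), p=p, k=k,
    )


def adjusted_effect(y, is_case, covariates, cohort_id: str = "",
                    min_complete: int = 10) -> StudyEffect | None:
    """Covariate-adjusted per-cohort effect: OLS class coefficient / its SE.

    ``y`` is the transformed abundance, ``is_case`` a 0/1 indicator, and
    ``covariates`` an (n, p) array (e.g. age, sex, BMI).  Rows with any
    missing covariate are dropped (count logged).  Returns None when fewer
    than ``min_complete`` complete rows remain or the design is
    rank-deficient.  The returned ``g`` is the class coefficient standardized
    by its standard error's scale convention used downstream: effect = coef,
    var = SE^2.
    """
    y = np.asarray(y, dtype=float)
    is_case = np.asarray(is_case, dtype=float)
    X_cov = np.asarray(covariates, dtype=float)
    if X_cov.ndim == 1:
        X_cov = X_cov[:, None]
    keep = np.isfinite(y) & np.isfinite(is_case) & np.all(np.isfinite(X_cov), axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("adjusted_effect(%s): dropped %d incomplete rows", cohort_id, dropped)
    y, is_case, X_cov = y[keep], is_case[keep], X_cov[keep]
    n = len(y)
    if n < min_complete:
        return None
    X = np.column_stack([np.ones(n), is_case, X_cov])
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        logger.warning("adjusted_effect(%s): rank-deficient design, cohort skipped", cohort_id)
        return None
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    if dof <= 0:
        return None
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(sigma2 * XtX_inv[1, 1])
    n1 = int(is_case.sum())
    n2 = n - n1
    return StudyEffect(
        cohort_id=cohort_id, n1=n1, n2=n2,
        mean1=math.nan, mean2=math.nan, sd1=math.nan, sd2=math.nan,
        g=float(beta[1]), var_g=float(se**2),
        degenerate=se == 0.0,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m p_(j) / j, capped at 1, original order restored.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def meta_analyse(profiles: list[CohortProfile], group_of, feature_ids=None,
                 tau2_method: str = "REML", hartung_knapp: bool = True,
                 apply_eligibility: bool = True,
                 covariates_of=None) -> list[MetaAnalysisRecord]:
    """Run the full per-feature meta-analysis across cohorts.

    ``group_of`` maps a sample_id to 1 (group 1, e.g. CRC), 0 (group 2) or
    None (excluded).  When ``covariates_of`` is given (sample_id -> covariate
    vector with NaN for missing), the covariate-adjusted per-cohort effect is
    used instead of the raw Hedges' g.
    """
    # resolve the union feature space
    if feature_ids is None:
        feature_ids = []
        seen = set()
        for prof in profiles:
            for f in prof.feature_ids:
                if f not in seen:
                    seen.add(f)
                    feature_ids.append(f)

    per_cohort = []  # (cohort_id, feature->row, idx1, idx2, matrix, sample_ids)
    for prof in profiles:
        labels = [group_of(s) for s in prof.sample_ids]
        idx1 = [j for j, lab in enumerate(labels) if lab == 1]
        idx2 = [j for j, lab in enumerate(labels) if lab == 0]
        if len(idx1) >= 2 and len(idx2) >= 2:
            fmap = {f: i for i, f in enumerate(prof.feature_ids)}
            per_cohort.append((prof, fmap, idx1, idx2))

    records = []
    eligible_flags = {}
    if apply_eligibility:
        for f in feature_ids:
            presence, sizes = {}, {}
            for prof, fmap, idx1, idx2 in per_cohort:
                row = prof.abundances[fmap[f]] if f in fmap else None
                for cls, idx in (("g1", idx1), ("g2", idx2)):
                    sizes[(prof.cohort_id, cls)] = len(idx)
                    presence[(prof.cohort_id, cls)] = (
                        int((row[idx] > 0).sum()) if row is not None else 0
                    )
            eligible_flags[f] = feature_eligible(presence, sizes)

    for f in feature_ids:
        if apply_eligibility and not eligible_flags[f]:
            continue
        effects = []
        for prof, fmap, idx1, idx2 in per_cohort:
            if f not in fmap:
                continue
            row = prof.abundances[fmap[f]]
            if covariates_of is None:
                y1 = asin_sqrt_transform(row[idx1])
                y2 = asin_sqrt_transform(row[idx2])
                eff = hedges_g(y1, y2, cohort_id=prof.cohort_id)
            else:
                idx = idx1 + idx2
                y = asin_sqrt_transform(row[idx])
                is_case = np.array([1.0] * len(idx1) + [0.0] * len(idx2))
                cov = np.array([covariates_of(prof.sample_ids[j]) for j in idx], dtype=float)
                eff = adjusted_effect(y, is_case, cov, cohort_id=prof.cohort_id)
                if eff is None:
                    continue
            if not eff.degenerate:
                effects.append(eff)
        if not effects:
            continue
        records.append(
            pool_random_effects(effects, feature_id=f, tau2_method=tau2_method,
                                hartung_knapp=hartung_knapp)
        )

    if records:
        qs = bh_fdr([r.p for r in records])
        for r, qv in zip(records, qs):
            r.q = float(qv)
    return records
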