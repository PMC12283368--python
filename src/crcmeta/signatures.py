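"""Signature-level analytics: overlap statistics, the covariate-adjusted
cardiometabolic rank score and the disease-signature meta-analysis recipe.

The cardiometabolic score follows a rank-of-partial-correlations scheme:
for every feature, partial Spearman correlations against each health index
(adjusting for sex, age and BMI) are converted to normalized ranks, averaged
first within index categories and then across categories; features with a
global rank above the third quartile are the risk-associated set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import SignatureSet
from .meta import StudyEffect, adjusted_effect, asin_sqrt_transform, bh_fdr, pool_random_effects

logger = logging.getLogger(__name__)


@dataclass
class RankScore:
    feature_id: str
    per_index_partial_rho: dict
    rank: float
    selected: bool


def jaccard_similarity(a, b) -> float:
    """|a ∩ b| / |a ∪ b|; 0 (flagged via log) when both sets are empty."""
    sa = a.members if hasattr(a, "members") else set(a)
    sb = b.members if hasattr(b, "members") else set(b)
    union = sa | sb
    if not union:
        logger.info("jaccard_similarity of two empty sets defined as 0")
        return 0.0
    return len(sa & sb) / len(union)


def overlap_fraction(signature, reference) -> float:
    """Fraction of the signature found in the reference panel."""
    sig = signature.members if hasattr(signature, "members") else set(signature)
    ref = reference.members if hasattr(reference, "members") else set(reference)
    if not sig:
        return math.nan
    return len(sig & ref) / len(sig)


def partial_spearman(x, y, covariates=None) -> float:
    """Partial Spearman correlation of x and y given covariates.

    Both variables are rank-transformed (average ranks for ties), each is
    residualized on [1, covariates] by least squares, and the Pearson
    correlation of the residuals is returned.  Incomplete rows are dropped.
    NaN signals an undefined correlation (constant variable after ranking).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((len(x), 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("partial_spearman: dropped %d incomplete rows", dropped)
    x, y, Z = x[keep], y[keep], Z[keep]
    n = len(x)
    if n <= Z.shape[1] + 2:
        raise ValueError("too few complete observations")
    rx, ry = rankdata(x), rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return math.nan
    design = np.column_stack([np.ones(n), Z])
    bx, _, _, _ = np.linalg.lstsq(design, rx, rcond=None)
    by, _, _, _ = np.linalg.lstsq(design, ry, rcond=None)
    ex, ey = rx - design @ bx, ry - design @ by
    sx, sy = np.linalg.norm(ex), np.linalg.norm(ey)
    if sx == 0 or sy == 0:
        return math.nan
    return float(ex @ ey / (sx * sy))


def cardiometabolic_rank(abundances, feature_ids, indices, index_categories,
                         covariates=None, unfavorable=None) -> list[RankScore]:
    """Global cardiometabolic-risk rank per feature.

    ``abundances``: (n_samples, n_features); ``indices``: (n_samples, n_index)
    with column names in ``index_categories`` (index name -> category).
    ``unfavorable`` optionally maps index name -> False for indices where
    LOWER values mean risk (their correlations are sign-flipped so that rank
    1 always means risk-associated).  Features with rank above the third
    quartile of the global-rank distribution are selected.
    """
    A = np.asarray(abundances, dtype=float)
    idx_names = list(index_categories)
    I = np.asarray(indices, dtype=float)
    if I.shape[1] != len(idx_names):
        raise ValueError("indices width must match index_categories")
    if I.shape[1] < 2:
        raise ValueError("need at least 2 indices")
    n_feat = A.shape[1]
    categories: dict[str, list[str]] = {}
    for name, cat in index_categories.items():
        categories.setdefault(cat, []).append(name)

    rho = np.full((n_feat, len(idx_names)), np.nan)
    for j, name in enumerate(idx_names):
        sign = 1.0
        if unfavorable is not None and unfavorable.get(name) is False:
            sign = -1.0
        for f in range(n_feat):
            rho[f, j] = sign * partial_spearman(A[:, f], I[:, j], covariates)

    # per-index normalized ranks in [0, 1] (higher rho -> closer to 1)
    per_index_rank = np.full_like(rho, np.nan)
    for j in range(len(idx_names)):
        col = rho[:, j]
        ok = np.isfinite(col)
        if ok.sum() > 1:
            r = rankdata(col[ok])
            per_index_rank[ok, j] = (r - 1) / (ok.sum() - 1)

    cat_means = []
    for cat, names in categories.items():
        cols = [idx_names.index(nm) for nm in names]
        sub = per_index_rank[:, cols]
        if np.all(np.isnan(sub)):
            logger.warning("cardiometabolic_rank: empty category %r skipped", cat)
            continue
        cat_means.append(np.nanmean(sub, axis=1))
    if not cat_means:
        raise ValueError("no usable categories")
    global_rank = np.nanmean(np.column_stack(cat_means), axis=1)

    q3 = np.nanquantile(global_rank, 0.75)
    out = []
    for f in range(n_feat):
        out.append(
            RankScore(
                feature_id=feature_ids[f],
                per_index_partial_rho={nm: float(rho[f, j]) for j, nm in enumerate(idx_names)},
                rank=float(global_rank[f]),
                selected=bool(global_rank[f] > q3),
            )
        )
    return out


def disease_signature_meta(profiles, disease_of, country_of,
                           fdr_max: float = 0.1, min_datasets: int = 3,
                           tau2_method: str = "PM",
                           hartung_knapp: bool = True) -> SignatureSet:
    """Country-adjusted SMD meta-analysis signature for a disease contrast.

    Per cohort, the arcsine-sqrt abundance of each feature is regressed on
    the disease indicator plus country dummies (dropped when the cohort has
    a single country level); the standardized class coefficients are pooled
    with a Paule–Mandel random-effects model.  The signature keeps features
    with q < ``fdr_max`` that pass per-cohort eligibility (nonzero in >= 1
    sample per class) in at least ``min_datasets`` cohorts.
    """
    feature_ids: list[str] = []
    seen = set()
    for prof in profiles:
        for f in prof.feature_ids:
            if f not in seen:
                seen.add(f)
                feature_ids.append(f)

    records = []
    found_in: dict[str, int] = {f: 0 for f in feature_ids}
    effects_by_feature: dict[str, list[StudyEffect]] = {f: [] for f in feature_ids}
    for prof in profiles:
        labels = np.array([disease_of(s) for s in prof.sample_ids], dtype=float)
        countries = [country_of(s) for s in prof.sample_ids]
        levels = sorted(set(countries))
        if len(levels) > 1:
            dummies = np.column_stack(
                [[1.0 if c == lv else 0.0 for c in countries] for lv in levels[1:]]
            )
        else:
            dummies = np.empty((len(countries), 0))
        fmap = {f: i for i, f in enumerate(prof.feature_ids)}
        for f in feature_ids:
            if f not in fmap:
                continue
            row = prof.abundances[fmap[f]]
            case = row[labels == 1]
            ctrl = row[labels == 0]
            if (case > 0).any() and (ctrl > 0).any():
                found_in[f] += 1
            y = asin_sqrt_transform(row)
            eff = adjusted_effect(y, labels, dummies, cohort_id=prof.cohort_id)
            if eff is not None and not eff.degenerate:
                effects_by_feature[f].append(eff)

    pooled = []
    for f in feature_ids:
        effs = effects_by_feature[f]
        if len(effs) >= 2:
            pooled.append(
                pool_random_effects(effs, feature_id=f, tau2_method=tau2_method,
                                    hartung_knapp=hartung_knapp)
            )
    if pooled:
        qs = bh_fdr([r.p for r in pooled])
        for r, qv in zip(pooled, qs):
            r.q = float(qv)
    members = {
        r.feature_id
        for r in pooled
        if r.q < fdr_max and found_in[r.feature_id] >= min_datasets
    }
    return SignatureSet(
        name="disease_signature", members=members,
        provenance=f"country-adjusted SMD meta-analysis, q<{fdr_max}, "
                   f">={min_datasets} datasets",
    )
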