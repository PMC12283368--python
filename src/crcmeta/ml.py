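"""Three-mode classifier evaluation: per-dataset CV, cross-dataset, LODO.

The harness is classifier-agnostic: any object exposing sklearn's
``fit(X, y)`` / ``predict_proba(X)`` works.  The default configuration
mirrors the study design this framework targets — a random forest of 1,000
trees with a minimum of 5 samples per leaf and the per-split feature count
grid-searched in an inner CV — but lightweight configurations are accepted
for rapid experimentation.

Eligibility: per-dataset CV requires at least 15 samples per class in the
cohort; cross-dataset and LODO require 15 per class in both the training and
validation sets.  A cohort failing validation eligibility may still serve in
a LODO training pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .io import CohortProfile
from .meta import asin_sqrt_transform

logger = logging.getLogger(__name__)

MIN_PER_CLASS = 15


@dataclass
class ClassifierConfig:
    """Random-forest settings for the evaluation harness."""

    n_estimators: int = 1000
    min_samples_leaf: int = 5
    max_features_grid: tuple = ("sqrt", 0.1, 0.2, 0.3)
    inner_cv: int = 5
    grid_search: bool = True
    n_jobs: int = 1

    def build(self, seed: int):
        base = RandomForestClassifier(
            n_estimators=self.n_estimators,
            min_samples_leaf=self.min_samples_leaf,
            random_state=int(seed) % (2**31),
            n_jobs=self.n_jobs,
        )
        if not self.grid_search or len(self.max_features_grid) == 1:
            base.set_params(max_features=self.max_features_grid[0])
            return base
        return GridSearchCV(
            base,
            {"max_features": list(self.max_features_grid)},
            cv=StratifiedKFold(self.inner_cv, shuffle=True,
                               random_state=int(seed) % (2**31)),
            scoring="roc_auc",
            n_jobs=self.n_jobs,
        )


#: small forest for quick runs (tests, demos); same interface
LIGHT_CONFIG = ClassifierConfig(
    n_estimators=200, min_samples_leaf=5, max_features_grid=("sqrt",),
    grid_search=False,
)


def prepare_features(profile: CohortProfile, feature_set: str = "all",
                     signature=None, custom_features=None) -> np.ndarray:
    """(n_samples, n_features) design matrix for one cohort.

    For subset modes (oral / nonoral / custom) each sample's retained
    abundances are renormalized by their sum (mapping back onto [0, 1])
    before the arcsine-sqrt transform; a sample with zero retained abundance
    yields an all-zero row (logged), not a dropped sample.
    """
    X = profile.abundances.T  # samples x features
    if feature_set == "all":
        return np.asarray(asin_sqrt_transform(X))
    members = None
    if feature_set in ("oral", "nonoral"):
        if signature is None:
            raise ValueError(f"{feature_set} mode needs an oral signature")
        members = signature.members if hasattr(signature, "members") else set(signature)
    elif feature_set == "custom":
        if custom_features is None:
            raise ValueError("custom mode needs custom_features")
        members = set(custom_features)
    else:
        raise ValueError(f"unknown feature_set: {feature_set}")
    mask = np.array([f in members for f in profile.feature_ids])
    if feature_set == "nonoral":
        mask = ~mask
    sub = X[:, mask]
    totals = sub.sum(axis=1, keepdims=True)
    n_empty = int((totals == 0).sum())
    if n_empty:
        logger.info("prepare_features(%s): %d samples with zero retained abundance",
                    profile.cohort_id, n_empty)
    with np.errstate(invalid="ignore", divide="ignore"):
        rescaled = np.where(totals > 0, sub / totals, 0.0)
    return np.asarray(asin_sqrt_transform(rescaled))


def subset_feature_mask(feature_ids, feature_set: str, signature=None,
                        custom_features=None) -> np.ndarray:
    members = set()
    if signature is not None:
        members = signature.members if hasattr(signature, "members") else set(signature)
    if custom_features is not None:
        members = set(custom_features)
    mask = np.array([f in members for f in feature_ids])
    if feature_set == "nonoral":
        mask = ~mask
    if feature_set == "all":
        mask = np.ones(len(feature_ids), dtype=bool)
    return mask


def auc_rank(scores, labels) -> float:
    """Rank-based AUC (Mann–Whitney statistic / (n+ n-)); ties count 0.5."""
    from scipy.stats import rankdata

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _eligible(y, min_per_class: int = MIN_PER_CLASS) -> bool:
    y = np.asarray(y).astype(int)
    return int((y == 1).sum()) >= min_per_class and int((y == 0).sum()) >= min_per_class


def per_dataset_cv(X, y, k: int = 10, repeats: int = 20,
                   min_per_class: int = MIN_PER_CLASS,
                   classifier_config: ClassifierConfig | None = None,
                   seed: int = 0):
    """Stratified k-fold CV repeated ``repeats`` times on one cohort.

    AUC is pooled per repeat on the concatenated out-of-fold scores;
    returns (mean, sd) over repeats, or None when the cohort is ineligible.
    """
    y = np.asarray(y).astype(int)
    if not _eligible(y, min_per_class):
        logger.info("per_dataset_cv: cohort ineligible (<%d per class)", min_per_class)
        return None
    cfg = classifier_config or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    aucs = []
    for rep in range(repeats):
        rep_seed = int(rng.integers(2**31))
        folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        oof = np.full(len(y), np.nan)
        for tr, te in folds.split(X, y):
            clf = cfg.build(rep_seed)
            clf.fit(X[tr], y[tr])
            oof[te] = clf.predict_proba(X[te])[:, 1]
        aucs.append(auc_rank(oof, y))
    return float(np.mean(aucs)), float(np.std(aucs, ddof=1)) if repeats > 1 else 0.0


def cross_dataset(X_train, y_train, X_test, y_test,
                  classifier_config: ClassifierConfig | None = None,
                  seed: int = 0, min_per_class: int = MIN_PER_CLASS,
                  _same_cohort: bool = False):
    """Train on one cohort, test on another; returns AUC or None if ineligible."""
    if _same_cohort:
        raise ValueError("cross_dataset refuses train == test; use per_dataset_cv")
    y_train = np.asarray(y_train).astype(int)
    y_test = np.asarray(y_test).astype(int)
    if not (_eligible(y_train, min_per_class) and _eligible(y_test, min_per_class)):
        logger.info("cross_dataset: ineligible pair skipped")
        return None
    cfg = classifier_config or ClassifierConfig()
    clf = cfg.build(seed)
    clf.fit(np.asarray(X_train, dtype=float), y_train)
    scores = clf.predict_proba(np.asarray(X_test, dtype=float))[:, 1]
    return auc_rank(scores, y_test)


def lodo(cohort_data: dict, left_out: str,
         classifier_config: ClassifierConfig | None = None,
         seed: int = 0, min_per_class: int = MIN_PER_CLASS):
    """Leave-one-dataset-out: train pooled on all cohorts but one.

    ``cohort_data`` maps cohort_id -> (X, y).  Cohorts ineligible as
    validation sets can still contribute to training pools.  Returns the AUC
    on the left-out cohort, or None when it is validation-ineligible.
    """
    if left_out not in cohort_data:
        raise KeyError(left_out)
    X_te, y_te = cohort_data[left_out]
    y_te = np.asarray(y_te).astype(int)
    if not _eligible(y_te, min_per_class):
        logger.info("lodo: %s validation-ineligible (training-only role)", left_out)
        return None
    X_parts, y_parts = [], []
    for cid, (X, y) in cohort_data.items():
        if cid == left_out:
            continue
        X_parts.append(np.asarray(X, dtype=float))
        y_parts.append(np.asarray(y).astype(int))
    if not X_parts:
        raise ValueError("LODO needs at least one training cohort")
    X_tr = np.vstack(X_parts)
    y_tr = np.concatenate(y_parts)
    cfg = classifier_config or ClassifierConfig()
    clf = cfg.build(seed)
    clf.fit(X_tr, y_tr)
    scores = clf.predict_proba(np.asarray(X_te, dtype=float))[:, 1]
    return auc_rank(scores, y_te)


def evaluate_all(cohort_data: dict, mode: str = "lodo",
                 classifier_config: ClassifierConfig | None = None,
                 seed: int = 0, cv_k: int = 10, cv_repeats: int = 20):
    """Run one evaluation mode over every cohort (pair); returns a dict.

    cv:    cohort_id -> (mean_auc, sd) or None
    cross: (train_id, test_id) -> auc or None
    lodo:  cohort_id (left out) -> auc or None
    """
    out = {}
    ids = list(cohort_data)
    if mode == "cv":
        for i, cid in enumerate(ids):
            X, y = cohort_data[cid]
            out[cid] = per_dataset_cv(X, y, k=cv_k, repeats=cv_repeats,
                                      classifier_config=classifier_config,
                                      seed=seed + i)
    elif mode == "cross":
        for i, tr in enumerate(ids):
            for j, te in enumerate(ids):
                if tr == te:
                    continue
                Xtr, ytr = cohort_data[tr]
                Xte, yte = cohort_data[te]
                out[(tr, te)] = cross_dataset(
                    Xtr, ytr, Xte, yte, classifier_config=classifier_config,
                    seed=seed + i * len(ids) + j,
                )
    elif mode == "lodo":
        for i, cid in enumerate(ids):
            out[cid] = lodo(cohort_data, cid, classifier_config=classifier_config,
                            seed=seed + i)
    else:
        raise ValueError(f"unknown mode: {mode}")
    return out
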