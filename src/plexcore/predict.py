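"""Bagged-tree classification of disease status, disability and IPS
impairment from coreness-disruption indices plus conventional MRI measures.

Decision trees are combined with bootstrap aggregation (per-split feature
subsampling makes the ensemble a random forest); hyperparameters are tuned
with a seeded random search minimizing 10-fold cross-validated error.
Performance is reported as out-of-bag (OOB) accuracy — each subject is
scored only by trees whose bootstrap excluded it — and predictor relevance
as OOB permutation feature importance: the mean per-tree OOB accuracy drop
when one feature's values are shuffled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

from .stats import adjust_confounders, dichotomize_clinical

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionReport",
    "BaggedTreeClassifier",
    "fit_bagged_trees",
    "oob_permutation_importance",
    "build_feature_tables",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "kappa_multiplex", "kappa_mc", "kappa_sc", "kappa_fc", "bpf_adj_z", "log_tlv",
]

# Documented search grid: tree count, leaf size, features per split.
SEARCH_GRID = {
    "n_estimators": [100, 200],
    "min_samples_leaf": [1, 3, 5, 8],
    "max_features": ["sqrt", 0.5, 1.0],
}


@dataclass
class PredictionReport:
    task: str
    features: list[str]
    oob_accuracy: float
    importance: dict[str, float]
    importance_sd: dict[str, float]
    hyperparameters: dict
    cv_accuracy: float
    seed: int | None
    n_samples: int = 0
    class_counts: dict[str, int] = field(default_factory=dict)


class BaggedTreeClassifier(BaseEstimator, ClassifierMixin):
    """Tuned bagging ensemble of decision trees with OOB diagnostics.

    Parameters
    ----------
    search_budget : int, default 6
        Number of hyperparameter configurations sampled (without
        replacement) from the documented grid; each is scored by 10-fold
        stratified CV accuracy.
    n_splits : int, default 10
        CV folds for tuning (reduced to the smallest class count when
        classes are small).
    random_state : int or None
        Seeds the search, the CV splits, the bootstrap and the permutation
        importance; fixing it makes the whole report reproducible.
    """

    def __init__(self, search_budget: int = 6, n_splits: int = 10,
                 n_importance_repeats: int = 5, random_state=None):
        self.search_budget = search_budget
        self.n_splits = n_splits
        self.n_importance_repeats = n_importance_repeats
        self.random_state = random_state

    def _grid(self, rng):
        configs = [
            {"n_estimators": ne, "min_samples_leaf": msl, "max_features": mf}
            for ne in SEARCH_GRID["n_estimators"]
            for msl in SEARCH_GRID["min_samples_leaf"]
            for mf in SEARCH_GRID["max_features"]
        ]
        order = rng.permutation(len(configs))[: max(1, self.search_budget)]
        return [configs[i] for i in order]

    @staticmethod
    def _make_ensemble(cfg, seed):
        tree = DecisionTreeClassifier(
            min_samples_leaf=cfg["min_samples_leaf"],
            max_features=cfg["max_features"],
            random_state=seed,
        )
        return BaggingClassifier(
            estimator=tree, n_estimators=cfg["n_estimators"],
            bootstrap=True, oob_score=True, random_state=seed,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        if y.size < 20:
            raise ValueError(f"need at least 20 samples, got {y.size}")
        rng = np.random.default_rng(self.random_state)
        seed = int(rng.integers(2 ** 31 - 1))
        n_splits = int(min(self.n_splits, counts.min()))
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)

        best_cfg, best_score = None, -np.inf
        for cfg in self._grid(rng):
            scores = cross_val_score(
                self._make_ensemble(cfg, seed), X, y, cv=cv, scoring="accuracy"
            )
            if scores.mean() > best_score:
                best_score, best_cfg = float(scores.mean()), cfg
        self.best_params_ = best_cfg
        self.cv_accuracy_ = best_score

        self.ensemble_ = self._make_ensemble(best_cfg, seed)
        self.ensemble_.fit(X, y)
        self.classes_ = self.ensemble_.classes_
        self.oob_accuracy_ = float(self.ensemble_.oob_score_)
        self._fit_X_, self._fit_y_ = X, y
        self._importance_seed_ = int(rng.integers(2 ** 31 - 1))
        return self

    def predict(self, X):
        return self.ensemble_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return self.ensemble_.predict_proba(np.asarray(X, dtype=float))

    def _oob_masks(self):
        n = self._fit_y_.size
        for est, samples in zip(self.ensemble_.estimators_,
                                self.ensemble_.estimators_samples_):
            mask = np.ones(n, dtype=bool)
            mask[samples] = False
            if mask.any():
                yield est, mask

    def oob_permutation_importance(self, n_repeats: int | None = None, seed=None):
        """Per-feature mean OOB accuracy drop under within-OOB permutation.

        For each tree and repeat, the feature's values are shuffled among
        that tree's out-of-bag samples and the tree's OOB accuracy drop is
        recorded; reported as mean and SD across trees and repeats.
        """
        if not hasattr(self, "ensemble_"):
            raise ValueError("model is not fitted")
        X = self._fit_X_
        # base trees predict encoded class indices, so compare on encodings
        y = np.searchsorted(self.classes_, self._fit_y_)
        n_repeats = n_repeats or self.n_importance_repeats
        rng = np.random.default_rng(self._importance_seed_ if seed is None else seed)
        n_features = X.shape[1]
        drops = [[] for _ in range(n_features)]
        for est, oob in self._oob_masks():
            Xo, yo = X[oob], y[oob]
            base = accuracy_score(yo, est.predict(Xo))
            for j in range(n_features):
                for _ in range(n_repeats):
                    Xp = Xo.copy()
                    Xp[:, j] = Xp[rng.permutation(Xo.shape[0]), j]
                    drops[j].append(base - accuracy_score(yo, est.predict(Xp)))
        mean = np.array([np.mean(d) for d in drops])
        sd = np.array([np.std(d, ddof=1) for d in drops])
        return mean, sd

    def report(self, task: str = "status", feature_names=None) -> PredictionReport:
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"f{j}" for j in range(self._fit_X_.shape[1])]
        )
        imp, sd = self.oob_permutation_importance()
        classes, counts = np.unique(self._fit_y_, return_counts=True)
        return PredictionReport(
            task=task,
            features=names,
            oob_accuracy=self.oob_accuracy_,
            importance={n: float(v) for n, v in zip(names, imp)},
            importance_sd={n: float(v) for n, v in zip(names, sd)},
            hyperparameters=dict(self.best_params_),
            cv_accuracy=self.cv_accuracy_,
            seed=self.random_state,
            n_samples=int(self._fit_y_.size),
            class_counts={str(c): int(k) for c, k in zip(classes, counts)},
        )


def fit_bagged_trees(features, labels, search_budget: int = 6, seed=None,
                     task: str = "status", feature_names=None):
    """Fit the tuned ensemble and return ``(model, PredictionReport)``."""
    model = BaggedTreeClassifier(search_budget=search_budget, random_state=seed)
    model.fit(features, labels)
    return model, model.report(task=task, feature_names=feature_names)


def oob_permutation_importance(model: BaggedTreeClassifier, n_repeats: int = 5,
                               seed=None):
    """Importance vector (mean OOB accuracy drop) for a fitted model."""
    return model.oob_permutation_importance(n_repeats=n_repeats, seed=seed)


def build_feature_tables(kappa_table: pd.DataFrame, records: pd.DataFrame,
                         task: str, log_tlv: bool = True):
    """Assemble (features, labels) for one prediction task.

    Features: kappa in the multiplex and the three single-layer domains,
    age/sex-adjusted BPF z-score (HC-anchored), and lesion volume (log(1 +
    TLV) by default; HC lesion volume is taken as 0).  Tasks: ``status``
    (HC vs MS, all subjects), ``disability`` (EDSS >= 4, MS only), ``ips``
    (SDMT z < -1.5, MS only).  Rows with missing inputs are dropped and
    counted in the log.
    """
    if task not in ("status", "disability", "ips"):
        raise ValueError(f"unknown task {task!r}")
    for col in ("multiplex", "MC", "SC", "FC"):
        if col not in kappa_table.columns:
            raise ValueError(f"kappa table is missing column {col!r}")
    records = records.set_index("subject_id") if "subject_id" in records.columns else records
    records = records.loc[kappa_table.index]

    bpf = pd.to_numeric(records["bpf"], errors="coerce")
    if bpf.isna().any():
        raise ValueError("BPF must be present for all subjects in the kappa table")
    covs = np.column_stack(
        [records["age"].to_numpy(float), (records["sex"] == "M").to_numpy(float)]
    )
    hc_mask = (records["group"] == "HC").to_numpy()
    bpf_adj = adjust_confounders(bpf.to_numpy(float), covs, hc_mask).z

    tlv = pd.to_numeric(records["tlv"], errors="coerce").fillna(0.0).to_numpy(float)
    tlv_feat = np.log1p(tlv) if log_tlv else tlv

    feats = pd.DataFrame(
        {
            "kappa_multiplex": kappa_table["multiplex"],
            "kappa_mc": kappa_table["MC"],
            "kappa_sc": kappa_table["SC"],
            "kappa_fc": kappa_table["FC"],
            "bpf_adj_z": bpf_adj,
            "log_tlv": tlv_feat,
        },
        index=kappa_table.index,
    )

    if task == "status":
        labels = records["group"].astype(str)
        keep = feats.notna().all(axis=1)
    else:
        dich = dichotomize_clinical(records)
        col = "high_disability" if task == "disability" else "ips_impaired"
        is_ms = records["group"] == "MS"
        keep = is_ms & dich[col].notna() & feats.notna().all(axis=1)
        labels = dich[col].map({True: "impaired" if task == "ips" else "high",
                                False: "preserved" if task == "ips" else "low"})
    dropped = int((~keep).sum())
    if dropped:
        logger.info("task %s: dropped %d subject(s) with missing inputs", task, dropped)
    feats, labels = feats.loc[keep], labels.loc[keep].astype(str)
    if feats.empty:
        raise ValueError(f"no usable subjects for task {task!r}")
    return feats, labels
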