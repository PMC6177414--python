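"""Train/test design, classifier registry, CV, AUROC and top-k metrics.

Scores are always oriented so that larger means more PsA-like; classifiers
emitting class probabilities contribute ``P(PsA)``.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .core import Cohort, CohortMap, PSA, PSC, PhenotypeTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Split plan
# ---------------------------------------------------------------------------
@dataclass
class SplitPlan:
    """Held-out test set (3:7 PsA:PsC by default), balanced training set,
    tenfold assignment, and per-trial seeds."""

    train_ids: np.ndarray
    test_ids: np.ndarray
    folds: dict  # sample_id -> fold index
    trial_seeds: tuple
    seed: int

    def assert_no_test_leak(self, sample_ids: Sequence[str]) -> None:
        """Partition audit: fail loudly if any id belongs to the test set."""
        leak = set(sample_ids) & set(self.test_ids)
        if leak:
            raise RuntimeError(
                f"test-set isolation violated by {len(leak)} sample(s), "
                f"e.g. {sorted(leak)[:3]}"
            )


def make_split(
    pheno: PhenotypeTable,
    test_frac: float = 0.10,
    test_psa_frac: float = 0.30,
    seed: int = 0,
    n_folds: int = 10,
    n_trials: int = 50,
    stratify_cohort: bool = True,
) -> SplitPlan:
    """Deterministic train/test design.

    The test set holds ``test_frac`` of the PsA+PsC samples at a
    ``test_psa_frac`` PsA fraction; the training set balances the two
    subtypes by subsampling the majority class.
    """
    df = pheno.df
    psa_ids = np.sort(df.loc[df["status"] == PSA, "sample_id"].to_numpy())
    psc_ids = np.sort(df.loc[df["status"] == PSC, "sample_id"].to_numpy())
    n_total = len(psa_ids) + len(psc_ids)
    n_test = int(round(test_frac * n_total))
    n_test_psa = int(round(test_psa_frac * n_test))
    n_test_psc = n_test - n_test_psa
    if n_test_psa > len(psa_ids) or n_test_psc > len(psc_ids) \
            or min(len(psa_ids) - n_test_psa, len(psc_ids) - n_test_psc) < 1:
        raise ValueError(
            f"infeasible split: need >= {n_test_psa + 1} PsA and "
            f">= {n_test_psc + 1} PsC samples (have {len(psa_ids)}, {len(psc_ids)})"
        )

    rng = np.random.default_rng(seed)
    test_psa = rng.choice(psa_ids, size=n_test_psa, replace=False)
    test_psc = rng.choice(psc_ids, size=n_test_psc, replace=False)
    rest_psa = np.setdiff1d(psa_ids, test_psa)
    rest_psc = np.setdiff1d(psc_ids, test_psc)

    n_train_per_class = min(len(rest_psa), len(rest_psc))
    train_psa = rng.choice(rest_psa, size=n_train_per_class, replace=False)
    train_psc = rng.choice(rest_psc, size=n_train_per_class, replace=False)

    cohort_of = dict(zip(df["sample_id"], df["cohort"]))
    folds: dict = {}
    for class_ids in (train_psa, train_psc):
        if stratify_cohort:
            strata: dict = {}
            for s in class_ids:
                strata.setdefault(cohort_of[s], []).append(s)
            groups = [np.sort(np.asarray(v, dtype=object)) for _, v in sorted(strata.items())]
        else:
            groups = [np.sort(class_ids)]
        for grp in groups:
            perm = rng.permutation(len(grp))
            for k, i in enumerate(perm):
                folds[grp[i]] = k % n_folds

    ss = np.random.SeedSequence(seed)
    trial_seeds = tuple(int(c.generate_state(1)[0]) for c in ss.spawn(n_trials))
    train_ids = np.sort(np.concatenate([train_psa, train_psc]))
    test_ids = np.sort(np.concatenate([test_psa, test_psc]))
    return SplitPlan(train_ids, test_ids, folds, trial_seeds, seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------
def auroc(scores, labels) -> float:
    """AUROC via the Mann-Whitney statistic, ties counted 0.5."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("auroc requires both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def topk_metrics(scores, labels, k_percent: float, sample_ids=None):
    """Precision/recall/specificity calling the top ceil(k%) as PsA.

    Ties at the cutoff are broken by stable sample-id order (logged).
    """
    if not 0.0 < k_percent <= 100.0:
        raise ValueError("k_percent must lie in (0, 100]")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n = len(s)
    ids = np.asarray(sample_ids if sample_ids is not None
                     else [f"s{i}" for i in range(n)], dtype=object)
    order = np.lexsort((ids, -s))  # score desc, then id asc
    n_called = math.ceil(k_percent / 100.0 * n)
    called = np.zeros(n, dtype=bool)
    called[order[:n_called]] = True
    if n_called < n and s[order[n_called - 1]] == s[order[n_called]]:
        logger.info("topk_metrics: tie straddles the %g%% cutoff; "
                    "broken by sample-id order", k_percent)
    tp = int((called & (y == 1)).sum())
    tn = int((~called & (y == 0)).sum())
    precision = tp / n_called
    recall = tp / int(y.sum()) if y.sum() else float("nan")
    specificity = tn / int((y == 0).sum()) if (y == 0).sum() else float("nan")
    return precision, recall, specificity


# ---------------------------------------------------------------------------
# Classifier registry
# ---------------------------------------------------------------------------
_REGISTRY = {
    "logistic_ridge": "L2-penalized logistic regression (C=1.0)",
    "lda": "linear discriminant analysis (default solver)",
    "sda": "shrinkage discriminant analysis: LDA with analytic (Ledoit-Wolf) "
           "covariance shrinkage",
    "random_forest": "random forest, 100 trees, Gini splits",
    "gradient_boosting": "gradient-boosted trees (documented stand-in for a "
                         "conditional-inference forest)",
    "elastic_net": "elastic-net logistic regression (saga, l1_ratio=0.5, C=1.0)",
}


def registry() -> dict:
    """Available classifier names with their documented default parameters."""
    return dict(_REGISTRY)


def make_classifier(name: str, random_state: Optional[int] = None):
    """Instantiate a registry classifier with its default hyperparameters."""
    if name == "logistic_ridge":
        return LogisticRegression(C=1.0, max_iter=1000)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "sda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=random_state)
    if name == "gradient_boosting":
        return GradientBoostingClassifier(random_state=random_state)
    if name == "elastic_net":
        return LogisticRegression(solver="saga", l1_ratio=0.5, C=1.0,
                                  max_iter=5000)
    raise ValueError(f"unknown model {name!r}; registry: {sorted(_REGISTRY)}")


def psa_scores(model, X: np.ndarray) -> np.ndarray:
    """P(PsA) (or a monotone decision score) from a fitted classifier."""
    if hasattr(model, "predict_proba"):
        idx = int(np.flatnonzero(model.classes_ == 1)[0])
        return model.predict_proba(X)[:, idx]
    return model.decision_function(X)


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------
def assemble_features(
    cohorts: CohortMap,
    marker_ids: Sequence[str],
    sample_ids: Optional[Sequence[str]] = None,
    statuses: Sequence[str] = (PSA, PSC),
):
    """Stack dosages of the given markers across cohorts.

    Returns ``(X, y, ids)`` where ``y`` is 1 for PsA and 0 otherwise and
    rows follow ``sample_ids`` when given (restricted to the requested
    statuses).  Missing dosages are mean-imputed per marker.
    """
    blocks, labels, ids = [], [], []
    wanted = set(sample_ids) if sample_ids is not None else None
    for name in sorted(cohorts):
        co = cohorts[name]
        df = co.phenotypes.df
        mask = df["status"].isin(statuses)
        sel = df.loc[mask, "sample_id"].to_numpy()
        if wanted is not None:
            sel = np.array([s for s in sel if s in wanted], dtype=object)
        if len(sel) == 0:
            continue
        sub = co.genotypes.subset_samples(sel)
        blocks.append(sub.dosages[:, sub.marker_index(marker_ids)])
        labels.append((co.phenotypes.status_of(sel) == PSA).astype(int))
        ids.append(sel)
    if not blocks:
        raise ValueError("no samples matched the requested statuses/ids")
    X = np.vstack(blocks)
    y = np.concatenate(labels)
    ids = np.concatenate(ids)
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(col_mean, inds[1])
    return X, y, ids


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------
def cross_validate(
    model_name: str,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    trials: int = 50,
    seed: int = 0,
) -> dict:
    """Repeated stratified k-fold CV; per-trial mean AUROC and overall mean.

    Each trial reshuffles the folds with a seed derived from ``seed``; the
    classifier's own randomness (if any) is tied to the same trial seed.
    """
    if model_name not in _REGISTRY:
        raise ValueError(f"unknown model {model_name!r}; registry: {sorted(_REGISTRY)}")
    ss = np.random.SeedSequence(seed)
    trial_seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(trials)]
    per_trial = []
    for ts in trial_seeds:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=ts)
        fold_auc = []
        for tr, te in skf.split(X, y):
            model = make_classifier(model_name, random_state=ts)
            model.fit(X[tr], y[tr])
            fold_auc.append(auroc(psa_scores(model, X[te]), y[te]))
        per_trial.append(float(np.mean(fold_auc)))
    return {
        "mean_auroc": float(np.mean(per_trial)),
        "sd_auroc": float(np.std(per_trial)),
        "per_trial": np.asarray(per_trial),
        "trial_seeds": trial_seeds,
    }


# ---------------------------------------------------------------------------
# Elastic-net comparison model
# ---------------------------------------------------------------------------
def elastic_net_model(
    X: np.ndarray,
    y: np.ndarray,
    assoc_p: Optional[np.ndarray] = None,
    p_max: float = 0.05,
    l1_ratio: float = 0.5,
    alphas: Optional[np.ndarray] = None,
    cv_folds: int = 5,
    seed: int = 0,
):
    """Elastic-net logistic model on association-prefiltered features.

    Features with association p-value above ``p_max`` are dropped before
    fitting.  Returns ``(best_model, path)`` where ``path`` has one row per
    regularization strength with the nonzero-coefficient count and CV AUROC.
    """
    if not 0.0 < p_max <= 1.0:
        raise ValueError("p_max must lie in (0, 1]")
    kept = np.arange(X.shape[1])
    if assoc_p is not None:
        assoc_p = np.asarray(assoc_p, dtype=float)
        kept = np.flatnonzero(assoc_p <= p_max)
        if kept.size == 0:
            raise ValueError(f"no features pass the association p <= {p_max} prefilter")
        X = X[:, kept]
    n = X.shape[0]
    if alphas is None:
        alphas = np.geomspace(1e-4, 1.0, 8)
    rows = []
    best = None
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for alpha in alphas:
        C = 1.0 / max(alpha * n, 1e-12)
        fold_auc = []
        for tr, te in skf.split(X, y):
            m = LogisticRegression(solver="saga", l1_ratio=l1_ratio, C=C,
                                   max_iter=5000)
            m.fit(X[tr], y[tr])
            fold_auc.append(auroc(psa_scores(m, X[te]), y[te]))
        m = LogisticRegression(solver="saga", l1_ratio=l1_ratio, C=C,
                               max_iter=5000)
        m.fit(X, y)
        nz = int(np.sum(m.coef_ != 0))
        cv_auc = float(np.mean(fold_auc))
        rows.append({"alpha": float(alpha), "n_nonzero": nz, "cv_auroc": cv_auc})
        if best is None or cv_auc > best[0]:
            best = (cv_auc, m)
    path = pd.DataFrame(rows)
    path.attrs["kept_feature_indices"] = kept
    return best[1], path
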