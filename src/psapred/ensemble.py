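"""Tenfold ensemble with per-fold conditional selection and rank
combination, plus leave-one-cohort-out evaluation."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import select as select_mod
from .classify import (SplitPlan, assemble_features, auroc, make_classifier,
                       make_split, psa_scores)
from .core import CohortMap, PSA, PSC, PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class EnsembleMember:
    fold: int
    marker_ids: list
    model: object
    train_sample_ids: np.ndarray


@dataclass
class EnsembleModel:
    members: list
    test_ids: np.ndarray
    combination: str = "mean_rank"
    diagnostics: dict = field(default_factory=dict)


def _pooled_phenotypes(cohorts: CohortMap) -> PhenotypeTable:
    frames = [cohorts[c].phenotypes.df for c in sorted(cohorts)]
    cov = cohorts[sorted(cohorts)[0]].phenotypes.covariate_names
    return PhenotypeTable(pd.concat(frames, ignore_index=True), cov)


def _case_folds(pheno: PhenotypeTable, train_ids: np.ndarray, folds: int,
                rng) -> dict:
    """Partition training cases into folds preserving per-cohort subtype ratio."""
    df = pheno.df.set_index("sample_id").loc[list(train_ids)]
    assignment: dict = {}
    for (_, _), grp in df.groupby(["cohort", "status"]):
        ids = np.sort(grp.index.to_numpy())
        perm = rng.permutation(len(ids))
        for k, i in enumerate(perm):
            assignment[ids[i]] = k % folds
    return assignment


def ensemble_train(
    cohorts: CohortMap,
    test_frac: float = 0.10,
    folds: int = 10,
    select_params: Optional[dict] = None,
    model_name: str = "sda",
    covariate_names: Sequence[str] = (),
    seed: int = 0,
) -> EnsembleModel:
    """Per-fold stepwise selection and model fitting; common test set.

    The non-test PsA/PsC samples are partitioned into ``folds`` disjoint
    folds preserving the per-cohort subtype ratio.  Stepwise conditional
    selection runs separately inside each fold (fold cases plus all
    controls); one classifier per fold is trained on that fold's cases.
    A partition audit guarantees no member ever sees a test sample.
    """
    select_params = dict(select_params or {})
    pheno = _pooled_phenotypes(cohorts)
    plan = make_split(pheno, test_frac=test_frac, test_psa_frac=0.30, seed=seed)
    rng = np.random.default_rng(seed + 1)
    non_test = np.sort(np.setdiff1d(
        pheno.ids_with_status(PSA, PSC), plan.test_ids))
    fold_of = _case_folds(pheno, non_test, folds, rng)

    controls = pheno.ids_with_status("CONTROL")
    members = []
    for k in range(folds):
        fold_cases = np.sort(np.array(
            [s for s, f in fold_of.items() if f == k], dtype=object))
        classes = set(pheno.status_of(fold_cases))
        if len(fold_cases) < 4 or {PSA, PSC} - classes:
            raise ValueError(f"fold {k}: fewer than 2 samples per class")
        plan.assert_no_test_leak(fold_cases)
        fold_samples = np.concatenate([fold_cases, controls])
        path = select_mod.stepwise_select(
            cohorts, covariate_names=covariate_names,
            sample_ids=fold_samples, **select_params,
        )
        X, y, ids = assemble_features(cohorts, path.markers,
                                      sample_ids=fold_cases)
        plan.assert_no_test_leak(ids)
        model = make_classifier(model_name, random_state=seed + k)
        model.fit(X, y)
        members.append(EnsembleMember(k, list(path.markers), model, ids))
        logger.info("ensemble fold %d: %d markers, stop=%s",
                    k, len(path.markers), path.stop_reason)

    diag = {"fold_of": fold_of, "plan": plan,
            "n_test": len(plan.test_ids), "folds": folds}
    return EnsembleModel(members, plan.test_ids, "mean_rank", diag)


def member_test_scores(model: EnsembleModel, cohorts: CohortMap) -> pd.DataFrame:
    """Score the common test set with every member; one column per member."""
    cols = {}
    index = None
    for m in model.members:
        X, _, ids = assemble_features(cohorts, m.marker_ids,
                                      sample_ids=model.test_ids)
        order = np.argsort(ids)
        if index is None:
            index = ids[order]
        cols[f"fold{m.fold}"] = psa_scores(m.model, X)[order]
    return pd.DataFrame(cols, index=pd.Index(index, name="sample_id"))


def rank_combine(member_scores: pd.DataFrame) -> pd.DataFrame:
    """Average per-member ranks (rank 1 = most PsA-like) into one score.

    The combined score is the negative mean rank rescaled to [0, 1]; ties
    within a member are broken by stable sample-id order.  Missing entries
    are an error: every member must have scored every sample.
    """
    if member_scores.isna().any().any():
        bad = member_scores.columns[member_scores.isna().any()].tolist()
        raise ValueError(f"member(s) missing sample scores: {bad}")
    n = len(member_scores)
    ranks = pd.DataFrame(index=member_scores.index)
    ids = member_scores.index.to_numpy()
    for col in member_scores.columns:
        order = np.lexsort((ids, -member_scores[col].to_numpy()))
        r = np.empty(n, dtype=float)
        r[order] = np.arange(1, n + 1)
        ranks[col] = r
    mean_rank = ranks.mean(axis=1)
    combined = 1.0 if n == 1 else (n - mean_rank) / (n - 1)
    out = pd.DataFrame({"mean_rank": mean_rank, "combined_score": combined})
    return out.sort_values(["mean_rank"], kind="mergesort")


def ensemble_test_auroc(model: EnsembleModel, cohorts: CohortMap) -> float:
    """Rank-combined AUROC of the ensemble on its common test set."""
    scores = member_test_scores(model, cohorts)
    combined = rank_combine(scores)
    pheno = _pooled_phenotypes(cohorts)
    y = (pheno.status_of(combined.index.to_numpy()) == PSA).astype(int)
    return auroc(combined["combined_score"].to_numpy(), y)


def leave_one_cohort_out(
    cohorts: CohortMap,
    select_params: Optional[dict] = None,
    model_name: str = "sda",
    covariate_names: Sequence[str] = (),
    seed: int = 0,
) -> dict:
    """Train on all-but-one cohort, test subtype AUROC on the left-out one.

    Cohorts lacking one of the subtypes cannot serve as a test set; they
    are reported as ``None`` with a logged notice (they still contribute
    to training when other cohorts are left out).
    """
    if len(cohorts) < 2:
        raise ValueError("leave_one_cohort_out requires >= 2 cohorts")
    select_params = dict(select_params or {})
    out: dict = {}
    for name in sorted(cohorts):
        co = cohorts[name]
        if not (co.has_status(PSA) and co.has_status(PSC)):
            logger.info("leave_one_cohort_out: %s lacks a subtype; skipped", name)
            out[name] = None
            continue
        rest = {k: v for k, v in cohorts.items() if k != name}
        path = select_mod.stepwise_select(
            rest, covariate_names=covariate_names, **select_params)
        X_tr, y_tr, _ = assemble_features(rest, path.markers)
        model = make_classifier(model_name, random_state=seed)
        model.fit(X_tr, y_tr)
        X_te, y_te, _ = assemble_features({name: co}, path.markers)
        out[name] = auroc(psa_scores(model, X_te), y_te)
    return out
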