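"""End-to-end orchestration: split -> stepwise selection -> classifier ->
calibrated risk.  Used by the CLI and as the single-model baseline the
ensemble is compared against."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import risk as risk_mod
from . import select as select_mod
from .classify import (SplitPlan, assemble_features, auroc, make_classifier,
                       make_split, psa_scores, topk_metrics)
from .core import CONTROL, CohortMap, PSA, PSC, PhenotypeTable, UNKNOWN_SUBTYPE

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    plan: SplitPlan
    markers: list
    stop_reason: str
    model: object
    cv_scores: pd.DataFrame       # sample_id, score, label (training folds)
    test_scores: pd.DataFrame     # sample_id, score, label
    cv_auroc: float
    test_auroc: float
    topk: pd.DataFrame            # k_percent, precision, recall, specificity
    densities: Optional[object] = None
    extras: dict = field(default_factory=dict)


def pooled_phenotypes(cohorts: CohortMap) -> PhenotypeTable:
    frames = [cohorts[c].phenotypes.df for c in sorted(cohorts)]
    cov = cohorts[sorted(cohorts)[0]].phenotypes.covariate_names
    return PhenotypeTable(pd.concat(frames, ignore_index=True), cov)


def single_model_run(
    cohorts: CohortMap,
    covariate_names: Sequence[str] = (),
    select_params: Optional[dict] = None,
    model_name: str = "logistic_ridge",
    test_frac: float = 0.10,
    test_psa_frac: float = 0.30,
    n_folds: int = 10,
    top_k: Sequence[float] = (5.0, 10.0, 20.0),
    priors: Sequence[float] = risk_mod.DEFAULT_PRIORS,
    seed: int = 0,
) -> PipelineResult:
    """The single-model pipeline.

    Selection and training see only non-test samples (plus all controls,
    which never enter the classifier); the partition audit enforces this.
    CV scores come from out-of-fold predictions on the training set and
    feed the KDE calibration; the held-out test set is scored once.
    """
    select_params = dict(select_params or {})
    pheno = pooled_phenotypes(cohorts)
    plan = make_split(pheno, test_frac=test_frac, test_psa_frac=test_psa_frac,
                      seed=seed, n_folds=n_folds)

    controls = pheno.ids_with_status(CONTROL)
    train_pool = np.concatenate([plan.train_ids, controls])
    plan.assert_no_test_leak(plan.train_ids)

    # evaluator for the stopping rule runs inside the training partition only
    def evaluator(markers):
        return select_mod.block_auroc(markers, cohorts,
                                      sample_ids=plan.train_ids,
                                      n_folds=n_folds, model_name=model_name,
                                      seed=seed)

    path = select_mod.stepwise_select(
        cohorts, covariate_names=covariate_names, sample_ids=train_pool,
        ml_evaluator=evaluator, **select_params,
    )

    X_tr, y_tr, ids_tr = assemble_features(cohorts, path.markers,
                                           sample_ids=plan.train_ids)
    plan.assert_no_test_leak(ids_tr)

    # out-of-fold CV scores over the training set using the frozen markers
    fold_of = np.array([plan.folds[s] for s in ids_tr])
    cv_scores = np.full(len(ids_tr), np.nan)
    for k in np.unique(fold_of):
        tr, te = fold_of != k, fold_of == k
        if len(np.unique(y_tr[tr])) < 2:
            continue
        m = make_classifier(model_name, random_state=seed)
        m.fit(X_tr[tr], y_tr[tr])
        cv_scores[te] = psa_scores(m, X_tr[te])
    cv_mask = np.isfinite(cv_scores)
    cv_df = pd.DataFrame({"sample_id": ids_tr[cv_mask],
                          "score": cv_scores[cv_mask],
                          "label": y_tr[cv_mask]})
    cv_auc = auroc(cv_df["score"], cv_df["label"])

    model = make_classifier(model_name, random_state=seed)
    model.fit(X_tr, y_tr)

    X_te, y_te, ids_te = assemble_features(cohorts, path.markers,
                                           sample_ids=plan.test_ids)
    s_te = psa_scores(model, X_te)
    test_df = pd.DataFrame({"sample_id": ids_te, "score": s_te, "label": y_te})
    test_auc = auroc(s_te, y_te)

    topk_rows = [
        dict(zip(("precision", "recall", "specificity"),
                 topk_metrics(s_te, y_te, k, sample_ids=ids_te)), k_percent=k)
        for k in top_k
    ]

    densities = None
    try:
        densities = risk_mod.fit_densities(cv_df["score"], cv_df["label"])
    except ValueError as exc:
        logger.warning("calibration densities not fitted: %s", exc)

    return PipelineResult(
        plan=plan, markers=list(path.markers), stop_reason=path.stop_reason,
        model=model, cv_scores=cv_df, test_scores=test_df,
        cv_auroc=cv_auc, test_auroc=test_auc,
        topk=pd.DataFrame(topk_rows), densities=densities,
        extras={"block_auroc_trace": path.block_auroc_trace,
                "steps": path.steps, "priors": tuple(priors)},
    )


def assess_unknown_samples(
    result: PipelineResult,
    cohorts: CohortMap,
    priors: Sequence[float] = risk_mod.DEFAULT_PRIORS,
    thresholds: Sequence[float] = (0.80, 0.98),
):
    """Calibrated posterior risk for UNKNOWN_SUBTYPE samples."""
    if result.densities is None:
        raise ValueError("pipeline result has no fitted densities")
    pheno = pooled_phenotypes(cohorts)
    unk = pheno.ids_with_status(UNKNOWN_SUBTYPE)
    if len(unk) == 0:
        return risk_mod.assess_unknowns(
            np.empty((0, len(result.markers))), [], result.model,
            result.densities, priors=priors, thresholds=thresholds)
    X, _, ids = assemble_features(cohorts, result.markers, sample_ids=unk,
                                  statuses=(UNKNOWN_SUBTYPE,))
    return risk_mod.assess_unknowns(X, ids, result.model, result.densities,
                                    priors=priors, thresholds=thresholds)
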