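"""Stepwise conditional feature selection with a CV-AUROC stopping rule.

The candidate pool is fixed once: markers with unconditional indirect
case-case p-value <= ``p_pool_max``.  At each step the marker with the
smallest conditional indirect p-value (conditioning on everything selected
so far) is appended.  After every block of ``block_size`` additions, a
cross-validated median AUROC is computed on the markers selected so far;
selection stops when the gain over the previous block stays below
``min_gain`` for ``patience`` consecutive blocks, or when the marker
budget/pool is exhausted, or when separation prevents further fits.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import meta as meta_mod
from .assoc import logistic_wald
from .classify import assemble_features, auroc, make_classifier, psa_scores
from .core import CONTROL, CohortMap, PSA, PSC

logger = logging.getLogger(__name__)


@dataclass
class ConditionalPath:
    """Ordered selected markers with per-step statistics and AUROC trace."""

    markers: list
    steps: pd.DataFrame          # step, marker_id, chi2, p_value
    block_auroc_trace: list      # median CV AUROC after each complete block
    stop_reason: str             # auroc_plateau | max_markers | pool_exhausted | separation


def indirect_scan(
    cohorts: CohortMap,
    covariate_names: Sequence[str] = (),
    conditioning_markers: Sequence[str] = (),
    marker_subset: Optional[Sequence[str]] = None,
    sample_ids: Optional[Sequence[str]] = None,
    rho: float = 0.0,
    gc_correct: bool = False,
    min_r2: Optional[float] = None,
) -> pd.DataFrame:
    """Per-cohort PsA-vs-ctl and PsC-vs-ctl scans, pooled, then the
    indirect case-case statistic.

    A cohort contributes to an arm only if it has cases of that subtype
    (a PsA-only cohort contributes to the PsA arm alone).  When
    ``sample_ids`` is given, every cohort is restricted to those samples
    first (used by the per-fold ensemble mode).
    """
    arm_results = {PSA: {}, PSC: {}}
    for name in sorted(cohorts):
        co = cohorts[name]
        g, ph = co.genotypes, co.phenotypes
        if sample_ids is not None:
            keep = ph.df["sample_id"].isin(set(sample_ids))
            if not keep.any():
                continue
            sel = ph.df.loc[keep, "sample_id"].to_numpy()
            g = g.subset_samples(sel)
            ph = type(ph)(ph.df.loc[keep], ph.covariate_names)
        for case_label in (PSA, PSC):
            has_cases = (ph.df["status"] == case_label).any()
            has_ctl = (ph.df["status"] == CONTROL).any()
            if not (has_cases and has_ctl):
                continue
            arm_results[case_label][name] = logistic_wald(
                g, ph, case_label=case_label, control_label=CONTROL,
                covariate_names=covariate_names,
                conditioning_markers=conditioning_markers,
                marker_subset=marker_subset,
            )
    if not arm_results[PSA] or not arm_results[PSC]:
        raise ValueError("indirect scan needs both a PsA and a PsC arm")
    psa_meta = meta_mod.fixed_effects_meta(arm_results[PSA], gc_correct=gc_correct,
                                           min_r2=min_r2)
    psc_meta = meta_mod.fixed_effects_meta(arm_results[PSC], gc_correct=gc_correct,
                                           min_r2=min_r2)
    return meta_mod.indirect_meta(psa_meta, psc_meta, rho=rho)


def _pick_best(scan: pd.DataFrame) -> Optional[pd.Series]:
    """Smallest conditional p; ties by genomic coordinate then marker id."""
    ok = scan[np.isfinite(scan["p_value"])]
    if ok.empty:
        return None
    ordered = ok.sort_values(
        ["p_value", "chrom", "pos", "marker_id"], kind="mergesort"
    )
    return ordered.iloc[0]


def block_auroc(
    selected_markers: Sequence[str],
    cohorts: CohortMap,
    sample_ids: Optional[Sequence[str]] = None,
    n_folds: int = 10,
    model_name: str = "logistic_ridge",
    seed: int = 0,
) -> float:
    """Median across-fold CV AUROC of a classifier on the selected markers."""
    if len(selected_markers) == 0:
        raise ValueError("block_auroc requires at least one selected marker")
    X, y, _ = assemble_features(cohorts, list(selected_markers),
                                sample_ids=sample_ids, statuses=(PSA, PSC))
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("block_auroc requires both subtypes present")
    n_splits = min(n_folds, int(y.sum()), int((1 - y).sum()))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    fold_auc = []
    for tr, te in skf.split(X, y):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            warnings.warn("block_auroc: fold lacking one class skipped")
            continue
        model = make_classifier(model_name, random_state=seed)
        model.fit(X[tr], y[tr])
        fold_auc.append(auroc(psa_scores(model, X[te]), y[te]))
    if not fold_auc:
        raise ValueError("block_auroc: all folds skipped")
    return float(np.median(fold_auc))


def stepwise_select(
    cohorts: CohortMap,
    covariate_names: Sequence[str] = (),
    p_pool_max: float = 0.05,
    block_size: int = 10,
    min_gain: float = 0.002,
    patience: int = 3,
    max_markers: int = 200,
    ml_evaluator: Optional[Callable[[Sequence[str]], float]] = None,
    sample_ids: Optional[Sequence[str]] = None,
    rho: float = 0.0,
    gc_correct: bool = False,
    min_r2: Optional[float] = None,
) -> ConditionalPath:
    """Stepwise conditional indirect meta-analysis feature selection.

    ``ml_evaluator`` maps a marker list to a scalar (median CV AUROC); when
    None the AUROC plateau rule is disabled and selection runs until the
    budget or the pool is exhausted.
    """
    unconditional = indirect_scan(
        cohorts, covariate_names, sample_ids=sample_ids,
        rho=rho, gc_correct=gc_correct, min_r2=min_r2,
    )
    pool_df = unconditional[
        np.isfinite(unconditional["p_value"])
        & (unconditional["p_value"] <= p_pool_max)
    ]
    pool = list(pool_df["marker_id"])
    if not pool:
        raise ValueError(f"no candidates at p <= {p_pool_max}")
    logger.info("stepwise_select: candidate pool of %d markers", len(pool))

    selected: list = []
    step_rows = []
    trace: list = []
    low_gain_streak = 0
    prev_block_auc: Optional[float] = None
    stop_reason = "pool_exhausted"

    scan = unconditional.set_index("marker_id", drop=False).rename_axis(None)
    while pool:
        sub = scan.loc[scan["marker_id"].isin(pool)]
        best = _pick_best(sub)
        if best is None:
            stop_reason = "separation"
            break
        mid = best["marker_id"]
        selected.append(mid)
        pool.remove(mid)
        step_rows.append({
            "step": len(selected), "marker_id": mid,
            "chi2": float(best["chi2"]), "p_value": float(best["p_value"]),
        })

        if len(selected) >= max_markers:
            stop_reason = "max_markers"
            break

        if ml_evaluator is not None and len(selected) % block_size == 0:
            block_auc = float(ml_evaluator(list(selected)))
            trace.append(block_auc)
            if prev_block_auc is not None:
                gain = block_auc - prev_block_auc
                low_gain_streak = low_gain_streak + 1 if gain < min_gain else 0
                if low_gain_streak >= patience:
                    stop_reason = "auroc_plateau"
                    prev_block_auc = block_auc
                    break
            prev_block_auc = block_auc

        if not pool:
            stop_reason = "pool_exhausted"
            break
        # conditional rescan of the remaining pool
        scan = indirect_scan(
            cohorts, covariate_names, conditioning_markers=selected,
            marker_subset=pool, sample_ids=sample_ids,
            rho=rho, gc_correct=gc_correct, min_r2=min_r2,
        ).set_index("marker_id", drop=False).rename_axis(None)
        fitted = set(scan.loc[np.isfinite(scan["p_value"]), "marker_id"])
        dropped = [m for m in pool if m not in fitted]
        if dropped:
            logger.info("stepwise_select: dropping %d unfittable markers", len(dropped))
            pool = [m for m in pool if m in fitted]
            if not pool:
                stop_reason = "separation"
                break

    steps = pd.DataFrame(step_rows, columns=["step", "marker_id", "chi2", "p_value"])
    return ConditionalPath(selected, steps, trace, stop_reason)
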