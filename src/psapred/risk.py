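"""Bayes/KDE calibration of classifier scores into posterior PsA risk.

    P(PsA | s) = d(s|PsA) P(PsA) / [ d(s|PsA) P(PsA) + d(s|PsC) P(PsC) ]

with class-conditional Gaussian kernel densities fitted on
cross-validation scores only, and P(PsA) a configurable prior prevalence
(default grid 10/20/30/40%).  Scores outside the training range are
evaluated at the clipped boundary so the KDE tails cannot underflow to a
0/0 posterior.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .classify import psa_scores

logger = logging.getLogger(__name__)

DEFAULT_PRIORS = (0.10, 0.20, 0.30, 0.40)


@dataclass
class ScoreDensities:
    """Class-conditional score densities plus the training score range."""

    kde_psa: gaussian_kde
    kde_psc: gaussian_kde
    lo: float
    hi: float

    def evaluate(self, s) -> tuple:
        s = np.clip(np.asarray(s, dtype=float), self.lo, self.hi)
        return self.kde_psa(s), self.kde_psc(s)


@dataclass
class RiskProfile:
    """Per-sample raw score and posterior per prior prevalence."""

    table: pd.DataFrame          # sample_id, score, posterior_<prior> ...
    priors: tuple
    high_risk_counts: dict       # threshold -> count (at the first prior)


def fit_densities(
    cv_scores,
    cv_labels,
    bandwidth_rule: str = "silverman",
) -> ScoreDensities:
    """Gaussian KDEs of PsA and PsC score distributions.

    Requires >= 10 scores per class and non-degenerate (non-constant)
    scores; both are preconditions of a usable density ratio.
    """
    s = np.asarray(cv_scores, dtype=float)
    y = np.asarray(cv_labels).astype(int)
    s_psa, s_psc = s[y == 1], s[y == 0]
    if len(s_psa) < 10 or len(s_psc) < 10:
        raise ValueError("fit_densities requires >= 10 scores per class")
    if np.std(s_psa) == 0.0 or np.std(s_psc) == 0.0:
        raise ValueError(
            "zero-variance scores in one class; add a small score jitter"
        )
    kde_psa = gaussian_kde(s_psa, bw_method=bandwidth_rule)
    kde_psc = gaussian_kde(s_psc, bw_method=bandwidth_rule)
    return ScoreDensities(kde_psa, kde_psc, float(s.min()), float(s.max()))


def posterior_risk(s, densities: ScoreDensities, prior_psa: float) -> np.ndarray:
    """Posterior P(PsA | s) at the given prior prevalence."""
    if not 0.0 < prior_psa < 1.0:
        raise ValueError("prior must lie in (0, 1)")
    d_psa, d_psc = densities.evaluate(s)
    num = d_psa * prior_psa
    den = num + d_psc * (1.0 - prior_psa)
    out = np.full_like(num, prior_psa, dtype=float)
    ok = den > 0
    if not ok.all():
        warnings.warn("both class densities are 0 at some scores; "
                      "posterior set to the prior there")
    out[ok] = num[ok] / den[ok]
    return out


def calibration_curve(posteriors, true_labels, n_bins: int = 10) -> pd.DataFrame:
    """Reliability table: per bin, mean prediction vs. empirical PsA rate.

    Bins partition [0, 1]; empty bins are reported with count 0 and NaN
    summaries so they drop out of any aggregate error.
    """
    p = np.asarray(posteriors, dtype=float)
    y = np.asarray(true_labels).astype(int)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        rows.append({
            "bin_lo": edges[b],
            "bin_hi": edges[b + 1],
            "count": int(mask.sum()),
            "mean_predicted": float(p[mask].mean()) if mask.any() else np.nan,
            "empirical_fraction": float(y[mask].mean()) if mask.any() else np.nan,
        })
    return pd.DataFrame(rows)


def calibration_error(curve: pd.DataFrame) -> float:
    """Count-weighted mean |predicted - empirical| over occupied bins."""
    occ = curve[curve["count"] > 0]
    w = occ["count"].to_numpy(dtype=float)
    err = np.abs(occ["mean_predicted"] - occ["empirical_fraction"]).to_numpy()
    return float(np.sum(w * err) / np.sum(w))


def assess_unknowns(
    X_unknown: np.ndarray,
    sample_ids: Sequence[str],
    model,
    densities: ScoreDensities,
    priors: Sequence[float] = DEFAULT_PRIORS,
    thresholds: Sequence[float] = (0.80, 0.98),
    expected_n_features: Optional[int] = None,
) -> RiskProfile:
    """Posterior PsA risk for samples of unknown subtype.

    ``expected_n_features`` guards against marker mismatch between the
    trained model and the supplied genotypes.
    """
    X = np.asarray(X_unknown, dtype=float)
    ids = np.asarray(sample_ids, dtype=object)
    priors = tuple(priors)
    if X.ndim != 2 or len(ids) != X.shape[0]:
        raise ValueError("X_unknown must be 2-D with one row per sample id")
    n_expected = expected_n_features
    if n_expected is None:
        n_expected = getattr(model, "n_features_in_", None)
    if n_expected is not None and X.shape[1] != n_expected:
        raise ValueError(
            f"marker mismatch: model expects {n_expected} features, "
            f"got {X.shape[1]}"
        )
    if len(ids) == 0:
        cols = {"sample_id": [], "score": []}
        cols.update({f"posterior_{p:g}": [] for p in priors})
        return RiskProfile(pd.DataFrame(cols), priors, {t: 0 for t in thresholds})

    scores = psa_scores(model, X)
    table = pd.DataFrame({"sample_id": ids, "score": scores})
    for p in priors:
        table[f"posterior_{p:g}"] = posterior_risk(scores, densities, p)
    first = f"posterior_{priors[0]:g}"
    counts = {t: int((table[first] > t).sum()) for t in thresholds}
    return RiskProfile(table, priors, counts)
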