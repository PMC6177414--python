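"""Marker QC and per-cohort logistic Wald association.

The association scan fits, per marker, a logistic regression of
case/control status on dosage plus covariates plus optional conditioning
marker dosages, and reports the Wald statistic for the dosage term.
Separation and collinearity are flagged (``converged=False``) rather than
patched: the stepwise selection layer treats them as stopping conditions.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from .core import CONTROL, GenotypeMatrix, PSA, PhenotypeTable

logger = logging.getLogger(__name__)

#: chi-square(1 df) median, the genomic-control null reference.
CHI2_1_MEDIAN = float(chi2.ppf(0.5, df=1))

RESULT_COLUMNS = [
    "marker_id", "chrom", "pos", "risk_allele", "nonrisk_allele",
    "imputation_r2", "genotyped", "beta", "se", "wald_z", "p_value",
    "case_af", "control_af", "n_cases", "n_controls", "converged", "reason",
]


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Wigginton-style enumeration over het counts)
# ---------------------------------------------------------------------------
def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value from genotype counts.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts and sums probabilities <= that of the observed table.
    """
    n_het, n_hom1, n_hom2 = int(n_het), int(n_hom1), int(n_hom2)
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het  # rare-allele count
    # unnormalized probabilities over all het counts with the same parity
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downward recurrence:  P(h-2)/P(h) = h*(h-1) / (4*(hom1+1)*(hom2+1))
    h, p = mid, 1.0
    hom1 = (rare - mid) // 2
    hom2 = n - mid - hom1
    c1, c2 = hom1, hom2
    while h >= 2:
        p = p * h * (h - 1) / (4.0 * (c1 + 1) * (c2 + 1))
        h -= 2
        c1 += 1
        c2 += 1
        probs[h] = p
    h, p = mid, 1.0
    c1, c2 = hom1, hom2
    while h + 2 <= rare:
        p = p * 4.0 * c1 * c2 / ((h + 1.0) * (h + 2.0))
        h += 2
        c1 -= 1
        c2 -= 1
        probs[h] = p
    total = sum(probs.values())
    target = probs[n_het] / total
    return float(min(1.0, sum(v for v in probs.values() if v / total <= target * (1 + 1e-12)) / total))


# ---------------------------------------------------------------------------
# Marker QC
# ---------------------------------------------------------------------------
def marker_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 1e-6,
) -> GenotypeMatrix:
    """Remove markers failing MAF, call-rate, or HWE thresholds.

    HWE is tested on hard calls of genotyped markers only; imputed-only
    markers skip the HWE criterion.  Per-criterion removal counts are
    logged.  Idempotent.
    """
    for name, v in (("maf_min", maf_min), ("call_rate_min", call_rate_min),
                    ("hwe_p_min", hwe_p_min)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie in (0, 1)")
    if g.n_markers == 0:
        logger.warning("marker_qc: empty genotype matrix")
        return g

    maf_ok = g.maf() >= maf_min
    cr_ok = g.call_rate() >= call_rate_min

    hwe_ok = np.ones(g.n_markers, dtype=bool)
    genotyped = g.markers["genotyped"].to_numpy(dtype=bool)
    for j in np.flatnonzero(genotyped):
        d = g.dosages[:, j]
        d = d[~np.isnan(d)]
        n_hom1 = int((d == 0).sum())
        n_het = int((d == 1).sum())
        n_hom2 = int((d == 2).sum())
        hwe_ok[j] = hwe_exact_p(n_het, n_hom1, n_hom2) >= hwe_p_min

    keep = maf_ok & cr_ok & hwe_ok
    logger.info(
        "marker_qc: %d/%d kept (removed: maf %d, call-rate %d, hwe %d)",
        int(keep.sum()), g.n_markers, int((~maf_ok).sum()),
        int((~cr_ok).sum()), int((~hwe_ok).sum()),
    )
    return g.subset_markers(keep)


# ---------------------------------------------------------------------------
# Logistic regression (Newton / IRLS)
# ---------------------------------------------------------------------------
def _fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    beta0: Optional[np.ndarray] = None,
    max_iter: int = 25,
    tol: float = 1e-8,
    beta_cap: float = 15.0,
):
    """Newton-Raphson logistic fit.

    Returns ``(beta, se, converged, reason)``; ``se`` is None unless
    converged.  Declares separation when any coefficient exceeds
    ``beta_cap`` in absolute value, and collinearity when the observed
    information matrix is numerically singular.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, None, False, "collinear"
        if not np.all(np.isfinite(delta)):
            return beta, None, False, "collinear"
        beta = beta + delta
        if np.max(np.abs(beta)) > beta_cap:
            return beta, None, False, "separation"
        if np.max(np.abs(delta)) < tol:
            mu = expit(X @ beta)
            w = mu * (1.0 - mu)
            H = (X * w[:, None]).T @ X
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                return beta, None, False, "collinear"
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            if not np.all(np.isfinite(se)) or np.any(se == 0.0):
                return beta, None, False, "collinear"
            return beta, se, True, ""
    return beta, None, False, "no_convergence"


def logistic_wald(
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    case_label: str = PSA,
    control_label: str = CONTROL,
    covariate_names: Sequence[str] = (),
    conditioning_markers: Sequence[str] = (),
    marker_subset: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-marker logistic Wald association scan.

    For every tested marker, fits status ~ dosage + covariates +
    conditioning-marker dosages and reports beta/se/p for the dosage term.
    Rows with a missing dosage (for the marker or any conditioning marker)
    are dropped per marker (complete-case).  Markers in the conditioning
    set, and monomorphic markers, are skipped with a reason.
    """
    ph = pheno.df
    keep = ph["status"].isin([case_label, control_label])
    ids = ph.loc[keep, "sample_id"].to_numpy()
    if len(ids) == 0 or not (ph.loc[keep, "status"] == case_label).any() \
            or not (ph.loc[keep, "status"] == control_label).any():
        raise ValueError(
            f"need at least one {case_label} and one {control_label} sample"
        )
    sub = g.subset_samples(ids)
    y_all = (pheno.status_of(ids) == case_label).astype(float)

    cov = np.empty((len(ids), 0))
    if covariate_names:
        cov = PhenotypeTable(ph, tuple(covariate_names)).covariates_for(ids)

    cond_set = list(conditioning_markers)
    cond_idx = sub.marker_index(cond_set) if cond_set else np.array([], dtype=np.intp)
    cond_dos = sub.dosages[:, cond_idx]

    test_ids = list(marker_subset) if marker_subset is not None else list(sub.marker_ids)
    test_idx = sub.marker_index(test_ids)

    meta = sub.markers
    warm = None  # warm start for the no-marker nuisance model
    base_X = np.column_stack([np.ones(len(ids)), cov, cond_dos])
    base_ok = ~np.isnan(base_X).any(axis=1)
    if base_ok.all():
        b, _, conv, _ = _fit_logistic(base_X[base_ok], y_all[base_ok])
        if conv:
            warm = b

    records = []
    cond_lookup = set(cond_set)
    for mid, j in zip(test_ids, test_idx):
        row = meta.iloc[j]
        rec = {
            "marker_id": mid, "chrom": row["chrom"], "pos": row["pos"],
            "risk_allele": row["risk_allele"], "nonrisk_allele": row["nonrisk_allele"],
            "imputation_r2": row["imputation_r2"], "genotyped": bool(row["genotyped"]),
            "beta": np.nan, "se": np.nan, "wald_z": np.nan, "p_value": np.nan,
            "case_af": np.nan, "control_af": np.nan,
            "n_cases": 0, "n_controls": 0, "converged": False, "reason": "",
        }
        if mid in cond_lookup:
            rec["reason"] = "conditioned"
            records.append(rec)
            continue
        d = sub.dosages[:, j]
        ok = base_ok & ~np.isnan(d)
        dj, yj = d[ok], y_all[ok]
        rec["n_cases"] = int(yj.sum())
        rec["n_controls"] = int((1 - yj).sum())
        if rec["n_cases"] > 0:
            rec["case_af"] = float(dj[yj == 1].mean() / 2.0)
        if rec["n_controls"] > 0:
            rec["control_af"] = float(dj[yj == 0].mean() / 2.0)
        if rec["n_cases"] == 0 or rec["n_controls"] == 0:
            rec["reason"] = "single_class"
            records.append(rec)
            continue
        if np.std(dj) == 0.0:
            rec["reason"] = "monomorphic"
            records.append(rec)
            continue
        X = np.column_stack([np.ones(ok.sum()), dj, base_X[ok, 1:]])
        beta0 = None
        if warm is not None:
            beta0 = np.insert(warm, 1, 0.0)
        beta, se, converged, reason = _fit_logistic(X, yj, beta0=beta0)
        rec["converged"] = converged
        rec["reason"] = reason
        if converged:
            rec["beta"] = float(beta[1])
            rec["se"] = float(se[1])
            rec["wald_z"] = rec["beta"] / rec["se"]
            rec["p_value"] = float(2.0 * norm.sf(abs(rec["wald_z"])))
        records.append(rec)

    res = pd.DataFrame.from_records(records, columns=RESULT_COLUMNS)
    n_failed = int((~res["converged"]).sum())
    if n_failed:
        logger.debug("logistic_wald: %d/%d markers not fit", n_failed, len(res))
    return res


# ---------------------------------------------------------------------------
# Genomic control
# ---------------------------------------------------------------------------
def genomic_inflation(p_values) -> float:
    """Genomic-control lambda: median chi2(1) quantile over the null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("genomic_inflation: no finite p-values")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / CHI2_1_MEDIAN)
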