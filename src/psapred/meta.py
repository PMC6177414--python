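"""Fixed-effects inverse-variance meta-analysis and the indirect case-case
chi-square statistic.

Per-cohort estimates are harmonized to a common risk allele, optionally
genomic-control corrected (per-cohort standard errors inflated by
``sqrt(max(lambda, 1))``), and pooled with weights ``1/V_i``.  The indirect
statistic compares two case-control meta-analyses:

    chi2 = (b_A - b_C)^2 / (V_A + V_C - 2 rho sqrt(V_A V_C))

with ``rho = 0`` by default (conservative, since the two arms share
controls and their estimates are positively correlated).
"""
from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .assoc import genomic_inflation

logger = logging.getLogger(__name__)

META_COLUMNS = [
    "marker_id", "chrom", "pos", "risk_allele", "nonrisk_allele",
    "beta_meta", "se_meta", "z", "p_value", "direction", "n_cohorts_used",
]

METAL_COLUMNS = [
    "MarkerName", "Allele1", "Allele2", "Effect", "StdErr", "P-value", "Direction",
]


def _usable(df: pd.DataFrame, min_r2: Optional[float]) -> pd.Series:
    ok = df["converged"].astype(bool) & np.isfinite(df["beta"]) & (df["se"] > 0)
    if min_r2 is not None:
        ok &= df["imputation_r2"].astype(float) >= min_r2
    return ok


def fixed_effects_meta(
    results: Mapping[str, pd.DataFrame],
    cohort_order: Optional[Sequence[str]] = None,
    gc_correct: bool = False,
    min_r2: Optional[float] = None,
) -> pd.DataFrame:
    """Inverse-variance pooling of per-cohort association results.

    Parameters
    ----------
    results
        Mapping cohort name -> association result frame (``assoc`` schema).
    cohort_order
        Declared cohort order for the direction string; defaults to the
        mapping's iteration order.
    gc_correct
        Inflate each cohort's standard errors by ``sqrt(max(lambda, 1))``
        before pooling (never deflates).
    min_r2
        Estimates below this imputation quality count as unusable ('?').

    Returns a frame with one row per marker in the union across cohorts;
    markers with no usable cohort get missing ``p_value`` and an all-'?'
    direction.  The frame's ``attrs['lambda_applied']`` records per-cohort
    inflation factors actually applied.
    """
    order = list(cohort_order) if cohort_order is not None else list(results)
    if not order:
        raise ValueError("no cohorts supplied")

    lambdas: dict[str, float] = {}
    aligned: dict[str, pd.DataFrame] = {}
    ref: Optional[pd.DataFrame] = None
    for name in order:
        df = results[name].set_index("marker_id", drop=False)
        if gc_correct:
            finite = df["p_value"].to_numpy(dtype=float)
            lam = genomic_inflation(finite) if np.isfinite(finite).any() else 1.0
            lam = max(lam, 1.0)
            lambdas[name] = lam
            df = df.copy()
            df["se"] = df["se"] * np.sqrt(lam)
            df["p_value"] = 2.0 * norm.sf(np.abs(df["beta"] / df["se"]))
        else:
            lambdas[name] = 1.0
        aligned[name] = df
        meta_cols = df[["marker_id", "chrom", "pos", "risk_allele", "nonrisk_allele"]]
        ref = meta_cols if ref is None else pd.concat(
            [ref, meta_cols.loc[~meta_cols.index.isin(ref.index)]]
        )

    union = ref
    n = len(union)
    beta_mat = np.full((len(order), n), np.nan)
    var_mat = np.full((len(order), n), np.nan)

    for k, name in enumerate(order):
        df = aligned[name].reindex(union.index)
        present = df["marker_id"].notna().to_numpy()
        usable = np.zeros(n, dtype=bool)
        usable[present] = _usable(df.loc[present], min_r2).to_numpy()
        # allele harmonization against the reference orientation
        same = (df["risk_allele"] == union["risk_allele"]) & (
            df["nonrisk_allele"] == union["nonrisk_allele"]
        )
        flipped = (df["risk_allele"] == union["nonrisk_allele"]) & (
            df["nonrisk_allele"] == union["risk_allele"]
        )
        mismatch = usable & ~(same | flipped).to_numpy()
        if mismatch.any():
            logger.warning(
                "%s: %d markers with unharmonizable alleles treated as unusable",
                name, int(mismatch.sum()),
            )
            usable &= ~mismatch
        sign = np.where(flipped.to_numpy(), -1.0, 1.0)
        b = df["beta"].to_numpy(dtype=float) * sign
        v = df["se"].to_numpy(dtype=float) ** 2
        beta_mat[k, usable] = b[usable]
        var_mat[k, usable] = v[usable]

    w = np.where(np.isfinite(var_mat), 1.0 / var_mat, 0.0)
    wsum = w.sum(axis=0)
    used = (w > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta_meta = np.where(wsum > 0,
                             np.nansum(w * np.nan_to_num(beta_mat), axis=0) / wsum,
                             np.nan)
        se_meta = np.where(wsum > 0, 1.0 / np.sqrt(wsum), np.nan)
        z = beta_meta / se_meta
    p = np.where(np.isfinite(z), 2.0 * norm.sf(np.abs(z)), np.nan)

    dir_chars = np.where(
        np.isfinite(beta_mat), np.where(beta_mat >= 0, "+", "-"), "?"
    )
    direction = ["".join(dir_chars[:, j]) for j in range(n)]

    out = pd.DataFrame(
        {
            "marker_id": union["marker_id"].to_numpy(),
            "chrom": union["chrom"].to_numpy(),
            "pos": union["pos"].to_numpy(),
            "risk_allele": union["risk_allele"].to_numpy(),
            "nonrisk_allele": union["nonrisk_allele"].to_numpy(),
            "beta_meta": beta_meta,
            "se_meta": se_meta,
            "z": z,
            "p_value": p,
            "direction": direction,
            "n_cohorts_used": used,
        },
        columns=META_COLUMNS,
    ).reset_index(drop=True)
    out.attrs["lambda_applied"] = lambdas
    out.attrs["cohort_order"] = order
    return out


def indirect_meta(
    psa_vs_ctl: pd.DataFrame,
    psc_vs_ctl: pd.DataFrame,
    rho: float = 0.0,
) -> pd.DataFrame:
    """Indirect case-case chi-square comparing two case-control meta results.

    Markers usable in only one arm are emitted with missing ``p_value``.
    Raises if ``rho`` is outside [-1, 1] or a marker's denominator is <= 0.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    a = psa_vs_ctl.set_index("marker_id")
    c = psc_vs_ctl.set_index("marker_id")
    idx = a.index.union(c.index, sort=False)
    a = a.reindex(idx)
    c = c.reindex(idx)

    beta_a = a["beta_meta"].to_numpy(dtype=float)
    beta_c = c["beta_meta"].to_numpy(dtype=float)
    v_a = a["se_meta"].to_numpy(dtype=float) ** 2
    v_c = c["se_meta"].to_numpy(dtype=float) ** 2
    both = np.isfinite(beta_a) & np.isfinite(beta_c) & np.isfinite(v_a) & np.isfinite(v_c)

    denom = v_a + v_c - 2.0 * rho * np.sqrt(v_a * v_c)
    bad = both & (denom <= 0)
    if bad.any():
        raise ValueError(
            f"non-positive indirect variance for marker(s) {list(idx[bad][:5])}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(both, (beta_a - beta_c) ** 2 / denom, np.nan)
    p = np.where(np.isfinite(stat), chi2.sf(stat, df=1), np.nan)

    chrom = a["chrom"].where(a["chrom"].notna(), c["chrom"])
    pos = a["pos"].where(a["pos"].notna(), c["pos"])
    out = pd.DataFrame(
        {
            "marker_id": idx.to_numpy(),
            "chrom": chrom.to_numpy(),
            "pos": pos.to_numpy(),
            "chi2": stat,
            "p_value": p,
            "beta_psa": beta_a,
            "beta_psc": beta_c,
            "v_psa": v_a,
            "v_psc": v_c,
            "rho": rho,
        }
    ).reset_index(drop=True)
    return out


def direct_case_case_meta(
    results: Mapping[str, Optional[pd.DataFrame]],
    cohort_order: Optional[Sequence[str]] = None,
    gc_correct: bool = False,
    min_r2: Optional[float] = None,
) -> pd.DataFrame:
    """Pool per-cohort PsA-vs-PsC results; single-subtype cohorts excluded.

    Cohorts supplied as ``None`` (or with an empty frame) are treated as
    ineligible -- e.g. a PsA-only cohort that cannot contribute a case-case
    estimate -- and are dropped with a logged notice.
    """
    eligible = {k: v for k, v in results.items() if v is not None and len(v) > 0}
    skipped = sorted(set(results) - set(eligible))
    if skipped:
        logger.info("direct_case_case_meta: excluded cohort(s) %s", skipped)
    if not eligible:
        raise ValueError("no cohort with both subtypes available for direct meta")
    order = [c for c in (cohort_order or list(results)) if c in eligible]
    return fixed_effects_meta(eligible, cohort_order=order,
                              gc_correct=gc_correct, min_r2=min_r2)


# ---------------------------------------------------------------------------
# METAL-style summary interchange
# ---------------------------------------------------------------------------
def write_metal(meta: pd.DataFrame, path) -> None:
    """Write a meta result in METAL's whitespace-delimited column dialect."""
    out = pd.DataFrame(
        {
            "MarkerName": meta["marker_id"],
            "Allele1": meta["risk_allele"],
            "Allele2": meta["nonrisk_allele"],
            "Effect": meta["beta_meta"],
            "StdErr": meta["se_meta"],
            "P-value": meta["p_value"],
            "Direction": meta["direction"],
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_metal(path) -> pd.DataFrame:
    """Read a METAL-style summary file back into the meta result schema."""
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    missing = [c for c in METAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"METAL file lacks columns: {missing}")
    out = pd.DataFrame(
        {
            "marker_id": df["MarkerName"],
            "chrom": df.get("Chrom", pd.Series(["NA"] * len(df))),
            "pos": df.get("Pos", pd.Series([-1] * len(df))),
            "risk_allele": df["Allele1"],
            "nonrisk_allele": df["Allele2"],
            "beta_meta": df["Effect"].astype(float),
            "se_meta": df["StdErr"].astype(float),
            "z": df["Effect"].astype(float) / df["StdErr"].astype(float),
            "p_value": df["P-value"].astype(float),
            "direction": df["Direction"].astype(str),
            "n_cohorts_used": [
                sum(ch in "+-" for ch in str(d)) for d in df["Direction"]
            ],
        },
        columns=META_COLUMNS,
    )
    return out
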