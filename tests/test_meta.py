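import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, norm

from psapred import meta

COLS = ["marker_id", "chrom", "pos", "risk_allele", "nonrisk_allele",
        "imputation_r2", "genotyped", "beta", "se", "p_value", "converged"]


def assoc_frame(rows):
    """rows: list of dicts with marker_id, beta, se (+ optional overrides)."""
    out = []
    for i, r in enumerate(rows):
        rec = {"marker_id": r["marker_id"], "chrom": "1", "pos": 100 + i,
               "risk_allele": "A", "nonrisk_allele": "G",
               "imputation_r2": 1.0, "genotyped": True,
               "beta": r.get("beta", np.nan), "se": r.get("se", np.nan),
               "converged": r.get("converged", True)}
        rec.update({k: v for k, v in r.items() if k in rec})
        b, s = rec["beta"], rec["se"]
        rec["p_value"] = (2 * norm.sf(abs(b / s))
                          if np.isfinite(b) and np.isfinite(s) and s > 0 else np.nan)
        out.append(rec)
    return pd.DataFrame(out, columns=COLS)


# ---------------------------------------------------------------------------
# fixed_effects_meta
# ---------------------------------------------------------------------------
def test_hand_computed_inverse_variance_pooling():
    res = meta.fixed_effects_meta({
        "a": assoc_frame([{"marker_id": "m1", "beta": 0.2, "se": 0.1}]),
        "b": assoc_frame([{"marker_id": "m1", "beta": 0.5, "se": 0.2}]),
    })
    row = res.iloc[0]
    assert row["beta_meta"] == pytest.approx(0.26)          # (20+12.5)/125
    assert row["se_meta"] == pytest.approx(np.sqrt(1 / 125))
    assert row["z"] == pytest.approx(0.26 * np.sqrt(125), rel=1e-9)
    assert row["p_value"] == pytest.approx(2 * norm.sf(0.26 * np.sqrt(125)), rel=1e-6)
    assert row["direction"] == "++"
    assert row["n_cohorts_used"] == 2


def test_single_cohort_identity():
    df = assoc_frame([{"marker_id": "m1", "beta": 0.37, "se": 0.08}])
    res = meta.fixed_effects_meta({"only": df})
    assert res.iloc[0]["beta_meta"] == pytest.approx(0.37)
    assert res.iloc[0]["se_meta"] == pytest.approx(0.08)
    assert res.iloc[0]["p_value"] == pytest.approx(df.iloc[0]["p_value"])


def test_opposite_effects_cancel():
    res = meta.fixed_effects_meta({
        "a": assoc_frame([{"marker_id": "m1", "beta": 0.3, "se": 0.1}]),
        "b": assoc_frame([{"marker_id": "m1", "beta": -0.3, "se": 0.1}]),
    })
    assert res.iloc[0]["beta_meta"] == pytest.approx(0.0, abs=1e-12)
    assert res.iloc[0]["p_value"] == pytest.approx(1.0)
    assert res.iloc[0]["direction"] == "+-"


def test_se_meta_never_exceeds_min_cohort_se():
    rng = np.random.default_rng(0)
    results = {}
    for c in range(4):
        results[f"c{c}"] = assoc_frame([
            {"marker_id": f"m{j}", "beta": rng.normal(), "se": rng.uniform(0.05, 0.5)}
            for j in range(20)
        ])
    pooled = meta.fixed_effects_meta(results)
    min_se = np.min([results[c]["se"].to_numpy() for c in results], axis=0)
    assert (pooled["se_meta"].to_numpy() <= min_se + 1e-12).all()


def test_pooling_invariant_to_cohort_order():
    a = assoc_frame([{"marker_id": "m1", "beta": 0.2, "se": 0.1}])
    b = assoc_frame([{"marker_id": "m1", "beta": 0.5, "se": 0.2}])
    r1 = meta.fixed_effects_meta({"a": a, "b": b}, cohort_order=["a", "b"])
    r2 = meta.fixed_effects_meta({"b": b, "a": a}, cohort_order=["b", "a"])
    assert r1.iloc[0]["beta_meta"] == pytest.approx(r2.iloc[0]["beta_meta"])
    assert r1.iloc[0]["p_value"] == pytest.approx(r2.iloc[0]["p_value"])


def test_allele_flip_harmonized():
    flipped = assoc_frame([{"marker_id": "m1", "beta": -0.2, "se": 0.1}])
    flipped.loc[0, ["risk_allele", "nonrisk_allele"]] = ["G", "A"]
    res = meta.fixed_effects_meta({
        "ref": assoc_frame([{"marker_id": "m1", "beta": 0.2, "se": 0.1}]),
        "flip": flipped,
    })
    assert res.iloc[0]["beta_meta"] == pytest.approx(0.2)
    assert res.iloc[0]["direction"] == "++"


def test_allele_mismatch_unusable():
    other = assoc_frame([{"marker_id": "m1", "beta": 0.2, "se": 0.1}])
    other.loc[0, ["risk_allele", "nonrisk_allele"]] = ["C", "T"]
    res = meta.fixed_effects_meta({
        "ref": assoc_frame([{"marker_id": "m1", "beta": 0.2, "se": 0.1}]),
        "odd": other,
    })
    assert res.iloc[0]["direction"] == "+?"
    assert res.iloc[0]["n_cohorts_used"] == 1


def test_missing_and_nonconverged_marked_question():
    a = assoc_frame([{"marker_id": "m1", "beta": 0.2, "se": 0.1},
                     {"marker_id": "m2", "beta": 0.1, "se": 0.1}])
    b = assoc_frame([{"marker_id": "m1", "converged": False}])
    res = meta.fixed_effects_meta({"a": a, "b": b}).set_index("marker_id")
    assert res.loc["m1", "direction"] == "+?"
    assert res.loc["m2", "direction"] == "+?"
    assert res.loc["m2", "n_cohorts_used"] == 1


def test_no_usable_cohort_emits_missing():
    res = meta.fixed_effects_meta({"a": assoc_frame([{"marker_id": "m1",
                                                      "converged": False}])})
    assert np.isnan(res.iloc[0]["p_value"])
    assert res.iloc[0]["direction"] == "?"


def test_low_r2_excluded_with_min_r2():
    low = assoc_frame([{"marker_id": "m1", "beta": 0.2, "se": 0.1}])
    low.loc[0, "imputation_r2"] = 0.4
    res = meta.fixed_effects_meta(
        {"a": assoc_frame([{"marker_id": "m1", "beta": 0.2, "se": 0.1}]),
         "b": low}, min_r2=0.7)
    assert res.iloc[0]["direction"] == "+?"


def test_gc_correction_never_deflates():
    rng = np.random.default_rng(4)
    # p-values strongly sub-uniform => lambda < 1, must be floored at 1
    deflated = assoc_frame([
        {"marker_id": f"m{j}", "beta": rng.normal(0, 0.01), "se": 1.0}
        for j in range(200)
    ])
    res = meta.fixed_effects_meta({"a": deflated}, gc_correct=True)
    assert res.attrs["lambda_applied"]["a"] == 1.0
    np.testing.assert_allclose(res["se_meta"], deflated["se"], rtol=1e-12)


def test_gc_correction_inflates_se():
    rng = np.random.default_rng(8)
    inflated = assoc_frame([
        {"marker_id": f"m{j}", "beta": rng.normal(0, 2.0), "se": 1.0}
        for j in range(500)
    ])
    res = meta.fixed_effects_meta({"a": inflated}, gc_correct=True)
    lam = res.attrs["lambda_applied"]["a"]
    assert lam > 1.5
    np.testing.assert_allclose(res["se_meta"], np.sqrt(lam), rtol=1e-9)


# ---------------------------------------------------------------------------
# indirect_meta
# ---------------------------------------------------------------------------
def _meta_frame(beta, se, marker="m1"):
    return pd.DataFrame({
        "marker_id": [marker], "chrom": ["1"], "pos": [100],
        "risk_allele": ["A"], "nonrisk_allele": ["G"],
        "beta_meta": [beta], "se_meta": [se],
        "z": [beta / se], "p_value": [2 * norm.sf(abs(beta / se))],
        "direction": ["+"], "n_cohorts_used": [1],
    })


def test_indirect_identical_effects_chi2_zero():
    res = meta.indirect_meta(_meta_frame(0.3, 0.1), _meta_frame(0.3, 0.1))
    assert res.iloc[0]["chi2"] == pytest.approx(0.0, abs=1e-12)
    assert res.iloc[0]["p_value"] == pytest.approx(1.0)


def test_indirect_hand_computed():
    res = meta.indirect_meta(_meta_frame(0.3, 0.1), _meta_frame(0.1, 0.1), rho=0.0)
    assert res.iloc[0]["chi2"] == pytest.approx(2.0)
    assert res.iloc[0]["p_value"] == pytest.approx(chi2.sf(2.0, 1), rel=1e-9)
    assert res.iloc[0]["p_value"] == pytest.approx(0.1573, abs=2e-4)


def test_indirect_rho_half_larger_chi2():
    r0 = meta.indirect_meta(_meta_frame(0.3, 0.1), _meta_frame(0.1, 0.1), rho=0.0)
    r5 = meta.indirect_meta(_meta_frame(0.3, 0.1), _meta_frame(0.1, 0.1), rho=0.5)
    assert r5.iloc[0]["chi2"] == pytest.approx(4.0)
    assert r5.iloc[0]["chi2"] > r0.iloc[0]["chi2"]


def test_indirect_chi2_monotone_over_rho_grid():
    chis = [meta.indirect_meta(_meta_frame(0.4, 0.12), _meta_frame(0.1, 0.2),
                               rho=r).iloc[0]["chi2"]
            for r in np.linspace(0, 0.9, 10)]
    assert all(b >= a - 1e-12 for a, b in zip(chis, chis[1:]))


def test_indirect_rho_out_of_range():
    with pytest.raises(ValueError, match="rho"):
        meta.indirect_meta(_meta_frame(0.3, 0.1), _meta_frame(0.1, 0.1), rho=1.5)


def test_indirect_nonpositive_denominator_names_marker():
    with pytest.raises(ValueError, match="m1"):
        meta.indirect_meta(_meta_frame(0.3, 0.1), _meta_frame(0.1, 0.1), rho=1.0)


def test_indirect_one_armed_marker_missing_p():
    psa = _meta_frame(0.3, 0.1, marker="mA")
    psc = _meta_frame(0.1, 0.1, marker="mB")
    res = meta.indirect_meta(psa, psc).set_index("marker_id")
    assert np.isnan(res.loc["mA", "p_value"])
    assert np.isnan(res.loc["mB", "p_value"])


# ---------------------------------------------------------------------------
# direct_case_case_meta
# ---------------------------------------------------------------------------
def test_direct_excludes_ineligible_cohorts():
    df = assoc_frame([{"marker_id": "m1", "beta": 0.4, "se": 0.1}])
    res = meta.direct_case_case_meta({"both": df, "psa_only": None})
    assert res.iloc[0]["n_cohorts_used"] == 1
    assert res.iloc[0]["beta_meta"] == pytest.approx(0.4)


def test_direct_single_eligible_identity():
    df = assoc_frame([{"marker_id": "m1", "beta": 0.4, "se": 0.1}])
    res = meta.direct_case_case_meta({"only": df})
    assert res.iloc[0]["se_meta"] == pytest.approx(0.1)


def test_direct_no_eligible_errors():
    with pytest.raises(ValueError, match="no cohort"):
        meta.direct_case_case_meta({"a": None, "b": None})


def test_direct_and_indirect_rank_planted_locus_first(small_sim):
    """Concordance on simulation: both rank the strongest subtype locus top."""
    from psapred.assoc import logistic_wald
    from psapred.core import PSA, PSC
    from psapred.select import indirect_scan

    cohorts = small_sim.cohorts
    direct_results = {}
    for name, co in cohorts.items():
        direct_results[name] = logistic_wald(
            co.genotypes, co.phenotypes, case_label=PSA, control_label=PSC)
    direct = meta.direct_case_case_meta(direct_results)
    indirect = indirect_scan(cohorts, covariate_names=("subpop",))
    top_direct = direct.sort_values("p_value").iloc[0]["marker_id"]
    top_indirect = indirect.sort_values("p_value").iloc[0]["marker_id"]
    mhc_id = f"m{small_sim.truth.mhc_idx:05d}"
    assert top_direct == mhc_id
    assert top_indirect == mhc_id


# ---------------------------------------------------------------------------
# METAL interchange
# ---------------------------------------------------------------------------
def test_metal_round_trip(tmp_path):
    pooled = meta.fixed_effects_meta({
        "a": assoc_frame([{"marker_id": "m1", "beta": 0.2, "se": 0.1},
                          {"marker_id": "m2", "beta": -0.1, "se": 0.2}]),
        "b": assoc_frame([{"marker_id": "m1", "beta": 0.5, "se": 0.2}]),
    })
    path = tmp_path / "out.meta"
    meta.write_metal(pooled, path)
    back = meta.read_metal(path)
    np.testing.assert_allclose(back["beta_meta"], pooled["beta_meta"], rtol=1e-6)
    np.testing.assert_allclose(back["se_meta"], pooled["se_meta"], rtol=1e-6)
    assert list(back["direction"]) == list(pooled["direction"])
    assert list(back["n_cohorts_used"]) == list(pooled["n_cohorts_used"])


def test_metal_missing_columns_rejected(tmp_path):
    p = tmp_path / "bad.meta"
    p.write_text("MarkerName\tEffect\nm1\t0.2\n")
    with pytest.raises(ValueError, match="lacks columns"):
        meta.read_metal(p)
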