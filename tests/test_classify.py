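import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from psapred import classify
from psapred.core import PhenotypeTable


def auroc_bruteforce(scores, labels):
    """Oracle: count concordant case-control pairs, ties as 0.5."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def _pheno(n_psa, n_psc, n_cohorts=1):
    rows = []
    i = 0
    for c in range(n_cohorts):
        for _ in range(n_psa // n_cohorts):
            rows.append((f"s{i:05d}", f"c{c}", "PSA")); i += 1
        for _ in range(n_psc // n_cohorts):
            rows.append((f"s{i:05d}", f"c{c}", "PSC")); i += 1
    return PhenotypeTable(pd.DataFrame(rows, columns=["sample_id", "cohort", "status"]))


# ---------------------------------------------------------------------------
# make_split
# ---------------------------------------------------------------------------
def test_split_arithmetic_1000_1000():
    plan = classify.make_split(_pheno(1000, 1000), seed=0)
    assert len(plan.test_ids) == 200
    statuses = pd.Series([s[:1] for s in plan.test_ids])  # not usable; recount
    ph = _pheno(1000, 1000)
    status = ph.status_of(plan.test_ids)
    assert (status == "PSA").sum() == 60
    assert (status == "PSC").sum() == 140


def test_split_balanced_training_and_disjoint():
    ph = _pheno(800, 1200)
    plan = classify.make_split(ph, seed=1)
    assert set(plan.train_ids).isdisjoint(plan.test_ids)
    status = ph.status_of(plan.train_ids)
    assert (status == "PSA").sum() == (status == "PSC").sum()


def test_split_deterministic():
    a = classify.make_split(_pheno(500, 500), seed=42)
    b = classify.make_split(_pheno(500, 500), seed=42)
    assert list(a.train_ids) == list(b.train_ids)
    assert list(a.test_ids) == list(b.test_ids)
    assert a.folds == b.folds
    assert a.trial_seeds == b.trial_seeds


def test_split_infeasible_errors():
    with pytest.raises(ValueError, match="infeasible"):
        classify.make_split(_pheno(10, 1000), seed=0)


def test_split_folds_partition_training():
    ph = _pheno(400, 400, n_cohorts=2)
    plan = classify.make_split(ph, seed=3)
    assert set(plan.folds) == set(plan.train_ids)
    counts = pd.Series(list(plan.folds.values())).value_counts()
    assert len(counts) == 10
    assert counts.max() - counts.min() <= 4


def test_split_audit_detects_leak():
    plan = classify.make_split(_pheno(200, 200), seed=0)
    with pytest.raises(RuntimeError, match="isolation"):
        plan.assert_no_test_leak([plan.test_ids[0]])
    plan.assert_no_test_leak(plan.train_ids)  # no raise


def test_trial_seeds_count():
    plan = classify.make_split(_pheno(200, 200), seed=0, n_trials=50)
    assert len(plan.trial_seeds) == 50
    assert len(set(plan.trial_seeds)) == 50


# ---------------------------------------------------------------------------
# auroc
# ---------------------------------------------------------------------------
def test_auroc_perfect():
    assert classify.auroc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0


def test_auroc_all_ties():
    assert classify.auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5


def test_auroc_worked_example():
    scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
    labels = [1, 1, 1, 0, 0, 0]
    assert classify.auroc(scores, labels) == pytest.approx(8 / 9)


def test_auroc_single_class_errors():
    with pytest.raises(ValueError):
        classify.auroc([1, 2], [1, 1])


def test_auroc_monotone_transform_invariant():
    rng = np.random.default_rng(0)
    s = rng.standard_normal(50)
    y = rng.integers(0, 2, 50)
    y[0], y[1] = 0, 1
    base = classify.auroc(s, y)
    assert classify.auroc(3 * s + 2, y) == pytest.approx(base)
    assert classify.auroc(np.exp(s), y) == pytest.approx(base)


@settings(max_examples=40, deadline=None)
@given(st.integers(2, 60), st.integers(0, 2**31 - 1))
def test_auroc_matches_bruteforce(n, seed):
    rng = np.random.default_rng(seed)
    scores = rng.integers(0, 8, size=n).astype(float)  # force ties
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
    if labels.sum() in (0, n):
        return
    assert classify.auroc(scores, labels) == pytest.approx(
        auroc_bruteforce(scores, labels))


# ---------------------------------------------------------------------------
# topk_metrics
# ---------------------------------------------------------------------------
def test_topk_perfect_at_prevalence():
    y = np.r_[np.ones(30), np.zeros(70)].astype(int)
    s = np.r_[np.ones(30), np.zeros(70)]
    p, r, sp = classify.topk_metrics(s, y, 30)
    assert (p, r, sp) == (1.0, 1.0, 1.0)


def test_topk_call_everyone():
    y = np.r_[np.ones(30), np.zeros(70)].astype(int)
    s = np.arange(100, dtype=float)
    p, r, sp = classify.topk_metrics(s, y, 100)
    assert r == 1.0
    assert p == pytest.approx(0.3)
    assert sp == 0.0


def test_topk_random_scores_precision_near_prevalence():
    rng = np.random.default_rng(1)
    n = 10_000
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=3000, replace=False)] = 1
    s = rng.random(n)
    p, _, _ = classify.topk_metrics(s, y, 10)
    assert p == pytest.approx(0.30, abs=0.03)


def test_topk_recall_monotone_in_k():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, 500)
    y[:5] = 1
    s = rng.random(500)
    recalls = [classify.topk_metrics(s, y, k)[1] for k in (5, 10, 20, 50, 90)]
    assert all(b >= a for a, b in zip(recalls, recalls[1:]))


def test_topk_integer_consistency():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 203)
    y[:2] = [0, 1]
    s = rng.random(203)
    p, _, _ = classify.topk_metrics(s, y, 7)
    n_called = int(np.ceil(0.07 * 203))
    assert (p * n_called) == pytest.approx(round(p * n_called))


def test_topk_bad_k():
    with pytest.raises(ValueError):
        classify.topk_metrics([1, 2], [0, 1], 0)


# ---------------------------------------------------------------------------
# registry / cross_validate
# ---------------------------------------------------------------------------
def test_registry_has_required_families():
    reg = classify.registry()
    assert {"logistic_ridge", "lda", "sda", "random_forest",
            "elastic_net"} <= set(reg)
    assert len(reg) >= 5
    for name in reg:
        model = classify.make_classifier(name, random_state=0)
        assert hasattr(model, "fit")


def test_unknown_model_lists_registry():
    with pytest.raises(ValueError, match="logistic_ridge"):
        classify.make_classifier("nope")
    with pytest.raises(ValueError, match="registry"):
        classify.cross_validate("nope", np.zeros((4, 1)), np.array([0, 1, 0, 1]))


def _informative_data(n=300, p=20, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    eta = X[:, :5].sum(axis=1)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return X, y


def test_cross_validate_informative_beats_permuted():
    X, y = _informative_data()
    rng = np.random.default_rng(1)
    res = classify.cross_validate("logistic_ridge", X, y, folds=5, trials=3, seed=0)
    y_perm = rng.permutation(y)
    null = classify.cross_validate("logistic_ridge", X, y_perm, folds=5,
                                   trials=3, seed=0)
    assert res["mean_auroc"] > 0.75
    assert null["mean_auroc"] == pytest.approx(0.5, abs=0.05)


def test_cross_validate_deterministic():
    X, y = _informative_data(n=200, p=5, seed=2)
    a = classify.cross_validate("logistic_ridge", X, y, folds=4, trials=5, seed=9)
    b = classify.cross_validate("logistic_ridge", X, y, folds=4, trials=5, seed=9)
    np.testing.assert_array_equal(a["per_trial"], b["per_trial"])


# ---------------------------------------------------------------------------
# elastic net
# ---------------------------------------------------------------------------
def test_elastic_net_full_shrinkage_zero_coefs():
    X, y = _informative_data(n=150, p=10, seed=3)
    _, path = classify.elastic_net_model(X, y, alphas=np.array([1e3]), cv_folds=3)
    assert path.iloc[0]["n_nonzero"] == 0


def test_elastic_net_weak_penalty_matches_unpenalized():
    X, y = _informative_data(n=600, p=4, seed=4)
    model, path = classify.elastic_net_model(X, y, alphas=np.array([1e-8]),
                                             cv_folds=4)
    from sklearn.linear_model import LogisticRegression
    unpen = LogisticRegression(C=np.inf, max_iter=2000).fit(X, y)
    a = classify.auroc(classify.psa_scores(model, X), y)
    b = classify.auroc(classify.psa_scores(unpen, X), y)
    assert a == pytest.approx(b, abs=0.01)


def test_elastic_net_prefilter_errors_when_empty():
    X, y = _informative_data(n=100, p=5, seed=5)
    with pytest.raises(ValueError, match="prefilter"):
        classify.elastic_net_model(X, y, assoc_p=np.ones(5), p_max=0.05)


def test_elastic_net_planted_features_enter_path_first():
    rng = np.random.default_rng(6)
    n, p = 800, 50
    X = rng.standard_normal((n, p))
    eta = 1.2 * X[:, :5].sum(axis=1)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    alphas = np.geomspace(1e-4, 0.3, 25)[::-1]  # strong -> weak
    entry = np.full(p, np.inf)
    from sklearn.linear_model import LogisticRegression
    for i, alpha in enumerate(alphas):
        m = LogisticRegression(solver="saga", l1_ratio=0.5,
                               C=1.0 / (alpha * n), max_iter=5000).fit(X, y)
        nz = np.flatnonzero(m.coef_[0])
        entry[nz] = np.minimum(entry[nz], i)
    planted_entry = entry[:5]
    null_entry = entry[5:]
    # each planted feature enters before >= 90% of null features
    for e in planted_entry:
        assert (null_entry > e).mean() >= 0.9
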