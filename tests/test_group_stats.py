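"""Group statistics: associations, ANOVA/Tukey, effect sizes, ROC, counts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netfailq import group_stats as gs
from netfailq.datasets import GROUP_MEDIAN_SUVR, load_patient_zscore_table


# ---------------------------------------------------------------- associations


def test_perfect_association():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(50)
    res = gs.simple_associations(x, pd.DataFrame({"x": x}))
    assert res[0].coefficient == pytest.approx(1.0)
    assert res[0].p_fdr < 1e-10


def test_spearman_used_for_skewed_score(rng):
    x = rng.standard_normal(100)
    tmtb = np.exp(x + rng.normal(0, 0.1, 100))
    res = gs.simple_associations(
        x, pd.DataFrame({"TMTB": tmtb}), methods={"TMTB": "spearman"}
    )
    assert res[0].method == "spearman"
    assert res[0].coefficient > 0.9


def test_bh_hand_computation():
    from statsmodels.stats.multitest import multipletests

    adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_bh_monotone_and_never_smaller(rng):
    p = rng.uniform(0, 1, 20)
    from statsmodels.stats.multitest import multipletests

    adj = multipletests(p, method="fdr_bh")[1]
    assert (adj >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_zero_variance_covariate_skipped(rng):
    y = rng.standard_normal(30)
    with pytest.warns(UserWarning, match="zero-variance"):
        res = gs.simple_associations(
            y, pd.DataFrame({"flat": np.ones(30), "x": rng.standard_normal(30)})
        )
    assert [r.predictor for r in res] == ["x"]


def test_multivariate_recovers_planted_coefficients(rng):
    n, p = 200, 4
    q, _ = np.linalg.qr(rng.standard_normal((n, p)))
    beta = np.array([1.0, -2.0, 0.5, 3.0])
    y = q @ beta
    model = gs.multivariate_regression(y, pd.DataFrame(q, columns=list("abcd")))
    np.testing.assert_allclose(model.params.iloc[1:].to_numpy(), beta, atol=1e-6)
    assert model.rsquared > 1 - 1e-10


def test_multivariate_duplicated_column_errors(rng):
    x = rng.standard_normal(50)
    df = pd.DataFrame({"a": x, "b": x})
    with pytest.raises(ValueError, match="aliased"):
        gs.multivariate_regression(rng.standard_normal(50), df)


# ---------------------------------------------------------------- ANOVA / Tukey


def test_anova_identical_groups():
    values = np.tile(np.arange(6.0), 3)
    groups = np.repeat(["a", "b", "c"], 6)
    res = gs.anova_tukey(values, groups)
    assert res.f == pytest.approx(0.0, abs=1e-12)
    assert (res.tukey["p_adj"].astype(float) > 0.9).all()


def test_two_group_tukey_matches_permutation_oracle(rng):
    a = rng.normal(0.0, 1.0, 8)
    b = rng.normal(1.0, 1.0, 10)
    values = np.concatenate([a, b])
    groups = np.array(["a"] * 8 + ["b"] * 10)
    res = gs.anova_tukey(values, groups)
    p_tukey = float(res.tukey["p_adj"].iloc[0])
    # permutation distribution of |mean difference|
    rng2 = np.random.default_rng(1)
    observed = abs(a.mean() - b.mean())
    count = 0
    n_perm = 4000
    for _ in range(n_perm):
        perm = rng2.permutation(values)
        count += abs(perm[:8].mean() - perm[8:].mean()) >= observed - 1e-12
    p_perm = count / n_perm
    assert abs(p_tukey - p_perm) < 0.02


def test_planted_shift_power_and_phenotype_equivalence():
    """Patients shifted +1.5 SD separate from the normative cohort but not
    from each other in most replicates."""
    rng = np.random.default_rng(2)
    hits_norm, hits_pheno = 0, 0
    n_rep = 25
    for _ in range(n_rep):
        z_norm = rng.standard_normal(150)
        z_dad = rng.standard_normal(10) + 1.5
        z_ad = rng.standard_normal(8) + 1.5
        values = np.concatenate([z_norm, z_dad, z_ad])
        groups = np.array(["norm"] * 150 + ["dAD"] * 10 + ["AD"] * 8)
        res = gs.anova_tukey(values, groups)
        tk = res.tukey.set_index(["group1", "group2"])["p_adj"].astype(float)
        def p_of(a, b):
            return tk.get((a, b), tk.get((b, a)))
        if p_of("dAD", "norm") < 0.05 and p_of("AD", "norm") < 0.05:
            hits_norm += 1
        if p_of("AD", "dAD") > 0.05:
            hits_pheno += 1
    assert hits_norm >= 0.8 * n_rep
    assert hits_pheno >= 0.8 * n_rep


def test_singleton_group_excluded_with_warning(rng):
    values = np.concatenate([rng.standard_normal(5), rng.standard_normal(5), [1.0]])
    groups = np.array(["a"] * 5 + ["b"] * 5 + ["c"])
    with pytest.raises(ValueError):
        gs.anova_tukey(values, groups)


# ---------------------------------------------------------------- Cohen's D


def test_cohens_d_hand_value():
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([2.0, 3.0, 4.0])
    out = gs.pairwise_cohens_d(a, b)
    assert out["d"] == pytest.approx(-1.0)
    assert out["ci"][0] < -1.0 < out["ci"][1]


def test_cohens_d_zero_and_scale_invariance(rng):
    a = rng.standard_normal(20)
    out = gs.pairwise_cohens_d(a, a.copy())
    assert out["d"] == pytest.approx(0.0, abs=1e-12)
    b = rng.standard_normal(25) + 1
    d1 = gs.pairwise_cohens_d(a, b)["d"]
    d2 = gs.pairwise_cohens_d(10 * a, 10 * b)["d"]
    assert d1 == pytest.approx(d2)


def test_cohens_d_magnitude_labels(rng):
    a = rng.standard_normal(400)
    b = rng.standard_normal(400) + 1.0
    out = gs.pairwise_cohens_d(a, b)
    assert out["magnitude"] == "large"


def test_cohens_d_zero_pooled_sd_errors():
    with pytest.raises(ValueError, match="pooled"):
        gs.pairwise_cohens_d(np.ones(5), np.ones(5))


# ---------------------------------------------------------------- ROC / AUC


def test_auc_perfect_separation():
    scores = np.array([1, 2, 3, 10, 11, 12], dtype=float)
    labels = np.array([0, 0, 0, 1, 1, 1])
    assert gs.roc_auc(scores, labels)["auc"] == pytest.approx(1.0)


def test_auc_small_set_brute_force():
    scores = np.array([3.0, 4.0, 1.0, 2.0, 3.0])
    labels = np.array([1, 1, 0, 0, 0])
    out = gs.roc_auc(scores, labels)
    # exhaustive pair enumeration
    cases, controls = scores[labels == 1], scores[labels == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    assert out["auc"] == pytest.approx(wins / 6.0) == pytest.approx(5.5 / 6.0)


def test_auc_null_and_symmetry(rng):
    scores = rng.standard_normal(200)
    labels = rng.integers(0, 2, 200)
    while labels.sum() in (0, 200):
        labels = rng.integers(0, 2, 200)
    out = gs.roc_auc(scores, labels)
    m, n = labels.sum(), 200 - labels.sum()
    se = np.sqrt((m + n + 1) / (12 * m * n))
    assert abs(out["auc"] - 0.5) < 3 * se
    flipped = gs.roc_auc(-scores, labels)
    assert out["auc"] == pytest.approx(1.0 - flipped["auc"])


def test_auc_matches_sklearn(rng):
    sklearn = pytest.importorskip("sklearn.metrics")
    scores = rng.standard_normal(120)
    labels = (rng.random(120) < 0.4).astype(int)
    ours = gs.roc_auc(scores, labels)["auc"]
    theirs = sklearn.roc_auc_score(labels, scores)
    assert ours == pytest.approx(theirs, abs=1e-12)


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        gs.roc_auc(np.arange(5.0), np.ones(5, dtype=int))


def test_delong_ci_contains_point(rng):
    scores = np.concatenate([rng.standard_normal(40), rng.standard_normal(40) + 1])
    labels = np.array([0] * 40 + [1] * 40)
    out = gs.roc_auc(scores, labels)
    assert out["ci"][0] <= out["auc"] <= out["ci"][1]
    boot = gs.roc_auc(scores, labels, ci_method="bootstrap", n_boot=500)
    assert abs(boot["ci"][0] - out["ci"][0]) < 0.1


# ---------------------------------------------------------------- counts, A/T


def test_threshold_counts_from_published_table():
    ztable = load_patient_zscore_table()
    rules = [
        gs.ThresholdRule("nfq", "above", 0.90),
        gs.ThresholdRule("inferior_parietal", "at_or_below", 0.02),
        gs.ThresholdRule("right_hippocampus", "at_or_below", 0.10),
    ]
    counts = gs.centile_threshold_counts(
        ztable[ztable["group"].isin(["dAD", "AD"])], rules
    ).set_index(["biomarker", "group"])["count"]
    assert counts[("nfq", "dAD")] == 7
    assert counts[("nfq", "AD")] == 5
    assert counts[("inferior_parietal", "dAD")] == 8
    assert counts[("right_hippocampus", "AD")] == 6


def test_threshold_counts_empty_rules_and_unknown_biomarker():
    ztable = load_patient_zscore_table()
    assert gs.centile_threshold_counts(ztable, []).empty
    with pytest.raises(KeyError):
        gs.centile_threshold_counts(ztable, [gs.ThresholdRule("nope", "above", 0.9)])


def test_at_classification_group_medians():
    for group, expect in (("dAD", (True, True)), ("AD", (True, True)), ("control", (False, False))):
        suvr = GROUP_MEDIAN_SUVR[group]
        assert gs.at_classify(suvr["amyloid"], suvr["tau"]) == expect


def test_at_classification_strict_boundary():
    assert gs.at_classify(1.42, 1.23) == (False, False)
    assert gs.at_classify(1.4201, 1.2301) == (True, True)


def test_chi2_sex_utility():
    out = gs.chi2_sex(np.array([[319, 405], [3, 7]]))
    assert 0 <= out["p"] <= 1 and out["dof"] == 1
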