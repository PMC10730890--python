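"""Consensus NMF subtyping, survival ordering and subtype characterization."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

import spatialsurv as ss
from spatialsurv.survival import SurvivalOutcome


def planted_blocks(n_groups=3, per_group=20, n_feats_per_group=3, noise=0.05,
                   seed=0):
    rng = np.random.default_rng(seed)
    n = n_groups * per_group
    groups = np.repeat(np.arange(n_groups), per_group)
    X = np.zeros((n, n_groups * n_feats_per_group))
    for g in range(n_groups):
        X[groups == g, g * n_feats_per_group:(g + 1) * n_feats_per_group] = 1.0
    X += rng.uniform(0, noise, X.shape)
    ids = [f"P{i}" for i in range(n)]
    return pd.DataFrame(X, index=ids), groups


def toy_outcome(time, event=None, ids=None):
    time = np.asarray(time, float)
    event = np.ones_like(time, int) if event is None else np.asarray(event, int)
    ids = ids or [f"P{i}" for i in range(len(time))]
    return SurvivalOutcome(list(ids), time, event)


# ---------------------------------------------------------------------------
# consensus clustering


def test_consensus_recovers_planted_blocks():
    X, groups = planted_blocks(seed=1)
    res = ss.nmf_consensus(X, K=3, n_runs=15, seed=0)
    assert adjusted_rand_score(groups, res.labels.to_numpy()) == 1.0
    # block structure: within-group consensus near 1, cross-group near 0
    c = res.consensus
    same = groups[:, None] == groups[None, :]
    assert c[same].mean() > 0.95
    assert c[~same].mean() < 0.05


def test_consensus_matrix_properties():
    X, _ = planted_blocks(seed=2, noise=0.3)
    res = ss.nmf_consensus(X, K=3, n_runs=8, seed=1)
    c = res.consensus
    np.testing.assert_allclose(c, c.T)
    np.testing.assert_allclose(np.diag(c), 1.0)
    assert ((0 <= c) & (c <= 1)).all()


def test_single_run_consensus_is_binary():
    X, _ = planted_blocks(seed=3)
    res = ss.nmf_consensus(X, K=3, n_runs=1, seed=0)
    assert set(np.unique(res.consensus)) <= {0.0, 1.0}


def test_duplicated_patients_cluster_together():
    X, _ = planted_blocks(seed=4)
    dup = pd.concat([X, X.iloc[[0]].rename(index={"P0": "P_dup"})])
    res = ss.nmf_consensus(dup, K=3, n_runs=10, seed=0)
    assert res.labels["P_dup"] == res.labels["P0"]


def test_consensus_input_validation():
    X, _ = planted_blocks()
    with pytest.raises(ValueError):
        ss.nmf_consensus(X, K=1)
    with pytest.raises(ValueError):
        ss.nmf_consensus(X, K=len(X) + 1)
    with pytest.raises(ValueError):
        ss.nmf_consensus(-X, K=3)


def test_consensus_invariant_to_patient_permutation():
    X, groups = planted_blocks(seed=5)
    res1 = ss.nmf_consensus(X, K=3, n_runs=10, seed=0)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(X))
    res2 = ss.nmf_consensus(X.iloc[perm], K=3, n_runs=10, seed=0)
    aligned = res2.labels.reindex(res1.labels.index)
    assert adjusted_rand_score(res1.labels, aligned) == 1.0


# ---------------------------------------------------------------------------
# rank selection


def test_rank_search_recovers_planted_k():
    X, _ = planted_blocks(n_groups=4, per_group=15, seed=6)
    quality, chosen = ss.rank_search(X, k_range=range(2, 8), n_runs=10, seed=0)
    assert chosen == 4
    assert len(quality) == 6
    assert set(quality.columns) >= {"K", "cophenetic", "silhouette"}


def test_crisp_consensus_has_cophenetic_one():
    from spatialsurv.subtyping import consensus_quality

    groups = np.repeat([1, 2], 10)
    consensus = (groups[:, None] == groups[None, :]).astype(float)
    coph, sil = consensus_quality(consensus, groups)
    assert coph == pytest.approx(1.0)
    assert sil == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# survival ordering, KM, log-rank


def test_order_by_survival_disjoint_groups():
    time = np.r_[np.full(10, 100.0), np.full(10, 10.0)]
    labels = pd.Series(np.r_[np.full(10, 7), np.full(10, 3)],
                       index=[f"P{i}" for i in range(20)], dtype=int)
    ordered = ss.order_by_survival(labels, toy_outcome(time))
    assert (ordered.iloc[:10] == 1).all()  # long-lived group becomes 1
    assert (ordered.iloc[10:] == 2).all()


def test_order_by_survival_label_id_invariance():
    rng = np.random.default_rng(0)
    time = rng.exponential(30, 30) + 1
    labels = pd.Series(rng.integers(1, 4, 30),
                       index=[f"P{i}" for i in range(30)])
    y = toy_outcome(time)
    ordered1 = ss.order_by_survival(labels, y)
    shuffled = labels.map({1: 9, 2: 4, 3: 6})
    ordered2 = ss.order_by_survival(shuffled, y)
    pd.testing.assert_series_equal(ordered1, ordered2)


def test_order_by_survival_three_cluster_hand_check():
    # medians by hand: group a ~ 50, b ~ 20, c ~ 80 -> order c, a, b
    time = np.r_[[50, 52, 48], [20, 22, 18], [80, 82, 78]].astype(float)
    labels = pd.Series([1, 1, 1, 2, 2, 2, 3, 3, 3],
                       index=[f"P{i}" for i in range(9)])
    ordered = ss.order_by_survival(labels, toy_outcome(time))
    assert list(ordered) == [2, 2, 2, 3, 3, 3, 1, 1, 1]


def test_km_starts_at_one_and_logrank_null():
    rng = np.random.default_rng(1)
    time = rng.exponential(30, 60) + 1
    labels = pd.Series(np.repeat([1, 2], 30), index=[f"P{i}" for i in range(60)])
    curves, stat, p = ss.km_and_logrank(labels, toy_outcome(time))
    for df in curves.values():
        assert df.iloc[0, 0] == pytest.approx(1.0)
    assert p > 0.01  # identical generating distributions


def test_logrank_two_group_hand_computation():
    # groups A={2, 4}, B={1, 3}, all events; observed-expected sums by hand:
    # t=1: risk A=2,B=2, event B -> E_A = 0.5
    # t=2: risk A=2,B=1, event A -> E_A = 2/3
    # t=3: risk A=1,B=1, event B -> E_A = 0.5
    # t=4: risk A=1,B=0, event A -> E_A = 1
    # O_A = 2, E_A = 0.5 + 2/3 + 0.5 + 1 = 8/3
    # V = sum of hypergeometric variances: 0.25 + 2/9 + 0.25 + 0 = 13/18
    # chi2 = (O-E)^2 / V = (2/3)^2 / (13/18) = 8/13
    labels = pd.Series([1, 2, 1, 2], index=["P0", "P1", "P2", "P3"])
    y = toy_outcome([2.0, 1.0, 4.0, 3.0], ids=["P0", "P1", "P2", "P3"])
    _, stat, p = ss.km_and_logrank(labels, y)
    assert stat == pytest.approx(8 / 13, abs=1e-9)


def test_logrank_single_group_rejected():
    labels = pd.Series([1, 1, 1], index=["P0", "P1", "P2"])
    with pytest.raises(ValueError):
        ss.km_and_logrank(labels, toy_outcome([1, 2, 3]))


def test_logrank_null_distribution_is_chi_square():
    # under the null, the 3-group statistic ~ chi2(2): check mean/median
    from scipy.stats import chi2

    rng = np.random.default_rng(2)
    stats = []
    for _ in range(120):
        time = rng.exponential(20, 45) + 0.5
        labels = pd.Series(rng.integers(1, 4, 45),
                           index=[f"P{i}" for i in range(45)])
        _, stat, _ = ss.km_and_logrank(labels, toy_outcome(time))
        stats.append(stat)
    assert np.mean(stats) == pytest.approx(2.0, abs=0.5)
    assert np.median(stats) == pytest.approx(chi2(2).median(), abs=0.5)


def test_stratification_cindex_oracle_and_extremes():
    time = np.array([80, 70, 60, 30, 20, 10], dtype=float)
    labels = pd.Series([1, 1, 2, 2, 3, 3], index=[f"P{i}" for i in range(6)])
    y = toy_outcome(time)
    assert ss.stratification_cindex(labels, y) == pytest.approx(
        (12 + 0.5 * 3) / 15
    )  # exhaustive pairs: 12 concordant, 3 within-label ties
    perfect = pd.Series([1, 2, 3, 4, 5, 6], index=[f"P{i}" for i in range(6)])
    assert ss.stratification_cindex(perfect, y) == 1.0


def test_stratification_cindex_shuffled_labels_near_half():
    rng = np.random.default_rng(3)
    time = rng.exponential(30, 200) + 1
    labels = pd.Series(rng.integers(1, 8, 200),
                       index=[f"P{i}" for i in range(200)])
    assert abs(ss.stratification_cindex(labels, toy_outcome(time)) - 0.5) < 0.06


# ---------------------------------------------------------------------------
# molecular subtypes and characterization


@pytest.mark.parametrize(
    "er,pr,her2,expected",
    [
        (0, 0, 0, "TNBC"),
        (0, 0, 1, "HER2-enriched"),
        (1, 1, 0, "Luminal A"),
        (1, 0, 0, "Luminal A"),
        (0, 1, 0, "Luminal A"),
        (1, 1, 1, "Luminal B"),
        (None, 1, 0, "Unknown"),
    ],
)
def test_molecular_subtype_definitions(er, pr, her2, expected):
    clin = pd.DataFrame([{"patient_id": "P0", "er": er, "pr": pr, "her2": her2}])
    assert ss.molecular_subtype(clin).iloc[0] == expected


def test_characterize_identical_distributions():
    rng = np.random.default_rng(4)
    ids = [f"P{i}" for i in range(60)]
    feats = pd.DataFrame(rng.uniform(0, 1, (60, 4)), index=ids,
                         columns=list("abcd"))
    labels = pd.Series(np.repeat([1, 2, 3], 20), index=ids)
    tab = ss.characterize_subtypes(feats, labels)
    assert (tab["p_adj"].dropna() > 0.2).all()
    assert (tab["p_adj"].dropna() >= tab["p"].dropna() - 1e-12).all()
    assert (tab["mark"] == "").all()


def test_characterize_planted_shift_detected():
    rng = np.random.default_rng(5)
    ids = [f"P{i}" for i in range(60)]
    labels = pd.Series(np.repeat([1, 2], 30), index=ids)
    feats = pd.DataFrame({"shifted": rng.normal(0, 1, 60),
                          "flat": rng.normal(0, 1, 60)}, index=ids)
    feats.loc[labels == 2, "shifted"] += 3.0
    tab = ss.characterize_subtypes(feats, labels)
    sig = tab[(tab.feature == "shifted")]
    assert (sig["p_adj"] < 0.01).all()
    assert (sig["mark"] == "*").all()


def test_characterize_constant_feature_skipped():
    ids = [f"P{i}" for i in range(10)]
    feats = pd.DataFrame({"const": np.ones(10)}, index=ids)
    labels = pd.Series(np.repeat([1, 2], 5), index=ids)
    tab = ss.characterize_subtypes(feats, labels)
    assert (tab["note"] == "constant feature").all()
    assert tab["p"].isna().all()


# ---------------------------------------------------------------------------
# correlation networks and dichotomization


def test_correlation_monotone_transform_invariance():
    rng = np.random.default_rng(6)
    ids = [f"P{i}" for i in range(20)]
    base = rng.normal(size=20)
    feats = pd.DataFrame({"x": base, "y": base + rng.normal(0, 0.2, 20)},
                         index=ids)
    labels = pd.Series(1, index=ids)
    net1 = ss.correlation_network(feats, labels, threshold=0.5)
    feats2 = feats.copy()
    feats2["x"] = np.exp(feats2["x"])  # strictly monotone
    net2 = ss.correlation_network(feats2, labels, threshold=0.5)
    assert net1["rho"].tolist() == net2["rho"].tolist()


def test_correlation_matches_hand_rank_computation():
    ids = [f"P{i}" for i in range(5)]
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
    feats = pd.DataFrame({"x": x, "y": y}, index=ids)
    labels = pd.Series(1, index=ids)
    net = ss.correlation_network(feats, labels, threshold=0.0)
    rx, ry = rankdata(x), rankdata(y)
    rho_hand = np.corrcoef(rx, ry)[0, 1]
    assert net.iloc[0]["rho"] == pytest.approx(rho_hand)


def test_correlation_small_subtype_skipped():
    ids = [f"P{i}" for i in range(5)]
    feats = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)),
                         index=ids, columns=["x", "y"])
    labels = pd.Series([1, 1, 1, 2, 2], index=ids)
    with pytest.warns(UserWarning, match="fewer than 3"):
        net = ss.correlation_network(feats, labels, threshold=-1.1)
    assert set(net["subtype"]) <= {1}


def test_dichotomize_crosstab_and_planted_hazard():
    rng = np.random.default_rng(7)
    n = 240
    ids = [f"P{i}" for i in range(n)]
    labels = pd.Series(rng.integers(1, 8, n), index=ids)
    clin = pd.DataFrame({
        "patient_id": ids,
        "er": np.ones(n, int), "pr": np.ones(n, int),
        "her2": np.zeros(n, int), "grade": 2,
    })  # everyone Luminal A
    bad = labels.isin([5, 6, 7]).to_numpy()
    lp = np.where(bad, 1.5, 0.0)
    death = rng.exponential(1.0 / (0.02 * np.exp(lp)))
    censor = rng.uniform(0, 150, n)
    y = toy_outcome(np.maximum(np.minimum(death, censor), 1e-6),
                    (death <= censor).astype(int), ids)
    results, crosstab = ss.dichotomize_and_compare(labels, clin, y)
    luma = results[results.molecular_subtype == "Luminal A"].iloc[0]
    assert luma["computable"] and luma["p"] < 0.05
    # contingency column sums equal molecular class sizes
    assert crosstab["Luminal A"].sum() == n


def test_dichotomize_empty_arm_not_computable():
    ids = [f"P{i}" for i in range(20)]
    labels = pd.Series(np.full(20, 2), index=ids)  # only "good" arm occupied
    clin = pd.DataFrame({"patient_id": ids, "er": 0, "pr": 0, "her2": 0})
    y = toy_outcome(np.arange(1.0, 21.0), ids=ids)
    results, _ = ss.dichotomize_and_compare(labels, clin, y)
    assert not results.iloc[0]["computable"]
    assert np.isnan(results.iloc[0]["p"])
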