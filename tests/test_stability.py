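import numpy as np
import pytest
import scipy.sparse as sp
from scipy import stats

from divprop.stability import (
    CoefficientCollection,
    consistency_matrix,
    diversity_anova,
    diversity_groups,
    network_correlation,
    node_coefficients,
    permutation_cluster_correct,
    tfce_enhance,
)


def ring_adjacency(P):
    rows = list(range(P))
    cols = [(i + 1) % P for i in range(P)]
    adj = sp.csr_matrix((np.ones(P), (rows, cols)), shape=(P, P))
    return adj + adj.T


def test_identical_weights_give_all_ones():
    coll = CoefficientCollection(np.tile([1.0, 2.0, 3.0], (4, 1)), np.arange(4))
    C = consistency_matrix(coll)
    assert np.allclose(C, 1.0)


def test_sign_flipped_weights_anticorrelate():
    w = np.array([1.0, -2.0, 0.5, 3.0])
    C = consistency_matrix(CoefficientCollection(np.vstack([w, -w]), [0.1, 0.2]))
    assert C[0, 1] == pytest.approx(-1.0)


def test_consistency_matches_direct_correlation(rng):
    W = rng.normal(size=(3, 4))
    wd = np.array([0.3, 0.1, 0.2])
    C = consistency_matrix(CoefficientCollection(W, wd))
    order = np.argsort(wd)
    for a in range(3):
        for b in range(3):
            expected = stats.pearsonr(W[order[a]], W[order[b]])[0]
            assert C[a, b] == pytest.approx(expected)
    assert np.allclose(C, C.T)
    assert np.allclose(np.diag(C), 1.0)


def test_consistency_invariant_to_common_rescaling(rng):
    W = rng.normal(size=(5, 10))
    wd = rng.random(5)
    C1 = consistency_matrix(CoefficientCollection(W, wd))
    C2 = consistency_matrix(CoefficientCollection(W * 7.3, wd))
    assert np.allclose(C1, C2)


def test_zero_variance_weight_vector_reported_missing(rng):
    W = np.vstack([rng.normal(size=4), np.full(4, 2.0)])
    with pytest.warns(UserWarning, match="zero-variance"):
        C = consistency_matrix(CoefficientCollection(W, [0.1, 0.2]))
    assert np.isnan(C[1, 0]) and np.isnan(C[1, 1])


def test_node_means_over_incident_edges():
    # P=3, edges (0,1)=+1, (0,2)=-1, (1,2)=0
    w = np.array([1.0, -1.0, 0.0])
    vals = node_coefficients(w, 3, "all")
    assert vals[0] == pytest.approx(0.0)
    assert vals[1] == pytest.approx(0.5)
    assert vals[2] == pytest.approx(-0.5)
    pos, neg = node_coefficients(w, 3, "signed")
    assert pos[0] == pytest.approx(1.0) and neg[0] == pytest.approx(-1.0)
    assert np.isnan(neg[1])  # node 1 has no negative edge


def test_constant_edge_weights_give_constant_nodes():
    w = np.full(10, 0.7)  # P=5
    assert np.allclose(node_coefficients(w, 5, "all"), 0.7)


def test_edge_provenance_mismatch_rejected():
    with pytest.raises(ValueError, match="edges"):
        node_coefficients(np.ones(5), 4)


def test_null_anova_p_values_roughly_uniform(rng):
    frac = []
    for _ in range(20):
        vals = rng.normal(size=(50, 40))
        _, p = diversity_anova(vals, rng.random(50), 5)
        frac.append((p < 0.05).mean())
    assert 0.01 <= np.mean(frac) <= 0.12


def test_shifted_region_detected_with_tiny_p(rng):
    vals = rng.normal(size=(50, 10))
    wd = np.sort(rng.random(50))
    groups = diversity_groups(wd, 5)
    vals[groups == 4, 3] += 5.0  # five within-group SDs
    _, p = diversity_anova(vals, wd, 5)
    assert p[3] < 1e-4
    assert np.median(p[np.arange(10) != 3]) > 0.05


def test_two_group_anova_matches_t_squared(rng):
    vals = rng.normal(size=(20, 6))
    wd = np.arange(20.0)
    F, _ = diversity_anova(vals, wd, 2)
    groups = diversity_groups(wd, 2)
    for k in range(6):
        t = stats.ttest_ind(vals[groups == 0, k], vals[groups == 1, k])[0]
        assert F[k] == pytest.approx(t**2, rel=1e-9)


def test_degenerate_zero_variance_groups_handled():
    vals = np.array([[1.0], [1.0], [2.0], [2.0]])
    wd = np.array([0.1, 0.2, 0.8, 0.9])
    F, p = diversity_anova(vals, wd, 2)
    assert np.isinf(F[0]) and p[0] == 0.0


def test_tfce_zero_statistics_give_p_one(rng):
    vals = rng.normal(size=(20, 8)) * 0 + 5.0  # constant: F = 0 everywhere
    groups = diversity_groups(np.arange(20.0), 4)
    _, p = permutation_cluster_correct(vals, groups, ring_adjacency(8), n_perm=50, seed=0)
    assert np.all(p >= 1.0 - 1.0 / 51)


def test_tfce_detects_strong_isolated_effect(rng):
    P, D = 12, 40
    vals = rng.normal(size=(D, P))
    wd = np.sort(rng.random(D))
    groups = diversity_groups(wd, 5)
    vals[groups == 4, 0] += 6.0
    adj = ring_adjacency(P)
    _, p = permutation_cluster_correct(vals, groups, adj, n_perm=200, seed=0)
    assert p[0] <= 0.05


def test_tfce_empty_adjacency_falls_back_with_warning(rng):
    vals = rng.normal(size=(20, 5))
    groups = diversity_groups(np.arange(20.0), 4)
    with pytest.warns(UserWarning, match="max-statistic"):
        _, p = permutation_cluster_correct(vals, groups, None, n_perm=50, seed=0)
    assert np.all((p > 0) & (p <= 1))


def test_tfce_enhancement_monotone_transform_without_adjacency():
    s = np.array([0.5, 1.0, 2.0, 0.0])
    enh = tfce_enhance(s, None)
    assert enh[2] > enh[1] > enh[0] > enh[3] == 0.0


def test_network_correlation_recovers_planted_trend(rng):
    D, P = 252, 50
    wd = np.sort(rng.random(D))
    nets = [f"n{i % 5}" for i in range(P)]
    vals = rng.normal(0, 0.3, (D, P))
    vals[:, np.array(nets) == "n2"] += wd[:, None] * 2.0
    r = network_correlation(vals, wd, nets)
    assert r["n2"] > 0.8
    assert all(abs(r[k]) < 0.2 for k in r if k != "n2")


def test_network_correlation_null_is_small(rng):
    D, P = 252, 35
    vals = rng.normal(size=(D, P))
    r = network_correlation(vals, rng.random(D), [f"n{i % 7}" for i in range(P)])
    assert all(abs(v) < 0.15 for v in r.values())


def test_two_draw_correlation_degenerates_to_unit_magnitude(rng):
    vals = rng.normal(size=(2, 6))
    with pytest.warns(UserWarning, match="two draws"):
        r = network_correlation(vals, [0.1, 0.9], ["a"] * 3 + ["b"] * 3)
    assert all(abs(abs(v) - 1.0) < 1e-9 for v in r.values())
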