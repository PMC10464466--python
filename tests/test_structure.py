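"""Polychoric estimation, ICLUST refinement, EGA, weighted topological overlap."""

import numpy as np
import pandas as pd
import pytest

from sensescale.indices import LoadingMatrix
from sensescale.itembank import ResponseTable
from sensescale.structure import (
    ega,
    iclust_refine,
    polychoric,
    polychoric_pair,
    wto,
)
from sensescale.synth import BifactorSpec, default_thresholds, simulate_responses


def _discretize(z, cuts):
    return (z[:, None] > np.asarray(cuts)).sum(axis=1)


def _pair_table(x, y, k):
    tab = np.zeros((k, k))
    np.add.at(tab, (x, y), 1.0)
    return tab


def test_polychoric_null_pair():
    rng = np.random.default_rng(1)
    z = rng.standard_normal((5000, 2))
    cuts = [-1.0, 0.0, 1.0]
    tab = _pair_table(_discretize(z[:, 0], cuts), _discretize(z[:, 1], cuts), 4)
    assert abs(polychoric_pair(tab)) < 0.04


def test_polychoric_monte_carlo_oracle_rho_half():
    rng = np.random.default_rng(2)
    z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 10_000)
    cuts = [-1.0, 0.0, 1.0, 2.0]
    tab = _pair_table(_discretize(z[:, 0], cuts), _discretize(z[:, 1], cuts), 5)
    assert polychoric_pair(tab) == pytest.approx(0.5, abs=0.03)


def test_polychoric_perfect_monotone_pair():
    z = np.random.default_rng(3).standard_normal(4000)
    cuts = [-1.0, 0.0, 1.0]
    x = _discretize(z, cuts)
    tab = _pair_table(x, x, 4)
    assert polychoric_pair(tab) >= 0.99


def test_polychoric_matrix_symmetric_with_missing_policy():
    lam = LoadingMatrix(["a", "b", "c"], [0.6, 0.6, 0.6], [0, 0, 0], [None] * 3)
    spec = BifactorSpec(lam, default_thresholds(3))
    tab = simulate_responses(spec, 300, seed=4)
    df = tab.data.copy()
    df.loc[df.index[:290], "c"] = np.nan  # only 10 joint cases with c
    t2 = ResponseTable(df, tab.study_id, tab.n_categories)
    sim = polychoric(t2, min_pair_n=30)
    m = sim.to_numpy()
    assert np.allclose(m, m.T, equal_nan=True)
    assert np.isnan(m[0, 2]) and np.isnan(m[2, 1])
    assert not np.isnan(m[0, 1])


def _block_similarity(n_a=4, n_b=4, within=0.6, between=0.0, noise_items=0):
    p = n_a + n_b + noise_items
    R = np.full((p, p), between)
    R[:n_a, :n_a] = within
    R[n_a:n_a + n_b, n_a:n_a + n_b] = within
    if noise_items:
        R[-noise_items:, :] = 0.0
        R[:, -noise_items:] = 0.0
    np.fill_diagonal(R, 1.0)
    items = [f"i{j:02d}" for j in range(p)]
    idx = pd.Index(items)
    from sensescale.structure import SimilarityMatrix

    return SimilarityMatrix(pd.DataFrame(R, index=idx, columns=idx),
                            pd.DataFrame(500, index=idx, columns=idx))


def test_iclust_recovers_two_clean_clusters():
    sim = _block_similarity()
    retained, tree, removals = iclust_refine(sim)
    assert removals == []
    assert sorted(retained) == sim.items
    clusters = sorted(tuple(sorted(v)) for v in tree.clusters.values())
    assert clusters == [tuple(f"i{j:02d}" for j in range(4)),
                        tuple(f"i{j:02d}" for j in range(4, 8))]


def test_iclust_removes_planted_noise_item_first_round():
    sim = _block_similarity(noise_items=1)
    retained, tree, removals = iclust_refine(sim)
    assert any(r[0] == "i08" for r in removals)
    assert "i08" not in retained
    assert len(retained) == 8


def test_iclust_three_items_single_cluster_two_merges():
    R = np.array([[1, 0.5, 0.45], [0.5, 1, 0.55], [0.45, 0.55, 1]])
    idx = pd.Index(["a", "b", "c"])
    from sensescale.structure import SimilarityMatrix

    sim = SimilarityMatrix(pd.DataFrame(R, index=idx, columns=idx),
                           pd.DataFrame(100, index=idx, columns=idx))
    retained, tree, removals = iclust_refine(sim)
    assert retained == ["a", "b", "c"]
    assert len(tree.merges) == 2
    assert len(tree.clusters) == 1


def test_iclust_deterministic_and_reconstructible():
    sim = _block_similarity(noise_items=1)
    r1 = iclust_refine(sim)
    r2 = iclust_refine(sim)
    assert r1[0] == r2[0] and r1[2] == r2[2]
    assert sorted(r1[0] + [x[0] for x in r1[2]]) == sim.items


def test_iclust_requires_three_items():
    sim = _block_similarity(n_a=1, n_b=1)
    with pytest.raises(ValueError, match="3 items"):
        iclust_refine(sim)


# ---------------------------------------------------------------------------
# EGA


def test_ega_recovers_planted_subscales():
    """Strong specific loadings, n >= 1000: communities = generating subscales."""
    from sklearn.metrics import adjusted_rand_score

    lam = LoadingMatrix(
        [f"i{j}" for j in range(9)],
        [0.45] * 9,
        [0.6, 0.65, 0.55, 0.6, 0.65, 0.55, 0.6, 0.65, 0.55],
        ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
    )
    spec = BifactorSpec(lam, default_thresholds(9))
    data = simulate_responses(spec, 1500, seed=6)
    sol = ega(data)
    truth = list(lam.subscale)
    pred = [sol.membership[i] for i in lam.item_ids]
    assert adjusted_rand_score(truth, pred) >= 0.9


def test_ega_single_factor_gives_one_community():
    lam = LoadingMatrix([f"i{j}" for j in range(6)], [0.7] * 6, [0.0] * 6,
                        [None] * 6)
    spec = BifactorSpec(lam, default_thresholds(6))
    sol = ega(simulate_responses(spec, 1500, seed=7))
    assert sol.n_communities == 1


def test_ega_two_orthogonal_doublets():
    lam = LoadingMatrix(["a1", "a2", "b1", "b2"], [0.0] * 4,
                        [0.75, 0.75, 0.75, 0.75], ["A", "A", "B", "B"])
    spec = BifactorSpec(lam, default_thresholds(4))
    sol = ega(simulate_responses(spec, 1500, seed=8))
    assert sol.n_communities == 2
    assert sol.membership["a1"] == sol.membership["a2"]
    assert sol.membership["b1"] == sol.membership["b2"]


def test_ega_community_count_invariant_to_relabeling():
    lam = LoadingMatrix(["a1", "a2", "b1", "b2"], [0.0] * 4,
                        [0.75, 0.75, 0.75, 0.75], ["A", "A", "B", "B"])
    spec = BifactorSpec(lam, default_thresholds(4))
    data = simulate_responses(spec, 1200, seed=9)
    sol1 = ega(data)
    renamed = ResponseTable(
        data.data.rename(columns={"a1": "z9", "b2": "a0"}),
        data.study_id,
        {{"a1": "z9", "b2": "a0"}.get(k, k): v for k, v in data.n_categories.items()})
    sol2 = ega(renamed)
    assert sol1.n_communities == sol2.n_communities


# ---------------------------------------------------------------------------
# wTO


def test_wto_maximal_and_null_cases():
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 1.0
    assert wto(w, 0, 1) == pytest.approx(1.0)
    # disjoint neighborhoods, no direct edge
    w2 = np.zeros((4, 4))
    w2[0, 2] = w2[2, 0] = 0.8
    w2[1, 3] = w2[3, 1] = 0.8
    assert wto(w2, 0, 1) == 0.0


def test_wto_matches_brute_force_double_loop():
    rng = np.random.default_rng(11)
    W = rng.uniform(-1, 1, (6, 6))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    for i in range(6):
        for j in range(6):
            if i == j:
                continue
            num = sum(abs(W[i, u]) * abs(W[j, u]) for u in range(6)
                      if u not in (i, j)) + abs(W[i, j])
            ki = sum(abs(W[i, u]) for u in range(6) if u != i)
            kj = sum(abs(W[j, u]) for u in range(6) if u != j)
            expected = num / (min(ki, kj) + 1 - abs(W[i, j]))
            assert wto(W, i, j) == pytest.approx(expected, abs=1e-12)


def test_wto_rejects_identical_nodes():
    with pytest.raises(ValueError):
        wto(np.eye(3), 1, 1)
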