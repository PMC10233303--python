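"""Network primitives and module machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from resilnet.network import (
    NetworkParams,
    bicor,
    bicor_matrix,
    consensus_tom,
    detect_modules,
    eigenprotein,
    kme,
    merge_modules,
    preservation_zsummary,
    reassign_proteins,
    signed_adjacency,
    tom_similarity,
)


# --- bicor --------------------------------------------------------------------


def test_bicor_self_and_antisymmetry(rng):
    x = rng.normal(size=200)
    assert bicor(x, x) == pytest.approx(1.0)
    assert bicor(x, -x) == pytest.approx(-1.0)


def test_bicor_close_to_pearson_on_gaussian(rng):
    n = 2000
    x = rng.normal(size=n)
    y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
    assert abs(bicor(x, y) - np.corrcoef(x, y)[0, 1]) < 0.05


def test_bicor_requires_four_pairs():
    assert np.isnan(bicor([1, 2, 3], [3, 2, 1]))


def test_bicor_mad_zero_pearson_fallback(rng):
    # median-heavy vector: MAD = 0, Pearson centering takes over
    x = np.array([1.0] * 10 + [5.0, -5.0])
    y = rng.normal(size=12)
    assert np.isfinite(bicor(x, y))


def test_bicor_matrix_agrees_with_scalar(rng):
    X = rng.normal(size=(8, 60))
    M = bicor_matrix(X)
    for i in range(8):
        for j in range(8):
            assert M[i, j] == pytest.approx(bicor(X[i], X[j]), abs=1e-10)


def test_bicor_is_outlier_resistant(rng):
    x = rng.normal(size=300)
    y = 0.8 * x + 0.3 * rng.normal(size=300)
    x2, y2 = x.copy(), y.copy()
    x2[:3], y2[:3] = 40.0, -40.0  # gross outliers
    assert abs(bicor(x2, y2) - bicor(x, y)) < 0.05
    assert abs(np.corrcoef(x2, y2)[0, 1] - np.corrcoef(x, y)[0, 1]) > 0.2


# --- adjacency / TOM ------------------------------------------------------------


@pytest.mark.parametrize("c,expected", [(1.0, 1.0), (-1.0, 0.0),
                                        (0.0, 0.5**7)])
def test_signed_adjacency_closed_form(c, expected):
    C = np.array([[1.0, c], [c, 1.0]])
    a = signed_adjacency(C, 7.0)
    assert a[0, 1] == pytest.approx(expected)
    assert a[0, 0] == 1.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_signed_adjacency_symmetric_unit_interval(seed):
    rng = np.random.default_rng(seed)
    C = rng.uniform(-1, 1, (6, 6))
    C = (C + C.T) / 2
    np.fill_diagonal(C, 1.0)
    A = signed_adjacency(C, 7.0)
    assert np.allclose(A, A.T)
    assert A.min() >= 0.0 and A.max() <= 1.0


def _tom_bruteforce(A, denominator):
    n = A.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            ki = sum(A[i, u] for u in range(n) if u != i)
            kj = sum(A[j, u] for u in range(n) if u != j)
            f = (ki + kj) / 2 if denominator == "mean" else min(ki, kj)
            out[i, j] = (shared + A[i, j]) / (f + 1 - A[i, j])
    return out


def test_tom_hand_example():
    A = np.array([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1]])
    T = tom_similarity(A, "mean")
    assert T[0, 1] == pytest.approx(0.5)


def test_tom_isolated_node_and_all_ones():
    A = np.eye(4)
    T = tom_similarity(A)
    assert np.allclose(T - np.eye(4), 0.0)
    T1 = tom_similarity(np.ones((4, 4)))
    assert np.allclose(T1, 1.0)


@pytest.mark.parametrize("denominator", ["mean", "min"])
def test_tom_matches_bruteforce(denominator, rng):
    for _ in range(20):
        A = rng.uniform(0, 1, (10, 10))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        assert np.allclose(
            tom_similarity(A, denominator), _tom_bruteforce(A, denominator),
            atol=1e-12,
        )


# --- consensus -------------------------------------------------------------------


def test_consensus_identical_and_minimum(rng):
    T = rng.uniform(0, 1, (5, 5))
    T = (T + T.T) / 2
    np.fill_diagonal(T, 1.0)
    assert np.allclose(consensus_tom([T, T.copy()]), T)
    T2 = T.copy()
    T2[0, 1] = T2[1, 0] = 0.8
    T[0, 1] = T[1, 0] = 0.2
    cons = consensus_tom([T, T2], quantile=0.0, scale=False)
    assert cons[0, 1] == pytest.approx(0.2)


def test_consensus_scaling_aligns_proportional_toms(rng):
    T = rng.uniform(0, 0.4, (20, 20))
    T = (T + T.T) / 2
    np.fill_diagonal(T, 1.0)
    T2 = np.clip(2.0 * T, 0, 1)
    np.fill_diagonal(T2, 1.0)
    cons = consensus_tom([T, T2], scale=True)
    off = ~np.eye(20, dtype=bool)
    assert np.allclose(cons[off], T[off], atol=1e-6)


def test_consensus_shape_mismatch():
    with pytest.raises(ValueError):
        consensus_tom([np.eye(3), np.eye(4)])


# --- module detection -------------------------------------------------------------


def _planted_tom(rng, sizes, n_total, loading=0.9, noise=0.2, n_samples=100):
    X = rng.standard_normal((n_total, n_samples))
    truth = np.zeros(n_total, dtype=int)
    pos = 0
    for m, s in enumerate(sizes, start=1):
        lat = rng.standard_normal(n_samples)
        X[pos : pos + s] = loading * lat + noise * rng.standard_normal((s, n_samples))
        truth[pos : pos + s] = m
        pos += s
    T = tom_similarity(signed_adjacency(bicor_matrix(X), 7.0))
    return T, truth


def test_detect_recovers_planted_blocks(rng):
    T, truth = _planted_tom(rng, [100, 100, 100], 500)
    labels = detect_modules(T, NetworkParams())
    assert adjusted_rand_score(truth, labels) >= 0.9
    assert len(set(labels) - {0}) == 3


def test_detect_rejects_pure_noise():
    fracs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((500, 100))
        T = tom_similarity(signed_adjacency(bicor_matrix(X), 7.0))
        labels = detect_modules(T, NetworkParams())
        fracs.append(np.mean(labels == 0))
    assert np.mean(fracs) >= 0.95


def test_detect_respects_min_module_size(rng):
    T, truth = _planted_tom(rng, [20], 220)
    labels = detect_modules(T, NetworkParams(min_module_size=30))
    # the 20-member block must not be emitted as its own module
    block = labels[truth == 1]
    mods, counts = np.unique(block[block != 0], return_counts=True)
    for m, c in zip(mods, counts):
        assert np.sum(labels == m) != c or c < 20


def test_detect_label_order_invariance(rng):
    T, truth = _planted_tom(rng, [80, 60], 300)
    labels = detect_modules(T, NetworkParams())
    perm = rng.permutation(300)
    labels_p = detect_modules(T[np.ix_(perm, perm)], NetworkParams())
    assert adjusted_rand_score(labels, labels_p[np.argsort(perm)]) == pytest.approx(1.0)


def test_detect_too_few_proteins():
    assert (detect_modules(np.eye(10), NetworkParams(min_module_size=30)) == 0).all()


# --- eigenproteins / kME -----------------------------------------------------------


def test_eigenprotein_of_identical_rows(rng):
    row = rng.normal(size=40)
    m = pd.DataFrame(np.tile(row, (5, 1)), columns=[f"s{i}" for i in range(40)])
    mes, ve = eigenprotein(m, np.ones(5, dtype=int))
    z = (row - row.mean()) / row.std(ddof=1)
    assert np.allclose(mes[1].to_numpy(), z, atol=1e-8)
    assert ve[1] == pytest.approx(1.0)


def test_eigenprotein_sign_invariance_and_orientation(rng):
    X = 0.9 * rng.normal(size=50) + 0.2 * rng.normal(size=(20, 50))
    m = pd.DataFrame(X)
    mes, _ = eigenprotein(m, np.ones(20, dtype=int))
    mes_flipped, _ = eigenprotein(-m, np.ones(20, dtype=int))
    assert np.allclose(mes[1], -mes_flipped[1], atol=1e-8)
    r = np.corrcoef(np.vstack([mes[1], X]))[0, 1:]
    assert r.mean() >= 0


def test_eigenprotein_variance_optimality(rng):
    X = rng.normal(size=(15, 60))
    m = pd.DataFrame(X)
    mes, _ = eigenprotein(m, np.ones(15, dtype=int))
    me = mes[1].to_numpy()
    z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)

    def explained(v):
        v = (v - v.mean()) / v.std(ddof=1)
        return np.mean([np.corrcoef(v, z[i])[0, 1] ** 2 for i in range(15)])

    best_single = max(explained(X[i]) for i in range(15))
    assert explained(me) >= best_single - 1e-9


def test_kme_identical_protein_and_null(rng):
    lat = rng.normal(size=200)
    X = np.vstack([lat, rng.normal(size=(30, 200))])
    m = pd.DataFrame(X)
    mes = pd.DataFrame({1: (lat - lat.mean()) / lat.std(ddof=1)})
    K = kme(m, mes)
    assert K.iloc[0, 0] == pytest.approx(1.0, abs=1e-10)
    assert (K.iloc[1:, 0].abs() < 0.2).mean() >= 0.9


def test_kme_hub_ordering(rng):
    lat = rng.normal(size=150)
    hub = 0.95 * lat + 0.1 * rng.normal(size=150)
    weak = 0.6 * lat + 0.5 * rng.normal(size=150)
    rest = 0.8 * lat + 0.3 * rng.normal(size=(10, 150))
    m = pd.DataFrame(np.vstack([hub, weak, rest]))
    labels = np.ones(12, dtype=int)
    mes, _ = eigenprotein(m, labels)
    K = kme(m, mes)
    assert K.iloc[0, 0] > K.iloc[1, 0]


# --- merge / reassign --------------------------------------------------------------


def test_merge_split_block_and_orthogonal(rng):
    lat1, lat2 = rng.normal(size=(2, 80))
    X = np.vstack([
        0.9 * lat1 + 0.15 * rng.normal(size=(40, 80)),
        0.9 * lat1 + 0.15 * rng.normal(size=(40, 80)),  # same latent, split labels
        0.9 * lat2 + 0.15 * rng.normal(size=(40, 80)),
    ])
    data = {"r1": pd.DataFrame(X)}
    labels = np.repeat([1, 2, 3], 40)
    merged, history = merge_modules(data, labels, cut_height=0.07)
    assert len(set(merged) - {0}) == 2
    assert history
    # orthogonal modules stay apart
    labels2 = np.repeat([1, 2], 60)
    X2 = np.vstack([
        0.9 * lat1 + 0.15 * rng.normal(size=(60, 80)),
        0.9 * lat2 + 0.15 * rng.normal(size=(60, 80)),
    ])
    merged2, h2 = merge_modules({"r1": pd.DataFrame(X2)}, labels2, 0.07)
    assert len(set(merged2) - {0}) == 2 and not h2
    # zero cut height never merges
    merged3, h3 = merge_modules(data, labels, cut_height=0.0)
    assert (merged3 == labels).all() and not h3


def test_reassign_moves_mislabelled_protein(rng):
    latA, latB = rng.normal(size=(2, 120))
    X = np.vstack([
        0.9 * latA + 0.2 * rng.normal(size=(30, 120)),
        0.9 * latB + 0.2 * rng.normal(size=(30, 120)),
    ])
    labels = np.repeat([1, 2], 30)
    labels[0] = 2  # protein driven by A mislabelled as B
    m = pd.DataFrame(X)
    mes, _ = eigenprotein(m, labels)
    K = kme(m, mes)
    out = reassign_proteins(labels, K, n_samples=120, threshold=0.05)
    assert out[0] == 1
    # already-optimal labels unchanged
    good = np.repeat([1, 2], 30)
    mes2, _ = eigenprotein(m, good)
    K2 = kme(m, mes2)
    assert (reassign_proteins(good, K2, 120, 0.05) == good).all()
    # threshold 1: no current p-value can exceed it
    assert (reassign_proteins(labels, K, 120, 1.0) == labels).all()


# --- preservation -----------------------------------------------------------------


def test_preservation_deterministic(rng):
    X = rng.normal(size=(60, 40))
    idx = pd.Index([f"P{i}" for i in range(60)])
    df = pd.DataFrame(X, index=idx)
    labels = pd.Series(np.repeat([1, 2, 0], 20), index=idx)
    z1 = preservation_zsummary(df, df, labels, n_perms=50, seed=3)
    z2 = preservation_zsummary(df, df, labels, n_perms=50, seed=3)
    pd.testing.assert_frame_equal(z1, z2)


def test_preservation_small_module_is_nan(rng):
    X = rng.normal(size=(30, 40))
    idx = pd.Index([f"P{i}" for i in range(30)])
    df = pd.DataFrame(X, index=idx)
    labels = pd.Series([1, 1] + [0] * 28, index=idx)
    z = preservation_zsummary(df, df, labels, n_perms=20, seed=1)
    assert np.isnan(z.loc[1, "zsummary"])
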