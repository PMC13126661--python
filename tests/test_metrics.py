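"""Nodal graph metrics against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wmnet.builder import build_multiscale
from wmnet.metrics import (
    DegenerateStrengthsError,
    MetricError,
    clustering_coefficient,
    compute_metric_table,
    eigenvector_centrality,
    local_assortativity,
    participation_coefficient,
)
from conftest import random_graph

# ---------------------------------------------------------------- oracles


def cc_oracle(w):
    """Exhaustive triangle enumeration of the Onnela clustering coefficient."""
    n = w.shape[0]
    wmax = w.max()
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, h = nbrs[a], nbrs[b]
                total += (w[i, j] * w[i, h] * w[j, h] / wmax**3) ** (1 / 3)
        out[i] = 2.0 * total / (k * (k - 1))
    return out


def ec_oracle(w):
    """Dense symmetric eigendecomposition; nonnegative dominant eigenvector."""
    vals, vecs = np.linalg.eigh(w)
    v = vecs[:, np.argmax(vals)]
    if v.sum() < 0:
        v = -v
    return np.abs(v)


def global_assortativity_oracle(w):
    """Weighted Pearson correlation of endpoint strengths over stubs."""
    s = w.sum(axis=1)
    i, j = np.nonzero(w)
    wts = w[i, j]
    x, y = s[i], s[j]
    mx = np.average(x, weights=wts)
    my = np.average(y, weights=wts)
    cov = np.average((x - mx) * (y - my), weights=wts)
    vx = np.average((x - mx) ** 2, weights=wts)
    vy = np.average((y - my) ** 2, weights=wts)
    return cov / np.sqrt(vx * vy)


def la_oracle(w):
    """Direct per-node evaluation of the edge-decomposition formula."""
    s = w.sum(axis=1)
    w_tot = w.sum()
    mu = sum(w[i, j] * s[j] for i in range(len(w)) for j in range(len(w))) / w_tot
    sigma2 = (
        sum(w[i, j] * (s[j] - mu) ** 2 for i in range(len(w)) for j in range(len(w)))
        / w_tot
    )
    return np.array(
        [
            sum(w[i, j] * (s[i] - mu) * (s[j] - mu) for j in range(len(w)))
            / (sigma2 * w_tot)
            for i in range(len(w))
        ]
    )


def pc_oracle(w, partition):
    """Independent per-module summation."""
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        s = w[i].sum()
        if s == 0:
            continue
        out[i] = 1.0 - sum(
            (w[i, [k for k in range(n) if partition[k] == m]].sum() / s) ** 2
            for m in set(partition)
        )
    return out


# ------------------------------------------------------- analytic limits


class TestAnalyticLimits:
    def test_equal_triangle_cc_is_one(self):
        w = np.array([[0, 2.0, 2.0], [2.0, 0, 2.0], [2.0, 2.0, 0]])
        np.testing.assert_allclose(clustering_coefficient(w), 1.0)

    def test_path_cc_is_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 2.0
        np.testing.assert_allclose(clustering_coefficient(w), 0.0)

    def test_all_zero_matrix_cc_warns(self, caplog):
        with caplog.at_level("WARNING", logger="wmnet.metrics"):
            out = clustering_coefficient(np.zeros((4, 4)))
        assert (out == 0).all() and "all-zero" in caplog.text

    @pytest.mark.parametrize("n", [3, 6, 11])
    def test_complete_graph_ec_uniform(self, n):
        w = np.ones((n, n)) - np.eye(n)
        np.testing.assert_allclose(eigenvector_centrality(w), 1 / np.sqrt(n), rtol=1e-8)

    def test_star_centre_dominates(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        ec = eigenvector_centrality(w)
        assert (ec[0] > ec[1:]).all()

    def test_disconnected_graph_warns(self, caplog):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 2.0
        with caplog.at_level("WARNING", logger="wmnet.metrics"):
            eigenvector_centrality(w)
        assert "components" in caplog.text

    def test_equal_ring_la_degenerate(self):
        w = np.zeros((5, 5))
        for i in range(5):
            w[i, (i + 1) % 5] = w[(i + 1) % 5, i] = 1.0
        with pytest.raises(DegenerateStrengthsError):
            local_assortativity(w)

    def test_disjoint_dyads_all_positive(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 10.0
        la = local_assortativity(w)
        assert (la > 0).all()
        assert la.sum() == pytest.approx(1.0)  # perfectly assortative strengths

    def test_pc_within_module_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 3.0
        pc = participation_coefficient(w, [0, 0, 1, 1])
        assert pc[0] == 0.0

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_pc_equal_split_limit(self, m):
        # hub node 0 with one unit edge into each of m modules
        n = m + 1
        w = np.zeros((n, n))
        w[0, 1:] = w[1:, 0] = 1.0
        partition = [0] + list(range(m))
        pc = participation_coefficient(w, partition)
        assert pc[0] == pytest.approx(1 - 1 / m)

    def test_pc_partition_mismatch(self):
        with pytest.raises(MetricError, match="partition"):
            participation_coefficient(np.zeros((3, 3)), [0, 1])


# ------------------------------------------------------- oracle sweeps


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_all_metrics_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        w = random_graph(rng, n)
        part = rng.integers(0, 3, size=n).tolist()
        np.testing.assert_allclose(clustering_coefficient(w), cc_oracle(w), atol=1e-12)
        np.testing.assert_allclose(
            eigenvector_centrality(w), ec_oracle(w), atol=1e-8
        )
        np.testing.assert_allclose(local_assortativity(w), la_oracle(w), atol=1e-10)
        np.testing.assert_allclose(
            participation_coefficient(w, part), pc_oracle(w, part), atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(15))
    def test_la_sums_to_global_assortativity(self, seed):
        rng = np.random.default_rng(100 + seed)
        w = random_graph(rng, int(rng.integers(5, 13)))
        la = local_assortativity(w)
        assert la.sum() == pytest.approx(global_assortativity_oracle(w), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_networkx_crosscheck(self, seed):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(200 + seed)
        w = random_graph(rng, 10)
        g = nx.from_numpy_array(w)
        nx_cc = np.array([nx.clustering(g, weight="weight")[i] for i in range(10)])
        np.testing.assert_allclose(clustering_coefficient(w), nx_cc, atol=1e-10)
        nx_ec = nx.eigenvector_centrality_numpy(g, weight="weight")
        v = np.array([nx_ec[i] for i in range(10)])
        v = np.abs(v) / np.linalg.norm(v)
        np.testing.assert_allclose(eigenvector_centrality(w), v, atol=1e-6)


class TestInvariances:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), c=st.floats(0.01, 100.0))
    def test_scale_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        w = random_graph(rng, n)
        part = rng.integers(0, 2, size=n).tolist()
        np.testing.assert_allclose(
            clustering_coefficient(c * w), clustering_coefficient(w), atol=1e-10
        )
        np.testing.assert_allclose(
            eigenvector_centrality(c * w), eigenvector_centrality(w), atol=1e-8
        )
        np.testing.assert_allclose(
            local_assortativity(c * w), local_assortativity(w), atol=1e-9
        )
        np.testing.assert_allclose(
            participation_coefficient(c * w, part),
            participation_coefficient(w, part),
            atol=1e-10,
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = 9
        w = random_graph(rng, n)
        part = rng.integers(0, 3, size=n).tolist()
        perm = rng.permutation(n)
        wp = w[np.ix_(perm, perm)]
        for fn in (clustering_coefficient, eigenvector_centrality, local_assortativity):
            np.testing.assert_allclose(fn(wp), fn(w)[perm], atol=1e-8)
        np.testing.assert_allclose(
            participation_coefficient(wp, [part[p] for p in perm]),
            participation_coefficient(w, part)[perm],
            atol=1e-10,
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_ranges(self, seed):
        rng = np.random.default_rng(400 + seed)
        n = int(rng.integers(5, 13))
        w = random_graph(rng, n)
        m = 3
        part = (np.arange(n) % m).tolist()
        cc = clustering_coefficient(w)
        assert ((cc >= 0) & (cc <= 1 + 1e-12)).all()
        ec = eigenvector_centrality(w)
        assert (ec >= -1e-12).all()
        assert np.linalg.norm(ec) == pytest.approx(1.0)
        pc = participation_coefficient(w, part)
        assert ((pc >= -1e-12) & (pc <= 1 - 1 / m + 1e-12)).all()


class TestMetricTable:
    def test_cohort_table_shape_and_determinism(self, hierarchy_wb, small_cohort):
        cfg, (conns, cov, vols) = small_cohort
        fine = [build_multiscale(c, vols, hierarchy_wb)[0] for c in conns[:6]]
        t1 = compute_metric_table(fine, hierarchy_wb, "fine76")
        t2 = compute_metric_table(fine, hierarchy_wb, "fine76")
        assert len(t1.data) == 6 * 76 * 4
        assert t1.data.equals(t2.data)

    def test_scale_mismatch_raises(self, hierarchy_wb, small_cohort):
        cfg, (conns, cov, vols) = small_cohort
        fine = [build_multiscale(conns[0], vols, hierarchy_wb)[0]]
        with pytest.raises(MetricError, match="scale"):
            compute_metric_table(fine, hierarchy_wb, "coarse24")

    def test_systems_partition_bounds_coarse_pc(self, hierarchy_wb, small_cohort):
        cfg, (conns, cov, vols) = small_cohort
        coarse = [build_multiscale(c, vols, hierarchy_wb)[1] for c in conns[:4]]
        table = compute_metric_table(coarse, hierarchy_wb, "coarse24")
        pc = table.data[table.data.metric == "PC"]["value"]
        assert (pc <= 1 - 1 / 4 + 1e-12).all()  # 4 systems
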