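"""Network wiring: EPSP sampling, weight conversion, lattice and rewiring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dualnet.network import (NetworkConfig, SYNAPSE_CLASSES,
                             build_dual_network, build_ring_lattice,
                             epsp_to_weight, rewire, sample_epsp_amplitudes,
                             transmission_failure_prob)


def truncated_tail_prob(threshold, cfg):
    """P(X > threshold | X <= cap) for the capped log-normal, closed form."""
    dist = stats.lognorm(s=cfg.sigma, scale=np.exp(cfg.mu))
    return (dist.cdf(cfg.epsp_cap) - dist.cdf(threshold)) / dist.cdf(cfg.epsp_cap)


class TestEpspSampling:
    def test_rejects_nonpositive_n(self):
        cfg = NetworkConfig(N_E=100, N_I=20)
        with pytest.raises(ValueError):
            sample_epsp_amplitudes(0, cfg, np.random.default_rng(0))

    def test_cap_enforced_and_positive(self, rng):
        cfg = NetworkConfig(N_E=100, N_I=20)
        x = sample_epsp_amplitudes(50_000, cfg, rng)
        assert x.min() > 0
        assert x.max() <= cfg.epsp_cap

    def test_histogram_mode_near_configured_mode(self, rng):
        # sigma=1, mu-sigma^2=log 0.2 puts the density mode at 0.2 mV
        cfg = NetworkConfig(N_E=100, N_I=20)
        x = sample_epsp_amplitudes(400_000, cfg, rng)
        bins = np.geomspace(0.01, 15.0, 120)
        hist, edges = np.histogram(x, bins=bins, density=True)
        peak = np.sqrt(edges[np.argmax(hist)] * edges[np.argmax(hist) + 1])
        assert 0.1 < peak < 0.4

    def test_strong_tail_fraction_matches_cdf_oracle(self, rng):
        cfg = NetworkConfig(N_E=100, N_I=20)
        n = 1_000_000
        x = sample_epsp_amplitudes(n, cfg, rng)
        p = truncated_tail_prob(cfg.strong_threshold, cfg)
        observed = np.mean(x > cfg.strong_threshold)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 3 * se


class TestWeightAndFailure:
    @pytest.mark.parametrize("epsp,expected", [(1.0, 0.01), (0.0, 0.0),
                                               (9.0, 0.09)])
    def test_linear_conversion(self, epsp, expected):
        assert epsp_to_weight(epsp) == pytest.approx(expected)

    def test_conversion_factor_override(self):
        assert epsp_to_weight(1.0, calibration_factor=50.0) == pytest.approx(0.02)

    def test_negative_epsp_rejected(self):
        with pytest.raises(ValueError):
            epsp_to_weight(-1.0)

    @pytest.mark.parametrize("epsp,a,expected", [(0.1, 0.1, 0.5),
                                                 (0.9, 0.1, 0.1)])
    def test_failure_prob_values(self, epsp, a, expected):
        assert transmission_failure_prob(epsp, a) == pytest.approx(expected)

    def test_failure_prob_monotone_decreasing(self):
        e = np.geomspace(0.01, 1e6, 200)
        p = transmission_failure_prob(e, 0.1)
        assert np.all(np.diff(p) < 0)
        assert p[-1] < 1e-6

    def test_failure_prob_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            transmission_failure_prob(0.0, 0.1)
        with pytest.raises(ValueError):
            transmission_failure_prob(1.0, 0.0)


class TestRingLattice:
    def test_one_full_round(self):
        pre, post = build_ring_lattice(4, 4)
        assert set(zip(pre.tolist(), post.tolist())) == {(0, 1), (1, 2),
                                                         (2, 3), (3, 0)}

    def test_two_full_rounds_offsets(self):
        pre, post = build_ring_lattice(5, 10)
        out_deg = np.bincount(pre, minlength=5)
        assert np.all(out_deg == 2)
        offsets = {(p - q) % 5 for q, p in zip(pre.tolist(), post.tolist())}
        assert offsets == {1, 2}

    def test_partial_round_fills_from_node_zero(self):
        pre, post = build_ring_lattice(6, 8)
        extra = [(q, p) for q, p in zip(pre.tolist(), post.tolist())
                 if (p - q) % 6 == 2]
        assert sorted(q for q, _ in extra) == [0, 1]

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError):
            build_ring_lattice(4, 13)

    @given(n_nodes=st.integers(2, 40), frac=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_no_duplicates_or_self_loops(self, n_nodes, frac):
        n_edges = int(frac * n_nodes * (n_nodes - 1))
        pre, post = build_ring_lattice(n_nodes, n_edges)
        assert pre.size == n_edges
        assert np.all(pre != post)
        keys = pre.astype(np.int64) * n_nodes + post
        assert np.unique(keys).size == n_edges


def brute_force_triangles(pre, post, n):
    """Exhaustive per-node triangle count on the symmetrized graph."""
    adj = np.zeros((n, n), dtype=bool)
    adj[pre, post] = True
    adj |= adj.T
    np.fill_diagonal(adj, False)
    tri = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if not adj[i, j]:
                continue
            for k in range(j + 1, n):
                if adj[i, k] and adj[j, k]:
                    tri[i] += 1
    return tri


def symmetrized_cc(pre, post, n):
    adj = np.zeros((n, n), dtype=bool)
    adj[pre, post] = True
    adj |= adj.T
    np.fill_diagonal(adj, False)
    k = adj.sum(1)
    tri = brute_force_triangles(pre, post, n)
    with np.errstate(invalid="ignore"):
        local = np.where(k >= 2, 2 * tri / np.maximum(k * (k - 1), 1), 0.0)
    return local.mean()


class TestRewire:
    def test_beta_zero_is_identity(self, rng):
        pre, post = build_ring_lattice(50, 150)
        assert np.array_equal(rewire(pre, post, 0.0, 50, rng), post)

    def test_edge_count_and_sources_preserved(self, rng):
        pre, post = build_ring_lattice(100, 400)
        new_post = rewire(pre, post, 0.7, 100, rng)
        assert new_post.size == post.size
        assert np.all(new_post != pre)  # no self-loops
        keys = pre.astype(np.int64) * 100 + new_post
        assert np.unique(keys).size == keys.size  # no duplicate pairs

    def test_beta_one_targets_uniform(self, rng):
        # chi-square of rewired targets against uniform over nodes
        n = 200
        pre, post = build_ring_lattice(n, 20 * n)
        new_post = rewire(pre, post, 1.0, n, rng)
        counts = np.bincount(new_post, minlength=n)
        _, p = stats.chisquare(counts)
        assert p > 1e-4

    def test_clustering_decay_tracks_watts_strogatz_prediction(self, rng):
        # symmetrized CC(beta)/CC(0) ~ (1-beta)^3 for a fixed-degree lattice
        from dualnet.graph import adjacency_from_edges, clustering
        n = 2000
        pre, post = build_ring_lattice(n, 4 * n)
        cc0, _ = clustering(adjacency_from_edges(pre, post, n))
        for beta in (0.1, 0.3, 0.5, 0.7, 0.9):
            new_post = rewire(pre, post, beta, n, rng)
            cc, _ = clustering(adjacency_from_edges(pre, new_post, n))
            assert cc / cc0 == pytest.approx((1 - beta) ** 3, abs=0.05)


class TestBuildDualNetwork:
    def test_ee_count_and_partition(self, small_table, small_config):
        counts = small_table.class_counts()
        assert counts["strong_EE"] + counts["weak_EE"] == \
            small_config.ee_connection_count
        strong = small_table.syn_class == SYNAPSE_CLASSES["strong_EE"]
        weak = small_table.syn_class == SYNAPSE_CLASSES["weak_EE"]
        assert np.all(small_table.epsp[strong] > small_config.strong_threshold)
        assert np.all(small_table.epsp[weak] > 0)
        assert np.all(small_table.epsp[weak] <= small_config.strong_threshold)

    def test_weights_follow_conversion_and_failure_rule(self, small_table,
                                                        small_config):
        ee = small_table.class_mask("strong_EE", "weak_EE")
        np.testing.assert_allclose(
            small_table.weight[ee], small_table.epsp[ee] / 100.0, rtol=1e-6)
        np.testing.assert_allclose(
            small_table.p_fail[ee],
            transmission_failure_prob(small_table.epsp[ee].astype(float),
                                      small_config.failure_a), rtol=1e-6)
        assert np.all(small_table.p_fail[~ee] == 0)

    def test_fixed_weights_for_other_classes(self, small_table, small_config):
        for name, g in (("EI", small_config.G_EI), ("IE", small_config.G_IE),
                        ("II", small_config.G_II)):
            m = small_table.class_mask(name)
            assert np.all(small_table.weight[m] == np.float32(g))

    def test_populations_of_endpoints(self, small_table, small_config):
        n_e = small_config.N_E
        ee = small_table.class_mask("strong_EE", "weak_EE")
        assert np.all(small_table.pre[ee] < n_e)
        assert np.all(small_table.post[ee] < n_e)
        ei = small_table.class_mask("EI")
        assert np.all(small_table.pre[ei] < n_e)
        assert np.all(small_table.post[ei] >= n_e)
        ii = small_table.class_mask("II")
        assert np.all(small_table.pre[ii] >= n_e)
        assert np.all(small_table.pre[ii] != small_table.post[ii])

    def test_delays_on_grid_within_ranges(self, small_table, small_config):
        dt = small_config.dt
        ee = small_table.class_mask("strong_EE", "weak_EE")
        d_ee = small_table.delay_ms[ee]
        lo, hi = small_config.delay_ee_range
        assert d_ee.min() >= lo - dt / 2 and d_ee.max() <= hi + dt / 2
        d_o = small_table.delay_ms[~ee]
        lo, hi = small_config.delay_other_range
        assert d_o.min() >= 0 and d_o.max() <= hi + dt / 2
        # integral step counts by construction
        assert small_table.delay_steps.dtype == np.int16

    def test_determinism_byte_identical(self, small_config, small_table):
        other = build_dual_network(small_config)
        for f in ("pre", "post", "weight", "delay_steps", "p_fail",
                  "syn_class", "epsp"):
            assert getattr(small_table, f).tobytes() == \
                getattr(other, f).tobytes()

    def test_bernoulli_class_counts_within_4sd(self):
        cfg = NetworkConfig(N_E=400, N_I=80, beta=1.0, seed=3)
        counts = build_dual_network(cfg).class_counts()
        for name, n_pairs, p in (
                ("EI", cfg.N_E * cfg.N_I, cfg.p_EI),
                ("IE", cfg.N_I * cfg.N_E, cfg.p_IE),
                ("II", cfg.N_I * (cfg.N_I - 1), cfg.p_II)):
            mean = n_pairs * p
            sd = np.sqrt(n_pairs * p * (1 - p))
            assert abs(counts[name] - mean) < 4 * sd

    def test_strong_count_tracks_lognormal_tail(self):
        cfg = NetworkConfig(N_E=500, N_I=100, seed=11)
        table = build_dual_network(cfg)
        p = truncated_tail_prob(cfg.strong_threshold, cfg)
        n = cfg.ee_connection_count
        se = np.sqrt(n * p * (1 - p))
        assert abs(table.class_counts()["strong_EE"] - n * p) < 3 * se

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(N_E=100, N_I=20, beta=1.5)
        with pytest.raises(ValueError):
            NetworkConfig(N_E=10, N_I=2, ee_connection_count=95)
        with pytest.raises(ValueError):
            NetworkConfig(N_E=100, N_I=20, p_EI=-0.2)
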