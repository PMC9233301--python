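import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_panel
from hapshare import profiles


def frame(M, ids):
    return pd.DataFrame(np.asarray(M, dtype=float), index=ids, columns=ids)


class TestCopyingVectors:
    def test_single_cluster_normalises_to_one(self):
        ids = list("abcd")
        M = frame(np.ones((4, 4)) - np.eye(4), ids)
        assign = pd.Series("c0", index=ids)
        v = profiles.copying_vectors(M, assign)
        assert v.shape == (1, 1) and np.isclose(v.iloc[0, 0], 1.0)

    def test_block_construction_values(self):
        # two 2-member clusters; every member donates 8 within, 2 across
        ids = list("abcd")
        M = np.array(
            [[0, 8, 1, 1], [8, 0, 1, 1], [1, 1, 0, 8], [1, 1, 8, 0]], dtype=float
        )
        assign = pd.Series(["A", "A", "B", "B"], index=ids)
        v = profiles.copying_vectors(frame(M, ids), assign)
        assert np.allclose(v.loc["A"].values, [0.8, 0.2])
        assert np.allclose(v.loc["B"].values, [0.2, 0.8])

    def test_within_cluster_permutation_invariance(self):
        rng = np.random.default_rng(0)
        ids = [f"i{k}" for k in range(8)]
        M = rng.uniform(1, 5, (8, 8))
        np.fill_diagonal(M, 0)
        assign = pd.Series(["A"] * 4 + ["B"] * 4, index=ids)
        v1 = profiles.copying_vectors(frame(M, ids), assign)
        perm = [2, 0, 3, 1, 6, 7, 4, 5]  # permutes within clusters only
        ids2 = [ids[p] for p in perm]
        M2 = M[np.ix_(perm, perm)]
        v2 = profiles.copying_vectors(frame(M2, ids2), assign.loc[ids2])
        assert np.allclose(v1.values, v2.values)


class TestNnlsProfile:
    def _three_cluster_matrix(self, x_profile):
        """6 individuals in clusters A,B,T (2 each); T's received profile from
        (A, B) is x_profile; A and B have distinct source profiles."""
        ids = ["a1", "a2", "b1", "b2", "t1", "t2"]
        M = np.zeros((6, 6))
        M[0, 1] = M[1, 0] = 10.0  # A <- A
        M[0, 2:4] = M[1, 2:4] = 1.0  # A <- B
        M[2, 3] = M[3, 2] = 10.0  # B <- B
        M[2, 0:2] = M[3, 0:2] = 1.0  # B <- A
        M[4, 0:2] = M[5, 0:2] = x_profile[0] / 2
        M[4, 2:4] = M[5, 2:4] = x_profile[1] / 2
        M[4, 5] = M[5, 4] = 3.0
        return frame(M, ids), pd.Series(["A", "A", "B", "B", "T", "T"], index=ids)

    def test_exact_source_row_gives_unit_vector(self):
        # target receives exactly A's source profile (A<-A=20, A<-B=2)
        M, assign = self._three_cluster_matrix((20.0, 2.0))
        beta = profiles.nnls_profile(M, assign, "T")
        assert np.isclose(beta["A"], 1.0) and np.isclose(beta["B"], 0.0)

    def test_identity_system_returns_normalised_means(self):
        ids = ["a1", "a2", "b1", "b2", "t1", "t2"]
        M = np.zeros((6, 6))
        M[0, 1] = M[1, 0] = 5.0
        M[2, 3] = M[3, 2] = 5.0
        M[4, 0:2] = M[5, 0:2] = 1.5  # T <- A total 3
        M[4, 2:4] = M[5, 2:4] = 0.5  # T <- B total 1
        assign = pd.Series(["A", "A", "B", "B", "T", "T"], index=ids)
        beta = profiles.nnls_profile(frame(M, ids), assign, "T")
        assert np.allclose([beta["A"], beta["B"]], [0.75, 0.25])

    def test_degenerate_source_system_rejected(self):
        ids = list("abcd")
        M = frame(np.zeros((4, 4)), ids)
        assign = pd.Series(["A", "A", "T", "T"], index=ids)
        with pytest.raises(ValueError, match="degenerate"):
            profiles.nnls_profile(M, assign, "T")

    def test_needs_two_clusters(self):
        ids = list("ab")
        M = frame([[0, 1], [1, 0]], ids)
        with pytest.raises(ValueError, match=">= 2 clusters"):
            profiles.nnls_profile(M, pd.Series(["T", "T"], index=ids), "T")


class TestTvd:
    def test_worked_example(self):
        assert profiles.tvd((0.5, 0.5, 0.0), (0.25, 0.25, 0.5)) == 0.5

    def test_identical_and_disjoint(self):
        assert profiles.tvd((0.3, 0.7), (0.3, 0.7)) == 0.0
        assert profiles.tvd((1.0, 0.0), (0.0, 1.0)) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            profiles.tvd((0.5, 0.5), (1.0,))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
           st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
           st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3))
    def test_metric_properties_on_simplex(self, a, b, c):
        a, b, c = (np.array(v) / np.sum(v) for v in (a, b, c))
        assert profiles.tvd(a, b) == pytest.approx(profiles.tvd(b, a))
        assert profiles.tvd(a, a) == 0.0
        assert profiles.tvd(a, c) <= profiles.tvd(a, b) + profiles.tvd(b, c) + 1e-12
        assert 0.0 <= profiles.tvd(a, b) <= 1.0


class TestHudsonFst:
    def test_single_site_worked_example(self):
        # p1=0.3 (100 copies), p2=0.5 (200 copies): hand evaluation of the
        # unbiased single-site estimator
        num = (0.3 - 0.5) ** 2 - 0.3 * 0.7 / 99 - 0.5 * 0.5 / 199
        den = 0.3 * 0.5 + 0.5 * 0.7
        expected = num / den
        got = profiles.hudson_fst(([0.3], [100], [0.5], [200]), None, None)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.0732, abs=5e-4)

    def test_fixed_difference_is_exactly_one(self):
        assert profiles.hudson_fst(([1.0], [50], [0.0], [60]), None, None) == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        p = np.full(200, 0.4)
        n = np.full(200, 1000)
        assert abs(profiles.hudson_fst((p, n, p, n), None, None)) < 5e-3

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        p1, p2 = rng.uniform(0.1, 0.9, 50), rng.uniform(0.1, 0.9, 50)
        n1, n2 = np.full(50, 120), np.full(50, 80)
        f = profiles.hudson_fst((p1, n1, p2, n2), None, None)
        g = profiles.hudson_fst((1 - p1, n1, 1 - p2, n2), None, None)
        assert f == pytest.approx(g)

    def test_panel_interface_and_small_group_error(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, (8, 100)).astype(np.uint8)
        panel = make_panel(a)
        v = profiles.hudson_fst(panel, ["I0", "I1"], ["I2", "I3"])
        assert np.isfinite(v)
        with pytest.raises(ValueError):
            profiles.hudson_fst(([0.5], [1], [0.5], [10]), None, None)

    def test_drifted_pair_ranks_above_recent_pair(self):
        # three subpopulations, one with a much smaller size: the drifted
        # population should show larger FST and TVD to both others
        from hapshare import paint, simdata

        cfg = simdata.SimConfig(
            n_subpops=3,
            size_per_generation=(200, 200, 40),
            n_generations=15,
            chromosomes=((60.0, 800, 60_000_000),),
            sample_size=20,
            seed=4,
        )
        sim = simdata.simulate(cfg)
        fst = profiles.fst_matrix(sim.panel, sim.labels)
        assert fst.loc["pop0", "pop2"] > fst.loc["pop0", "pop1"]
        assert fst.loc["pop1", "pop2"] > fst.loc["pop0", "pop1"]
        co = paint.paint_panel(sim.panel, paint.PaintConfig(seed=4))
        vec = profiles.copying_vectors(co, sim.labels)
        tvd = profiles.tvd_matrix(vec)
        assert tvd.loc["pop0", "pop2"] > tvd.loc["pop0", "pop1"]
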