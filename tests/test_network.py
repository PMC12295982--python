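"""Network construction: normalization, local thresholding, Laplacians."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rinse import (
    ThresholdConfig,
    local_threshold,
    normalize_weights,
    normalized_laplacian,
)
from rinse.network import apply_sign_policy

from conftest import random_symmetric


def sym_weight_matrices(n_min=3, n_max=8):
    """Strategy: random symmetric nonnegative zero-diagonal matrices."""

    def build(n, seed):
        rng = np.random.default_rng(seed)
        return random_symmetric(rng, n, density=0.6)

    return st.builds(
        build,
        st.integers(n_min, n_max),
        st.integers(0, 2**31 - 1),
    )


class TestNormalize:
    def test_single_frame_arithmetic(self):
        stack = np.zeros((1, 3, 3))
        stack[0, 0, 1] = stack[0, 1, 0] = -2.5
        stack[0, 1, 2] = stack[0, 2, 1] = 5.0
        w, scale = normalize_weights(stack)
        assert scale == 5.0
        assert w[0, 0, 1] == 0.5

    def test_global_max_over_frames(self, rng):
        a = random_symmetric(rng, 5) * 2
        b = random_symmetric(rng, 5) * 8
        a /= np.abs(a).max() / 2  # frame maxima exactly 2 and 8
        b /= np.abs(b).max() / 8
        w, scale = normalize_weights(np.stack([a, b]))
        assert scale == pytest.approx(8.0)
        np.testing.assert_allclose(w[0], np.abs(a) / 8.0)

    def test_renormalization_is_identity(self, rng):
        stack = np.stack([random_symmetric(rng, 6)])
        w, _ = normalize_weights(stack)
        w2, scale2 = normalize_weights(w)
        assert scale2 == pytest.approx(1.0)
        np.testing.assert_allclose(w2, w)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="scale"):
            normalize_weights(np.zeros((2, 4, 4)))

    def test_sign_flip_invariance_under_magnitude(self, rng):
        stack = np.stack([random_symmetric(rng, 6)]) * np.where(
            np.arange(6) % 2, 1, -1
        )
        stack = 0.5 * (stack + stack.transpose(0, 2, 1))
        w1, _ = normalize_weights(stack)
        w2, _ = normalize_weights(-stack)
        np.testing.assert_array_equal(w1, w2)

    def test_negative_only_policy(self):
        e = np.array([[0.0, -2.0], [-2.0, 0.0]])
        assert apply_sign_policy(e, "negative-only")[0, 1] == 2.0
        assert apply_sign_policy(-e, "negative-only")[0, 1] == 0.0


def brute_force_threshold(w, q):
    """Literal per-endpoint-quantile union rule, edge by edge."""
    n = w.shape[0]
    thr = {}
    for i in range(n):
        inc = w[i][w[i] > 0]
        thr[i] = np.quantile(inc, q) if inc.size else np.inf
    out = np.zeros_like(w)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0 and (w[i, j] >= thr[i] or w[i, j] >= thr[j]):
                out[i, j] = w[i, j]
    return out


class TestLocalThreshold:
    def test_q0_keeps_everything(self, rng):
        w = random_symmetric(rng, 7)
        net = local_threshold(w, 0.0)
        np.testing.assert_array_equal(net.weights, w)
        assert net.retained_fraction == 1.0

    def test_q1_keeps_per_node_maxima(self, rng):
        w = random_symmetric(rng, 7)
        net = local_threshold(w, 1.0)
        np.testing.assert_allclose(net.weights, brute_force_threshold(w, 1.0))

    def test_triangle_oracle(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        w[1, 2] = w[2, 1] = 0.5
        w[0, 2] = w[2, 0] = 0.1
        np.testing.assert_allclose(
            local_threshold(w, 0.5).weights, brute_force_threshold(w, 0.5)
        )

    @given(sym_weight_matrices(), st.floats(0.0, 1.0))
    def test_matches_brute_force(self, w, q):
        np.testing.assert_allclose(
            local_threshold(w, q).weights, brute_force_threshold(w, q)
        )

    @given(sym_weight_matrices(), st.floats(0.0, 1.0))
    def test_never_creates_edges_and_stays_symmetric(self, w, q):
        out = local_threshold(w, q).weights
        np.testing.assert_array_equal(out, out.T)
        assert np.all((out == 0) | np.isclose(out, w))
        assert not np.any((out != 0) & (w == 0))

    @given(sym_weight_matrices(), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_in_q(self, w, q1, q2):
        lo, hi = sorted([q1, q2])
        kept_hi = local_threshold(w, hi).weights != 0
        kept_lo = local_threshold(w, lo).weights != 0
        assert np.all(~kept_hi | kept_lo)  # higher q keeps a subset

    def test_empty_graph(self):
        net = local_threshold(np.zeros((4, 4)), 0.5)
        assert net.retained_fraction == 0.0
        assert not net.weights.any()


class TestNormalizedLaplacian:
    def test_k2_closed_form(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        L = normalized_laplacian(w).L
        np.testing.assert_allclose(L, [[1.0, -1.0], [-1.0, 1.0]])
        np.testing.assert_allclose(np.linalg.eigvalsh(L), [0.0, 2.0], atol=1e-12)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_complete_graph_spectrum(self, n):
        w = np.ones((n, n)) - np.eye(n)
        lam = np.linalg.eigvalsh(normalized_laplacian(w).L)
        expected = np.r_[0.0, np.full(n - 1, n / (n - 1))]
        np.testing.assert_allclose(lam, expected, atol=1e-10)

    def test_empty_graph_is_zero(self):
        L = normalized_laplacian(np.zeros((5, 5))).L
        np.testing.assert_array_equal(L, np.zeros((5, 5)))

    def test_isolated_node_row_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        L = normalized_laplacian(w).L
        assert np.all(L[2] == 0) and np.all(L[:, 2] == 0)

    @given(sym_weight_matrices(3, 10))
    def test_eigenvalues_in_range(self, w):
        lam = np.linalg.eigvalsh(normalized_laplacian(w).L)
        assert lam.min() >= -1e-9 and lam.max() <= 2 + 1e-9

    def test_negative_weight_rejected(self):
        w = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="sign"):
            normalized_laplacian(w)


class TestThresholdConfig:
    @pytest.mark.parametrize("q", [-0.1, 1.1])
    def test_bad_quantile(self, q):
        with pytest.raises(ValueError):
            ThresholdConfig(q=q)

    def test_bad_policy(self):
        with pytest.raises(ValueError):
            ThresholdConfig(sign_policy="abs")
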