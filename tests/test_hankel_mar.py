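"""Hankel embedding, SVD decomposition and correlation-based removal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hankelppg as hp
from hankelppg.hankel_mar import (
    ComponentSelection,
    all_component_series,
    build_hankel,
    component_series,
    decompose,
    hankelize,
    pearson,
    reconstruct,
    select_components,
)


def brute_force_hankel(x):
    """Loop-based oracle: materialize the trajectory matrix element-wise."""
    n = len(x)
    L = (n + 1) // 2
    K = n - L + 1
    H = [[x[i + j] for j in range(K)] for i in range(L)]
    return np.array(H)


def brute_force_hankelize(mat):
    """Loop-based anti-diagonal averaging oracle."""
    L, K = mat.shape
    n = L + K - 1
    out = np.zeros(n)
    for k in range(n):
        vals = [mat[i, k - i] for i in range(L) if 0 <= k - i < K]
        out[k] = float(np.mean(vals))
    return out


class TestBuildHankel:
    def test_four_sample_layout(self):
        H = build_hankel([1, 2, 3, 4])
        assert H.tolist() == [[1, 2, 3], [2, 3, 4]]

    @pytest.mark.parametrize("n", [4, 5, 11, 100, 101])
    def test_shape_covers_all_samples(self, n, rng):
        x = rng.standard_normal(n)
        H = build_hankel(x)
        L, K = H.shape
        assert L + K - 1 == n
        assert L == (n + 1) // 2
        assert H[-1, -1] == x[-1]

    @given(st.integers(min_value=4, max_value=60), st.integers())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_hankel_property_and_roundtrip(self, n, seed):
        x = np.random.default_rng(abs(seed) % 2**31).standard_normal(n)
        H = build_hankel(x)
        assert np.array_equal(H[1:, :-1], H[:-1, 1:])  # constant anti-diags
        assert np.array_equal(hankelize(H), x)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            build_hankel([1.0, 2.0, 3.0])


class TestDecompose:
    def test_constant_series_is_rank_one(self):
        h = decompose(np.full(20, 3.5))
        assert np.sum(h.S > 1e-10 * h.S[0]) == 1

    def test_energy_identity_and_ordering(self, rng):
        x = rng.standard_normal(64)
        h = decompose(x)
        H = build_hankel(x)
        assert np.all(np.diff(h.S) <= 1e-12)
        assert np.isclose((h.S ** 2).sum(), np.linalg.norm(H, "fro") ** 2,
                          rtol=1e-10)

    def test_sinusoid_energy_in_two_components(self):
        t = np.arange(1000) / 125.0
        h = decompose(np.sin(2 * np.pi * 1.2 * t))
        assert (h.S[:2] ** 2).sum() / (h.S ** 2).sum() > 0.99


class TestComponentSeries:
    def test_sum_equals_original(self, rng):
        x = rng.standard_normal(50)
        h = decompose(x)
        total = sum(component_series(h, i) for i in range(h.rank))
        assert np.allclose(total, x, atol=1e-8 * np.abs(x).max())

    def test_all_component_series_matches_single(self, rng):
        x = rng.standard_normal(40)
        h = decompose(x)
        batch = all_component_series(h)
        for i in range(h.rank):
            assert np.allclose(batch[i], component_series(h, i), atol=1e-10)

    def test_constant_series_component_zero(self):
        x = np.full(12, 2.0)
        h = decompose(x)
        assert np.allclose(component_series(h, 0), x, atol=1e-10)

    def test_two_components_rebuild_sinusoid(self):
        t = np.arange(1000) / 125.0
        x = np.sin(2 * np.pi * 1.2 * t)
        h = decompose(x)
        rebuilt = component_series(h, 0) + component_series(h, 1)
        rel_rms = np.sqrt(np.mean((rebuilt - x) ** 2) / np.mean(x ** 2))
        assert rel_rms < 1e-2

    def test_index_out_of_range(self, rng):
        h = decompose(rng.standard_normal(10))
        with pytest.raises(IndexError):
            component_series(h, h.rank)


class TestPearson:
    def test_self_and_negation(self, rng):
        x = rng.standard_normal(100)
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_quadrature_orthogonality(self):
        # exactly 8 whole periods sampled on [0, 8)
        t = np.arange(1000) / 125.0
        assert abs(pearson(np.sin(2 * np.pi * t),
                           np.cos(2 * np.pi * t))) < 1e-6

    def test_zero_variance_defined_as_zero(self, rng):
        x = rng.standard_normal(30)
        assert pearson(x, np.zeros(30)) == 0.0
        assert pearson(np.ones(30), x) == 0.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounded(self, seed):
        r = np.random.default_rng(seed)
        assert -1.0 <= pearson(r.standard_normal(20),
                               r.standard_normal(20)) <= 1.0


class TestSelectComponents:
    def test_zero_accel_removes_nothing(self, clean_window):
        h = decompose(clean_window)
        sel = select_components(h, np.zeros((3, len(clean_window))))
        assert sel.removed.size == 0
        assert np.all(sel.corr_matrix == 0.0)

    def test_artifact_components_flagged_and_removed(self):
        # pulse at 1.2 Hz plus a strong tone at 2.4 Hz fed to accel_x
        t = np.arange(1000) / 125.0
        artifact = 2.0 * np.sin(2 * np.pi * 2.4 * t + 0.7)
        ppg = np.sin(2 * np.pi * 1.2 * t) + artifact
        accel = np.vstack([artifact, np.zeros_like(t), np.zeros_like(t)])
        h = decompose(ppg)
        sel = select_components(h, accel, threshold=0.5)
        top = np.abs(sel.corr_matrix[sel.removed]).max(axis=1)
        assert sel.removed.size >= 2
        assert np.all(np.sort(top)[-2:] >= 0.9)

    def test_high_threshold_keeps_weakly_coupled_noise(self, rng):
        ppg = rng.standard_normal(400)
        accel = rng.standard_normal((3, 400))
        h = decompose(ppg)
        sel = select_components(h, accel, threshold=0.999)
        assert sel.removed.size == 0

    def test_corr_matrix_bounded_and_partition(self, clean_window):
        h = decompose(clean_window)
        accel = np.vstack([clean_window, clean_window, clean_window])
        sel = select_components(h, accel)
        assert np.all(np.abs(sel.corr_matrix) <= 1.0)
        both = np.concatenate([sel.kept, sel.removed])
        assert np.array_equal(np.sort(both), np.arange(h.rank))
        assert sel.kept.size >= 1

    def test_invalid_threshold(self, clean_window):
        h = decompose(clean_window)
        accel = np.zeros((3, len(clean_window)))
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError, match="threshold"):
                select_components(h, accel, threshold=bad)


class TestReconstruct:
    def test_keep_all_is_identity(self, rng):
        x = rng.standard_normal(200)
        h = decompose(x)
        sel = ComponentSelection(kept=np.arange(h.rank),
                                 removed=np.array([], dtype=int),
                                 corr_matrix=np.zeros((h.rank, 3)),
                                 threshold=0.5)
        assert np.allclose(reconstruct(h, sel), x,
                           atol=1e-8 * np.abs(x).max())

    def test_empty_kept_rejected(self, rng):
        x = rng.standard_normal(20)
        h = decompose(x)
        sel = ComponentSelection(kept=np.array([], dtype=int),
                                 removed=np.arange(h.rank),
                                 corr_matrix=np.zeros((h.rank, 3)),
                                 threshold=0.5)
        with pytest.raises(ValueError, match="empty"):
            reconstruct(h, sel)

    def test_denoising_moves_toward_clean_signal(self):
        from tests_support import corrupted_window_with_truth

        ppg, accel, clean = corrupted_window_with_truth(seed=3)
        cleaned, _ = hp.remove_motion_artifacts(ppg, accel)
        assert pearson(cleaned, clean) > pearson(ppg, clean)


class TestOracleEquivalence:
    """Brute-force loop oracle on tiny series."""

    @pytest.mark.parametrize("n", range(4, 13))
    def test_matches_brute_force(self, n, rng):
        x = rng.standard_normal(n)
        H = build_hankel(x)
        assert np.array_equal(H, brute_force_hankel(x))
        h = decompose(x)
        total = sum(component_series(h, i) for i in range(h.rank))
        # oracle: full SVD product hankelized by explicit loops
        M = h.U @ np.diag(h.S) @ h.V.T
        assert np.allclose(total, brute_force_hankelize(M), atol=1e-10)
        assert np.allclose(total, x, atol=1e-10)
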