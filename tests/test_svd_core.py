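import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pasvd.preprocess import FrameStack, Scale
from pasvd.svd_core import (
    Block,
    BlockGrid,
    FilterConfig,
    NoBoundaryError,
    SingularSpectrumField,
    ThresholdField,
    blockwise_filter,
    build_casorati,
    compute_spectrum,
    high_order_threshold,
    low_order_threshold,
    median_filter_thresholds,
    reconstruct_components,
    scatter_block,
    smooth_spectra,
)

from oracles import oracle_high, oracle_low

class TestBlockGrid:
    def test_tiles_without_overlap_and_covers_everything(self):
        grid = BlockGrid((128, 126), 64, 40)
        cover = np.zeros((128, 126), dtype=int)
        for _, _, blk in grid.blocks():
            cover[blk.row_start : blk.row_end, blk.col_start : blk.col_end] += 1
        np.testing.assert_array_equal(cover, 1)

    @given(
        h=st.integers(2, 60),
        w=st.integers(2, 60),
        br=st.integers(1, 60),
        bc=st.integers(1, 60),
    )
    @settings(max_examples=60, deadline=None)
    def test_every_pixel_in_exactly_one_block(self, h, w, br, bc):
        if br > h or bc > w:
            with pytest.raises(ValueError):
                BlockGrid((h, w), br, bc)
            return
        cover = np.zeros((h, w), dtype=int)
        for _, _, blk in BlockGrid((h, w), br, bc).blocks():
            cover[blk.row_start : blk.row_end, blk.col_start : blk.col_end] += 1
        assert (cover == 1).all()

    def test_oversized_block_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            BlockGrid((10, 10), 11, 5)


class TestCasorati:
    def test_known_element_placement(self):
        data = np.arange(2 * 2 * 3, dtype=float).reshape(2, 2, 3)
        mat = build_casorati(FrameStack(data, scale=Scale.LOG_DB), Block(0, 2, 0, 2))
        assert mat.shape == (4, 3)
        # row-major pixel order: (0,0), (0,1), (1,0), (1,1)
        np.testing.assert_array_equal(mat[0], data[0, 0, :])
        np.testing.assert_array_equal(mat[1], data[0, 1, :])
        np.testing.assert_array_equal(mat[2], data[1, 0, :])
        np.testing.assert_array_equal(mat[3], data[1, 1, :])

    def test_round_trip_scatter(self, rng):
        data = rng.standard_normal((7, 9, 4))
        blk = Block(1, 5, 2, 8)
        mat = build_casorati(data, blk)
        out = np.zeros_like(data)
        scatter_block(mat, blk, out)
        np.testing.assert_array_equal(
            out[1:5, 2:8, :], data[1:5, 2:8, :]
        )

    def test_constant_in_time_gives_identical_columns(self):
        frame = np.arange(6, dtype=float).reshape(2, 3)
        data = np.dstack([frame] * 5)
        mat = build_casorati(data, Block(0, 2, 0, 3))
        for t in range(1, 5):
            np.testing.assert_array_equal(mat[:, t], mat[:, 0])

    def test_empty_block_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            build_casorati(rng.random((4, 4, 2)), Block(2, 2, 0, 4))


class TestComputeSpectrum:
    def test_rank_one_matrix(self, rng):
        u = rng.standard_normal(10)
        v = rng.standard_normal(4)
        curve = compute_spectrum(np.outer(u, v))
        assert curve[0] == pytest.approx(0.0)
        assert (curve[1:] < -200).all()

    def test_diagonal_421(self):
        curve = compute_spectrum(np.diag([4.0, 2.0, 1.0]))
        np.testing.assert_allclose(curve, [0.0, -6.0206, -12.0412], atol=1e-4)

    def test_matches_gram_eigendecomposition_oracle(self, rng):
        m = rng.standard_normal((50, 12))
        curve, (u, s, vt) = compute_spectrum(m, return_factors=True)
        eig = np.linalg.eigvalsh(m.T @ m)[::-1]
        s_oracle = np.sqrt(np.clip(eig, 0, None))
        np.testing.assert_allclose(s, s_oracle, rtol=1e-8)
        np.testing.assert_allclose(curve, 20 * np.log10(s_oracle / s_oracle[0]), atol=1e-8)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            compute_spectrum(np.zeros((5, 3)))

    def test_curve_is_non_increasing(self, rng):
        curve = compute_spectrum(rng.standard_normal((30, 8)))
        assert (np.diff(curve) <= 1e-12).all()


class TestSmoothSpectra:
    def test_single_block_grid_identity(self):
        field = SingularSpectrumField(curves_db=np.random.default_rng(0).standard_normal((1, 1, 8)))
        with pytest.warns(UserWarning, match="identity"):
            out = smooth_spectra(field, (3, 3))
        np.testing.assert_array_equal(out.smoothed_db, field.curves_db)

    def test_identical_curves_unchanged(self):
        curve = np.linspace(0, -30, 12)
        field = SingularSpectrumField(curves_db=np.tile(curve, (3, 4, 1)))
        out = smooth_spectra(field, (3, 3))
        np.testing.assert_allclose(out.smoothed_db, field.curves_db, atol=1e-12)

    def test_three_block_column_averages_to_center(self):
        c = np.linspace(0, -20, 10)
        delta = 2.5
        field = SingularSpectrumField(curves_db=np.stack([[c], [c + delta], [c - delta]]))
        out = smooth_spectra(field, (3, 1))
        np.testing.assert_allclose(out.smoothed_db[1, 0], c, atol=1e-12)

    def test_even_window_rejected(self):
        field = SingularSpectrumField(curves_db=np.zeros((2, 2, 5)))
        with pytest.raises(ValueError, match="odd"):
            smooth_spectra(field, (2, 3))


class TestLowOrderThreshold:
    def test_hand_computed_example(self):
        curve = [66.0, 60.0, 55.0, 54.0, 53.5]
        # ratios: 1.100, 1.091, 1.0185..., 1.0093...; first < 1.05 at i=3
        assert low_order_threshold(curve, 1.05, ratio_domain="raw") == 3
        assert oracle_low(curve, 1.05, shifted=False) == 3

    def test_two_point_curve(self):
        assert low_order_threshold([10.0, 9.9], 1.05, ratio_domain="raw") == 1

    def test_no_boundary_raises_with_trace(self):
        curve = [100.0, 50.0, 25.0, 12.5]  # every ratio is 2
        with pytest.raises(NoBoundaryError) as exc:
            low_order_threshold(curve, 1.05, ratio_domain="raw")
        np.testing.assert_allclose(exc.value.ratios, 2.0)

    def test_shifted_domain_handles_negative_curves(self):
        # shifted: [41, 31, 21, 20.9, 20.8, 1]; first ratio < 1.05 at i=3
        curve = np.array([0.0, -10.0, -20.0, -20.1, -20.2, -40.0])
        t = low_order_threshold(curve, 1.05, ratio_domain="shifted")
        assert t == 3
        assert t == oracle_low(curve, 1.05, shifted=True)

    def test_raw_domain_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="positive"):
            low_order_threshold([10.0, -1.0], 1.05, ratio_domain="raw")

    def test_preset_must_exceed_one(self):
        with pytest.raises(ValueError):
            low_order_threshold([2.0, 1.0], 0.9)


class TestHighOrderThreshold:
    def test_linear_curve_tie_broken_to_smallest(self):
        curve = np.linspace(0, -40, 60)
        assert high_order_threshold(curve) == oracle_high(curve)

    def test_constructed_knee_curve(self):
        # gentle slope, steep knee at order 40 of 60, gentle tail
        curve = np.concatenate(
            [np.linspace(0, -8, 39), np.linspace(-30, -34, 21)]
        )
        t = high_order_threshold(curve)
        assert t == oracle_high(curve)
        w = round(0.30 * len(curve))
        assert abs(t - 40) <= w // 2 + 3  # knee recovered up to filter delay

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError, match="short"):
            high_order_threshold(np.linspace(0, -10, 9))

    @pytest.mark.parametrize("frac", [0.25, 0.30, 0.35])
    def test_matches_explicit_loop_oracle_random_curves(self, frac, rng):
        for _ in range(30):
            n = int(rng.integers(12, 80))
            curve = np.sort(rng.standard_normal(n) * 10)[::-1]
            assert high_order_threshold(curve, frac) == oracle_high(curve, frac)


class TestMedianFilterThresholds:
    def test_uniform_field_identity(self):
        f = ThresholdField(t_low=np.full((4, 4), 3), t_high=np.full((4, 4), 40))
        out = median_filter_thresholds(f, (3, 3))
        np.testing.assert_array_equal(out.t_low, 3)
        np.testing.assert_array_equal(out.t_high, 40)

    def test_center_outlier_removed(self):
        t_low = np.full((3, 3), 3)
        t_low[1, 1] = 40
        f = ThresholdField(t_low=t_low, t_high=np.full((3, 3), 50))
        out = median_filter_thresholds(f, (3, 3))
        assert out.t_low[1, 1] == 3
        np.testing.assert_array_equal(out.t_low_raw, t_low)

    def test_checkerboard_matches_brute_force(self):
        g = np.indices((5, 6)).sum(axis=0) % 2
        field = ThresholdField(t_low=3 + 2 * g, t_high=np.full((5, 6), 9))
        out = median_filter_thresholds(field, (3, 3))
        for r in range(5):
            for c in range(6):
                win = field.t_low[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2]
                assert out.t_low[r, c] == round(float(np.median(win)))

    def test_even_window_rejected(self):
        f = ThresholdField(t_low=np.ones((2, 2), int), t_high=np.ones((2, 2), int))
        with pytest.raises(ValueError, match="odd"):
            median_filter_thresholds(f, (2, 2))


class TestReconstructComponents:
    def test_rank_one_temporal_constant(self, rng):
        col = rng.random(12) + 0.5
        mat = np.tile(col[:, None], (1, 6))
        _, fac = compute_spectrum(mat, return_factors=True)
        st_, fl, no = reconstruct_components(fac, 1, 6)
        np.testing.assert_allclose(st_, mat, atol=1e-10)
        np.testing.assert_allclose(fl, 0, atol=1e-10)
        np.testing.assert_allclose(no, 0, atol=1e-10)

    def test_three_orthogonal_terms_recovered_exactly(self):
        q, _ = np.linalg.qr(np.random.default_rng(3).standard_normal((9, 3)))
        p, _ = np.linalg.qr(np.random.default_rng(4).standard_normal((5, 3)))
        terms = [s * np.outer(q[:, i], p[:, i]) for i, s in enumerate([100.0, 10.0, 1.0])]
        mat = sum(terms)
        _, fac = compute_spectrum(mat, return_factors=True)
        st_, fl, no = reconstruct_components(fac, 1, 2)
        np.testing.assert_allclose(st_, terms[0], atol=1e-9)
        np.testing.assert_allclose(fl, terms[1], atol=1e-9)
        np.testing.assert_allclose(no, terms[2], atol=1e-9)

    def test_components_sum_to_input(self, rng):
        mat = rng.standard_normal((40, 15))
        _, fac = compute_spectrum(mat, return_factors=True)
        st_, fl, no = reconstruct_components(fac, 3, 10)
        err = np.linalg.norm(st_ + fl + no - mat) / np.linalg.norm(mat)
        assert err <= 1e-6

    def test_noise_exactly_zero_when_t_high_is_last(self, rng):
        mat = rng.standard_normal((10, 5))
        _, fac = compute_spectrum(mat, return_factors=True)
        _, _, no = reconstruct_components(fac, 2, 5)
        np.testing.assert_array_equal(no, 0.0)

    def test_invalid_pair_rejected(self, rng):
        _, fac = compute_spectrum(rng.standard_normal((10, 5)), return_factors=True)
        with pytest.raises(ValueError, match="threshold pair"):
            reconstruct_components(fac, 3, 3)


class TestBlockwiseFilter:
    def test_single_block_equals_global_svd_filter(self, rng):
        data = rng.standard_normal((24, 20, 30))
        stack = FrameStack(data, scale=Scale.LOG_DB)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = blockwise_filter(
                stack, FilterConfig(block_rows_px=24, block_cols_px=20)
            )
        tl = comp.provenance["t_low"][0][0]
        th = comp.provenance["t_high"][0][0]
        # independent global route: plain SVD of the full Casorati matrix
        u, s, vt = np.linalg.svd(data.reshape(24 * 20, 30), full_matrices=False)
        stationary = (u[:, :tl] * s[:tl]) @ vt[:tl]
        flow = (u[:, tl:th] * s[tl:th]) @ vt[tl:th]
        noise = (u[:, th:] * s[th:]) @ vt[th:]
        scale = np.linalg.norm(data)
        assert np.linalg.norm(comp.stationary.data.reshape(480, 30) - stationary) / scale <= 1e-10
        assert np.linalg.norm(comp.flow.data.reshape(480, 30) - flow) / scale <= 1e-10
        assert np.linalg.norm(comp.noise.data.reshape(480, 30) - noise) / scale <= 1e-10

    def test_conservation_multiblock(self, rng):
        data = rng.standard_normal((50, 46, 16))
        stack = FrameStack(data, scale=Scale.LOG_DB)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = blockwise_filter(stack, FilterConfig(block_rows_px=16, block_cols_px=20))
        err = np.linalg.norm(comp.total() - data) / np.linalg.norm(data)
        assert err <= 1e-6

    def test_threshold_sanity_after_median_filter(self, us_components):
        tl = np.asarray(us_components.provenance["t_low"])
        th = np.asarray(us_components.provenance["t_high"])
        assert (tl >= 1).all()
        assert (tl < th).all()
        assert (th <= us_components.provenance["n_orders"]).all()

    def test_pure_noise_stationary_energy_is_small(self, rng):
        stack = FrameStack(rng.standard_normal((64, 64, 120)), scale=Scale.LOG_DB)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = blockwise_filter(stack, FilterConfig(block_rows_px=64, block_cols_px=64))
        e = {n: float((getattr(comp, n).data ** 2).sum()) for n in ("stationary", "flow", "noise")}
        total = sum(e.values())
        # energy bookkeeping: the bands partition the input energy exactly
        assert total == pytest.approx(float((stack.data**2).sum()), rel=1e-9)
        # an i.i.d. stack has no coherent tissue: the stationary band is tiny
        assert e["stationary"] / total < 0.05
        assert e["flow"] + e["noise"] > 0.9 * total

    def test_phantom_flow_energy_concentrates_in_flow_region(self, phantom, us_components):
        from scipy import ndimage

        _, _, truth = phantom
        energy = us_components.flow.data**2
        dilated = ndimage.binary_dilation(truth.flow_mask, iterations=3)
        assert energy[dilated].sum() / energy.sum() >= 0.70

    @staticmethod
    def _geometric_spectrum_stack():
        """Stack whose singular values fall by a constant 12 dB per order.

        Every shifted-domain ratio then stays above the 1.05 preset, so the
        low-order rule finds no tissue/flow boundary.
        """
        rng = np.random.default_rng(0)
        u, _ = np.linalg.qr(rng.standard_normal((144, 15)))
        v, _ = np.linalg.qr(rng.standard_normal((15, 15)))
        s = 100.0 * 4.0 ** -np.arange(15)
        data = ((u * s) @ v.T).reshape(12, 12, 15)
        return FrameStack(data, scale=Scale.LOG_DB), data

    def test_fallback_policy_fail_raises_with_coordinates(self):
        stack, _ = self._geometric_spectrum_stack()
        with pytest.raises(RuntimeError, match=r"row=0, col=0"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                blockwise_filter(
                    stack,
                    FilterConfig(block_rows_px=12, block_cols_px=12, fallback_policy="fail"),
                )

    def test_fallback_policy_all_stationary(self):
        stack, data = self._geometric_spectrum_stack()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = blockwise_filter(stack, FilterConfig(block_rows_px=12, block_cols_px=12))
        assert comp.provenance["fallback_blocks"] == [(0, 0)]
        # all but the last (clamped) order land in the stationary band
        np.testing.assert_allclose(comp.stationary.data, data, atol=1e-5)

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError, match="2 frames"):
            blockwise_filter(FrameStack(rng.random((8, 8, 1))), FilterConfig())

    def test_monotone_ordering_of_band_energies(self, rng):
        # orders 1..t_low carry at least as much energy as any equal count
        # of higher orders: guaranteed by the descending singular values
        _, (u, s, vt) = compute_spectrum(rng.standard_normal((60, 20)), return_factors=True)
        t_low = 4
        head = float((s[:t_low] ** 2).sum())
        for start in range(t_low, len(s) - t_low + 1):
            assert head >= float((s[start : start + t_low] ** 2).sum()) - 1e-12
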