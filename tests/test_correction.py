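import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colorboard import (apply_correction, fit_color_checker_baseline,
                        fit_correction, histogram_match, make_board_spec,
                        sample_pairs, subsample_pairs, theoretical_refmap,
                        render_board, compute_mrmse, stripe_mask)
from colorboard.board import generate_board
from colorboard.correction import CorrectionError, SamplePairs
from colorboard.simulate import (IlluminationCondition, compose_scene,
                                 generate_mosaic, simulate_illumination)


def _identity_pairs(spec, refmap, image):
    return sample_pairs(image, refmap, spec)


def _surface_pairs(spec, alpha_coef, beta_coef, n=60, seed=0):
    """Pairs whose observed values follow known order-1 alpha/beta surfaces.

    observed = (ref - beta(x, y)) / alpha(x, y), so the forward fit
    ref = alpha * observed + beta is exactly in-family.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.raster_shape
    pos = np.column_stack([rng.uniform(0, w - 1, n), rng.uniform(0, h - 1, n)])
    ref = rng.uniform(20, 235, (n, 3))
    xn, yn = pos[:, 0] / (w - 1), pos[:, 1] / (h - 1)
    a = (alpha_coef[0] * xn + alpha_coef[1] * yn + alpha_coef[2])[:, None]
    b = (beta_coef[0] * xn + beta_coef[1] * yn + beta_coef[2])[:, None]
    obs = (ref - b) / a
    return SamplePairs(pos, obs, ref, spec.raster_shape)


class TestSamplePairs:
    def test_counting_rule_floor_plus_one(self):
        # a vertical stripe of 46 mm at 5 px/mm has a 230-px centerline
        spec = make_board_spec("A", board_height_mm=74.0)
        left = next(s for s in spec.stripes if s.side == "left")
        rows, cols = spec.rect_to_slices(left.rect_mm)
        assert rows.stop - rows.start == 230
        refmap = theoretical_refmap(spec)
        pairs = sample_pairs(render_board(spec), refmap, spec)
        per_stripe = {}
        for s in spec.stripes:
            r, c = spec.rect_to_slices(s.rect_mm)
            length = (c.stop - c.start) if s.horizontal else (r.stop - r.start)
            per_stripe[s.side] = length // 10 + 1
        assert per_stripe["left"] == 24  # floor(230/10) + 1
        assert len(pairs) == sum(per_stripe.values())

    def test_interval_larger_than_stripe_gives_one_sample(self):
        spec = make_board_spec("A")
        refmap = theoretical_refmap(spec)
        pairs = sample_pairs(render_board(spec), refmap, spec,
                             interval_px=10_000)
        assert len(pairs) == len(spec.stripes)

    def test_identity_image_pairs_match(self, spec, refmap, board_image):
        pairs = _identity_pairs(spec, refmap, board_image)
        assert np.array_equal(pairs.observed, pairs.reference)

    def test_wrong_raster_rejected(self, spec, refmap):
        with pytest.raises(CorrectionError):
            sample_pairs(np.zeros((10, 10, 3), np.uint8), refmap, spec)


class TestFit:
    def test_identity_fit_is_identity_model(self, spec, refmap, board_image):
        pairs = _identity_pairs(spec, refmap, board_image)
        model = fit_correction(pairs, order=1)
        for c in "RGB":
            assert np.allclose(model.alpha[c].coefficients, [0, 0, 1],
                               atol=1e-9)
            assert np.allclose(model.beta[c].coefficients, [0, 0, 0],
                               atol=1e-9)

    def test_recovers_constructed_first_order_surfaces(self, spec):
        alpha = (0.3, -0.2, 1.1)
        beta = (12.0, -8.0, 10.0)
        pairs = _surface_pairs(spec, alpha, beta)
        model = fit_correction(pairs, order=1)
        for c in "RGB":
            assert np.allclose(model.alpha[c].coefficients, alpha, atol=1e-6)
            assert np.allclose(model.beta[c].coefficients, beta, atol=1e-6)

    def test_order0_matches_closed_form_ols(self, spec):
        rng = np.random.default_rng(3)
        n = 50
        pos = np.column_stack([rng.uniform(0, 499, n), rng.uniform(0, 349, n)])
        obs = rng.uniform(0, 255, (n, 3))
        ref = 0.8 * obs + 15 + rng.normal(0, 5, (n, 3))
        pairs = SamplePairs(pos, obs, ref, spec.raster_shape)
        model = fit_correction(pairs, order=0)
        for i, c in enumerate("RGB"):
            x, y = obs[:, i], ref[:, i]
            slope = (((x - x.mean()) * (y - y.mean())).sum()
                     / ((x - x.mean()) ** 2).sum())
            inter = y.mean() - slope * x.mean()
            assert model.alpha[c].coefficients[0] == pytest.approx(slope,
                                                                   abs=1e-9)
            assert model.beta[c].coefficients[0] == pytest.approx(inter,
                                                                  abs=1e-9)

    def test_nested_orders_never_increase_residual(self, spec, refmap):
        mosaic = generate_mosaic(seed=9)
        scene = compose_scene(spec, refmap, mosaic)
        cond = IlluminationCondition(4000.0, (1.0, 0.5), 0.15, 1.0)
        distorted = simulate_illumination(scene, cond, seed=4)
        pairs = sample_pairs(distorted, refmap, spec)
        rms = [np.mean(list(fit_correction(pairs, order=o).residual_rms
                            .values())) for o in (0, 1, 2)]
        assert rms[1] <= rms[0] + 1e-9
        assert rms[2] <= rms[1] + 1e-9

    def test_insufficient_pairs_rejected(self, spec):
        pairs = SamplePairs(np.zeros((5, 2)), np.zeros((5, 3)),
                            np.zeros((5, 3)), spec.raster_shape)
        with pytest.raises(CorrectionError):
            fit_correction(pairs, order=1)
        with pytest.raises(CorrectionError):
            fit_correction(SamplePairs(np.zeros((1, 2)), np.zeros((1, 3)),
                                       np.zeros((1, 3)), spec.raster_shape),
                           order=0)

    def test_constant_channel_falls_back_to_order0(self, spec):
        rng = np.random.default_rng(5)
        n = 40
        pos = np.column_stack([rng.uniform(0, 499, n), rng.uniform(0, 349, n)])
        obs = rng.uniform(10, 240, (n, 3))
        obs[:, 2] = 128.0  # constant blue: spatial-gain columns collinear
        ref = obs.copy()
        model = fit_correction(SamplePairs(pos, obs, ref, spec.raster_shape),
                               order=1)
        assert "B" in model.fallback_channels
        assert model.alpha["B"].order == 0


class TestApply:
    def test_identity_model_preserves_image(self, spec, refmap, board_image):
        model = fit_correction(_identity_pairs(spec, refmap, board_image), 1)
        out = apply_correction(model, board_image)
        assert np.array_equal(out, board_image)

    def test_gain_offset_and_clamping(self, spec, refmap, board_image):
        model = fit_correction(_identity_pairs(spec, refmap, board_image), 0)
        for c in "RGB":
            model.alpha[c].coefficients[:] = [2.0]
            model.beta[c].coefficients[:] = [10.0]
        img = np.full((4, 4, 3), 50, np.uint8)
        assert np.all(apply_correction(model, img) == 110)
        img2 = np.full((4, 4, 3), 200, np.uint8)
        assert np.all(apply_correction(model, img2) == 255)

    def test_self_fitted_correction_restores_stripes(self, spec, refmap,
                                                     scene, stripes_mask):
        cond = IlluminationCondition(4000.0, (0.0, 1.0), 0.2, 0.0)
        distorted = simulate_illumination(scene, cond, seed=1)
        model = fit_correction(sample_pairs(distorted, refmap, spec), 1)
        corrected = apply_correction(model, distorted)
        resid = np.mean(list(model.residual_rms.values()))
        report = compute_mrmse(corrected, scene, stripes_mask)
        assert report.mrmse <= resid + 1.0  # within OLS residual + rounding


class TestCheckerBaseline:
    def test_identity_pairs_give_identity_model(self, spec, refmap,
                                                board_image):
        pairs = subsample_pairs(_identity_pairs(spec, refmap, board_image), 24)
        model = fit_color_checker_baseline(pairs)
        for c in "RGB":
            assert model.alpha[c].coefficients[0] == pytest.approx(1.0,
                                                                   abs=1e-9)
            assert model.beta[c].coefficients[0] == pytest.approx(0.0,
                                                                  abs=1e-7)

    def test_wrong_count_rejected(self, spec, refmap, board_image):
        pairs = subsample_pairs(_identity_pairs(spec, refmap, board_image), 23)
        with pytest.raises(CorrectionError):
            fit_color_checker_baseline(pairs)

    def test_svcm_beats_checker_under_spatial_distortion(self, spec, refmap,
                                                         scene,
                                                         stripes_mask):
        cond = IlluminationCondition(2800.0, (1.0, 0.0), 0.25, 0.0)
        distorted = simulate_illumination(scene, cond, seed=2)
        pairs = sample_pairs(distorted, refmap, spec)
        svcm = apply_correction(fit_correction(pairs, 1), distorted)
        checker = apply_correction(
            fit_color_checker_baseline(subsample_pairs(pairs, 24)), distorted)
        m_svcm = compute_mrmse(svcm, scene, stripes_mask).mrmse
        m_checker = compute_mrmse(checker, scene, stripes_mask).mrmse
        assert m_svcm <= m_checker


class TestHistogramMatch:
    def test_identity(self, board_image):
        out = histogram_match(board_image, board_image)
        assert np.abs(out.astype(int) - board_image.astype(int)).max() <= 1

    def test_constant_maps_to_constant(self):
        img = np.full((8, 8, 3), 40, np.uint8)
        ref = np.full((8, 8, 3), 200, np.uint8)
        assert np.all(histogram_match(img, ref) == 200)

    def test_shape_mismatch_rejected(self, board_image):
        with pytest.raises(CorrectionError):
            histogram_match(board_image, board_image[:-1])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_mapping_is_monotone_per_channel(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        ref = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        out = histogram_match(img, ref)
        for c in range(3):
            x = img[..., c].ravel()
            y = out[..., c].ravel().astype(int)
            order = np.argsort(x, kind="stable")
            xs, ys = x[order], y[order]
            # equal inputs map to equal outputs; larger never maps lower
            d = np.diff(ys)
            same = np.diff(xs) == 0
            assert np.all(d[same] == 0)
            assert np.all(d[~same] >= 0)
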