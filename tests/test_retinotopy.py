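"""Fourier phase mapping, pRF grid fitting and ROI containment rules."""

import numpy as np
import pytest

from laminar_mvpa import (
    Disc,
    HRFParams,
    PRFGrid,
    PRFModel,
    RegionUnion,
    define_roi,
    fit_prf_grid,
    fourier_phase_map,
    grid_predictions,
    make_retinotopy_stimulus,
    predict_prf_timecourse,
    semicircle,
)


class TestFourierPhaseMap:
    def test_pure_sinusoid_phase_recovery(self):
        n, tr, period = 384, 2.0, 64.0
        t = np.arange(n) * tr
        for phi in (-2.0, 0.0, 1.3):
            ts = np.cos(2 * np.pi * t / period + phi)
            res = fourier_phase_map(ts, period, tr)
            assert res.phase[0] == pytest.approx(phi, abs=1e-6)
            assert res.f_ratio[0] > 1e3
            assert res.amplitude[0] == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_f_ratio_mean_is_one(self):
        rng = np.random.default_rng(0)
        ts = rng.standard_normal((10_000, 384))
        res = fourier_phase_map(ts, 64.0, 2.0)
        assert res.f_ratio.mean() == pytest.approx(1.0, abs=0.05)

    def test_constant_series(self):
        res = fourier_phase_map(np.full((1, 384), 5.0), 64.0, 2.0)
        assert res.amplitude[0] == 0.0
        assert res.f_ratio[0] == 0.0

    def test_baseline_exclusion_window(self):
        # 396 volumes with 6-volume baselines -> 384-volume window, 12 cycles
        rng = np.random.default_rng(1)
        ts = rng.standard_normal((2, 396))
        res = fourier_phase_map(ts, 64.0, 2.0, baseline_vols=6)
        assert res.amplitude.shape == (2,)

    def test_non_integer_cycles_rejected(self):
        with pytest.raises(ValueError, match="integer number"):
            fourier_phase_map(np.zeros((1, 100)), 64.0, 2.0)


class TestPRFGrid:
    def test_default_has_24_sigma_levels(self):
        grid = PRFGrid()
        assert len(grid.sigma_levels) == 24

    def test_centres_spaced_one_sigma_apart_within_extent(self):
        grid = PRFGrid(sigma_levels=(1.0, 2.0), field_extent=4.0)
        cands = grid.candidates()
        for s in (1.0, 2.0):
            xs = np.unique(cands[cands[:, 2] == s, 0])
            np.testing.assert_allclose(np.diff(xs), s)
            assert np.abs(xs).max() <= 4.0 + 1e-9


@pytest.fixture(scope="module")
def wedge_ring(small_grid):
    return (
        make_retinotopy_stimulus("wedge", small_grid),
        make_retinotopy_stimulus("ring", small_grid),
    )


@pytest.fixture(scope="module")
def small_prf_fit(small_grid, wedge_ring):
    """A reduced grid plus cached candidate predictions."""
    grid = PRFGrid(
        sigma_levels=tuple(float(s) for s in np.geomspace(0.6, 3.0, 6)),
        field_extent=4.5,
    )
    preds = grid_predictions(grid, list(wedge_ring))
    return grid, preds, wedge_ring


class TestPredictTimecourse:
    def test_no_overlap_gives_flat_zero(self, wedge_ring, small_grid):
        wedge, _ = wedge_ring
        # centre far outside the stimulated field
        pred = predict_prf_timecourse((25.0, 25.0, 0.5), wedge)
        np.testing.assert_allclose(pred, 0.0, atol=1e-12)

    def test_always_on_full_field_ramps_to_plateau(self, small_grid):
        from laminar_mvpa import StimulusAperture

        frames = np.ones((60, small_grid.n_pixels_per_side**2))
        ap = StimulusAperture(grid=small_grid, frames=frames, tr_s=2.0, kind="task_block")
        pred = predict_prf_timecourse((0.0, 0.0, 1.0), ap)
        plateau = pred[20:50]
        assert plateau.std() / plateau.mean() < 1e-6

    def test_single_frame_stimulus_is_scaled_hrf(self, small_grid):
        from laminar_mvpa import StimulusAperture
        from laminar_mvpa.glm import _hrf_at

        frames = np.zeros((40, small_grid.n_pixels_per_side**2))
        frames[0] = 1.0
        ap = StimulusAperture(grid=small_grid, frames=frames, tr_s=2.0, kind="task_block")
        pred = predict_prf_timecourse((0.0, 0.0, 1.0), ap)
        kern = _hrf_at(np.arange(0.0, 32.0, 2.0), HRFParams())
        scale = pred[np.argmax(np.abs(pred))] / kern[np.argmax(np.abs(kern))]
        np.testing.assert_allclose(pred[: len(kern)], scale * kern, atol=1e-9)


class TestFitPRFGrid:
    def test_noiseless_self_recovery(self, small_prf_fit):
        grid, (cands, preds), apertures = small_prf_fit
        rng = np.random.default_rng(2)
        idx = rng.choice(len(cands), 25, replace=False)
        models = fit_prf_grid(
            preds[idx], list(apertures), grid, predictions=(cands, preds)
        )
        for i, m in zip(idx, models):
            np.testing.assert_allclose([m.x, m.y, m.sigma], cands[i])
            assert m.r2 == pytest.approx(1.0, abs=1e-9)

    def test_off_grid_voxel_matches_brute_force_oracle(self, small_prf_fit):
        grid, (cands, preds), apertures = small_prf_fit
        rng = np.random.default_rng(3)
        for _ in range(5):
            x0 = rng.uniform(-2, 2)
            y0 = rng.uniform(-2, 2)
            s0 = rng.uniform(0.7, 2.5)
            ts = np.hstack(
                [predict_prf_timecourse((x0, y0, s0), ap) for ap in apertures]
            )
            m = fit_prf_grid(ts, list(apertures), grid, predictions=(cands, preds))
            # oracle: exhaustive correlation over every candidate
            scores = np.array(
                [
                    np.corrcoef(ts, preds[j])[0, 1] ** 2
                    for j in range(len(cands))
                ]
            )
            best = np.nanargmax(scores)
            np.testing.assert_allclose([m.x, m.y, m.sigma], cands[best])
            assert m.r2 == pytest.approx(np.nanmax(scores), abs=1e-9)

    def test_pure_noise_rarely_exceeds_threshold(self, small_prf_fit):
        grid, (cands, preds), apertures = small_prf_fit
        rng = np.random.default_rng(4)
        ts = rng.standard_normal((1000, preds.shape[1]))
        models = fit_prf_grid(ts, list(apertures), grid, predictions=(cands, preds))
        frac_below = np.mean([m.r2 < 0.2 for m in models])
        assert frac_below >= 0.99

    def test_affine_invariance(self, small_prf_fit):
        grid, (cands, preds), apertures = small_prf_fit
        rng = np.random.default_rng(5)
        ts = preds[10] + 0.3 * rng.standard_normal(preds.shape[1])
        m1 = fit_prf_grid(ts, list(apertures), grid, predictions=(cands, preds))
        m2 = fit_prf_grid(5.0 * ts - 40.0, list(apertures), grid, predictions=(cands, preds))
        assert (m1.x, m1.y, m1.sigma) == (m2.x, m2.y, m2.sigma)
        assert m1.r2 == pytest.approx(m2.r2, abs=1e-12)

    def test_constant_voxel_gives_sentinel(self, small_prf_fit):
        grid, (cands, preds), apertures = small_prf_fit
        m = fit_prf_grid(
            np.full(preds.shape[1], 3.0), list(apertures), grid,
            predictions=(cands, preds),
        )
        assert m.r2 == 0.0


class TestDefineROI:
    def test_central_model_inside_central_roi(self):
        models = [PRFModel(0.0, 0.0, 1.0, r2=0.5)]
        roi = define_roi(models, Disc(0.0, 0.0, 2.1), r2_threshold=0.2)
        assert list(roi.voxel_indices) == [0]

    def test_threshold_boundaries(self):
        models = [PRFModel(0.0, 0.0, 1.0, r2=0.15)]
        region = Disc(0.0, 0.0, 2.1)
        assert len(define_roi(models, region, 0.2)) == 0
        assert len(define_roi(models, region, 0.1)) == 1

    def test_sigma_disc_crossing_boundary_excluded(self):
        models = [PRFModel(1.5, 0.0, 1.0, r2=0.9)]  # 1.5 + 1.0 > 2.1
        assert len(define_roi(models, Disc(0.0, 0.0, 2.1), 0.2)) == 0

    def test_lowering_threshold_is_monotone(self):
        rng = np.random.default_rng(6)
        models = [
            PRFModel(rng.uniform(-2, 2), rng.uniform(-2, 2), rng.uniform(0.3, 1.5),
                     r2=rng.uniform(0, 1))
            for _ in range(60)
        ]
        region = Disc(0.0, 0.0, 3.0)
        previous: set = set()
        for thr in (0.6, 0.4, 0.2, 0.1, 0.0):
            members = set(define_roi(models, region, thr).voxel_indices.tolist())
            assert previous.issubset(members)
            previous = members

    def test_stacked_column_completion(self):
        models = [
            PRFModel(0.0, 0.0, 0.5, r2=0.9),   # passes
            PRFModel(0.0, 0.0, 0.5, r2=0.05),  # same column, fails r2
            PRFModel(5.0, 5.0, 0.5, r2=0.9),   # other column, fails region
        ]
        columns = np.array([7, 7, 8])
        roi = define_roi(models, Disc(0.0, 0.0, 2.1), 0.2, stacked_columns=columns)
        assert set(roi.voxel_indices.tolist()) == {0, 1}
        assert roi.completed == {1}
        assert roi.direct == {0}

    def test_zero_area_region_rejected(self):
        with pytest.raises(ValueError, match="zero area"):
            define_roi([PRFModel(0, 0, 1.0, 0.5)], Disc(0.0, 0.0, 0.0), 0.2)

    def test_semicircle_containment(self):
        # right half-disc of radius 3: the straight edge is the y-axis
        region = semicircle(0.0, 0.0, 3.0, edge_normal=(1.0, 0.0), edge_offset=0.0)
        assert region.contains_disc(1.5, 0.0, 0.5)
        assert not region.contains_disc(0.2, 0.0, 0.5)   # crosses the edge
        assert not region.contains_disc(2.8, 0.0, 0.5)   # crosses the arc

    def test_union_of_semicircles(self):
        left = semicircle(-4.0, 0.0, 2.0, edge_normal=(-1.0, 0.0), edge_offset=4.0 - 2.0)
        right = semicircle(4.0, 0.0, 2.0, edge_normal=(1.0, 0.0), edge_offset=2.0)
        union = RegionUnion((left, right))
        assert union.contains_disc(4.5, 0.0, 0.3)
        assert union.contains_disc(-4.5, 0.0, 0.3)
        assert not union.contains_disc(0.0, 0.0, 0.3)
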