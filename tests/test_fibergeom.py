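"""Fiber segmentation, axis extraction, template-diameter fitting, Q-Q/KS."""

import numpy as np
import pytest

from conftest import VOX, fitted_axis, make_fiber_scene
from fiberwrap import fibergeom as fg
from fiberwrap import synthgen as sg
from fiberwrap.errors import (EmptyForegroundError, InsufficientDataError,
                              NotAFiberError)


def sampled_template_score(mask, voxel_size, point, tangent, diameter,
                           template_length=1.0, guard_factor=1.5, lam=1.0,
                           ds=0.1):
    """Independent oracle: literally sample a voxelized template cylinder.

    Points are laid out on a fine Cartesian grid in the template's frame and
    looked up in the mask by nearest voxel; the score is the covered fraction
    of template points minus the covered fraction of guard-shell points.
    """
    u = np.asarray(tangent, dtype=float)
    u /= np.linalg.norm(u)
    _, e1, e2 = sg.fiber_frame(u)
    r_max = guard_factor * diameter / 2
    g = np.arange(-r_max, r_max + ds / 2, ds)
    ax = np.arange(-template_length / 2, template_length / 2 + ds / 2, ds)
    A, B, T = np.meshgrid(g, g, ax, indexing="ij")
    rr = np.sqrt(A ** 2 + B ** 2)
    pts = (np.asarray(point)[None, :]
           + A.ravel()[:, None] * e1 + B.ravel()[:, None] * e2
           + T.ravel()[:, None] * u)
    idx = np.round(pts / np.asarray(voxel_size)).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(mask.shape)), axis=1)
    covered = np.zeros(len(pts), dtype=bool)
    covered[ok] = mask[tuple(idx[ok].T)]
    rr = rr.ravel()
    inside = rr <= diameter / 2
    guard = (rr > diameter / 2) & (rr <= r_max)
    return covered[inside].mean() - lam * covered[guard].mean()


class TestSegmentation:
    def test_single_fiber_label_equals_analytic_support(self):
        cfg = make_fiber_scene(radius=5.0, shape=(48, 48, 100))
        stack, truth = sg.render_scene(cfg)
        labels = fg.segment_fibers(stack, threshold=0.5)
        assert labels.max() == 1
        analytic = sg.fiber_support_mask(truth.fibers[0], cfg.shape, cfg.voxel_size)
        assert np.array_equal(labels == 1, analytic)

    def test_two_parallel_fibers_two_labels(self):
        cfg = sg.SceneConfig(
            shape=(48, 48, 80), voxel_size=VOX,
            fibers=[sg.Fiber((5.0, 5.0, 2.0), (0, 0, 1), 2.0, 28.0),
                    sg.Fiber((14.0, 14.0, 2.0), (0, 0, 1), 2.0, 28.0)]).noise_free()
        stack, _ = sg.render_scene(cfg)
        assert fg.segment_fibers(stack, threshold=0.5).max() == 2

    def test_noisy_fiber_dice_at_least_09(self):
        cfg = make_fiber_scene(radius=5.0, shape=(48, 48, 100), noise=True, seed=3)
        stack, truth = sg.render_scene(cfg)
        labels = fg.segment_fibers(stack)  # Otsu
        seg = labels > 0
        ref = sg.fiber_support_mask(truth.fibers[0], cfg.shape, cfg.voxel_size)
        dice = 2 * (seg & ref).sum() / (seg.sum() + ref.sum())
        assert dice >= 0.9

    def test_empty_foreground_raises(self):
        cfg = make_fiber_scene()
        stack, _ = sg.render_scene(cfg)
        with pytest.raises(EmptyForegroundError):
            fg.segment_fibers(stack, threshold=1e6)


class TestAxisExtraction:
    def test_straight_fiber_axis_on_true_line(self):
        cfg = make_fiber_scene()
        stack, _ = sg.render_scene(cfg)
        axis, _ = fitted_axis(stack)
        # truth axis: z = y = 8 μm; tolerance half an in-plane voxel
        assert np.all(np.abs(axis.points[:, 0] - 8.0) <= 0.5 * VOX[0] + 1e-9)
        assert np.all(np.abs(axis.points[:, 1] - 8.0) <= 0.5 * VOX[1] + 1e-9)
        # endpoints within 2 μm of the mask extremes (x from 2 to 38 μm)
        assert axis.points[0, 2] <= 4.0
        assert axis.points[-1, 2] >= 36.0

    def test_curved_fiber_axis_within_one_voxel(self):
        # analytic tube mask around a circular arc of radius 50 μm (y-x plane)
        arc_r, tube_r, cz = 50.0, 2.5, 6.0
        yc, xc = -20.0, 24.0  # arc center, off-grid
        shape = (30, 90, 120)
        z, y, x = sg._grid_coords(shape, VOX)
        d = np.sqrt((y - yc) ** 2 + (x - xc) ** 2)
        phi = np.arctan2(y - yc, x - xc)
        mask = (((d - arc_r) ** 2 + (z - cz) ** 2) <= tube_r ** 2) \
            & (phi > 1.08) & (phi < 1.57)
        axis = fg.extract_axis(mask, VOX)
        dist_to_arc = np.sqrt(
            (np.sqrt((axis.points[:, 1] - yc) ** 2 + (axis.points[:, 2] - xc) ** 2)
             - arc_r) ** 2 + (axis.points[:, 0] - cz) ** 2)
        assert dist_to_arc.max() <= max(VOX)

    def test_blob_rejected(self):
        cfg = sg.SceneConfig(
            shape=(40, 40, 40), voxel_size=VOX,
            nuclei=[sg.Nucleus((8.0, 8.0, 8.0), (5.0, 5.0, 5.0))]).noise_free()
        stack, _ = sg.render_scene(cfg)
        blob = stack.channel("nuclei") > 0
        with pytest.raises(NotAFiberError):
            fg.extract_axis(blob, VOX)


class TestDiameterFitting:
    def test_recovers_six_micron_diameter(self):
        cfg = make_fiber_scene(radius=3.0)
        stack, _ = sg.render_scene(cfg)
        axis, _ = fitted_axis(stack)
        s = axis.arclength
        interior = (s > 2) & (s < s[-1] - 2)
        d = 2 * axis.local_radius[interior]
        assert np.isfinite(d).all()
        assert np.mean(np.abs(d - 6.0) <= 0.5 + 1e-9) >= 0.95

    def test_matches_sampled_template_oracle_on_coarse_grid(self):
        """Analytic radial-histogram scores agree with brute-force sampled
        templates: both pick the same best candidate on a coarse 2-μm grid."""
        cfg = make_fiber_scene(radius=3.0)
        stack, _ = sg.render_scene(cfg)
        labels = fg.segment_fibers(stack, threshold=0.5)
        mask = labels == 1
        axis = fg.extract_axis(mask, VOX)
        cand = np.arange(2.0, 12.1, 2.0)
        fit = fg.fit_local_diameter(mask, axis, cand, VOX)
        tangents = axis.tangents()
        mid = len(axis.points) // 2
        for i in (mid - 4, mid, mid + 4):
            oracle = [sampled_template_score(mask, VOX, axis.points[i],
                                             tangents[i], D) for D in cand]
            assert cand[int(np.argmax(oracle))] == 2 * fit.local_radius[i]
            assert 2 * fit.local_radius[i] == 6.0  # nearest grid value wins

    def test_dilated_mask_grows_diameter_at_most_two_voxels(self):
        from scipy import ndimage
        cfg = make_fiber_scene(radius=3.0)
        stack, _ = sg.render_scene(cfg)
        mask = stack.channel("fiber") > 0.5
        axis = fg.extract_axis(mask, VOX)
        base = fg.fit_local_diameter(mask, axis, voxel_size=VOX)
        dilated = ndimage.binary_dilation(mask)
        grown = fg.fit_local_diameter(dilated, axis, voxel_size=VOX)
        delta = 2 * (grown.local_radius - base.local_radius)
        ok = np.isfinite(delta)
        assert np.all(delta[ok] >= -1e-9)
        assert np.all(delta[ok] <= 2 * 2 * max(VOX) + 1e-9)

    def test_axis_point_outside_mask_flagged(self):
        cfg = make_fiber_scene(radius=3.0)
        stack, _ = sg.render_scene(cfg)
        mask = stack.channel("fiber") > 0.5
        axis = fg.extract_axis(mask, VOX)
        hollowed = mask.copy()
        hollowed[:, :, 45:55] = False  # carve out the middle
        fit = fg.fit_local_diameter(hollowed, axis, voxel_size=VOX)
        assert np.isnan(fit.local_radius).any()

    def test_diameter_recovery_across_range(self):
        """Median |assigned - true| <= 0.5 μm over noise-free fibers 2-16 μm."""
        errors = []
        for i, diam in enumerate(np.linspace(2.0, 16.0, 8)):
            r = diam / 2
            margin = int(np.ceil((r + 3) / VOX[0]))
            length = max(20.0, 4.5 * diam)
            nx = int(np.ceil((length + 4) / VOX[2]))
            cfg = sg.SceneConfig(
                shape=(2 * margin, 2 * margin, nx), voxel_size=VOX,
                fibers=[sg.Fiber((margin * VOX[0], margin * VOX[1], 2.0),
                                 (0, 0, 1), r, length)]).noise_free()
            stack, _ = sg.render_scene(cfg)
            axis, _ = fitted_axis(stack)
            s = axis.arclength
            interior = (s > 2) & (s < s[-1] - 2)
            d = 2 * axis.local_radius[interior]
            errors.extend(np.abs(d[np.isfinite(d)] - diam))
        assert np.median(errors) <= 0.5


@pytest.fixture(scope="module")
def two_fiber_scene():
    cfg = sg.SceneConfig(
        shape=(48, 48, 100), voxel_size=VOX,
        fibers=[sg.Fiber((5.0, 5.0, 2.0), (0, 0, 1), 2.0, 36.0),
                sg.Fiber((14.0, 14.0, 2.0), (0, 0, 1), 2.0, 36.0)],
        bands=[sg.Band(fiber=0, axial_center=18.0, axial_width=4.0,
                       coverage_deg=360.0, thickness=1.0)]).noise_free()
    stack, truth = sg.render_scene(cfg)
    labels = fg.segment_fibers(stack, threshold=0.5)
    axes = []
    for lab in (1, 2):
        a = fg.extract_axis(labels == lab, VOX, fiber_id=lab)
        axes.append(fg.fit_local_diameter(labels == lab, a, voxel_size=VOX))
    return stack, truth, axes


class TestAttachment:
    def test_only_banded_fiber_has_attachment_points(self, two_fiber_scene):
        stack, truth, axes = two_fiber_scene
        cells = fg.segment_cells(stack, threshold=0.5, min_volume_um3=10.0)
        flags = fg.attachment_sites(axes, cells, VOX, reach=2.0)
        # identify which extracted axis is the banded fiber (anchor y = 5 μm)
        banded = 0 if abs(axes[0].points[0, 1] - 5.0) < 1 else 1
        assert flags[banded].any()
        assert not flags[1 - banded].any()
        band = truth.bands[0]
        s_at = axes[banded].arclength[flags[banded]]
        centers = axes[banded].points[flags[banded], 2]  # x μm
        # attachment extends past the band's axial span by at most
        # local_radius + reach (the radial offset counts toward the distance)
        lo = 2.0 + band.axial_center - band.axial_width / 2 - (2.0 + 2.0)
        hi = 2.0 + band.axial_center + band.axial_width / 2 + (2.0 + 2.0)
        assert centers.min() >= lo - 0.5 and centers.max() <= hi + 0.5
        assert len(s_at) > 0

    def test_empty_cell_mask_all_false(self, two_fiber_scene):
        _, _, axes = two_fiber_scene
        flags = fg.attachment_sites(axes, np.zeros((48, 48, 100), bool), VOX)
        assert not any(f.any() for f in flags)

    def test_full_cell_mask_all_true(self, two_fiber_scene):
        _, _, axes = two_fiber_scene
        flags = fg.attachment_sites(axes, np.ones((48, 48, 100), bool), VOX)
        assert all(f.all() for f in flags)


class TestDistributionComparison:
    @staticmethod
    def _axes_from_diameters(diams, flags):
        pts = np.column_stack([np.zeros(len(diams)), np.zeros(len(diams)),
                               np.arange(len(diams)) * 0.5])
        axis = fg.FiberAxis(pts, np.asarray(diams) / 2, 0)
        return [axis], [np.asarray(flags, bool)]

    def test_identical_samples_ks_zero(self):
        d = np.linspace(4, 14, 30)
        axes, flags = self._axes_from_diameters(d, np.ones(30))
        res = fg.compare_diameter_distributions(axes, flags)
        assert res.ks_statistic == 0.0
        assert res.max_qq_deviation == 0.0

    def test_thin_biased_subset_falls_below_identity(self):
        overall = np.arange(4.0, 14.0 + 1e-9, 0.25)
        thin = overall <= 9.0
        axes, flags = self._axes_from_diameters(overall, thin)
        res = fg.compare_diameter_distributions(axes, flags)
        pct = np.arange(1, 100)
        # brute-force quantiles on the two explicit sets
        q_all = np.percentile(overall, pct)
        q_att = np.percentile(overall[thin], pct)
        np.testing.assert_allclose(res.qq_pairs[:, 0], q_all)
        np.testing.assert_allclose(res.qq_pairs[:, 1], q_att)
        upper = pct >= 60
        assert np.all(res.qq_pairs[upper, 1] < res.qq_pairs[upper, 0])
        assert 0 < res.ks_statistic <= 1

    def test_histograms_normalized_on_shared_grid(self):
        d = np.linspace(4, 14, 40)
        axes, flags = self._axes_from_diameters(d, d < 9)
        res = fg.compare_diameter_distributions(axes, flags)
        assert np.isclose(res.hist_overall.sum(), 1.0)
        assert np.isclose(res.hist_attachment.sum(), 1.0)
        assert len(res.hist_overall) == len(res.bin_edges) - 1

    def test_small_group_raises(self):
        d = np.linspace(4, 14, 30)
        axes, flags = self._axes_from_diameters(d, np.arange(30) < 5)
        with pytest.raises(InsufficientDataError):
            fg.compare_diameter_distributions(axes, flags)
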