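"""Sensitivity matrix, difference imaging and pixel analysis."""

import numpy as np
import pytest

from eitresp.reconstruct import (
    ReconstructionError,
    build_jacobian,
    correlate_pixels,
    make_pixel_grid,
    pixel_series,
    reconstruct_diff,
    reconstruct_series,
)
from eitresp.simulator import ForwardModel, disk_mesh
from eitresp.simulator.phantom import Ellipse, ThoraxPhantom

LUNG = Ellipse(center=(0.45, 0.0), semi_axes=(0.30, 0.42))


@pytest.fixture(scope="module")
def jac_tiny(protocol16, mesh_tiny):
    return build_jacobian(mesh_tiny, 0.5, protocol16)


@pytest.fixture(scope="module")
def jac_recon(protocol16):
    return build_jacobian(disk_mesh(6, 32), 0.48, protocol16)


class TestJacobian:
    def test_shape(self, jac_tiny, mesh_tiny):
        assert jac_tiny.matrix.shape == (208, mesh_tiny.n_elements)
        assert np.isfinite(jac_tiny.matrix).all()

    def test_finite_difference_oracle(self, protocol16, mesh_tiny, jac_tiny):
        """Brute-force perturbation of the forward model, element by element."""
        sigma = np.full(mesh_tiny.n_elements, 0.5)
        base = ForwardModel(mesh_tiny, sigma).solve_protocol(protocol16).ravel()
        fd = np.empty_like(jac_tiny.matrix)
        delta = 1e-6
        for e in range(mesh_tiny.n_elements):
            s = sigma.copy()
            s[e] += delta
            fd[:, e] = (
                ForwardModel(mesh_tiny, s).solve_protocol(protocol16).ravel() - base
            ) / delta
        rel = np.abs(fd - jac_tiny.matrix).max() / np.abs(jac_tiny.matrix).max()
        assert rel < 1e-3

    def test_reference_scaling(self, protocol16, mesh_tiny, jac_tiny):
        """Analytic: sensitivities scale as 1 / sigma^2."""
        jac2 = build_jacobian(mesh_tiny, 1.0, protocol16)
        np.testing.assert_allclose(jac2.matrix, jac_tiny.matrix * 0.25, rtol=1e-10)

    def test_zero_perturbation_zero_prediction(self, jac_tiny, mesh_tiny):
        dv = jac_tiny.matrix @ np.zeros(mesh_tiny.n_elements)
        np.testing.assert_array_equal(dv, 0.0)

    def test_rejects_bad_reference(self, protocol16, mesh_tiny):
        with pytest.raises(ReconstructionError):
            build_jacobian(mesh_tiny, 0.0, protocol16)


class TestReconstructDiff:
    def test_zero_difference_zero_image(self, jac_tiny):
        v = np.ones(208)
        img = reconstruct_diff(v, v, jac_tiny)
        np.testing.assert_allclose(img.element_values, 0.0, atol=1e-15)
        inside = img.grid.mask
        np.testing.assert_allclose(img.pixels[inside], 0.0, atol=1e-15)
        assert np.isnan(img.pixels[~inside]).all()

    def test_single_inclusion_localized(self, protocol16, jac_recon):
        """Known-inclusion oracle: centroid lands inside the true ellipse."""
        mesh = jac_recon.mesh
        sigma = np.full(mesh.n_elements, 0.48)
        cent = mesh.element_centroids()
        sigma[LUNG.contains(cent)] = 0.48 * 0.8
        v_ref = ForwardModel(mesh, 0.48).solve_protocol(protocol16).ravel()
        v_inc = ForwardModel(mesh, sigma).solve_protocol(protocol16).ravel()
        img = reconstruct_diff(v_inc, v_ref, jac_recon)
        ds = img.element_values
        assert ds.min() < 0  # conductivity drop reconstructed as negative
        w = np.maximum(0.0, -ds) * mesh.element_areas()
        cx = (w * cent[:, 0]).sum() / w.sum()
        cy = (w * cent[:, 1]).sum() / w.sum()
        err = np.hypot(cx - LUNG.center[0], cy - LUNG.center[1])
        assert err < max(LUNG.semi_axes) / 2
        assert LUNG.contains(np.array([cx, cy]))

    def test_lambda_monotonicity(self, protocol16, jac_recon, rng):
        dv = rng.normal(0, 1e-3, 208)
        zeros = np.zeros(208)
        norms = [
            np.linalg.norm(reconstruct_diff(dv, zeros, jac_recon, lam=lam).element_values)
            for lam in [1e-3, 2e-3, 4e-3, 1e-2, 1e-1]
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_input_validation(self, jac_tiny):
        with pytest.raises(ReconstructionError):
            reconstruct_diff(np.zeros(100), np.zeros(208), jac_tiny)
        with pytest.raises(ReconstructionError):
            reconstruct_diff(np.zeros(208), np.zeros(208), jac_tiny, lam=0.0)


class TestPixelGrid:
    def test_minimum_size(self, mesh_tiny):
        with pytest.raises(ReconstructionError):
            make_pixel_grid(mesh_tiny, 20)

    def test_row_zero_is_top(self, mesh_tiny):
        grid = make_pixel_grid(mesh_tiny, 32)
        # corners of the bounding square lie outside the disk
        assert not grid.mask[0, 0]
        assert not grid.mask[31, 31]
        assert grid.mask[16, 16]

    def test_map_dimensions(self, mesh_tiny):
        grid = make_pixel_grid(mesh_tiny, 32)
        assert grid.element_of_pixel.shape == (32, 32)


class TestPixelAnalysis:
    @pytest.fixture(scope="class")
    def breathing_images(self, protocol16, jac_recon):
        """Frames of a breathing phantom reconstructed against frame 0."""
        mesh = jac_recon.mesh
        phantom = ThoraxPhantom()
        t = np.arange(40) / 2.0
        volume = 0.4 * (1 - np.cos(2 * np.pi * t / 4.0))
        V = np.empty((208, t.size))
        for f, vol in enumerate(volume):
            sigma = phantom.element_sigma(mesh, float(vol))
            V[:, f] = ForwardModel(mesh, sigma).solve_protocol(protocol16).ravel()
        # a touch of measurement noise: with a single latent source every
        # pixel would otherwise correlate at exactly +/-1
        rng = np.random.default_rng(7)
        V = V * (1 + 2e-4 * rng.normal(size=V.shape))
        images = reconstruct_series(V, jac_recon)
        return images, volume

    def test_static_series_constant(self, jac_recon):
        V = np.tile(np.ones(208)[:, None], (1, 12))
        images = reconstruct_series(V, jac_recon)
        grid = images[0].grid
        row, col = map(int, np.argwhere(grid.mask)[0])
        series = pixel_series(images, row, col)
        np.testing.assert_allclose(series, series[0])

    def test_lung_pixel_tracks_volume(self, breathing_images):
        images, volume = breathing_images
        grid = images[0].grid
        # a pixel at the right-lung centre
        size = grid.size
        col = int(round((0.45 + 1) / 2 * size))
        row = size // 2
        assert grid.mask[row, col]
        series = pixel_series(images, row, col)
        r = np.corrcoef(series, volume)[0, 1]
        assert abs(r) > 0.8
        assert r < 0  # inspiration drops lung conductivity

    def test_correlation_map_and_best_pixel(self, breathing_images):
        images, volume = breathing_images
        rmap, best = correlate_pixels(images, volume)
        grid = images[0].grid
        assert rmap.shape == (grid.size, grid.size)
        assert np.isnan(rmap[~grid.mask]).all()
        # the best pixel falls in a lung region; the regularized image
        # blurs slightly past the true boundary, hence the 1.4x margin
        size = grid.size
        x = -1 + (best[1] + 0.5) * 2 / size
        y = 1 - (best[0] + 0.5) * 2 / size
        in_lung = any(
            Ellipse(e.center, (1.4 * e.semi_axes[0], 1.4 * e.semi_axes[1])).contains(
                np.array([x, y])
            )
            for e in ThoraxPhantom().lungs
        )
        assert in_lung

    def test_pixel_breath_detection(self, breathing_images):
        """Breaths detected on the best pixel series: Se = 1 on clean data."""
        from eitresp.breaths import detect_extrema, upsample_voltage

        images, volume = breathing_images
        rmap, best = correlate_pixels(images, volume)
        series = pixel_series(images, *best)
        sign = np.sign(rmap[best])
        ups = upsample_voltage(sign * series, fs_in=2.0, factor=100)
        ann = detect_extrema(ups, 200.0)
        truth = upsample_voltage(volume, fs_in=2.0, factor=100)
        truth_ann = detect_extrema(truth, 200.0)
        assert len(ann.peaks) == len(truth_ann.peaks)

    def test_background_pixel_rejected(self, jac_recon):
        V = np.tile(np.ones(208)[:, None], (1, 12))
        images = reconstruct_series(V, jac_recon)
        with pytest.raises(ReconstructionError):
            pixel_series(images, 0, 0)

    def test_too_few_frames(self, jac_recon):
        V = np.tile(np.ones(208)[:, None], (1, 5))
        images = reconstruct_series(V, jac_recon)
        with pytest.raises(ReconstructionError):
            correlate_pixels(images, np.zeros(5))
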