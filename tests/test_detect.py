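"""Measurement pipeline: masking, smoothing, detection, fitting, selection."""

import math

import numpy as np
import pytest

from telofish import (
    GaussianFit,
    ImageStack,
    NucleusMask,
    VoxelSize,
    detect_spots,
    fit_spot,
    mask_nuclei,
    match_to_truth,
    measure_stack,
    render_scene,
    select_brightness,
    smooth_stack,
)
from telofish.simulate import NucleusEllipsoid, SceneTruth, SpotTruth, generate_scene

from conftest import small_params


def _full_mask(shape):
    return NucleusMask(np.ones(shape, dtype=np.int32))


class TestNucleusMasking:
    def test_single_ellipsoid_high_jaccard(self, small_scene):
        truth, dapi, _ = small_scene
        mask = mask_nuclei(dapi)
        assert mask.n_nuclei == 1
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in dapi.shape], indexing="ij")
        grid = np.stack([zz * 200.0, yy * 80.0, xx * 80.0], axis=-1)
        inside = truth.nucleus.contains(grid)
        got = mask.labels > 0
        jaccard = np.logical_and(inside, got).sum() / np.logical_or(inside, got).sum()
        assert jaccard >= 0.95

    def test_two_disjoint_nuclei_two_labels(self):
        vs = VoxelSize()
        shape = (16, 64, 128)
        data = np.zeros(shape)
        n1 = NucleusEllipsoid((1500.0, 2500.0, 2500.0), (1000.0, 1800.0, 1800.0))
        n2 = NucleusEllipsoid((1500.0, 2500.0, 7500.0), (1000.0, 1800.0, 1800.0))
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        grid = np.stack([zz * 200.0, yy * 80.0, xx * 80.0], axis=-1)
        data[n1.contains(grid)] = 120
        data[n2.contains(grid)] = 120
        mask = mask_nuclei(ImageStack(data, vs, "dapi"))
        assert mask.n_nuclei == 2
        for nucleus in (n1, n2):
            cz, cy, cx = (int(round(c / s)) for c, s in zip(nucleus.center_nm, vs.zyx_nm))
            assert mask.labels[cz, cy, cx] > 0
        assert mask.labels[int(1500 / 200), int(2500 / 80), int(2500 / 80)] != \
               mask.labels[int(1500 / 200), int(2500 / 80), int(7500 / 80)]

    def test_all_zero_dapi_warns_and_returns_empty(self):
        stack = ImageStack(np.zeros((5, 8, 8)), VoxelSize(), "dapi")
        with pytest.warns(UserWarning, match="empty nucleus mask"):
            mask = mask_nuclei(stack)
        assert mask.n_nuclei == 0


class TestSmoothing:
    def test_constant_stack_unchanged(self):
        stack = ImageStack(np.full((6, 10, 10), 42.0), VoxelSize())
        out = smooth_stack(stack, sigma_nm=80)
        np.testing.assert_allclose(out.voxels, 42.0)

    def test_impulse_response_matches_brute_force_kernel(self):
        """Unit impulse response equals direct separable-Gaussian convolution."""
        vs = VoxelSize()
        data = np.zeros((15, 21, 21))
        data[7, 10, 10] = 1.0
        out = smooth_stack(ImageStack(data, vs), sigma_nm=80).voxels

        def kernel(sigma_vox):
            r = int(4.0 * sigma_vox + 0.5)
            x = np.arange(-r, r + 1, dtype=float)
            k = np.exp(-(x**2) / (2 * sigma_vox**2))
            return k / k.sum()

        kz, ky, kx = kernel(80 / 200), kernel(80 / 80), kernel(80 / 80)
        oracle = np.zeros_like(data)
        for dz_i, wz in enumerate(kz):
            for dy_i, wy in enumerate(ky):
                for dx_i, wx in enumerate(kx):
                    oracle[7 + dz_i - len(kz) // 2,
                           10 + dy_i - len(ky) // 2,
                           10 + dx_i - len(kx) // 2] += wz * wy * wx
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_total_intensity_conserved(self, rng):
        data = rng.uniform(0, 100, size=(10, 20, 20))
        stack = ImageStack(data, VoxelSize())
        out = smooth_stack(stack, sigma_nm=80)
        assert out.voxels.sum() == pytest.approx(data.sum(), rel=1e-9)

    def test_invalid_sigma(self):
        stack = ImageStack(np.zeros((2, 2, 2)), VoxelSize())
        with pytest.raises(ValueError):
            smooth_stack(stack, sigma_nm=0)


class TestSpotDetection:
    def test_subthreshold_stack_yields_nothing(self):
        data = np.full((8, 16, 16), 20.0)
        stack = ImageStack(data, VoxelSize())
        assert detect_spots(stack, _full_mask(data.shape), threshold=25, min_voxels=10) == []

    @pytest.mark.parametrize("n_voxels,expected", [(9, 0), (10, 1)])
    def test_minimum_spot_size_boundary(self, n_voxels, expected):
        """A 9-voxel supra-threshold region is rejected; 10 voxels are accepted."""
        data = np.zeros((9, 17, 17))
        # one connected region of exactly n_voxels voxels above 25, with values
        # decreasing away from the centre so it holds a single local maximum
        coords_vals = (
            [((4, 8, 8), 60.0)]
            + [((4, 8, 8 + d), 46.0 - abs(d)) for d in (-1, 1)]
            + [((4, 8 + d, 8), 44.0 - abs(d)) for d in (-1, 1)]
            + [((4, 8, 8 + d), 32.0 - abs(d)) for d in (-2, 2)]
            + [((4, 8 + d, 8), 30.0 - abs(d)) for d in (-2, 2)]
            + [((3, 8, 8), 27.0), ((5, 8, 8), 26.0)]
        )
        for (z, y, x), v in coords_vals[:n_voxels]:
            data[z, y, x] = v
        stack = ImageStack(data, VoxelSize())
        spots = detect_spots(stack, _full_mask(data.shape), threshold=25, min_voxels=10)
        assert len(spots) == expected

    def test_overlapping_spots_are_split_and_localized(self):
        """Two spots 400 nm apart (overlapping tails) give two candidates, each
        within one voxel of its truth position."""
        params = small_params(background_counts=0.0, lognormal_sigma=0.0,
                              lognormal_mu=math.log(300.0))
        nucleus = NucleusEllipsoid((1900.0, 3800.0, 3800.0), (1500.0, 3000.0, 3000.0))
        spots = [
            SpotTruth(x_nm=3600.0, y_nm=3800.0, z_nm=1800.0, amplitude_counts=300.0),
            SpotTruth(x_nm=4000.0, y_nm=3800.0, z_nm=1800.0, amplitude_counts=300.0),
        ]
        truth = SceneTruth(nucleus=nucleus, spots=spots, params=params, seed=0)
        _, telo = render_scene(truth, quantize=False)
        smoothed = smooth_stack(telo, sigma_nm=80)
        cands = detect_spots(smoothed, _full_mask(telo.shape), threshold=25, min_voxels=10)
        assert len(cands) == 2
        got = sorted(c.center_of_mass_nm[2] for c in cands)
        for measured_x, true_x in zip(got, [3600.0, 4000.0]):
            assert abs(measured_x - true_x) <= 80.0
        for c in cands:
            assert abs(c.center_of_mass_nm[0] - 1800.0) <= 200.0
            assert abs(c.center_of_mass_nm[1] - 3800.0) <= 80.0

    def test_shape_mismatch_raises(self):
        stack = ImageStack(np.zeros((4, 8, 8)), VoxelSize())
        with pytest.raises(ValueError, match="shapes differ"):
            detect_spots(stack, _full_mask((4, 8, 9)))

    def test_voxels_outside_mask_never_contribute(self):
        data = np.zeros((9, 17, 17))
        data[4, 8, 4:15] = 80.0  # bright bar crossing the mask edge
        mask = np.zeros(data.shape, dtype=np.int32)
        mask[:, :, :9] = 1
        spots = detect_spots(ImageStack(data, VoxelSize()), NucleusMask(mask),
                             threshold=25, min_voxels=3)
        for s in spots:
            assert s.center_of_mass_nm[2] < 9 * 80.0


class TestGaussianFitting:
    def _render_single(self, amplitude=100.0, offset=(0.0, 0.0, 0.0), noise=False, seed=0):
        params = small_params(background_counts=0.0, poisson_noise=noise)
        nucleus = NucleusEllipsoid((1900.0, 3800.0, 3800.0), (1500.0, 3000.0, 3000.0))
        spot = SpotTruth(x_nm=3840.0 + offset[2], y_nm=3840.0 + offset[1],
                         z_nm=1800.0 + offset[0], amplitude_counts=amplitude)
        truth = SceneTruth(nucleus=nucleus, spots=[spot], params=params, seed=seed)
        _, telo = render_scene(truth, rng=seed, quantize=noise)
        return telo, spot

    def test_noiseless_on_grid_spot_recovers_amplitude_exactly(self):
        telo, spot = self._render_single()
        from telofish.detect import SpotCandidate

        cand = SpotCandidate(center_of_mass_nm=spot.zyx_nm, voxel_count=50,
                             peak_smoothed_counts=80.0, nucleus_label=1)
        fx, fy = fit_spot(telo, cand, window_halfwidth=5)
        for f in (fx, fy):
            assert f.amplitude_counts == pytest.approx(100.0, rel=1e-3)
            assert f.r_squared > 0.999
            assert f.sigma_nm == pytest.approx(120.0, rel=0.01)

    def test_flat_profile_fails_the_gate(self):
        telo = ImageStack(np.full((9, 17, 17), 30.0), VoxelSize())
        from telofish.detect import SpotCandidate

        cand = SpotCandidate(center_of_mass_nm=(800.0, 640.0, 640.0), voxel_count=10,
                             peak_smoothed_counts=30.0, nucleus_label=1)
        fx, fy = fit_spot(telo, cand)
        assert fx.r_squared <= 0.8 and fy.r_squared <= 0.8
        m = select_brightness(fx, fy)
        assert not m.accepted

    def test_poisson_amplitude_estimation_near_unbiased(self):
        """Median fitted amplitude over 200 noisy replicates within 5% of truth."""
        from telofish.detect import SpotCandidate

        params = small_params(background_counts=5.0, poisson_noise=True,
                              n_spots_per_nucleus=1, shape_zyx=(12, 24, 24),
                              nucleus_semi_axes_nm=(700.0, 800.0, 800.0))
        nucleus = NucleusEllipsoid((1100.0, 920.0, 920.0), params.nucleus_semi_axes_nm)
        spot = SpotTruth(x_nm=960.0, y_nm=960.0, z_nm=1000.0, amplitude_counts=100.0)
        truth = SceneTruth(nucleus=nucleus, spots=[spot], params=params, seed=0)
        cand = SpotCandidate(center_of_mass_nm=spot.zyx_nm, voxel_count=20,
                             peak_smoothed_counts=70.0, nucleus_label=1)
        rng = np.random.default_rng(2024)
        amps = []
        for _ in range(200):
            _, telo = render_scene(truth, rng=rng)
            fx, fy = fit_spot(telo, cand)
            best = fx if fx.r_squared >= fy.r_squared else fy
            amps.append(best.amplitude_counts)
        assert np.median(amps) == pytest.approx(100.0, rel=0.05)

    def test_truncated_profile_needs_seven_points(self):
        from telofish.detect import SpotCandidate

        data = np.zeros((5, 17, 17))
        data[2, 8, 2] = 50.0
        telo = ImageStack(data, VoxelSize())
        cand = SpotCandidate(center_of_mass_nm=(400.0, 640.0, 160.0), voxel_count=10,
                             peak_smoothed_counts=50.0, nucleus_label=1)
        fx, _ = fit_spot(telo, cand, window_halfwidth=5)
        # 8 points remain along x (2-window clipped at 0): still fit
        assert fx.valid
        cand_edge = SpotCandidate(center_of_mass_nm=(400.0, 640.0, 0.0), voxel_count=10,
                                  peak_smoothed_counts=50.0, nucleus_label=1)
        fx_edge, _ = fit_spot(telo, cand_edge, window_halfwidth=5)
        assert not fx_edge.valid  # only 6 points survive


class TestBrightnessSelection:
    def _fit(self, axis, r2, amp=100.0):
        return GaussianFit(axis=axis, amplitude_counts=amp, center_nm=0.0,
                           sigma_nm=120.0, offset_counts=0.0, r_squared=r2)

    def test_better_fit_wins(self):
        m = select_brightness(self._fit("x", 0.95, 70.0), self._fit("y", 0.85, 80.0))
        assert m.accepted and m.best_fit.axis == "x" and m.brightness_counts == 70.0

    def test_gate_is_strict_inequality(self):
        m = select_brightness(self._fit("x", 0.79), self._fit("y", 0.80))
        assert not m.accepted
        m2 = select_brightness(self._fit("x", 0.79), self._fit("y", 0.801))
        assert m2.accepted

    def test_exact_tie_goes_to_x(self):
        m = select_brightness(self._fit("x", 0.9, 50.0), self._fit("y", 0.9, 60.0))
        assert m.accepted and m.brightness_counts == 50.0 and m.best_fit.axis == "x"


class TestFullPipeline:
    def test_empty_scene_yields_no_measurements(self):
        params = small_params(n_spots_per_nucleus=0)
        truth = generate_scene(params, seed=0)
        dapi, telo = render_scene(truth)
        assert measure_stack(dapi, telo) == []

    def test_measurements_stay_inside_nuclei(self, noisy_scene):
        _, dapi, telo = noisy_scene
        for m in measure_stack(dapi, telo):
            assert m.spot.nucleus_label > 0

    def test_localization_within_one_voxel(self, small_scene):
        truth, dapi, telo = small_scene
        ms = measure_stack(dapi, telo)
        matches = match_to_truth(ms, truth)
        assert len(matches) >= 0.8 * len(truth.spots)
        spacing = np.array([200.0, 80.0, 80.0])
        for mi, ti in matches:
            delta = np.abs(np.array(ms[mi].spot.center_of_mass_nm) - truth.positions_zyx_nm()[ti])
            assert np.all(delta <= spacing)

    def test_brightness_is_scale_equivariant(self):
        """Doubling all truth amplitudes doubles the median measured brightness."""
        params = small_params(background_counts=0.0)
        truth = generate_scene(params, seed=21)
        doubled = SceneTruth(
            truth.nucleus,
            [SpotTruth(s.x_nm, s.y_nm, s.z_nm, 2 * s.amplitude_counts) for s in truth.spots],
            params, truth.seed,
        )
        medians = []
        for scene in (truth, doubled):
            dapi, telo = render_scene(scene, quantize=False)
            ms = [m for m in measure_stack(dapi, telo) if m.accepted]
            medians.append(np.median([m.brightness_counts for m in ms]))
        assert medians[1] / medians[0] == pytest.approx(2.0, rel=0.02)
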