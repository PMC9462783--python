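"""Illumination-parameter recovery: masks, peaks, phases, sub-pixel frequency."""

import numpy as np
import pytest

import stripesim as ss
from stripesim._fft import ft2
from stripesim.errors import InvalidArgumentError, NoPeakError, UndefinedPhaseError
from stripesim.parameter_estimation import band_cross_correlation

from conftest import canonical_k_and_phases, wrapped_angle_diff_deg


class TestBandpassMask:
    def test_dc_always_excluded(self):
        mask = ss.bandpass_mask((64, 64), 1e-6, 0.5)
        assert not mask[32, 32]

    def test_invalid_radii(self):
        with pytest.raises(InvalidArgumentError):
            ss.bandpass_mask((64, 64), 0.3, 0.1)

    def test_area_monotone_in_outer_radius(self):
        areas = [ss.bandpass_mask((64, 64), 0.05, r).sum() for r in (0.1, 0.2, 0.4, 0.8)]
        assert all(a < b for a, b in zip(areas, areas[1:]))

    def test_large_outer_radius_keeps_everything_beyond_inner(self):
        mask = ss.bandpass_mask((64, 64), 0.1, 10.0)
        from stripesim._fft import radial_frequency

        r = radial_frequency((64, 64))
        assert np.array_equal(mask, (r >= 0.1))


class TestWienerPrefilter:
    def test_flat_otf_small_sigma_is_identity(self):
        rng = np.random.default_rng(0)
        spec = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        out = ss.wiener_prefilter(spec, np.ones((32, 32)), sigma=1e-12)
        assert np.abs(out - spec).max() < 1e-9

    def test_zero_otf_gives_zero(self):
        spec = np.ones((16, 16), dtype=complex)
        otf = np.zeros((16, 16))
        assert np.all(ss.wiener_prefilter(spec, otf, 0.1) == 0.0)

    def test_phase_preserved_for_positive_otf(self):
        rng = np.random.default_rng(1)
        spec = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        otf = rng.uniform(0.1, 1.0, (16, 16))
        out = ss.wiener_prefilter(spec, otf, 0.05)
        assert np.abs(np.angle(out) - np.angle(spec)).max() < 1e-12

    def test_sigma_must_be_positive(self):
        with pytest.raises(InvalidArgumentError):
            ss.wiener_prefilter(np.ones((8, 8)), np.ones((8, 8)), 0.0)


class TestFindModulationPeak:
    def test_on_grid_peak_located(self, system_small):
        n = 128
        truth = ss.make_ground_truth("custom", (n, n), values=np.ones((n, n)))
        k = np.array([[12 / n, 0.0]] * 3)
        model = ss.IlluminationModel(k_theta=k, phases_rad=np.zeros(9), m=0.8)
        frame = ss.simulate_frame(truth, system_small, model, 0)
        mask = ss.bandpass_mask((n, n), 5 / n, 30 / n)
        assert ss.find_modulation_peak(ft2(frame), mask) == (12, 0)

    def test_hermitian_pair_resolved_to_positive_x(self):
        spec = np.zeros((64, 64), dtype=complex)
        spec[32 - 5, 32 - 9] = 10.0  # (fx, fy) = (-9, -5)
        spec[32 + 5, 32 + 9] = 10.0
        mask = np.ones((64, 64), dtype=bool)
        assert ss.find_modulation_peak(spec, mask) == (9, 5)

    def test_unmodulated_data_raises(self, bead_truth_small, system_small):
        wf = ss.widefield_reference(bead_truth_small, system_small)
        stack = ss.RawStack(frames=np.stack([wf] * 9))
        otf = ss.analytic_otf(system_small)
        with pytest.raises(NoPeakError, match="orientation 0"):
            ss.estimate_all(stack, otf)

    def test_empty_mask_raises(self):
        with pytest.raises(NoPeakError):
            ss.find_modulation_peak(np.ones((16, 16), dtype=complex), np.zeros((16, 16), bool))


class TestEstimatePhase:
    def _constant_sample_frame(self, system, phi, k_grid=(20, 0), n=128):
        truth = ss.make_ground_truth("custom", (n, n), values=np.ones((n, n)))
        k = np.array([[k_grid[0] / n, k_grid[1] / n]] * 3)
        model = ss.IlluminationModel(k_theta=k, phases_rad=np.full(9, phi), m=0.8)
        return ss.simulate_frame(truth, system, model, 0)

    def test_zero_phase(self, system_small):
        frame = self._constant_sample_frame(system_small, 0.0)
        assert ss.estimate_phase(ft2(frame), (20, 0)) == pytest.approx(0.0, abs=1e-6)

    def test_ninety_degrees_sign_convention(self, system_small):
        """cos(2 pi k . r + phi) puts exp(+i phi) at +k_theta: a +90 deg
        stripe phase must read back as +pi/2, verified against direct
        summation of the field's DFT coefficient."""
        phi = np.pi / 2
        frame = self._constant_sample_frame(system_small, phi)
        assert ss.estimate_phase(ft2(frame), (20, 0)) == pytest.approx(phi, abs=1e-6)
        # independent direct-summation oracle on the raw field
        field = ss.illumination_field(
            ss.IlluminationModel(
                k_theta=np.array([[20 / 128, 0.0]] * 3),
                phases_rad=np.full(9, phi),
                m=0.8,
            ),
            0,
            (128, 128),
        )
        y, x = np.mgrid[0:128, 0:128]
        coeff = np.sum(field * np.exp(-2j * np.pi * (20 * (x - 64) / 128)))
        assert np.angle(coeff) == pytest.approx(phi, abs=1e-9)

    def test_phase_differences_sample_independent(self, system_small):
        """At an integer peak the absolute phase carries a sample-dependent
        offset, but the 120-degree steps between the three frames are
        recovered regardless of the sample — exactly for an on-grid
        frequency, where the conjugate band cannot leak into the peak."""
        n = 128
        rng = np.random.default_rng(5)
        sample = rng.random((n, n)) * 0.1 + 1.0  # dense sample, non-trivial
        truth = ss.make_ground_truth("custom", (n, n), values=sample)
        k = np.array([[20 / n, 0.0]] * 3)
        model = ss.IlluminationModel(
            k_theta=k, phases_rad=np.tile([0.3, 0.3 + 2 * np.pi / 3, 0.3 + 4 * np.pi / 3], 3),
            m=0.8,
        )
        stack = ss.simulate_stack(truth, system_small, model, noise=None, seed=5)
        frames = stack.orientation(0)
        avg = frames.mean(axis=0)
        phases = [ss.estimate_phase(ft2(f - avg), (20, 0)) for f in frames]
        d1 = np.rad2deg((phases[1] - phases[0]) % (2 * np.pi))
        d2 = np.rad2deg((phases[2] - phases[1]) % (2 * np.pi))
        assert d1 == pytest.approx(120.0, abs=1.0)
        assert d2 == pytest.approx(120.0, abs=1.0)

    def test_zero_value_raises(self):
        spec = np.zeros((16, 16), dtype=complex)
        with pytest.raises(UndefinedPhaseError):
            ss.estimate_phase(spec, (3, 2))


class TestRefineFrequency:
    def test_on_grid_frequency_is_fixed_point(self, system_small, otf_small):
        n = 128
        truth = ss.make_ground_truth("filaments", (n, n), seed=3)
        k = np.array([[12 / n, 0.0], [6 / n, 10 / n], [-6 / n, 10 / n]])
        model = ss.IlluminationModel(
            k_theta=k, phases_rad=np.tile([0, 2 * np.pi / 3, 4 * np.pi / 3], 3), m=0.8
        )
        stack = ss.simulate_stack(truth, system_small, model, noise=None, seed=3)
        k_est, ok = ss.refine_frequency_subpixel(stack.orientation(0), (12, 0), otf_small)
        assert ok
        assert np.abs(k_est - np.array([12 / n, 0.0])).max() < 1e-3  # cycles/px

    def test_off_grid_recovery(self, noiseless_stack_medium, model_medium, otf_medium):
        n = noiseless_stack_medium.shape[0]
        for o in range(3):
            coarse = tuple(np.round(model_medium.k_theta[o] * n).astype(int))
            k_est, ok = ss.refine_frequency_subpixel(
                noiseless_stack_medium.orientation(o), coarse, otf_medium
            )
            assert ok
            assert np.abs(k_est - model_medium.k_theta[o]).max() * n < 0.05

    def test_noisy_recovery(self, system_medium, model_medium, otf_medium):
        """Shot-noise-limited stacks (100 photons) still localise the
        frequency within 0.2 grid cycles."""
        n = 256
        failures = 0
        for seed in range(5):
            truth = ss.make_ground_truth("filaments", (n, n), seed=seed)
            stack = ss.simulate_stack(
                truth, system_medium, model_medium,
                noise=ss.NoiseModel(photons=100.0), seed=seed,
            )
            est = ss.estimate_all(stack, otf_medium)
            for o in range(3):
                k, _ = canonical_k_and_phases(
                    est.k_theta[o], est.orientation_phases(o), model_medium.k_theta[o]
                )
                if np.abs(k - model_medium.k_theta[o]).max() * n > 0.2:
                    failures += 1
        assert failures == 0


class TestEstimateAll:
    def test_noiseless_recovery(self, noiseless_stack_medium, model_medium, otf_medium):
        n = noiseless_stack_medium.shape[0]
        est = ss.estimate_all(noiseless_stack_medium, otf_medium)
        for o in range(3):
            k, ph = canonical_k_and_phases(
                est.k_theta[o], est.orientation_phases(o), model_medium.k_theta[o]
            )
            k_true = model_medium.k_theta[o]
            assert np.abs(k - k_true).max() * n < 0.05
            ang_est = np.rad2deg(np.arctan2(k[1], k[0]))
            ang_true = np.rad2deg(np.arctan2(k_true[1], k_true[0]))
            assert wrapped_angle_diff_deg(ang_est, ang_true, period=180.0) < 1.0
            dphi = wrapped_angle_diff_deg(
                np.rad2deg(ph), np.rad2deg(model_medium.phases_rad[3 * o : 3 * o + 3])
            )
            assert dphi.max() < 3.0

    def test_orientations_pairwise_sixty_degrees(self, noiseless_stack_medium, otf_medium):
        est = ss.estimate_all(noiseless_stack_medium, otf_medium)
        angles = np.sort(est.orientations_deg % 180.0)
        gaps = np.diff(angles)
        assert np.all(wrapped_angle_diff_deg(gaps, 60.0, period=180.0) < 1.0)

    def test_phases_wrapped(self, noiseless_stack_medium, otf_medium):
        est = ss.estimate_all(noiseless_stack_medium, otf_medium)
        assert np.all(est.phases_rad > -np.pi)
        assert np.all(est.phases_rad <= np.pi)

    def test_frame_shuffle_permutes_phases(self, noiseless_stack_medium, otf_medium):
        est = ss.estimate_all(noiseless_stack_medium, otf_medium)
        frames = noiseless_stack_medium.frames.copy()
        frames[[0, 1, 2]] = frames[[2, 0, 1]]
        shuffled = ss.RawStack(frames=frames, meta=noiseless_stack_medium.meta)
        est2 = ss.estimate_all(shuffled, otf_medium)
        assert np.abs(est2.k_theta[0] - est.k_theta[0]).max() * 256 < 0.02
        reordered = est.phases_rad[[2, 0, 1]]
        assert np.abs(
            np.angle(np.exp(1j * (est2.phases_rad[:3] - reordered)))
        ).max() < np.deg2rad(0.5)

    def test_transpose_equivariance(self, noiseless_stack_medium, otf_medium):
        est = ss.estimate_all(noiseless_stack_medium, otf_medium)
        transposed = ss.RawStack(
            frames=np.transpose(noiseless_stack_medium.frames, (0, 2, 1)),
            meta=noiseless_stack_medium.meta,
        )
        est_t = ss.estimate_all(transposed, otf_medium)
        for o in range(3):
            swapped, _ = canonical_k_and_phases(
                est_t.k_theta[o][::-1], est_t.orientation_phases(o), est.k_theta[o]
            )
            assert np.abs(swapped - est.k_theta[o]).max() * 256 < 0.02

    def test_degrades_monotonically_with_photon_count(self, system_medium, model_medium, otf_medium):
        """Median absolute phase error is non-decreasing as the photon
        budget drops 500 -> 100 -> 50."""
        n = 256
        medians = []
        for photons in (500.0, 100.0, 50.0):
            errors = []
            for seed in range(5):
                truth = ss.make_ground_truth("filaments", (n, n), seed=seed)
                stack = ss.simulate_stack(
                    truth, system_medium, model_medium,
                    noise=ss.NoiseModel(photons=photons), seed=seed,
                )
                est = ss.estimate_all(stack, otf_medium)
                for o in range(3):
                    _, ph = canonical_k_and_phases(
                        est.k_theta[o], est.orientation_phases(o), model_medium.k_theta[o]
                    )
                    errors.extend(
                        wrapped_angle_diff_deg(
                            np.rad2deg(ph),
                            np.rad2deg(model_medium.phases_rad[3 * o : 3 * o + 3]),
                        )
                    )
            medians.append(np.median(errors))
        assert medians[0] <= medians[1] <= medians[2]


class TestBandCrossCorrelation:
    def test_peak_at_signed_frequency(self, noiseless_stack_medium, model_medium, otf_medium):
        n = 256
        mask = ss.bandpass_mask((n, n), 0.3 * otf_medium.k_c_px, 1.1 * otf_medium.k_c_px)
        for o in range(3):
            corr = band_cross_correlation(noiseless_stack_medium.orientation(o), otf_medium)
            peak = ss.find_modulation_peak(corr, mask, half_plane=False)
            expected = model_medium.k_theta[o] * n
            assert np.abs(np.array(peak) - expected).max() < 1.5
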