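"""Illumination correction, spectral unmixing, calibration, segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eqdose.synthetic import (
    default_mixing_matrix,
    default_scene,
    gen_spectral_stack,
    quadratic_illumination,
)
from eqdose.unmixing import (
    CalibrationLine,
    MixingMatrix,
    build_mixing_matrix,
    calibrate,
    compartment_masks,
    correct_illumination,
    estimate_illumination,
    segment_cells,
    signal_to_concentration,
    unmix,
)

SHAPE = (96, 96)


class TestIllumination:
    def test_uniform_images_give_flat_field(self):
        field = estimate_illumination([np.full(SHAPE, 120.0)] * 3, radius=10)
        np.testing.assert_allclose(field.L, 1.0, atol=1e-9)

    def test_recovers_known_quadratic_vignetting(self):
        L = quadratic_illumination(SHAPE)
        scene = default_scene(SHAPE, n_cells=10, seed=1)
        background = 60.0
        frames = [L * (scene["s_maps"][0] + background) for _ in range(2)]
        est = estimate_illumination(frames, radius=15)
        rms = np.sqrt(np.mean((est.L - L) ** 2))
        assert rms <= 0.02
        assert est.L.max() == pytest.approx(1.0)
        assert np.all(est.L > 0)

    def test_all_zero_images_rejected(self):
        with pytest.raises(ValueError):
            estimate_illumination([np.zeros(SHAPE)], radius=5)

    def test_correction_is_exact_inverse(self):
        L = quadratic_illumination(SHAPE)
        truth = np.abs(np.random.default_rng(0).normal(100.0, 10.0, SHAPE))
        observed = L * truth
        np.testing.assert_allclose(correct_illumination(observed, L), truth, atol=1e-10)
        np.testing.assert_allclose(correct_illumination(L.copy(), L), 1.0, atol=1e-12)

    def test_nonpositive_field_rejected(self):
        bad = np.ones(SHAPE)
        bad[0, 0] = 0.0
        with pytest.raises(ValueError):
            correct_illumination(np.ones(SHAPE), bad)


class TestMixingMatrix:
    def test_single_channel_controls_give_unit_rows(self):
        controls = {
            name: np.eye(5)[i] * 300.0
            for i, name in enumerate(("H2B", "MDR", "Dox", "background"))
        }
        M = build_mixing_matrix(controls)
        np.testing.assert_allclose(M.T, np.eye(5)[:4])

    def test_known_spectra_recovered_exactly(self):
        T_true = default_mixing_matrix().T
        controls = {}
        for i, name in enumerate(("H2B", "MDR", "Dox", "background")):
            # control sample: one pure fluorophore at arbitrary brightness
            controls[name] = 731.0 * T_true[i] * (i + 1)
        M = build_mixing_matrix(controls)
        np.testing.assert_allclose(M.T, T_true, rtol=1e-12)

    def test_identical_spectra_rejected_as_rank_deficient(self):
        row = np.array([1.0, 0.5, 0.2, 0.1, 0.05])
        controls = {"H2B": row, "MDR": row, "Dox": np.eye(5)[2], "background": np.eye(5)[4]}
        with pytest.raises(ValueError, match="rank"):
            build_mixing_matrix(controls)

    def test_dark_control_rejected(self):
        controls = {"H2B": np.zeros(5), "MDR": np.eye(5)[1], "Dox": np.eye(5)[2],
                    "background": np.eye(5)[4]}
        with pytest.raises(ValueError, match="no signal"):
            build_mixing_matrix(controls)


class TestUnmix:
    def test_unit_spectra_pass_through_channel_means(self):
        T = MixingMatrix(T=np.eye(5)[:4])
        means = np.array([10.0, 20.0, 30.0, 40.0, 0.0])
        S, resid = unmix(means, T)
        np.testing.assert_allclose(S, means[:4])
        assert resid <= 1e-10

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_noiseless_mixtures_invert_exactly(self, seed):
        rng = np.random.default_rng(seed)
        T = default_mixing_matrix()
        S_true = rng.uniform(10.0, 1000.0, size=(3, 4))
        I = S_true @ T.T
        S, resid = unmix(I, T)
        np.testing.assert_allclose(S, S_true, rtol=1e-8)
        assert np.all(resid <= 1e-8 * np.abs(I).max())

    def test_noise_propagation_keeps_dox_signal_accurate(self):
        """1% channel noise perturbs the unmixed drug signal only modestly."""
        rng = np.random.default_rng(42)
        T = default_mixing_matrix()
        S_true = np.array([500.0, 200.0, 1030.0, 40.0])
        clean = S_true @ T.T
        errs = []
        for _ in range(100):
            noisy = clean * (1 + rng.normal(0.0, 0.01, 5))
            S, _ = unmix(noisy, T)
            errs.append(abs(S[2] - S_true[2]) / S_true[2])
        assert np.median(errs) <= 0.03

    def test_rank_deficient_matrix_rejected(self):
        T = np.eye(5)[:4]
        T[1] = T[0]
        with pytest.raises(ValueError, match="rank"):
            unmix(np.ones(5), T)


class TestCalibration:
    def test_identity_calibration(self):
        cal = CalibrationLine(a=1.0, b=0.0)
        conc, clipped = signal_to_concentration(123.4, cal)
        assert conc == 123.4 and not clipped

    def test_roundtrip_on_exact_standards(self):
        true = CalibrationLine(a=2.5, b=31.0)
        conc = np.array([0.0, 50.0, 200.0, 1000.0])
        cal = calibrate(conc, true.a * conc + true.b)
        np.testing.assert_allclose([cal.a, cal.b], [true.a, true.b], rtol=1e-12)
        back, clipped = signal_to_concentration(true.a * conc + true.b, cal)
        np.testing.assert_allclose(back, conc, atol=1e-9)
        assert not clipped.any()

    def test_subbackground_signal_clips_to_zero(self):
        cal = CalibrationLine(a=2.0, b=30.0)
        conc, clipped = signal_to_concentration(10.0, cal)
        assert conc == 0.0 and clipped

    def test_degenerate_standards_rejected(self):
        with pytest.raises(ValueError):
            calibrate([100.0, 100.0], [230.0, 231.0])


class TestSegmentation:
    def test_blank_image_counts_zero(self):
        mask, count = segment_cells(np.zeros(SHAPE), 10.0)
        assert count == 0 and not mask.any()

    def test_counts_separated_disks(self):
        scene = default_scene(SHAPE, n_cells=12, seed=0)
        image = scene["s_maps"][0]  # nuclei channel
        _, count = segment_cells(image, 100.0)
        assert count == len(scene["centers"]) == 12

    def test_threshold_above_max_gives_empty_mask(self):
        scene = default_scene(SHAPE, n_cells=5, seed=2)
        mask, count = segment_cells(scene["s_maps"][0], 1e9)
        assert count == 0 and not mask.any()

    def test_compartment_guard_band_excludes_cell_rims(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[8:13, 8:13] = True
        intra, extra = compartment_masks(mask, guard_px=2)
        assert (intra == mask).all()
        assert not extra[7, 10] and not extra[6, 10]  # within the 2-px band
        assert extra[5, 10] and extra[0, 0]  # beyond the band
        assert not (intra & extra).any()


class TestFullPipeline:
    def test_noiseless_stack_recovers_drug_concentration(self):
        """Forward model -> correct -> unmix -> calibrate is exact."""
        scene = default_scene(SHAPE, n_cells=12, seed=0)
        T = default_mixing_matrix()
        L = quadratic_illumination(SHAPE)
        stacks, _ = gen_spectral_stack(scene["s_maps"], T, L=L, noise_sd=0.0, seed=0)
        corrected = np.stack(
            [correct_illumination(im, L) for im in stacks[0].images]
        )
        mask, count = segment_cells(corrected[3], 400.0)
        assert count == 12
        means_in = corrected[:, mask].mean(axis=1)
        means_out = corrected[:, ~mask].mean(axis=1)
        S_in, _ = unmix(means_in, T)
        S_out, _ = unmix(means_out, T)
        cal = scene["cal"]
        conc_in, _ = signal_to_concentration(S_in[2], cal)
        conc_out, _ = signal_to_concentration(S_out[2], cal)
        np.testing.assert_allclose(conc_in, scene["dox_nM"], rtol=1e-6)
        np.testing.assert_allclose(conc_out, scene["dox_extracellular_nM"], rtol=1e-6)
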