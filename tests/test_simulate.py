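import numpy as np
import pytest

from boutonkit.core import ParameterError, StimulusProtocol
from boutonkit.flatfield import MosaicLayout
from boutonkit.preprocess import BleachModel
from boutonkit.simulate import (
    BoutonSpec,
    NoiseModel,
    random_bouton_field,
    render_spots,
    simulate_bleach_control,
    simulate_line_profiles,
    simulate_movie,
    simulate_tile_grid,
    spot_integral,
    transient_f_over_f0,
)

FLAT = BleachModel.identity()
NO_STIM = StimulusProtocol(onset_time_s=0.0, n_stimuli=0)


class TestMovie:
    def test_no_boutons_no_noise_constant_background(self):
        noise = NoiseModel(photon_gain=0.0, read_sigma=0.0,
                           background_level=20.0, background_smoothness_px=0.0)
        stack, _ = simulate_movie([], NO_STIM, noise, FLAT, (5, 8, 8), 0.1, 0)
        assert np.all(stack.green == 20.0)
        assert np.all(stack.green[0] == stack.green[-1])

    def test_single_stimulus_peak_f_over_f0(self):
        """Center-pixel F/F0 reaches 1 + amp right at the stimulus frame."""
        b = BoutonSpec(center=(10.0, 10.0), amp_per_stim=0.5,
                       responder=True)
        stim = StimulusProtocol(onset_time_s=1.0, n_stimuli=1)
        stack, _ = simulate_movie([b], stim, NoiseModel.noiseless(), FLAT,
                                  (30, 21, 21), 0.1, 0)
        trace = stack.green[:, 10, 10]
        f0 = trace[:10].mean()
        ratio = trace / f0
        assert ratio[10] == pytest.approx(1.5, abs=1e-9)
        assert np.all(ratio[:10] == pytest.approx(1.0, abs=1e-12))

    def test_same_seed_bit_identical(self, train_10x20hz):
        b = BoutonSpec(center=(5.0, 5.0))
        kw = dict(shape=(20, 16, 16), frame_interval_s=0.1, seed=42)
        s1, _ = simulate_movie([b], train_10x20hz, NoiseModel(), FLAT, **kw)
        s2, _ = simulate_movie([b], train_10x20hz, NoiseModel(), FLAT, **kw)
        assert np.array_equal(s1.green, s2.green)
        assert np.array_equal(s1.red, s2.red)
        kw["seed"] = 43
        s3, _ = simulate_movie([b], train_10x20hz, NoiseModel(), FLAT, **kw)
        assert not np.array_equal(s1.green, s3.green)

    def test_bouton_outside_frame_rejected(self, train_10x20hz):
        with pytest.raises(ParameterError):
            simulate_movie([BoutonSpec(center=(50.0, 5.0))], train_10x20hz,
                           NoiseModel(), FLAT, (20, 16, 16), 0.1, 0)

    def test_stack_too_short_for_protocol_rejected(self):
        stim = StimulusProtocol(onset_time_s=1.0, n_stimuli=100,
                                frequency_hz=10.0)
        with pytest.raises(ParameterError):
            simulate_movie([], stim, NoiseModel(), FLAT, (5, 8, 8), 0.1, 0)

    def test_total_intensity_conservation_noiseless(self, train_10x20hz):
        """Frame totals equal background + sum of analytic spot integrals
        scaled by (1 + c(t)) and the bleach curve."""
        bleach = BleachModel(a1=0.3, tau1_s=2.0, a2=0.0, tau2_s=2.0, c=0.7)
        boutons = [BoutonSpec(center=(20.0, 20.0), amp_per_stim=0.1),
                   BoutonSpec(center=(20.0, 44.0), responder=False),
                   BoutonSpec(center=(40.0, 32.0), amp_per_stim=0.2)]
        noise = NoiseModel(photon_gain=0.0, read_sigma=0.0,
                           background_level=10.0, background_smoothness_px=0.0)
        T = 40
        stack, truth = simulate_movie(boutons, train_10x20hz, noise, bleach,
                                      (T, 64, 64), 0.098, 0)
        t = np.arange(T) * 0.098
        bg_total = 10.0 * 64 * 64
        for k in range(T):
            expected = bg_total
            for b in boutons:
                c = transient_f_over_f0(
                    np.array([t[k]]), train_10x20hz, b.amp_per_stim,
                    b.tau_decay_s, b.saturation_cap)[0] if b.responder else 0.0
                expected += spot_integral(b) * (1.0 + c)
            expected *= bleach(t[k])
            assert stack.green[k].sum() == pytest.approx(expected, rel=1e-6)

    def test_red_channel_has_no_stimulus_locked_component(self, train_10x20hz):
        b = BoutonSpec(center=(10.0, 10.0), amp_per_stim=0.5)
        stack, _ = simulate_movie([b], train_10x20hz, NoiseModel.noiseless(),
                                  FLAT, (40, 21, 21), 0.098, 0)
        t = np.arange(40) * 0.098
        c = transient_f_over_f0(t, train_10x20hz, 0.5, 0.5, 2.0)
        red_mean = stack.red.mean(axis=(1, 2))
        slope = np.polyfit(c, red_mean, 1)[0]
        assert abs(slope) < 1e-9


class TestBleachControl:
    def test_flat_bleach_noiseless_all_frames_identical(self):
        noise = NoiseModel(photon_gain=0.0, read_sigma=0.0,
                           background_level=15.0)
        stack = simulate_bleach_control(noise, FLAT, (10, 8, 8), 0.1, 0)
        assert np.all(stack.green == stack.green[0])

    def test_frame_mean_follows_double_exponential(self, double_bleach):
        noise = NoiseModel(photon_gain=0.0, read_sigma=0.0,
                           background_level=20.0, background_smoothness_px=0.0)
        stack = simulate_bleach_control(noise, double_bleach, (101, 8, 8),
                                        0.05, 0)
        means = stack.green.mean(axis=(1, 2))
        # frame at t = 5 s relative to t = 0
        expected = 0.6 * np.exp(-1.0) + 0.4 * np.exp(-0.1)
        assert means[100] / means[0] == pytest.approx(expected, rel=1e-9)

    def test_noisy_controls_share_expectation(self, double_bleach):
        noise = NoiseModel(photon_gain=1.0, read_sigma=1.0,
                           background_level=50.0, background_smoothness_px=0.0)
        shape = (100, 16, 16)
        m = []
        for seed in (1, 2):
            stack = simulate_bleach_control(noise, double_bleach, shape,
                                            0.1, seed)
            m.append(stack.green.mean())
        # per-pixel variance ~ 50 + 1; SE of the mean over 100*256 samples
        se = np.sqrt(51.0 / (100 * 256))
        assert abs(m[0] - m[1]) < 3 * np.sqrt(2) * se


class TestTransient:
    def test_increments_sum_and_decay(self):
        stim = StimulusProtocol(onset_time_s=0.0, n_stimuli=2,
                                frequency_hz=10.0)
        c = transient_f_over_f0(np.array([0.0, 0.1, 0.2]), stim, 0.3, 0.5, 9.0)
        assert c[0] == pytest.approx(0.3)
        assert c[1] == pytest.approx(0.3 * np.exp(-0.2) + 0.3)
        assert c[2] == pytest.approx(
            0.3 * np.exp(-0.4) + 0.3 * np.exp(-0.2))

    def test_saturation_cap_clips(self):
        stim = StimulusProtocol(onset_time_s=0.0, n_stimuli=50,
                                frequency_hz=100.0)
        c = transient_f_over_f0(np.linspace(0, 0.5, 51), stim, 0.5, 10.0, 2.0)
        assert c.max() == pytest.approx(2.0)


class TestTileGrid:
    def test_zero_vignette_noiseless_exact_crops(self, rng, noiseless):
        truth = rng.uniform(50, 150, (99, 99))
        layout = MosaicLayout.for_image(truth.shape, 2, 2, 0.1)
        tiles, gt = simulate_tile_grid(truth, layout, 0.0, noiseless, 0)
        th, tw = layout.tile_shape
        assert np.array_equal(tiles[0], gt.truth_image[:th, :tw])

    def test_vignette_corner_center_ratio(self, noiseless):
        truth = np.full((99, 99), 100.0)
        layout = MosaicLayout.for_image(truth.shape, 2, 2, 0.1)
        tiles, _ = simulate_tile_grid(truth, layout, 0.5, noiseless, 0)
        th, tw = layout.tile_shape
        center = tiles[0][(th - 1) // 2, (tw - 1) // 2]
        assert tiles[0][0, 0] / center == pytest.approx(0.5, rel=0.01)

    def test_grid_layout_arithmetic_100px(self):
        """2x2 with 10% overlap on a 100x100 truth: integer layout places
        4 tiles of 52x52 covering a 99x99 region."""
        layout = MosaicLayout.for_image((100, 100), 2, 2, 0.1)
        assert layout.tile_shape == (52, 52)
        assert layout.mosaic_shape() == (99, 99)
        tiles, gt = simulate_tile_grid(np.zeros((100, 100)), layout, 0.0,
                                       NoiseModel.noiseless(), 0)
        assert len(tiles) == 4 and tiles[0].shape == (52, 52)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ParameterError):
            MosaicLayout(rows=2, cols=2, tile_shape=(10, 10),
                         overlap_frac=1.5)


class TestLineProfiles:
    def test_perfect_correlation(self):
        a, b = simulate_line_profiles(100, 1.0, seed=0)
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_zero_correlation_large_sample(self):
        a, b = simulate_line_profiles(100_000, 0.0, seed=1)
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.01

    def test_high_correlation_within_fisher_interval(self):
        a, b = simulate_line_profiles(10_000, 0.9, seed=2)
        assert 0.88 <= np.corrcoef(a, b)[0, 1] <= 0.92

    def test_invalid_rho_rejected(self):
        with pytest.raises(ParameterError):
            simulate_line_profiles(10, 1.5, seed=0)


class TestRandomField:
    def test_spacing_and_labels(self):
        boutons = random_bouton_field(30, (64, 256), responder_fraction=0.3,
                                      min_spacing_px=8.0, seed=0)
        centers = np.array([b.center for b in boutons])
        d = np.sqrt(((centers[:, None] - centers[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 8.0
        assert sum(b.responder for b in boutons) == 9

    def test_determinism(self):
        a = random_bouton_field(10, seed=5)
        b = random_bouton_field(10, seed=5)
        assert [x.center for x in a] == [x.center for x in b]
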