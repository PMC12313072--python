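"""Spectrograms, the feature hierarchy, modulation energies, acoustic
descriptors and the temporally disrupted control stimuli."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurosound import dsp, features, synth
from neurosound.features import (LayerFeature, MelSpectrogram,
                                 melspectrogram, temporal_downsample)
from neurosound.nnet import LAYER_TEMPORAL, HierarchyNet

T = np.arange(features.SEGMENT_SAMPLES) / dsp.SAMPLE_RATE


class TestMelSpectrogram:
    def test_frame_geometry(self, small_stimuli):
        seg = small_stimuli[0].wave[:features.SEGMENT_SAMPLES]
        raw = np.abs(dsp.stft(seg))
        assert raw.shape[1] == 345          # pre-crop frame count
        m = melspectrogram(seg)
        assert m.shape == (80, 336)         # after center cropping
        assert m.band_centers[0] > 125 - 1 and m.band_centers[-1] < 7600 + 1

    def test_rejects_wrong_length(self):
        with pytest.raises(ValueError):
            melspectrogram(np.zeros(1000))

    def test_pure_tone_lands_in_analytic_mel_band(self):
        tone = 0.5 * np.sin(2 * np.pi * 1000.0 * T)
        m = melspectrogram(tone)
        dominant = int(np.argmax(m.values.mean(axis=1)))
        expected = int(np.argmin(np.abs(m.band_centers - 1000.0)))
        assert abs(dominant - expected) <= 1


class TestHierarchy:
    def test_temporal_lengths_halve(self, small_specs, default_net):
        feats = features.extract_hierarchy(small_specs[0], net=default_net)
        for name, tlen in LAYER_TEMPORAL.items():
            assert feats[name].temporal_length == tlen

    def test_zero_input_gives_zero_features(self, default_net):
        zero = MelSpectrogram(values=np.zeros((80, 336)))
        feats = features.extract_hierarchy(zero, net=default_net)
        for name in ("L1", "L2", "L3", "L4", "L5"):
            np.testing.assert_allclose(feats[name].values, 0.0)

    def test_seeded_untrained_weights_are_deterministic(self, small_specs):
        a = features.extract_hierarchy(small_specs[0], net_seed=9)
        b = features.extract_hierarchy(small_specs[0], net_seed=9)
        for name in a:
            np.testing.assert_array_equal(a[name].values, b[name].values)

    def test_wrong_shape_rejected(self, default_net):
        bad = MelSpectrogram(values=np.zeros((80, 100)))
        with pytest.raises(ValueError):
            features.extract_hierarchy(bad, net=default_net)

    def test_classification_training_learns_categories(self, small_specs):
        """A briefly trained hierarchy separates the synthetic categories."""
        stims = synth.gen_stimulus_set(
            1, {c: 6 for c in synth.CATEGORIES}, seed=31)
        stims = [s for s in stims if s.id.startswith("test")]
        specs = [melspectrogram(s.wave[:features.SEGMENT_SAMPLES]).values
                 for s in stims]
        labels = [synth.CATEGORIES.index(s.category) for s in stims]
        net = HierarchyNet(seed=2)
        losses = net.fit_classifier(specs, labels, epochs=12, seed=3)
        assert net.trained
        assert losses[-1] < losses[0]
        preds = [int(np.argmax(net.forward(sp)["FC"])) for sp in specs]
        assert np.mean(np.array(preds) == labels) > 0.8


class TestTemporalDownsample:
    def test_336_frames_pool_to_21_means_of_16(self, rng):
        v = rng.normal(size=(7, 336))
        got = temporal_downsample(LayerFeature("L1", v))
        oracle = np.stack([v[:, 16 * k:16 * (k + 1)].mean(axis=1)
                           for k in range(21)], axis=1)
        np.testing.assert_allclose(got, oracle)

    def test_fc_broadcasts_21_identical_columns(self, rng):
        v = rng.normal(size=(5, 1))
        got = temporal_downsample(LayerFeature("FC", v))
        assert got.shape == (5, 21)
        np.testing.assert_allclose(got, np.tile(v, (1, 21)))

    def test_too_many_segments_rejected(self):
        with pytest.raises(ValueError):
            temporal_downsample(LayerFeature("L5", np.zeros((3, 10))),
                                n_segments=21)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_to_permutation_within_segments(self, seed):
        r = np.random.default_rng(seed)
        v = r.normal(size=(4, 42))  # 21 segments of 2 frames
        base = temporal_downsample(LayerFeature("L2", v))
        shuffled = v.copy()
        for k in range(21):
            shuffled[:, 2 * k:2 * k + 2] = shuffled[:, 2 * k:2 * k + 2][
                :, ::-1]
        np.testing.assert_allclose(
            temporal_downsample(LayerFeature("L2", shuffled)), base)


class TestModulationFeatures:
    def test_output_shape(self, small_stimuli):
        seg = small_stimuli[0].wave[:features.SEGMENT_SAMPLES]
        mf = features.modulation_features(seg)
        assert mf.values.shape == (128, 40, 6, 20)

    def test_silence_gives_zeros(self):
        mf = features.modulation_features(np.zeros(features.SEGMENT_SAMPLES))
        np.testing.assert_allclose(mf.values, 0.0)

    def test_upward_ripple_excites_upward_filters(self):
        """An analytically constructed upward-moving ripple puts more energy
        into the upward-direction filters at the matched rate pair."""
        carriers = np.geomspace(300, 5000, 60)
        wave = np.zeros_like(T)
        rate_hz, spec_rate = 4.0, 1.0
        for f in carriers:
            x_oct = np.log2(f / 300.0)
            amp = 1 + np.sin(2 * np.pi * (rate_hz * T - spec_rate * x_oct))
            wave += amp * np.sin(2 * np.pi * f * T + 7.0 * x_oct)
        wave *= 0.9 / np.abs(wave).max()
        mf = features.modulation_features(wave)
        si = 2          # 1.26 cyc/oct, nearest tuned spectral rate
        ti = np.argmin(np.abs(np.geomspace(1, 30, 10) - rate_hz))
        up = mf.values[:, :, si, ti].sum()
        down = mf.values[:, :, si, 10 + ti].sum()
        assert up > 2 * down


class TestAcousticSummary:
    def test_harmonic_tone_f0(self):
        wave = sum(np.sin(2 * np.pi * 220.0 * h * T) / h for h in (1, 2, 3))
        s = features.acoustic_summary(0.3 * wave / np.abs(wave).max())
        assert s.f0_mean is not None and abs(s.f0_mean - 220.0) <= 5.0
        assert s.hnr_mean is not None and s.hnr_mean > 0

    def test_white_noise_unpitched_with_flat_centroid(self):
        noise = 0.2 * np.random.default_rng(1).standard_normal(
            features.SEGMENT_SAMPLES)
        s = features.acoustic_summary(noise)
        assert s.f0_mean is None and s.hnr_mean is None
        # centroid of a flat magnitude spectrum sits near half Nyquist
        assert 4500 < s.sc_median < 6600

    def test_silence_all_undefined(self):
        s = features.acoustic_summary(np.zeros(22_050))
        assert s.f0_mean is None and s.sc_median is None and s.hnr_mean is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            features.acoustic_summary(np.array([]))


class TestTextureSurrogate:
    @pytest.fixture()
    def pair(self, small_specs):
        spec = small_specs[-1]  # environment half: energy in every band
        return spec, features.texture_surrogate(spec, seed=5)

    def test_time_averaged_moments_preserved(self, pair):
        spec, tex = pair
        x, y = spec.values, tex.values
        live = x.std(axis=1) > 1e-6
        assert np.max(np.abs(y.mean(1) - x.mean(1))[live]
                      / np.abs(x.mean(1))[live]) < 0.02
        assert np.max(np.abs(y.var(1) - x.var(1))[live] / x.var(1)[live]) < 0.02
        cx = np.corrcoef(x[live])
        cy = np.corrcoef(y[live])
        assert np.max(np.abs(cx - cy)) < 0.02

    def test_output_differs_from_input(self, pair):
        spec, tex = pair
        assert not np.allclose(spec.values, tex.values)

    def test_temporal_autocorrelation_destroyed(self, pair):
        spec, tex = pair
        live = spec.values.std(axis=1) > 1e-6
        acs = [np.corrcoef(tex.values[i, :-10], tex.values[i, 10:])[0, 1]
               for i in np.flatnonzero(live)]
        assert abs(np.mean(acs)) < 0.1


class TestShuffleTime:
    def test_2000ms_swaps_halves(self, small_specs):
        spec = small_specs[0]
        out = features.shuffle_time(spec, 2000, seed=0)
        np.testing.assert_array_equal(out.values[:, :168],
                                      spec.values[:, 168:])
        np.testing.assert_array_equal(out.values[:, 168:],
                                      spec.values[:, :168])

    def test_frame_multiset_preserved(self, small_specs):
        spec = small_specs[1]
        out = features.shuffle_time(spec, 96, seed=3)
        a = np.sort(spec.values.ravel())
        b = np.sort(out.values.ravel())
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("k", [2, 3, 4, 6, 8])
    def test_divisor_windows_permute_k_whole_blocks(self, small_specs, k):
        out = features.shuffle_time(small_specs[0], 4000.0 / k, seed=1)
        seg = 336 // k
        orig_blocks = [small_specs[0].values[:, i * seg:(i + 1) * seg]
                       for i in range(k)]
        out_blocks = [out.values[:, i * seg:(i + 1) * seg] for i in range(k)]
        # every output block is one of the original blocks, used once
        matches = [next(j for j, ob in enumerate(orig_blocks)
                        if np.array_equal(b, ob)) for b in out_blocks]
        assert sorted(matches) == list(range(k))
        assert matches != list(range(k))  # differs from the original order

    def test_subframe_window_rejected(self, small_specs):
        with pytest.raises(ValueError):
            features.shuffle_time(small_specs[0], 5.0, seed=0)

    def test_whole_duration_window_rejected(self, small_specs):
        with pytest.raises(ValueError):
            features.shuffle_time(small_specs[0], 4000.0, seed=0)
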