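"""Generator contracts: geometry, spectral structure, separability, determinism."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from eeg_augkit.synthetic import (DEFAULT_SLEEP_COMPOSITION, SLEEP_STAGES,
                                  STAGE_TO_ID, SyntheticConfig, build_subset,
                                  generate_focal_segment, generate_sleep_epoch,
                                  make_shifted_eval_set, pink_noise,
                                  relative_band_power)


@pytest.fixture(scope="module")
def sleep_cfg():
    return SyntheticConfig(task="sleep")


@pytest.fixture(scope="module")
def focal_cfg():
    return SyntheticConfig(task="focal")


class TestGeometry:
    def test_sleep_default_shape(self, sleep_cfg):
        seg = generate_sleep_epoch("N2", sleep_cfg, np.random.default_rng(0))
        assert seg.data.shape == (2, 3000)  # 30 s x 100 Hz
        assert seg.fs == 100.0
        assert seg.label == STAGE_TO_ID["N2"]

    def test_focal_default_shape(self, focal_cfg):
        seg = generate_focal_segment(True, focal_cfg, np.random.default_rng(0))
        assert seg.data.shape == (2, 10_240)  # 20 s x 512 Hz
        assert seg.fs == 512.0

    def test_unknown_stage_rejected(self, sleep_cfg):
        with pytest.raises(ValueError):
            generate_sleep_epoch("N5", sleep_cfg, np.random.default_rng(0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(task="sleep", fs=100, duration_s=0.505)
        with pytest.raises(ValueError):
            SyntheticConfig(task="other")
        with pytest.raises(ValueError):
            SyntheticConfig(composition={"N3": -1})


class TestSpectralContracts:
    """Welch-oracle checks over many seeded epochs (>= 95% must satisfy)."""

    def test_n3_delta_dominant(self, sleep_cfg):
        rng = np.random.default_rng(10)
        ok = sum(relative_band_power(
            generate_sleep_epoch("N3", sleep_cfg, rng), 0.5, 4.0) > 0.5
            for _ in range(100))
        assert ok >= 95

    def test_wake_alpha_exceeds_delta(self, sleep_cfg):
        rng = np.random.default_rng(11)
        ok = 0
        for _ in range(100):
            seg = generate_sleep_epoch("Wake", sleep_cfg, rng)
            ok += (relative_band_power(seg, 8, 12)
                   > relative_band_power(seg, 0.5, 4))
        assert ok >= 95

    def test_n2_has_spindle_band_power_above_rem(self, sleep_cfg):
        rng = np.random.default_rng(12)
        n2 = np.mean([relative_band_power(
            generate_sleep_epoch("N2", sleep_cfg, rng), 12, 14)
            for _ in range(30)])
        rem = np.mean([relative_band_power(
            generate_sleep_epoch("REM", sleep_cfg, rng), 12, 14)
            for _ in range(30)])
        assert n2 > rem

    def test_all_values_finite_and_scaled(self, sleep_cfg):
        rng = np.random.default_rng(13)
        for stage in SLEEP_STAGES:
            seg = generate_sleep_epoch(stage, sleep_cfg, rng)
            assert np.all(np.isfinite(seg.data))
            stds = seg.data.std(axis=1)
            assert np.all(stds > 0.05) and np.all(stds < 50)

    def test_pink_noise_spectrum_slopes_down(self):
        x = pink_noise((4, 8192), np.random.default_rng(3))
        freqs, psd = sp_signal.welch(x, fs=1.0, nperseg=2048, axis=1)
        lo = psd[:, (freqs > 0.001) & (freqs < 0.01)].mean()
        hi = psd[:, freqs > 0.1].mean()
        assert lo > 10 * hi


class TestFocalSeparability:
    def test_focal_segments_contain_spikes(self, focal_cfg):
        # Poisson tail: P(0 events) = exp(-rate*T) = exp(-20) -> every draw
        rng = np.random.default_rng(20)
        with_spike = sum(
            len(generate_focal_segment(True, focal_cfg, rng,
                                       return_events=True)[1]) >= 1
            for _ in range(100))
        assert with_spike >= 99

    def test_non_focal_has_no_spike_events(self, focal_cfg):
        _, events = generate_focal_segment(False, focal_cfg,
                                           np.random.default_rng(21),
                                           return_events=True)
        assert events == []

    def test_threshold_detector_fires_more_on_focal(self, focal_cfg):
        # detectability oracle: |z| > 5 after 10-60 Hz band-pass
        sos = sp_signal.butter(4, [10, 60], btype="bandpass", fs=512,
                               output="sos")

        def crossings(seg):
            f = sp_signal.sosfiltfilt(sos, seg.data, axis=1)
            z = (f - f.mean(axis=1, keepdims=True)) / f.std(axis=1, keepdims=True)
            return int((np.abs(z) > 5).sum())

        rng = np.random.default_rng(22)
        focal = [crossings(generate_focal_segment(True, focal_cfg, rng))
                 for _ in range(100)]
        nonfocal = [crossings(generate_focal_segment(False, focal_cfg, rng))
                    for _ in range(100)]
        assert np.mean(focal) > np.mean(nonfocal)


class TestBuildSubset:
    def test_toy_composition(self):
        cfg = SyntheticConfig(task="sleep", duration_s=1.0,
                              composition={"A": 3, "B": 2})
        segs = build_subset(cfg, np.random.default_rng(0))
        assert len(segs) == 5
        labels = sorted(s.label for s in segs)
        assert labels == [0, 0, 0, 1, 1]

    def test_default_composition_is_study_scale(self):
        assert sum(DEFAULT_SLEEP_COMPOSITION.values()) == 16_000
        assert DEFAULT_SLEEP_COMPOSITION["N3"] == 8000

    def test_composition_counts_exact(self):
        cfg = SyntheticConfig(task="sleep", duration_s=2.0,
                              composition={"N3": 6, "Wake": 3, "REM": 2})
        segs = build_subset(cfg, np.random.default_rng(1))
        counts = {}
        for s in segs:
            counts[s.label] = counts.get(s.label, 0) + 1
        assert counts == {STAGE_TO_ID["N3"]: 6, STAGE_TO_ID["Wake"]: 3,
                          STAGE_TO_ID["REM"]: 2}

    def test_determinism_and_seed_sensitivity(self):
        cfg = SyntheticConfig(task="sleep", duration_s=2.0,
                              composition={"N3": 4, "Wake": 4})
        a = build_subset(cfg, np.random.default_rng(5))
        b = build_subset(cfg, np.random.default_rng(5))
        c = build_subset(cfg, np.random.default_rng(6))
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.data, sb.data)
            assert sa.source_id == sb.source_id
        assert any(not np.array_equal(sa.data, sc.data) for sa, sc in zip(a, c))


class TestShiftedEvalSet:
    def _small_set(self, n=5):
        cfg = SyntheticConfig(task="sleep", duration_s=5.0,
                              composition={"N3": n})
        return build_subset(cfg, np.random.default_rng(7))

    def test_zero_perturbation_is_identity(self):
        segs = self._small_set()
        out = make_shifted_eval_set(segs, 0.0, 0.0, np.random.default_rng(0))
        for a, b in zip(segs, out):
            np.testing.assert_array_equal(a.data, b.data)

    def test_multiset_scaled_by_single_gain(self):
        segs = self._small_set()
        out = make_shifted_eval_set(segs, 0.3, 0.15, np.random.default_rng(1))
        for a, b in zip(segs, out):
            assert b.label == a.label
            sa = np.sort(a.data, axis=1)
            sb = np.sort(b.data, axis=1)
            ratios = sb / sa
            # one multiplicative gain for the whole segment
            np.testing.assert_allclose(ratios, ratios.ravel()[0], rtol=1e-5)
            assert 0.85 - 1e-9 <= abs(ratios.ravel()[0]) <= 1.15 + 1e-9

    def test_spectral_signature_survives_shift(self):
        cfg = SyntheticConfig(task="sleep")
        segs = build_subset(SyntheticConfig(
            task="sleep", composition={"N3": 10}), np.random.default_rng(2))
        out = make_shifted_eval_set(segs, 0.2, 0.15, np.random.default_rng(3))
        for seg in out:
            assert relative_band_power(seg, 0.5, 4.0) > 0.5

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            make_shifted_eval_set([], 0.1, 0.1, np.random.default_rng(0))
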