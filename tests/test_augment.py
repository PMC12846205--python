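"""Operator algebra of the three augmentation primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eeg_augkit.augment import (AugmentationPolicy, add_noise, amplitude_scale,
                                augment_sample, sample_augmentation, time_shift)
from eeg_augkit.segment import EEGSegment


def seg_from(values, fs=100.0):
    return EEGSegment(data=np.asarray(values, dtype=float), fs=fs, label=0)


class TestTimeShift:
    @pytest.mark.parametrize("dt,expected", [
        (1, [2, 3, 4, 1]),
        (0, [1, 2, 3, 4]),
        (4, [1, 2, 3, 4]),     # dt = T wraps to identity
        (-1, [4, 1, 2, 3]),
        (5, [2, 3, 4, 1]),     # reduced modulo T
    ])
    def test_circular_semantics(self, dt, expected):
        out = time_shift(seg_from([[1, 2, 3, 4]]), dt)
        assert out.data.tolist() == [expected]

    def test_shared_shift_across_channels(self):
        out = time_shift(seg_from([[1, 2, 3], [10, 20, 30]]), 1)
        assert out.data.tolist() == [[2, 3, 1], [20, 30, 10]]

    @given(dt=st.integers(-5000, 5000))
    @settings(max_examples=50, deadline=None)
    def test_invertible_and_multiset_preserving(self, dt):
        rng = np.random.default_rng(42)
        seg = EEGSegment(rng.standard_normal((2, 137)), fs=100.0, label=0)
        out = time_shift(seg, dt)
        for c in range(2):
            assert sorted(out.data[c]) == sorted(seg.data[c])
        back = time_shift(out, -dt)
        np.testing.assert_array_equal(back.data, seg.data)

    def test_preserves_metadata(self, segment):
        out = time_shift(segment, 17)
        assert (out.fs, out.label, out.channel_names, out.source_id) == (
            segment.fs, segment.label, segment.channel_names, segment.source_id)
        assert out.data.shape == segment.data.shape


class TestAmplitudeScale:
    def test_elementwise(self):
        out = amplitude_scale(seg_from([[2, -4]]), 0.5)
        assert out.data.tolist() == [[1, -2]]

    def test_identity(self, segment):
        np.testing.assert_array_equal(amplitude_scale(segment, 1.0).data,
                                      segment.data)

    def test_exact_std_scaling(self, segment):
        out = amplitude_scale(segment, 0.8)
        np.testing.assert_allclose(out.data.std(axis=1),
                                   0.8 * segment.data.std(axis=1), rtol=1e-12)

    @given(a=st.floats(0.1, 10), b=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_multiplicative_composition(self, a, b):
        seg = seg_from([[1.0, -2.0, 3.5]])
        lhs = amplitude_scale(amplitude_scale(seg, a), b)
        rhs = amplitude_scale(seg, a * b)
        np.testing.assert_allclose(lhs.data, rhs.data, rtol=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, -1.0])
    def test_rejects_nonpositive(self, segment, alpha):
        with pytest.raises(ValueError):
            amplitude_scale(segment, alpha)


class TestAddNoise:
    N = 10_240

    def _long_seg(self):
        return EEGSegment(np.zeros((1, self.N)), fs=512.0, label=0)

    def test_zero_sigma_identity(self, segment, rng):
        np.testing.assert_array_equal(add_noise(segment, 0.0, rng).data,
                                      segment.data)

    def test_negative_sigma_rejected(self, segment, rng):
        with pytest.raises(ValueError):
            add_noise(segment, -0.1, rng)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_residual_variance_concentration(self, seed):
        # chi-square concentration: sample variance within sigma^2(1 +/- 4*sqrt(2/n))
        sigma = 1.7
        seg = self._long_seg()
        out = add_noise(seg, sigma, np.random.default_rng(seed))
        resid = (out.data - seg.data).ravel()
        bound = 4 * np.sqrt(2.0 / self.N)
        assert abs(resid.var() - sigma**2) < sigma**2 * bound
        # CLT bound on the residual mean
        assert abs(resid.mean()) < 4 * sigma / np.sqrt(self.N)

    def test_seed_reproducible_and_seeds_uncorrelated(self):
        seg = self._long_seg()
        r1 = add_noise(seg, 1.0, np.random.default_rng(7)).data - seg.data
        r2 = add_noise(seg, 1.0, np.random.default_rng(7)).data - seg.data
        np.testing.assert_array_equal(r1, r2)
        r3 = add_noise(seg, 1.0, np.random.default_rng(8)).data - seg.data
        corr = np.corrcoef(r1.ravel(), r3.ravel())[0, 1]
        assert abs(corr) < 0.05


class TestPolicySampling:
    def test_invalid_policies_rejected(self):
        with pytest.raises(ValueError):
            AugmentationPolicy(ts_max_frac=1.5)
        with pytest.raises(ValueError):
            AugmentationPolicy(as_low=0.0)
        with pytest.raises(ValueError):
            AugmentationPolicy(na_frac_low=0.1, na_frac_high=0.05)
        with pytest.raises(ValueError):
            AugmentationPolicy(apply_prob=1.5)
        with pytest.raises(ValueError):
            AugmentationPolicy(enabled=("XX",))

    def test_empty_enabled_is_configuration_error(self, segment, rng):
        policy = AugmentationPolicy(enabled=())
        with pytest.raises(ValueError):
            sample_augmentation(policy, segment, rng)

    def test_as_only_policy_range(self, segment, rng):
        policy = AugmentationPolicy(enabled=("AS",))
        for _ in range(200):
            method, alpha = sample_augmentation(policy, segment, rng)
            assert method == "AS"
            assert 0.8 <= alpha <= 1.2

    def test_ts_range_covers_pm_30_percent(self, rng):
        seg = EEGSegment(np.zeros((1, 3000)), fs=100.0, label=0)
        policy = AugmentationPolicy(enabled=("TS",))
        dts = [sample_augmentation(policy, seg, rng)[1] for _ in range(5000)]
        assert min(dts) >= -900 and max(dts) <= 900
        assert min(dts) < -800 and max(dts) > 800  # range actually exercised

    def test_na_sigma_per_channel(self, segment, rng):
        policy = AugmentationPolicy(enabled=("NA",))
        _, sigma = sample_augmentation(policy, segment, rng)
        stds = segment.data.std(axis=1)
        u = sigma / stds
        np.testing.assert_allclose(u[0], u[1], rtol=1e-12)  # one u per segment
        assert 0.01 <= u[0] <= 0.05

    def test_method_frequencies_uniform(self, segment):
        # binomial concentration: each frequency within 1/3 +/- 0.02 at 10,000 draws
        rng = np.random.default_rng(123)
        policy = AugmentationPolicy()
        counts = {"TS": 0, "AS": 0, "NA": 0}
        for _ in range(10_000):
            counts[sample_augmentation(policy, segment, rng)[0]] += 1
        for method, c in counts.items():
            assert abs(c / 10_000 - 1 / 3) < 0.02, method


class TestAugmentSample:
    def test_apply_prob_zero_is_identity(self, segment):
        policy = AugmentationPolicy(apply_prob=0.0)
        rng = np.random.default_rng(3)
        out = augment_sample(segment, policy, rng)
        np.testing.assert_array_equal(out.data, segment.data)

    def test_ts_only_is_circular_shift(self, segment):
        policy = AugmentationPolicy(enabled=("TS",), apply_prob=1.0)
        out = augment_sample(segment, policy, np.random.default_rng(5))
        for c in range(segment.n_channels):
            assert sorted(out.data[c]) == sorted(segment.data[c])
        assert out.label == segment.label

    def test_same_seed_bit_identical(self, segment):
        policy = AugmentationPolicy(apply_prob=1.0)
        a = augment_sample(segment, policy, np.random.default_rng(11))
        b = augment_sample(segment, policy, np.random.default_rng(11))
        np.testing.assert_array_equal(a.data, b.data)

    def test_shape_fs_label_never_change(self, segment):
        policy = AugmentationPolicy(apply_prob=1.0)
        rng = np.random.default_rng(9)
        for _ in range(50):
            out = augment_sample(segment, policy, rng)
            assert out.data.shape == segment.data.shape
            assert out.fs == segment.fs
            assert out.label == segment.label
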