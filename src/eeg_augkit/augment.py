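"""Signal-domain augmentation operators for EEG training data.

Three lightweight, physiologically motivated perturbations:

* circular **time shift** ``x'(t) = x((t + dt) mod T)`` — models timing jitter
  and small sensor displacement;
* **amplitude scaling** ``x'(t) = alpha * x(t)`` — models electrode-impedance and
  inter-session gain variability;
* additive **Gaussian noise** ``x'(t) = x(t) + eps(t)``, ``eps ~ N(0, sigma^2)`` —
  models residual sensor/environment noise.

Operators never change a segment's shape, sampling rate or label. An
:class:`AugmentationPolicy` describes which operators are enabled and the ranges
their parameters are drawn from; :func:`augment_sample` realises the online
(draw-time) augmentation used inside training folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segment import EEGSegment

#: Method tags, in the order used for uniform sampling.
TS, AS, NA = "TS", "AS", "NA"
_KNOWN_METHODS = (TS, AS, NA)


def time_shift(seg: EEGSegment, dt: int) -> EEGSegment:
    """Circularly shift a segment by ``dt`` samples (same shift on every channel).

    ``out[c, t] = seg.data[c, (t + dt) mod T]``; ``dt`` may be any integer and is
    reduced modulo the segment length. The per-channel multiset of values (hence
    mean, std and energy) is preserved exactly.
    """
    dt = int(dt)
    # np.roll(x, -dt) realises out[t] = x[(t + dt) mod T]
    return seg.with_data(np.roll(seg.data, -dt, axis=1))


def amplitude_scale(seg: EEGSegment, alpha: float) -> EEGSegment:
    """Multiply all channels by a positive gain ``alpha``."""
    if not alpha > 0:
        raise ValueError(f"amplitude scale must be > 0, got {alpha}")
    return seg.with_data(alpha * seg.data)


def add_noise(seg: EEGSegment, sigma, rng: np.random.Generator) -> EEGSegment:
    """Add iid Gaussian noise of standard deviation ``sigma``.

    ``sigma`` may be a scalar or a per-channel array of shape ``(n_channels,)``
    (the policy draws per-channel sigmas relative to each channel's std). The
    residual ``out - in`` is fully reproducible from the generator state.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError(f"noise std must be >= 0, got {sigma}")
    if sigma.ndim == 1:
        sigma = sigma[:, np.newaxis]
    eps = rng.standard_normal(seg.data.shape) * sigma
    return seg.with_data(seg.data + eps)


@dataclass
class AugmentationPolicy:
    """Which operators are enabled and the ranges their parameters are drawn from.

    Defaults follow the standard signal-domain augmentation settings for EEG:
    time shifts within ±30% of the window length, gains U(0.8, 1.2), and noise
    std between 1% and 5% of the (per-channel) signal std.
    """

    enabled: tuple[str, ...] = (TS, AS, NA)
    ts_max_frac: float = 0.30
    as_low: float = 0.8
    as_high: float = 1.2
    na_frac_low: float = 0.01
    na_frac_high: float = 0.05
    #: probability that a drawn training sample is augmented at all
    apply_prob: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        self.enabled = tuple(self.enabled)
        unknown = set(self.enabled) - set(_KNOWN_METHODS)
        if unknown:
            raise ValueError(f"unknown augmentation methods {sorted(unknown)}; "
                             f"known: {_KNOWN_METHODS}")
        if not 0 < self.ts_max_frac < 1:
            raise ValueError(f"ts_max_frac must be in (0, 1), got {self.ts_max_frac}")
        if not 0 < self.as_low <= self.as_high:
            raise ValueError(f"need 0 < as_low <= as_high, got ({self.as_low}, {self.as_high})")
        if not 0 <= self.na_frac_low <= self.na_frac_high:
            raise ValueError(
                f"need 0 <= na_frac_low <= na_frac_high, got ({self.na_frac_low}, {self.na_frac_high})"
            )
        if not 0 <= self.apply_prob <= 1:
            raise ValueError(f"apply_prob must be in [0, 1], got {self.apply_prob}")

    @classmethod
    def disabled(cls) -> "AugmentationPolicy":
        """A policy that never perturbs anything (the 'raw' condition)."""
        return cls(apply_prob=0.0)


def sample_augmentation(
    policy: AugmentationPolicy, seg: EEGSegment, rng: np.random.Generator
) -> tuple[str, object]:
    """Draw one (method, concrete parameters) pair for a segment.

    The method is uniform over ``policy.enabled``. Parameters:

    * ``TS`` — integer ``dt`` uniform on ``[-floor(f*T), +floor(f*T)]``;
    * ``AS`` — ``alpha ~ U(as_low, as_high)``;
    * ``NA`` — one fraction ``u ~ U(na_frac_low, na_frac_high)`` per segment,
      returned as per-channel sigmas ``u * std(channel)``.
    """
    if not policy.enabled:
        raise ValueError("augmentation policy has no enabled methods")
    method = policy.enabled[rng.integers(len(policy.enabled))]
    if method == TS:
        max_dt = int(np.floor(policy.ts_max_frac * seg.n_samples))
        return TS, int(rng.integers(-max_dt, max_dt + 1))
    if method == AS:
        return AS, float(rng.uniform(policy.as_low, policy.as_high))
    u = rng.uniform(policy.na_frac_low, policy.na_frac_high)
    sigma = u * seg.data.std(axis=1)
    return NA, sigma


def apply_augmentation(seg: EEGSegment, method: str, param, rng: np.random.Generator) -> EEGSegment:
    """Apply one concrete operator drawn by :func:`sample_augmentation`."""
    if method == TS:
        return time_shift(seg, param)
    if method == AS:
        return amplitude_scale(seg, param)
    if method == NA:
        return add_noise(seg, param, rng)
    raise ValueError(f"unknown method {method!r}")


def augment_sample(
    seg: EEGSegment, policy: AugmentationPolicy, rng: np.random.Generator
) -> EEGSegment:
    """Online augmentation of one training draw.

    With probability ``policy.apply_prob`` one sampled operator is applied to a
    copy of the segment; otherwise the segment is returned unchanged. The label
    and all metadata are always preserved.
    """
    if policy.apply_prob > 0 and rng.uniform() < policy.apply_prob:
        method, param = sample_augmentation(policy, seg, rng)
        return apply_augmentation(seg, method, param, rng)
    return seg
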