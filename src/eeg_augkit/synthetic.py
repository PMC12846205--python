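"""Synthetic EEG-like data with the statistical structure of the two tasks.

The generator is a documented stand-in for two public corpora, built so every
pipeline stage is testable without downloads:

* **sleep task** — two-channel 30-s epochs at 100 Hz with stage-dependent
  spectra: N3 dominated by high-amplitude 0.5–2 Hz delta (relative delta power
  > 0.5), Wake alpha-dominant (8–12 Hz), N1 theta (4–7 Hz), N2 theta plus
  12–14 Hz spindle bursts (0.5–1 s, Gaussian-windowed), REM low-amplitude mixed
  theta/beta — all over a 1/f (pink) background;
* **focal task** — two-channel 20-s segments at 512 Hz (10,240 samples per
  channel); non-focal segments are stationary coloured noise plus a broadband
  oscillation, focal segments add interictal spike-wave transients (~70 ms
  biphasic spikes at ~1/s) and slow amplitude-modulated nonstationarity.

The obligations of the generator are class separability and the spectral
contracts above, not physiological realism; see the package methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .augment import amplitude_scale, time_shift
from .segment import EEGSegment

SLEEP_STAGES = ("Wake", "N1", "N2", "N3", "REM")
#: integer ids used for sleep-stage labels throughout the package
STAGE_TO_ID = {s: i for i, s in enumerate(SLEEP_STAGES)}
ID_TO_STAGE = {i: s for s, i in STAGE_TO_ID.items()}

#: balanced deep-sleep study composition: half N3, half evenly split others
DEFAULT_SLEEP_COMPOSITION = {"N3": 8000, "Wake": 2000, "REM": 2000, "N1": 2000, "N2": 2000}

FOCAL, NON_FOCAL = 1, 0


@dataclass
class SyntheticConfig:
    """Geometry, composition and spectral parameters of the generator."""

    task: str = "sleep"
    fs: float | None = None  # default 100 Hz (sleep) / 512 Hz (focal)
    duration_s: float | None = None  # default 30 s (sleep) / 20 s (focal)
    n_channels: int = 2
    composition: dict = field(default_factory=dict)
    #: 1/f background: power ~ 1/f^pink_exponent, scaled to this std (a.u.)
    pink_exponent: float = 1.0
    background_std: float = 1.0
    #: per-stage oscillation amplitude relative to the background std
    osc_gain: dict = field(default_factory=dict)
    spindle_rate_hz: float = 0.1  # expected spindles per second in N2
    spike_rate_hz: float = 1.0  # expected interictal spikes per second (focal)
    spike_amplitude: float = 6.0  # spike peak in background-std units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("sleep", "focal"):
            raise ValueError(f"task must be 'sleep' or 'focal', got {self.task!r}")
        if self.fs is None:
            self.fs = 100.0 if self.task == "sleep" else 512.0
        if self.duration_s is None:
            self.duration_s = 30.0 if self.task == "sleep" else 20.0
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"fs*duration_s must be integral, got {n}")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if not self.composition:
            self.composition = (dict(DEFAULT_SLEEP_COMPOSITION) if self.task == "sleep"
                                else {"focal": 1875, "non_focal": 1875})
        if any(v < 0 for v in self.composition.values()):
            raise ValueError("composition counts must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


def pink_noise(shape: tuple[int, ...], rng: np.random.Generator,
               exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent noise along the last axis, unit variance per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _narrowband(n: int, fs: float, f_lo: float, f_hi: float, n_ch: int,
                rng: np.random.Generator) -> np.ndarray:
    """Random-phase oscillation with power confined to [f_lo, f_hi], unit std.

    Realised in the frequency domain: Gaussian spectrum random phases inside
    the band, zero outside, so the band fraction of total power is ~1.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    spec = np.zeros((n_ch, len(freqs)), dtype=complex)
    k = band.sum()
    amp = rng.standard_normal((n_ch, k)) + 1j * rng.standard_normal((n_ch, k))
    spec[:, band] = amp
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


# stage -> list of (f_lo, f_hi, default relative amplitude)
_STAGE_BANDS = {
    "N3": [(0.5, 2.0, 3.0)],
    "Wake": [(8.0, 12.0, 1.8)],
    "N1": [(4.0, 7.0, 1.5)],
    "N2": [(4.0, 7.0, 1.2)],  # plus spindle bursts added separately
    "REM": [(4.0, 7.0, 0.6), (15.0, 30.0, 0.6)],
}


def _spindle_bursts(n: int, fs: float, n_ch: int, rate_hz: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Gaussian-windowed 12–14 Hz bursts of 0.5–1 s at Poisson times."""
    out = np.zeros((n_ch, n))
    t = np.arange(n) / fs
    n_events = rng.poisson(rate_hz * n / fs)
    for _ in range(n_events):
        centre = rng.uniform(0, n / fs)
        dur = rng.uniform(0.5, 1.0)
        f = rng.uniform(12.0, 14.0)
        phase = rng.uniform(0, 2 * np.pi)
        env = np.exp(-0.5 * ((t - centre) / (dur / 4)) ** 2)
        burst = env * np.sin(2 * np.pi * f * t + phase)
        out += 2.0 * burst  # same burst on both derivations
    return out


def generate_sleep_epoch(stage: str, cfg: SyntheticConfig,
                         rng: np.random.Generator, source_id: str = "") -> EEGSegment:
    """One sleep epoch with the stage's characteristic spectral signature."""
    if stage not in SLEEP_STAGES:
        raise ValueError(f"unknown sleep stage {stage!r}; known: {SLEEP_STAGES}")
    n, fs, n_ch = cfg.n_samples, cfg.fs, cfg.n_channels
    x = cfg.background_std * pink_noise((n_ch, n), rng, cfg.pink_exponent)
    for f_lo, f_hi, amp in _STAGE_BANDS[stage]:
        gain = cfg.osc_gain.get(stage, amp)
        x = x + gain * cfg.background_std * _narrowband(n, fs, f_lo, f_hi, n_ch, rng)
    if stage == "N2":
        x = x + cfg.background_std * _spindle_bursts(n, fs, n_ch, cfg.spindle_rate_hz, rng)
    if stage == "REM":
        x = 0.7 * x  # REM is low-amplitude relative to the other stages
    return EEGSegment(
        data=x.astype(np.float32), fs=fs, label=STAGE_TO_ID[stage],
        channel_names=(["Fpz-Cz-like", "Pz-Oz-like"][:n_ch] if n_ch <= 2
                       else [f"ch{i}" for i in range(n_ch)]),
        source_id=source_id or f"sleep-{stage}",
    )


def spike_template(fs: float, spike_ms: float = 70.0, wave_ms: float = 200.0) -> np.ndarray:
    """Biphasic interictal spike-wave: sharp ~70 ms spike then a slower wave."""
    n_spike = max(int(round(spike_ms / 1000 * fs)), 3)
    n_wave = max(int(round(wave_ms / 1000 * fs)), 3)
    t1 = np.linspace(0, np.pi, n_spike)
    spike = np.sin(t1) ** 2
    t2 = np.linspace(0, np.pi, n_wave)
    wave = -0.4 * np.sin(t2)
    return np.concatenate([spike, wave])


def generate_focal_segment(is_focal: bool, cfg: SyntheticConfig,
                           rng: np.random.Generator, source_id: str = "",
                           return_events: bool = False):
    """One two-channel iEEG-like segment, focal or non-focal.

    With ``return_events=True`` returns ``(segment, spike_onsets)`` where
    ``spike_onsets`` are the sample indices of the injected interictal spikes
    (always empty for non-focal segments) — instrumentation for tests of the
    event model.
    """
    n, fs, n_ch = cfg.n_samples, cfg.fs, cfg.n_channels
    x = cfg.background_std * pink_noise((n_ch, n), rng, cfg.pink_exponent)
    # broadband oscillatory content common to both classes
    x = x + 0.8 * cfg.background_std * _narrowband(n, fs, 4.0, 30.0, n_ch, rng)
    events: list[int] = []
    if is_focal:
        # slow amplitude-modulated nonstationarity
        t = np.arange(n) / fs
        f_mod = rng.uniform(0.05, 0.2)
        phase = rng.uniform(0, 2 * np.pi)
        x = x * (1.0 + 0.4 * np.sin(2 * np.pi * f_mod * t + phase))
        tmpl = spike_template(fs)
        n_events = rng.poisson(cfg.spike_rate_hz * n / fs)
        for _ in range(n_events):
            start = int(rng.integers(0, max(n - len(tmpl), 1)))
            events.append(start)
            amp = cfg.spike_amplitude * rng.uniform(0.7, 1.3)
            pol = rng.choice([-1.0, 1.0])
            for c in range(n_ch):
                ch_gain = rng.uniform(0.6, 1.0)
                x[c, start:start + len(tmpl)] += pol * amp * ch_gain * tmpl[: n - start]
    seg = EEGSegment(
        data=x.astype(np.float32), fs=fs,
        label=FOCAL if is_focal else NON_FOCAL,
        channel_names=[f"iEEG{i}" for i in range(n_ch)],
        source_id=source_id or ("focal" if is_focal else "non-focal"),
    )
    return (seg, events) if return_events else seg


def build_subset(cfg: SyntheticConfig, rng: np.random.Generator) -> list[EEGSegment]:
    """Generate exactly ``cfg.composition[class]`` segments per class, shuffled.

    Sleep-stage class names and ``focal``/``non_focal`` get their full
    generative model; ad-hoc class names (toy labels in tests) are labelled by
    their position in the sorted composition keys and filled with 1/f
    background noise.
    """
    segments: list[EEGSegment] = []
    for pos, (cls, count) in enumerate(sorted(cfg.composition.items())):
        if count < 0:
            raise ValueError(f"negative count for class {cls!r}")
        for j in range(count):
            sid = f"{cls}-{j:05d}"
            if cfg.task == "sleep" and cls in SLEEP_STAGES:
                seg = generate_sleep_epoch(cls, cfg, rng, sid)
            elif cfg.task == "focal" and cls in ("focal", "non_focal"):
                seg = generate_focal_segment(cls == "focal", cfg, rng, sid)
            else:
                x = cfg.background_std * pink_noise((cfg.n_channels, cfg.n_samples),
                                                    rng, cfg.pink_exponent)
                seg = EEGSegment(data=x.astype(np.float32), fs=cfg.fs, label=pos,
                                 source_id=sid)
            segments.append(seg)
    order = rng.permutation(len(segments))
    return [segments[i] for i in order]


def make_shifted_eval_set(dataset: list[EEGSegment], shift_frac: float,
                          gain_jitter: float, rng: np.random.Generator
                          ) -> list[EEGSegment]:
    """Distribution-shifted copy of a dataset: random circular shift + gain.

    Each segment is circularly shifted by a random integer within
    ±``shift_frac``·T and rescaled by a gain uniform in
    [1 − gain_jitter, 1 + gain_jitter]; labels are preserved. Emulates sensor
    timing jitter and impedance drift between acquisition sessions.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    out = []
    for seg in dataset:
        max_dt = int(np.floor(shift_frac * seg.n_samples))
        dt = int(rng.integers(-max_dt, max_dt + 1)) if max_dt > 0 else 0
        gain = float(rng.uniform(1 - gain_jitter, 1 + gain_jitter)) if gain_jitter > 0 else 1.0
        out.append(amplitude_scale(time_shift(seg, dt), gain))
    return out


def relative_band_power(seg: EEGSegment, f_lo: float, f_hi: float) -> float:
    """Welch-estimated fraction of total power inside [f_lo, f_hi], averaged
    over channels."""
    nper = min(seg.n_samples, int(4 * seg.fs))
    freqs, psd = sp_signal.welch(seg.data, fs=seg.fs, nperseg=nper, axis=1)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    total = psd.sum(axis=1)
    frac = (psd[:, band].sum(axis=1) / np.where(total > 0, total, 1.0))
    return float(frac.mean())
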