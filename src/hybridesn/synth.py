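"""Seeded synthetic biosignal generators and segment utilities.

Real benchmark recordings for the two target applications — single-channel
scalp EEG for seizure detection and 8-channel surface EMG for finger-
movement decoding — are external datasets.  These generators emulate
their *shape* so that every pipeline stage is testable offline:

* EEG-like: single channel at 173.61 Hz, 23.6 s segments; class 0 is
  pink-noise background with a moderate alpha-band oscillation, class 1
  superimposes high-amplitude rhythmic ~3 Hz bursts (ictal-like activity)
  over at least half the segment.
* EMG-like: 8 channels at 4 kHz band-limited to 20-450 Hz, 20 s segments,
  12-bit quantised; each class is a distinct per-channel contraction
  envelope modulating the band-limited noise.

The classes are deliberately easier to separate than real recordings:
passing tests demonstrate pipeline correctness, not clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

from ._exceptions import ConfigurationError, InputError

__all__ = [
    "SignalDataset",
    "gen_eeg_like",
    "gen_emg_like",
    "split_segments",
    "train_test_split",
]


@dataclass
class SignalDataset:
    """Labeled collection of equal-shape (channels x samples) segments."""

    segments: List[np.ndarray]
    labels: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.segments) != len(self.labels):
            raise InputError(
                f"{len(self.segments)} segments but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_channels(self) -> int:
        return self.segments[0].shape[0]

    def as_array(self) -> np.ndarray:
        """Stack segments into (n_segments, channels, samples)."""
        return np.stack(self.segments)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC divide
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """White noise restricted to [lo, hi] Hz by an FFT brick-wall mask."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    std = x.std()
    return x / std if std > 0 else x


def gen_eeg_like(
    n_per_class: int = 100,
    duration_s: float = 23.6,
    fs: float = 173.61,
    seed: int = 0,
    burst_freq: float = 3.0,
    burst_amplitude: float = 5.0,
    burst_fraction: float = 0.9,
    burst_cycle_s: float = 1.0,
) -> SignalDataset:
    """Two-class single-channel EEG-like dataset.

    Class 0 segments are pink-noise background plus a moderate 8-12 Hz
    oscillation; class 1 adds rhythmic ``burst_freq`` bursts of amplitude
    ``burst_amplitude`` (>= 3x background).  Bursts recur every
    ``burst_cycle_s`` seconds with duty cycle ``burst_fraction``, so the
    abnormal activity spans the segment the way ictal activity does while
    still arriving in discrete bursts.  Deterministic per seed.
    """
    n_samples = int(np.floor(duration_s * fs))
    if n_samples < 10:
        raise ConfigurationError(
            f"duration_s*fs = {duration_s * fs:.1f} gives fewer than 10 samples"
        )
    if burst_amplitude < 3.0:
        raise ConfigurationError(
            f"burst_amplitude={burst_amplitude} must be >= 3 (class contrast)"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    segments, labels = [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            x = _pink_noise(rng, n_samples)
            alpha_f = rng.uniform(8.0, 12.0)
            x = x + 0.5 * np.sin(2 * np.pi * alpha_f * t + rng.uniform(0, 2 * np.pi))
            if label == 1:
                # rhythmic high-amplitude bursts with duty cycle
                # burst_fraction, recurring every burst_cycle_s seconds
                phase = rng.uniform(0.0, burst_cycle_s)
                env = ((t + phase) % burst_cycle_s) < burst_fraction * burst_cycle_s
                f_b = burst_freq * rng.uniform(0.9, 1.1)
                burst = burst_amplitude * np.sin(
                    2 * np.pi * f_b * t + rng.uniform(0, 2 * np.pi)
                )
                x = x + env * burst
            segments.append(x[None, :])
            labels.append(label)
    return SignalDataset(
        segments=segments,
        labels=np.array(labels),
        fs=fs,
        meta={
            "generator": "eeg_like",
            "seed": seed,
            "n_per_class": n_per_class,
            "duration_s": duration_s,
            "burst_freq": burst_freq,
            "burst_amplitude": burst_amplitude,
            "burst_fraction": burst_fraction,
        },
    )


def gen_emg_like(
    n_segments_per_class: int = 24,
    n_classes: int = 5,
    channels: int = 8,
    duration_s: float = 20.0,
    fs: float = 4000.0,
    seed: int = 0,
    band: tuple[float, float] = (20.0, 450.0),
    envelope_contrast: float = 4.0,
) -> SignalDataset:
    """Multi-class multi-channel EMG-like dataset.

    Each class has a fixed per-channel activation profile (which channels
    "contract", drawn once per class) that modulates 20-450 Hz band-limited
    noise with a slow contraction envelope; signals are quantised to the
    12-bit ADC integer range.  Deterministic per seed.
    """
    if n_classes < 2:
        raise ConfigurationError(f"n_classes={n_classes} must be >= 2")
    if channels < 1:
        raise ConfigurationError(f"channels={channels} must be >= 1")
    lo, hi = band
    if not (0 < lo < hi) or hi > fs / 2:
        raise ConfigurationError(
            f"band={band} invalid for fs={fs} (need 0 < lo < hi <= fs/2)"
        )
    n_samples = int(np.floor(duration_s * fs))
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs

    # one activation profile per class: channel gains in [1, contrast]
    profiles = 1.0 + (envelope_contrast - 1.0) * rng.random((n_classes, channels))

    adc_max = 2**11 - 1  # 12-bit signed range
    segments, labels = [], []
    for c in range(n_classes):
        for _ in range(n_segments_per_class):
            seg = np.empty((channels, n_samples))
            # slow class-independent contraction rhythm, >= lo Hz kept out
            wob = 0.75 + 0.25 * np.sin(
                2 * np.pi * rng.uniform(0.3, 0.8) * t + rng.uniform(0, 2 * np.pi)
            )
            for ch in range(channels):
                # small inner margin keeps envelope sidebands inside the band
                noise = _bandlimited_noise(rng, n_samples, fs, lo + 2.0, hi - 2.0)
                seg[ch] = profiles[c, ch] * wob * noise
            # 12-bit quantisation: 4-sigma headroom in the design range
            seg = np.clip(seg / (4.0 * envelope_contrast), -1.0, 1.0)
            seg = np.round(seg * adc_max)
            segments.append(seg)
            labels.append(c)
    return SignalDataset(
        segments=segments,
        labels=np.array(labels),
        fs=fs,
        meta={
            "generator": "emg_like",
            "seed": seed,
            "n_segments_per_class": n_segments_per_class,
            "n_classes": n_classes,
            "channels": channels,
            "duration_s": duration_s,
            "band": band,
            "envelope_contrast": envelope_contrast,
            "profiles": profiles,
        },
    )


def split_segments(ds: SignalDataset, part_len_s: float) -> SignalDataset:
    """Cut every segment into consecutive non-overlapping parts.

    Parts are ``part_len_s`` seconds long; a leftover tail shorter than one
    part is discarded; labels are inherited.  Splitting 20 s segments into
    4 s parts multiplies the per-class count by five.
    """
    part_len = int(np.floor(part_len_s * ds.fs))
    if part_len < 1:
        raise InputError(f"part_len_s={part_len_s} is shorter than one sample")
    seg_len = ds.segments[0].shape[1]
    if part_len > seg_len:
        raise InputError(
            f"part of {part_len} samples is longer than segments of {seg_len}"
        )
    segments, labels = [], []
    for seg, label in zip(ds.segments, ds.labels):
        n_parts = seg.shape[1] // part_len
        for i in range(n_parts):
            segments.append(seg[:, i * part_len : (i + 1) * part_len])
            labels.append(label)
    return SignalDataset(
        segments=segments,
        labels=np.array(labels),
        fs=ds.fs,
        meta={**ds.meta, "split_part_len_s": part_len_s},
    )


def train_test_split(
    ds: SignalDataset,
    n_train_per_class: int,
    n_test_per_class: int,
    seed: int = 0,
) -> tuple[SignalDataset, SignalDataset]:
    """Disjoint seeded stratified split into train and test datasets."""
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for label in np.unique(ds.labels):
        idx = np.nonzero(ds.labels == label)[0]
        need = n_train_per_class + n_test_per_class
        if len(idx) < need:
            raise InputError(
                f"class {label!r} has {len(idx)} segments; "
                f"{need} requested for the split"
            )
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train_per_class])
        test_idx.extend(perm[n_train_per_class:need])

    def _subset(indices) -> SignalDataset:
        indices = np.array(sorted(indices))
        return SignalDataset(
            segments=[ds.segments[i] for i in indices],
            labels=ds.labels[indices],
            fs=ds.fs,
            meta={**ds.meta, "split_seed": seed},
        )

    return _subset(train_idx), _subset(test_idx)
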