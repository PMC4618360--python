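"""Synthetic motor-imagery-like EEG with planted class structure.

Real motor imagery modulates ongoing sensorimotor rhythms: imagining a hand
movement *attenuates* mu (8-12 Hz) and beta (18-26 Hz) band power over the
contralateral sensorimotor cortex (event-related desynchronization, ERD).
The generator reproduces exactly that mechanism at the signal level: every
channel carries pink background noise plus white sensor noise plus an ongoing
band-limited oscillation (band-passed white noise); at the informative
channels of a class, the oscillation amplitude is multiplied by an
attenuation factor < 1 for trials of that class and left at baseline
otherwise. Uninformative channels are statistically identical across classes.

The planted (channel, band) ground truth lets selection quality be scored
exactly, which no recorded dataset allows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core_data import TrialSet, ValidationError
from .feature_bank import FilterBank, design_constant_q_bank

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "default_benchmark",
           "BENCHMARK_CHANNELS"]


@dataclass
class SyntheticSpec:
    """Generation parameters.

    ``informative`` maps each class label to a list of
    ``(channel_index, (low_hz, high_hz), attenuation)`` entries: during trials
    of that class, the oscillation in that band at that channel has its
    amplitude multiplied by ``attenuation`` (< 1, ERD). ``osc_amplitude`` is
    the baseline RMS of each planted oscillation relative to the pink
    background's unit scale.
    """

    n_channels: int = 20
    n_classes: int = 2
    trials_per_class: int = 100
    rate: float = 200.0
    trial_s: float = 3.0
    informative: dict[int, list[tuple[int, tuple[float, float], float]]] = field(
        default_factory=dict
    )
    osc_amplitude: float = 1.0
    background_amplitude: float = 1.0
    pink_exponent: float = 1.0
    sensor_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 4):
            raise ValidationError("n_classes must be 2 or 4")
        if self.n_channels < 1 or self.trials_per_class < 1:
            raise ValidationError("need at least one channel and one trial per class")
        if self.rate <= 0 or self.trial_s <= 0:
            raise ValidationError("rate and trial length must be positive")
        lows = [band[0] for entries in self.informative.values()
                for _, band, _ in entries]
        if lows and self.trial_s * self.rate < 4 * self.rate / min(lows):
            raise ValidationError("trials must hold >= 4 cycles of the lowest band")
        for cls, entries in self.informative.items():
            if not (0 <= cls < self.n_classes):
                raise ValidationError(f"informative class {cls} out of range")
            for ch, (lo, hi), att in entries:
                if not (0 <= ch < self.n_channels):
                    raise ValidationError(f"informative channel {ch} out of range")
                if not (0 < lo < hi < self.rate / 2):
                    raise ValidationError(f"invalid band ({lo}, {hi})")
                if not (0 < att < 1):
                    raise ValidationError("attenuation must lie in (0, 1): ERD")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_s * self.rate))


@dataclass
class GroundTruth:
    """Planted structure: informative channels per class, and the matching
    (channel, band-index) pairs under a filter bank (default 13-band)."""

    informative_channels: dict[int, list[int]]
    informative_pairs: list[tuple[int, int]]

    @property
    def all_channels(self) -> np.ndarray:
        chans = sorted({c for chs in self.informative_channels.values() for c in chs})
        return np.array(chans, dtype=int)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                exponent: float) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise, unit variance."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    return out / np.where(sd > 0, sd, 1.0)


def _band_noise(rng: np.random.Generator, shape: tuple[int, ...],
                band: tuple[float, float], rate: float) -> np.ndarray:
    """Band-limited unit-RMS oscillation: band-passed white noise."""
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    rms = np.sqrt((x ** 2).mean(axis=-1, keepdims=True))
    return x / np.where(rms > 0, rms, 1.0)


def generate(spec: SyntheticSpec,
             bank: FilterBank | None = None) -> tuple[TrialSet, GroundTruth]:
    """Generate a labeled TrialSet and its ground truth.

    Every channel of every trial receives pink background plus white sensor
    noise. Each (class, channel, band) entry in ``spec.informative`` adds an
    ongoing oscillation in that band at that channel across *all* trials,
    whose amplitude is multiplied by the attenuation factor when the trial
    belongs to that class. Labels are balanced and trials are ordered by
    class, trial i having label i % n_classes. Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_trials = spec.n_classes * spec.trials_per_class
    n, c, s = n_trials, spec.n_channels, spec.n_samples
    labels = np.arange(n) % spec.n_classes

    data = spec.background_amplitude * _pink_noise(rng, (n, c, s), spec.pink_exponent)
    data += spec.sensor_noise_sd * rng.standard_normal((n, c, s))

    # ongoing oscillations with class-dependent amplitude at planted channels
    for cls, entries in spec.informative.items():
        for ch, band, att in entries:
            osc = _band_noise(rng, (n, s), band, spec.rate)
            amp = np.where(labels == cls, att, 1.0) * spec.osc_amplitude
            data[:, ch, :] += amp[:, None] * osc

    ts = TrialSet(
        data=data,
        labels=labels,
        rate=spec.rate,
        channel_names=[f"CH{i}" for i in range(c)],
    )
    bank = bank or design_constant_q_bank()
    pairs: set[tuple[int, int]] = set()
    for entries in spec.informative.values():
        for ch, (lo, hi), _ in entries:
            for b, (blo, bhi) in enumerate(bank.bands):
                if blo < hi and bhi > lo:  # overlapping bands share the signal
                    pairs.add((ch, b))
    gt = GroundTruth(
        informative_channels={
            cls: sorted({ch for ch, _, _ in entries})
            for cls, entries in spec.informative.items()
        },
        informative_pairs=sorted(pairs),
    )
    return ts, gt


# Planted channels of the default benchmark: two per "hemisphere" on the
# 4 x 5 grid montage (indices r*5 + c), none adjacent to another.
BENCHMARK_CHANNELS = {"left": [6, 8], "right": [16, 18]}

MU_BAND = (8.0, 12.0)


def default_benchmark(seed: int = 0) -> tuple[TrialSet, GroundTruth]:
    """The canonical recovery fixture.

    20 channels (a 4 x 5 grid), 2 classes, 100 trials per class, 200 Hz, 3 s
    trials. Four informative channels carry an ongoing mu-band (8-12 Hz)
    oscillation whose amplitude halves (attenuation 0.5, i.e. power x 0.25)
    during trials of the associated class: channels 6 and 8 desynchronize for
    class 0 ("left"), channels 16 and 18 for class 1 ("right") — the
    contralateral-ERD picture over sensorimotor cortex.
    """
    informative = {
        0: [(ch, MU_BAND, 0.5) for ch in BENCHMARK_CHANNELS["left"]],
        1: [(ch, MU_BAND, 0.5) for ch in BENCHMARK_CHANNELS["right"]],
    }
    spec = SyntheticSpec(
        n_channels=20,
        n_classes=2,
        trials_per_class=100,
        rate=200.0,
        trial_s=3.0,
        informative=informative,
        seed=seed,
    )
    return generate(spec)
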