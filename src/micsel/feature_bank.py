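"""Constant-Q sub-band decomposition and Hilbert-envelope band-power features.

Motor-imagery information in scalp EEG concentrates in narrow, subject-specific
rhythms between roughly 5 and 35 Hz (mu ~8-12 Hz, beta ~18-26 Hz). Rather than
committing to fixed mu/beta boxes, the 5-35 Hz range is decomposed into 13
partially overlapping sub-bands on a constant-Q (proportional-bandwidth) grid:
band centers form a geometric series ``center_k = f0 * ratio**(k-1)`` and each
band spans ``center_k * (1 +/- frac_bw/2)``. With the defaults (f0 = 6 Hz,
ratio = 8/7, fractional bandwidth 0.25) the first band is 5.25-6.75 Hz and the
thirteenth 26.07-33.51 Hz, consecutive lower edges coinciding with the
previous center.

Per trial and channel, each sub-band signal's instantaneous amplitude is taken
as the magnitude of the analytic signal (Hilbert transform), and the feature
is its average over the trial — a band-power summary robust to phase.
Features are min-max normalized to (-1, 1) per feature, with parameters fit
on training data only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_data import FeatureMap, FeatureMatrix, TrialSet, ValidationError

__all__ = [
    "FilterBank",
    "design_constant_q_bank",
    "bandpass",
    "hilbert_envelope",
    "extract_features",
    "minmax_normalize",
]


@dataclass(frozen=True)
class FilterBank:
    """An ordered set of (low, high) band edges in Hz with their centers."""

    bands: tuple[tuple[float, float], ...]
    centers: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.bands) != len(self.centers):
            raise ValidationError("bands and centers must have the same length")
        if len(self.bands) == 0:
            raise ValidationError("filter bank needs at least one band")
        fbw = [(hi - lo) / c for (lo, hi), c in zip(self.bands, self.centers)]
        if max(fbw) - min(fbw) > 1e-9:
            raise ValidationError("fractional bandwidth must be constant across bands")
        if any(c2 <= c1 for c1, c2 in zip(self.centers, self.centers[1:])):
            raise ValidationError("bands must be ordered by ascending center")

    @property
    def n_bands(self) -> int:
        return len(self.bands)


def design_constant_q_bank(
    f_start_center: float = 6.0,
    ratio: float = 8.0 / 7.0,
    frac_bw: float = 0.25,
    n_bands: int = 13,
) -> FilterBank:
    """Design the constant-Q filter bank.

    Parameters
    ----------
    f_start_center
        Center frequency of the first band, Hz.
    ratio
        Geometric step between consecutive centers. The default 8/7 together
        with ``frac_bw=0.25`` makes each band's lower edge coincide with the
        previous band's center, so consecutive bands overlap by construction.
    frac_bw
        Fractional bandwidth (high - low) / center, identical for all bands.
    n_bands
        Number of bands; 13 covers 5.25-33.51 Hz at the defaults.
    """
    if ratio <= 1:
        raise ValidationError("ratio must exceed 1")
    if not (0 < frac_bw < 2):
        raise ValidationError("fractional bandwidth must lie in (0, 2)")
    if n_bands < 1:
        raise ValidationError("need at least one band")
    centers = f_start_center * ratio ** np.arange(n_bands)
    lows = centers * (1 - frac_bw / 2)
    highs = centers * (1 + frac_bw / 2)
    return FilterBank(
        bands=tuple((float(lo), float(hi)) for lo, hi in zip(lows, highs)),
        centers=tuple(float(c) for c in centers),
    )


def _band_sos(band: tuple[float, float], rate: float) -> np.ndarray:
    low, high = band
    if not (0 < low < high):
        raise ValidationError(f"invalid band edges {band}")
    if high >= rate / 2:
        raise ValidationError(
            f"band {band} exceeds the Nyquist frequency {rate / 2} Hz"
        )
    return sps.butter(4, [low, high], btype="bandpass", fs=rate, output="sos")


def bandpass(ts: TrialSet, band: tuple[float, float]) -> TrialSet:
    """Zero-phase band-pass (4th-order Butterworth, forward-backward).

    The monotonic Butterworth response has no passband ripple, and the
    forward-backward pass squares the magnitude response, giving well over
    20 dB of attenuation one octave outside the band edges.
    """
    sos = _band_sos(band, ts.rate)
    out = sps.sosfiltfilt(sos, ts.data, axis=-1)
    return TrialSet(
        data=out,
        labels=ts.labels.copy(),
        rate=ts.rate,
        channel_names=list(ts.channel_names),
    )


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude: magnitude of the analytic signal.

    Operates along the last axis; for a narrow-band signal a(t)*sin(2*pi*f*t)
    with slowly varying a(t) > 0 this recovers a(t) away from the edges.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 8:
        raise ValidationError("signal too short for envelope extraction (< 8 samples)")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains NaN or infinite values")
    return np.abs(sps.hilbert(x, axis=-1))


def extract_features(ts: TrialSet, bank: FilterBank) -> FeatureMatrix:
    """Band-power feature table: mean Hilbert envelope per (trial, channel, band).

    Filtering and envelope extraction are performed trial-wise. Features are
    concatenated channel-major, band-minor (feature ``i`` = channel
    ``i // n_bands``, band ``i % n_bands``), giving ``n_channels * n_bands``
    columns — 767 for 59 channels or 806 for 62 with the 13-band bank.
    """
    lowest = bank.bands[0]
    min_len = int(np.ceil(3 * ts.rate / lowest[0]))
    if ts.n_samples < min_len:
        raise ValidationError(
            f"trials of {ts.n_samples} samples are too short for the lowest band "
            f"{lowest[0]:.2f}-{lowest[1]:.2f} Hz (need >= {min_len} samples)"
        )
    feats = np.empty((ts.n_trials, ts.n_channels, bank.n_bands))
    for b, band in enumerate(bank.bands):
        sub = sps.sosfiltfilt(_band_sos(band, ts.rate), ts.data, axis=-1)
        feats[:, :, b] = hilbert_envelope(sub).mean(axis=-1)
    fmap = FeatureMap(n_channels=ts.n_channels, n_bands=bank.n_bands)
    return FeatureMatrix(
        values=feats.reshape(ts.n_trials, fmap.n_features),
        labels=ts.labels.copy(),
        map=fmap,
    )


def minmax_normalize(
    fm: FeatureMatrix,
    new_min: float = -1.0,
    new_max: float = 1.0,
    params: tuple[np.ndarray, np.ndarray] | None = None,
) -> FeatureMatrix:
    """Min-max rescale each feature to ``[new_min, new_max]``.

    ``XN = (new_max - new_min) * (X - Min) / (Max - Min) + new_min``.

    When ``params`` (per-feature Min, Max) is omitted it is fit from ``fm``
    itself — the training convention. Supplying training-fit params to a test
    matrix may legitimately produce values outside the target range; they are
    left unclipped. Constant features (Max == Min) map to the range midpoint
    with a warning.
    """
    if new_max <= new_min:
        raise ValidationError("new_max must exceed new_min")
    if params is None:
        mn = fm.values.min(axis=0)
        mx = fm.values.max(axis=0)
    else:
        mn = np.asarray(params[0], dtype=float)
        mx = np.asarray(params[1], dtype=float)
        if mn.shape != (fm.n_features,) or mx.shape != (fm.n_features,):
            raise ValidationError("params must provide one (Min, Max) per feature")
    span = mx - mn
    degenerate = span <= 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} constant feature(s) mapped to the range midpoint",
            stacklevel=2,
        )
    safe_span = np.where(degenerate, 1.0, span)
    out = (new_max - new_min) * (fm.values - mn) / safe_span + new_min
    out[:, degenerate] = 0.5 * (new_min + new_max)
    return FeatureMatrix(
        values=out,
        labels=fm.labels.copy(),
        map=fm.map,
        norm_params=(mn.copy(), mx.copy()),
    )
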