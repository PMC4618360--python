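"""Resampling, execution-window cropping, and surface Laplacian filtering.

The surface Laplacian subtracts from each electrode the mean of its montage
neighbors, ``V_j - (1/n) * sum_{k in S_j} V_k``, accentuating localized
cortical activity and suppressing the spatial smearing introduced by volume
conduction. All channels are transformed simultaneously from the unfiltered
input; the filter is linear and annihilates spatially constant signals.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core_data import Montage, Recording, TrialSet, ValidationError

__all__ = ["downsample", "crop_execution", "laplacian_filter"]


def downsample(ts: TrialSet | Recording, target_rate: float) -> TrialSet | Recording:
    """Decimate to ``target_rate`` after zero-phase anti-alias low-pass.

    The original rate must be an integer multiple of the target (e.g. 1000 to
    200 Hz). The anti-alias filter is an order-8 zero-phase Butterworth with
    cutoff at 0.4 x target_rate, giving well over 40 dB of attenuation at the
    new Nyquist frequency.
    """
    if target_rate >= ts.rate:
        raise ValidationError(
            f"target rate {target_rate} Hz must be below current rate {ts.rate} Hz"
        )
    factor_f = ts.rate / target_rate
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9:
        raise ValidationError(
            f"rate {ts.rate} Hz is not an integer multiple of {target_rate} Hz"
        )
    sos = signal.butter(8, 0.4 * target_rate, btype="low", fs=ts.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=-1)
    decimated = filtered[..., ::factor]
    if isinstance(ts, TrialSet):
        return TrialSet(
            data=decimated,
            labels=ts.labels.copy(),
            rate=float(target_rate),
            channel_names=list(ts.channel_names),
        )
    return Recording(
        data=decimated, rate=float(target_rate), channel_names=list(ts.channel_names)
    )


def crop_execution(ts: TrialSet, start_s: float, end_s: float) -> TrialSet:
    """Restrict every trial to the execution window ``[start_s, end_s)``.

    Times are relative to trial start; the window is half-open with
    floor-based sample indexing, so an 11 s trial at 200 Hz cropped to
    [0.5, 3.0) keeps exactly 500 samples.
    """
    duration = ts.n_samples / ts.rate
    if not (0 <= start_s < end_s):
        raise ValidationError(
            f"need 0 <= start < end, got [{start_s}, {end_s})"
        )
    if end_s > duration + 1e-12:
        raise ValidationError(
            f"window end {end_s} s exceeds trial duration {duration} s"
        )
    i0 = int(np.floor(start_s * ts.rate))
    i1 = int(np.floor(end_s * ts.rate))
    return TrialSet(
        data=ts.data[:, :, i0:i1],
        labels=ts.labels.copy(),
        rate=ts.rate,
        channel_names=list(ts.channel_names),
    )


def laplacian_filter(ts: TrialSet, montage: Montage) -> TrialSet:
    """Apply the surface Laplacian to every channel of every trial.

    Each output channel is computed from the *raw* input of that channel and
    its montage neighbors; channels are never updated sequentially in place,
    so the result does not depend on channel order.
    """
    missing = [ch for ch in ts.channel_names if ch not in set(montage.channels)]
    if missing:
        raise ValidationError(f"channels missing from montage: {missing}")
    idx = {ch: i for i, ch in enumerate(ts.channel_names)}
    # neighbor-mean operator restricted to the channels present in the data
    op = np.eye(ts.n_channels)
    for ch in ts.channel_names:
        nbrs = [nb for nb in montage.neighbors[ch] if nb in idx]
        if not nbrs:
            raise ValidationError(
                f"channel {ch!r} has no montage neighbors among the data channels"
            )
        for nb in nbrs:
            op[idx[ch], idx[nb]] -= 1.0 / len(nbrs)
    out = np.einsum("ij,tjs->tis", op, ts.data)
    return TrialSet(
        data=out,
        labels=ts.labels.copy(),
        rate=ts.rate,
        channel_names=list(ts.channel_names),
    )
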