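"""Domain containers and file I/O shared by every pipeline stage.

Conventions used throughout the package: channel, trial, band and feature
indices are all 0-based; class labels are integers ``0..K-1``; epoched EEG is
stored as a dense float array of shape ``(n_trials, n_channels, n_samples)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ValidationError",
    "FormatError",
    "Montage",
    "Recording",
    "TrialSet",
    "FeatureMap",
    "FeatureMatrix",
    "read_edf",
    "write_edf",
    "read_matrix",
    "write_matrix",
    "load_montage",
    "save_montage",
    "default_montage",
    "grid_montage",
    "epoch_recording",
]


class ValidationError(ValueError):
    """Input violates a documented precondition or container invariant."""


class FormatError(ValueError):
    """A file is structurally unreadable as the format it claims to be."""


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------


@dataclass
class Montage:
    """Electrode layout: names, schematic 2-D positions, Laplacian neighbors.

    ``neighbors[name]`` is the set of surrounding electrodes subtracted (as a
    mean) from ``name`` by the surface Laplacian. Interior electrodes of the
    bundled layouts have 4 neighbors; peripheral ones 2 or 3.
    """

    channels: list[str]
    positions: dict[str, tuple[float, float]]
    neighbors: dict[str, list[str]]

    def __post_init__(self) -> None:
        known = set(self.channels)
        if len(known) != len(self.channels):
            raise ValidationError("duplicate channel names in montage")
        for ch in self.channels:
            if ch not in self.positions:
                raise ValidationError(f"channel {ch!r} has no position")
            nbrs = self.neighbors.get(ch)
            if not nbrs:
                raise ValidationError(f"channel {ch!r} has no neighbors")
            for nb in nbrs:
                if nb == ch:
                    raise ValidationError(f"channel {ch!r} lists itself as neighbor")
                if nb not in known:
                    raise ValidationError(
                        f"channel {ch!r} lists unknown neighbor {nb!r}"
                    )
            if len(set(nbrs)) != len(nbrs):
                raise ValidationError(f"channel {ch!r} has duplicate neighbors")

    def subset(self, channels: list[str]) -> "Montage":
        """Restrict the montage to ``channels``, dropping neighbor links that
        point outside the subset (peripheral channels simply lose neighbors)."""
        keep = set(channels)
        if not keep <= set(self.channels):
            missing = sorted(keep - set(self.channels))
            raise ValidationError(f"channels not in montage: {missing}")
        neighbors = {
            ch: [nb for nb in self.neighbors[ch] if nb in keep] for ch in channels
        }
        return Montage(
            channels=list(channels),
            positions={ch: self.positions[ch] for ch in channels},
            neighbors=neighbors,
        )


# ---------------------------------------------------------------------------
# Signal containers
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """A continuous multichannel recording (channels x samples), in µV."""

    data: np.ndarray
    rate: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("Recording data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError("channel_names length must match data")


@dataclass
class TrialSet:
    """Epoched EEG: ``data`` is (n_trials, n_channels, n_samples), one integer
    class label per trial, a common sampling rate, and ordered channel names."""

    data: np.ndarray
    labels: np.ndarray
    rate: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValidationError(
                "TrialSet data must be 3-D (trials x channels x samples)"
            )
        if self.labels.shape != (self.data.shape[0],):
            raise ValidationError("labels length must equal number of trials")
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValidationError("channel_names length must match channel axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def epoch_recording(
    rec: Recording,
    onsets_s: np.ndarray,
    duration_s: float,
    labels: np.ndarray,
) -> TrialSet:
    """Cut a continuous recording into fixed-length labeled trials."""
    onsets_s = np.asarray(onsets_s, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if onsets_s.shape != labels.shape:
        raise ValidationError("one label per onset required")
    n = int(round(duration_s * rec.rate))
    if n <= 0:
        raise ValidationError("duration must be positive")
    trials = []
    for t0 in onsets_s:
        i0 = int(np.floor(t0 * rec.rate))
        if i0 < 0 or i0 + n > rec.data.shape[1]:
            raise ValidationError(f"trial at {t0} s extends outside the recording")
        trials.append(rec.data[:, i0 : i0 + n])
    return TrialSet(
        data=np.stack(trials),
        labels=labels,
        rate=rec.rate,
        channel_names=list(rec.channel_names),
    )


# ---------------------------------------------------------------------------
# Feature containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureMap:
    """Bijection between flat feature indices and (channel, band) pairs.

    Features are concatenated channel-major, band-minor: feature ``i`` belongs
    to channel ``i // n_bands`` and band ``i % n_bands``.
    """

    n_channels: int
    n_bands: int

    @property
    def n_features(self) -> int:
        return self.n_channels * self.n_bands

    def channel_of(self, i: int | np.ndarray):
        return np.asarray(i) // self.n_bands

    def band_of(self, i: int | np.ndarray):
        return np.asarray(i) % self.n_bands

    def index_of(self, channel: int, band: int) -> int:
        if not (0 <= channel < self.n_channels and 0 <= band < self.n_bands):
            raise ValidationError("channel/band outside the map")
        return channel * self.n_bands + band

    def feature_names(self) -> list[str]:
        return [
            f"CH{c}_B{b}"
            for c in range(self.n_channels)
            for b in range(self.n_bands)
        ]


@dataclass
class FeatureMatrix:
    """Trials x features table plus labels, a FeatureMap, and (after
    normalization) the per-feature (min, max) parameters that produced it."""

    values: np.ndarray
    labels: np.ndarray
    map: FeatureMap
    norm_params: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValidationError("feature values must be 2-D (trials x features)")
        if self.labels.shape != (self.values.shape[0],):
            raise ValidationError("labels length must equal number of trials")
        if self.map.n_features != self.values.shape[1]:
            raise ValidationError("FeatureMap does not cover all feature columns")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------


def _parse_edf_header(path: Path) -> dict:
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            n_signals = int(hdr[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: malformed EDF header") from exc
        if n_signals <= 0:
            raise FormatError(f"{path}: EDF file declares {n_signals} signals")
        record_dur = float(hdr[244:252].decode("ascii").strip() or 1.0)
        sig = fh.read(256 * n_signals)
        if len(sig) < 256 * n_signals:
            raise FormatError(f"{path}: truncated EDF signal headers")
        # samples-per-record field: ns fields of 8 ASCII chars each
        off = n_signals * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
        spr = [
            int(sig[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
            for i in range(n_signals)
        ]
    return {"n_signals": n_signals, "samples_per_record": spr, "record_dur": record_dur}


def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ recording into a continuous :class:`Recording` (µV).

    Continuous recordings must be epoched (see :func:`epoch_recording`) before
    feature extraction or selection. All channels must share one sampling
    rate; mixed-rate EDF files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"EDF file not found: {path}")
    hdr = _parse_edf_header(path)
    if len(set(hdr["samples_per_record"])) != 1:
        raise FormatError(f"{path}: channels have inconsistent sampling rates")

    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    return Recording(data=data, rate=float(raw.info["sfreq"]), channel_names=raw.ch_names)


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF (one 1-second data record per second).

    The sampling rate must be a positive integer and the recording length a
    whole number of seconds. Values are quantized to the 16-bit digital range
    scaled to each channel's physical min/max.
    """
    path = Path(path)
    rate = int(rec.rate)
    if rate != rec.rate or rate <= 0:
        raise ValidationError("EDF writer requires an integer sampling rate")
    n_ch, n_samp = rec.data.shape
    if n_ch == 0:
        raise ValidationError("cannot write an EDF with zero channels")
    if n_samp % rate != 0:
        raise ValidationError("recording length must be a whole number of seconds")
    n_records = n_samp // rate

    dig_min, dig_max = -32768, 32767
    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("X X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        [pad(name, 16) for name in rec.channel_names],
        [pad("EEG", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{v:.8g}"[:8], 8) for v in phys_min],
        [pad(f"{v:.8g}"[:8], 8) for v in phys_max],
        [pad(str(dig_min), 8)] * n_ch,
        [pad(str(dig_max), 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(rate), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.rint((rec.data - phys_min[:, None]) * scale[:, None] + dig_min),
        dig_min,
        dig_max,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for fld in fields:
            fh.write(b"".join(fld))
        for r in range(n_records):
            block = digital[:, r * rate : (r + 1) * rate]
            fh.write(block.tobytes())


# ---------------------------------------------------------------------------
# Plain-matrix I/O (CSV + YAML sidecar)
# ---------------------------------------------------------------------------


def write_matrix(ts: TrialSet, data_path: str | Path, meta_path: str | Path) -> None:
    """Write a TrialSet as a delimited text matrix plus a YAML sidecar.

    The matrix holds one row per (trial, channel) pair, trial-major, with
    ``n_samples`` columns; the sidecar records shape, rate, labels and names.
    """
    data2d = ts.data.reshape(ts.n_trials * ts.n_channels, ts.n_samples)
    np.savetxt(data_path, data2d, delimiter=",", fmt="%.10g")
    meta = {
        "n_trials": int(ts.n_trials),
        "n_channels": int(ts.n_channels),
        "n_samples": int(ts.n_samples),
        "rate": float(ts.rate),
        "labels": [int(x) for x in ts.labels],
        "channel_names": list(ts.channel_names),
    }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh)


def read_matrix(data_path: str | Path, meta_path: str | Path) -> TrialSet:
    """Read the matrix format written by :func:`write_matrix`."""
    data_path, meta_path = Path(data_path), Path(meta_path)
    if not data_path.exists():
        raise IOError(f"matrix file not found: {data_path}")
    if not meta_path.exists():
        raise IOError(f"metadata file not found: {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    for key in ("n_trials", "n_channels", "n_samples", "rate", "labels"):
        if key not in meta:
            raise ValidationError(f"metadata missing required key {key!r}")
    n_t, n_c, n_s = meta["n_trials"], meta["n_channels"], meta["n_samples"]
    labels = np.asarray(meta["labels"], dtype=int)
    if labels.shape != (n_t,):
        raise ValidationError(
            f"metadata lists {labels.size} labels for {n_t} trials"
        )
    data2d = np.loadtxt(data_path, delimiter=",", ndmin=2)
    if data2d.shape != (n_t * n_c, n_s):
        raise ValidationError(
            f"matrix shape {data2d.shape} does not match metadata "
            f"({n_t}x{n_c} rows x {n_s} cols expected)"
        )
    names = meta.get("channel_names") or [f"CH{i}" for i in range(n_c)]
    return TrialSet(
        data=data2d.reshape(n_t, n_c, n_s),
        labels=labels,
        rate=float(meta["rate"]),
        channel_names=names,
    )


# ---------------------------------------------------------------------------
# Montage I/O and bundled layouts
# ---------------------------------------------------------------------------


def load_montage(path: str | Path) -> Montage:
    """Load a montage from a YAML file with ``channels``, ``positions`` and
    ``neighbors`` keys (see :func:`save_montage` for the schema)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"montage file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("channels", "positions", "neighbors"):
        if key not in cfg:
            raise ValidationError(f"montage file missing key {key!r}")
    positions = {k: (float(v[0]), float(v[1])) for k, v in cfg["positions"].items()}
    return Montage(
        channels=list(cfg["channels"]),
        positions=positions,
        neighbors={k: list(v) for k, v in cfg["neighbors"].items()},
    )


def save_montage(montage: Montage, path: str | Path) -> None:
    cfg = {
        "channels": list(montage.channels),
        "positions": {k: [float(v[0]), float(v[1])] for k, v in montage.positions.items()},
        "neighbors": {k: list(v) for k, v in montage.neighbors.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)


def _montage_from_grid(grid: dict[str, tuple[int, int]]) -> Montage:
    """Build a montage from integer grid coordinates: neighbors are the grid
    cells one step up/down/left/right, where occupied."""
    occupied = {rc: name for name, rc in grid.items()}
    channels = list(grid)
    positions = {name: (float(c), float(-r)) for name, (r, c) in grid.items()}
    neighbors: dict[str, list[str]] = {}
    for name, (r, c) in grid.items():
        nbrs = []
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if (rr, cc) in occupied:
                nbrs.append(occupied[(rr, cc)])
        neighbors[name] = nbrs
    return Montage(channels=channels, positions=positions, neighbors=neighbors)


# Rows of the bundled 10-20-style layout, front (row 0) to back, with the
# integer column of each electrode (midline = 0). 61 channels in total; any
# subset can be loaded for caps that record fewer.
_DEFAULT_ROWS: list[list[tuple[str, int]]] = [
    [("Fp1", -1), ("Fpz", 0), ("Fp2", 1)],
    [("AF7", -2), ("AF3", -1), ("AFz", 0), ("AF4", 1), ("AF8", 2)],
    [(n, c) for n, c in zip(
        ["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"], range(-4, 5))],
    [(n, c) for n, c in zip(
        ["FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"], range(-4, 5))],
    [(n, c) for n, c in zip(
        ["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"], range(-4, 5))],
    [(n, c) for n, c in zip(
        ["TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8"], range(-4, 5))],
    [(n, c) for n, c in zip(
        ["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"], range(-4, 5))],
    [("PO7", -2), ("PO3", -1), ("POz", 0), ("PO4", 1), ("PO8", 2)],
    [("O1", -1), ("Oz", 0), ("O2", 1)],
]


def default_montage() -> Montage:
    """The bundled 61-channel 10-20-style montage.

    Interior electrodes take their 4 grid neighbors (anterior, posterior,
    left, right); electrodes at the cap periphery take the 2-3 neighbors that
    exist. This is a schematic stand-in for standard extended 10-20 caps, not
    a measured head model.
    """
    grid = {
        name: (r, c)
        for r, row in enumerate(_DEFAULT_ROWS)
        for name, c in row
    }
    return _montage_from_grid(grid)


def grid_montage(n_rows: int, n_cols: int, prefix: str = "CH") -> Montage:
    """A full rectangular grid montage with generated channel names, useful
    for synthetic data. Channel ``{prefix}{r*n_cols+c}`` sits at row r, col c."""
    if n_rows < 1 or n_cols < 1:
        raise ValidationError("grid must have at least one row and column")
    grid = {
        f"{prefix}{r * n_cols + c}": (r, c)
        for r in range(n_rows)
        for c in range(n_cols)
    }
    return _montage_from_grid(grid)
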