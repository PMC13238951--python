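"""Reading, writing and conditioning of HD-MEA voltage recordings.

A recording is a channels × samples voltage matrix (µV) sampled on a regular
electrode grid (≤ 64 × 64, default 60 µm pitch). This module covers the
plumbing every analysis step relies on: an HDF5 container format, Fourier
anti-aliased temporal downsampling (e.g. 2 kHz acquisition → 100 Hz analysis
rate), spatial channel selection by id or anatomical region label, and a
robust SNR screen that flags dead or noisy electrodes.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal

MAX_GRID = 64  # largest supported electrode grid (64 × 64)
DEFAULT_PITCH_UM = 60.0
DEFAULT_SNR_THRESHOLD = 35.0


class FormatError(ValueError):
    """Raised when an HDF5 file does not conform to the documented layout."""


@dataclass
class Recording:
    """In-memory HD-MEA recording.

    Parameters
    ----------
    data:
        ``(n_channels, n_samples)`` float array of voltages in µV.
    fs:
        Sampling rate in Hz.
    coords:
        ``(n_channels, 2)`` integer array of 0-based ``(row, col)`` grid
        indices; physical position = index × ``pitch``.
    pitch:
        Electrode spacing in µm.
    channel_ids:
        Stable integer channel identifiers (defaults to ``0..n_channels-1``).
    groups:
        Optional map channel id → region label (e.g. ``"hippocampus"``).
    """

    data: np.ndarray
    fs: float
    coords: np.ndarray
    pitch: float = DEFAULT_PITCH_UM
    channel_ids: np.ndarray | None = None
    groups: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels × samples matrix")
        if self.data.shape[0] == 0:
            raise ValueError("recording must contain at least one channel")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.coords = np.asarray(self.coords, dtype=int)
        if self.coords.shape != (self.n_channels, 2):
            raise ValueError("coords must be (n_channels, 2)")
        if self.coords.min() < 0 or self.coords.max() >= MAX_GRID:
            raise ValueError(f"grid indices must lie in [0, {MAX_GRID})")
        uniq = {tuple(rc) for rc in self.coords}
        if len(uniq) != self.n_channels:
            raise ValueError("electrode coordinates must be unique per channel")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.n_channels)
        else:
            self.channel_ids = np.asarray(self.channel_ids, dtype=int)
            if self.channel_ids.shape != (self.n_channels,):
                raise ValueError("channel_ids length must match channel count")
            if len(set(self.channel_ids.tolist())) != self.n_channels:
                raise ValueError("channel_ids must be unique")
        if self.groups is not None:
            unknown = set(self.groups) - set(self.channel_ids.tolist())
            if unknown:
                raise ValueError(f"groups refer to unknown channels: {sorted(unknown)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def index_of(self, channel_id: int) -> int:
        idx = np.flatnonzero(self.channel_ids == channel_id)
        if idx.size == 0:
            raise KeyError(f"unknown channel id {channel_id}")
        return int(idx[0])

    def channel(self, channel_id: int) -> np.ndarray:
        """Single-channel trace by stable channel id."""
        return self.data[self.index_of(channel_id)]


@dataclass
class SnrReport:
    """Per-channel SNR and the channels excluded under a threshold."""

    snr: np.ndarray  # aligned with channel_ids
    channel_ids: np.ndarray
    threshold: float
    excluded: list[int] = field(default_factory=list)

    def passed(self) -> list[int]:
        return [int(c) for c, s in zip(self.channel_ids, self.snr) if s >= self.threshold]


def read_recording(path: str | os.PathLike) -> Recording:
    """Load a recording from the documented HDF5 layout.

    Layout: datasets ``/data`` (channels × samples, float or scaled int),
    ``/coords`` (channels × 2 int); optional ``/groups`` (per-channel label
    strings, empty = unlabeled) and ``/channel_ids``; root attributes ``fs``
    (Hz), optional ``pitch_um`` and ``voltage_scale`` (multiplier applied to
    integer-stored data).
    """
    with h5py.File(path, "r") as f:
        for name in ("data", "coords"):
            if name not in f:
                raise FormatError(f"missing required dataset '/{name}'")
        if "fs" not in f.attrs:
            raise FormatError("missing required root attribute 'fs'")
        data = np.asarray(f["data"], dtype=float)
        scale = float(f.attrs.get("voltage_scale", 1.0))
        if scale != 1.0:
            data = data * scale
        coords = np.asarray(f["coords"], dtype=int)
        fs = float(f.attrs["fs"])
        pitch = float(f.attrs.get("pitch_um", DEFAULT_PITCH_UM))
        channel_ids = None
        if "channel_ids" in f:
            channel_ids = np.asarray(f["channel_ids"], dtype=int)
        groups = None
        if "groups" in f:
            labels = [
                s.decode() if isinstance(s, bytes) else str(s) for s in f["groups"][()]
            ]
            ids = channel_ids if channel_ids is not None else np.arange(data.shape[0])
            groups = {int(c): lab for c, lab in zip(ids, labels) if lab}
    try:
        return Recording(data, fs, coords, pitch, channel_ids, groups)
    except ValueError as e:
        raise FormatError(str(e)) from e


def write_recording(rec: Recording, path: str | os.PathLike, overwrite: bool = False) -> None:
    """Write a recording to the documented HDF5 layout.

    Refuses to clobber an existing file unless ``overwrite`` is set.
    """
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("coords", data=rec.coords)
        f.create_dataset("channel_ids", data=rec.channel_ids)
        if rec.groups is not None:
            labels = [rec.groups.get(int(c), "") for c in rec.channel_ids]
            f.create_dataset("groups", data=labels, dtype=h5py.string_dtype())
        f.attrs["fs"] = rec.fs
        f.attrs["pitch_um"] = rec.pitch


def resample_temporal(rec: Recording, target_fs: float) -> Recording:
    """Fourier-domain downsampling to ``target_fs``.

    Output length is ``round(n_samples × target_fs / fs)``; spectral content
    above the new Nyquist limit (``target_fs / 2``) is removed by the
    frequency-domain truncation, so no separate anti-aliasing filter is
    needed. Upsampling is refused.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs > rec.fs:
        raise ValueError("upsampling is not supported (target_fs > fs)")
    n_out = int(round(rec.n_samples * target_fs / rec.fs))
    out = signal.resample(rec.data, n_out, axis=1)
    return dataclasses.replace(rec, data=out, fs=float(target_fs))


def select_channels(
    rec: Recording,
    channel_ids: "list[int] | None" = None,
    labels: "list[str] | None" = None,
) -> Recording:
    """Restrict a recording to a subset of channels (spatial downsampling).

    Channels may be named directly by id or indirectly through region labels
    in ``rec.groups``; the union of both selections is kept, in the original
    channel order.
    """
    if channel_ids is None and labels is None:
        raise ValueError("provide channel_ids and/or labels")
    want: set[int] = set()
    if channel_ids is not None:
        unknown = set(channel_ids) - set(rec.channel_ids.tolist())
        if unknown:
            raise KeyError(f"unknown channel ids: {sorted(unknown)}")
        want |= set(int(c) for c in channel_ids)
    if labels is not None:
        groups = rec.groups or {}
        known_labels = set(groups.values())
        bad = set(labels) - known_labels
        if bad:
            raise KeyError(f"unknown region labels: {sorted(bad)}")
        want |= {c for c, lab in groups.items() if lab in set(labels)}
    if not want:
        raise ValueError("selection is empty")
    mask = np.array([int(c) in want for c in rec.channel_ids])
    ids = rec.channel_ids[mask]
    groups = None
    if rec.groups is not None:
        groups = {int(c): rec.groups[int(c)] for c in ids if int(c) in rec.groups}
    return dataclasses.replace(
        rec,
        data=rec.data[mask],
        coords=rec.coords[mask],
        channel_ids=ids,
        groups=groups,
    )


def channel_snr(x: np.ndarray) -> float:
    """Robust SNR of one trace: peak |x − median| over 1.4826·MAD.

    A flat channel (MAD = 0) gets SNR 0, so dead electrodes are always
    excluded. The robust noise estimate keeps large discharges from
    inflating the denominator.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    dev = np.abs(x - med)
    mad = np.median(dev)
    if mad == 0:
        return 0.0
    return float(dev.max() / (1.4826 * mad))


def compute_snr(rec: Recording, threshold: float = DEFAULT_SNR_THRESHOLD) -> SnrReport:
    """SNR screen over all channels; channels with SNR < threshold are excluded."""
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples per channel")
    snr = np.array([channel_snr(x) for x in rec.data])
    excluded = [int(c) for c, s in zip(rec.channel_ids, snr) if s < threshold]
    return SnrReport(snr=snr, channel_ids=rec.channel_ids.copy(), threshold=float(threshold), excluded=excluded)
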