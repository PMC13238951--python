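"""Spectrograms and event-level band power for LFP traces.

Band power is reported the way seizure spectra usually are: the absolute
power per unit time in each canonical band — delta [1, 4), theta [4, 8),
alpha [8, 12), beta [12, 30) and low gamma [30, 50] Hz — and each band's
percentage of the total 1–50 Hz power. "Power normalized to time" is the
signal's energy in the band divided by segment duration, i.e. the integral
of the Welch power spectral density over the band, so stationary segments of
different lengths are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

#: Canonical LFP bands (Hz). Half-open [lo, hi) except the top band, which
#: includes its upper edge so the five bands tile the 1–50 Hz total exactly.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "low_gamma": (30.0, 50.0),
}
TOTAL_BAND: tuple[float, float] = (1.0, 50.0)


@dataclass
class SpectrogramConfig:
    window: float = 1.0        # s; frequency resolution = 1/window
    overlap: float = 0.5       # fraction of window
    window_fn: str = "hann"

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")


def spectrogram(x: np.ndarray, fs: float, cfg: SpectrogramConfig | None = None):
    """Short-time power spectral density of one trace.

    Returns ``(freqs, times, Sxx)`` with density scaling, so for stationary
    input the PSD integrates to the signal variance (Parseval-consistent).
    """
    cfg = cfg or SpectrogramConfig()
    x = np.asarray(x, dtype=float)
    nperseg = int(round(cfg.window * fs))
    if x.size < nperseg:
        raise ValueError("signal shorter than the spectrogram window")
    # remove the mean once globally; per-segment detrending would bite into
    # the 1 Hz bin through the window's spectral leakage
    return _signal.spectrogram(
        x - x.mean(), fs=fs, window=cfg.window_fn, nperseg=nperseg,
        noverlap=int(round(cfg.overlap * nperseg)), scaling="density",
        detrend=False,
    )


def _band_mask(freqs: np.ndarray, lo: float, hi: float, include_upper: bool) -> np.ndarray:
    if include_upper:
        return (freqs >= lo) & (freqs <= hi)
    return (freqs >= lo) & (freqs < hi)


def _welch(x: np.ndarray, fs: float, cfg: SpectrogramConfig):
    nperseg = min(x.size, int(round(cfg.window * fs)))
    # global (not per-segment) mean removal, for the same reason as above
    return _signal.welch(
        x - x.mean(), fs=fs, window=cfg.window_fn, nperseg=nperseg,
        noverlap=int(round(cfg.overlap * nperseg)), scaling="density",
        detrend=False,
    )


def band_power(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    cfg: SpectrogramConfig | None = None,
    include_upper: bool = True,
) -> float:
    """Absolute band power per unit time (µV²) over ``band = (f_lo, f_hi)``.

    Computed as the Welch PSD integrated over the band — the segment's
    energy in the band divided by its duration — so the value of a
    stationary signal does not depend on how long a stretch is analyzed.
    """
    cfg = cfg or SpectrogramConfig()
    lo, hi = band
    if hi > fs / 2:
        raise ValueError(f"band upper edge {hi} Hz exceeds the Nyquist limit {fs / 2} Hz")
    x = np.asarray(x, dtype=float)
    freqs, psd = _welch(x, fs, cfg)
    df = freqs[1] - freqs[0]
    mask = _band_mask(freqs, lo, hi, include_upper)
    return float(psd[mask].sum() * df)


def percent_total_power(
    x: np.ndarray,
    fs: float,
    bands: dict[str, tuple[float, float]] | None = None,
    cfg: SpectrogramConfig | None = None,
    total: tuple[float, float] = TOTAL_BAND,
) -> dict[str, float]:
    """Each band's share (%) of the total-band power.

    All bands except the last (by upper edge) are treated half-open, so
    together they partition the total band and the percentages sum to 100.
    """
    cfg = cfg or SpectrogramConfig()
    bands = bands or DEFAULT_BANDS
    x = np.asarray(x, dtype=float)
    freqs, psd = _welch(x, fs, cfg)
    df = freqs[1] - freqs[0]
    tot = float(psd[_band_mask(freqs, *total, include_upper=True)].sum() * df)
    if tot == 0:
        raise ValueError("total band power is zero; percentages undefined")
    top_edge = max(hi for _, hi in bands.values())
    out = {}
    for name, (lo, hi) in bands.items():
        p = float(psd[_band_mask(freqs, lo, hi, include_upper=(hi == top_edge))].sum() * df)
        out[name] = 100.0 * p / tot
    return out


def event_band_powers(
    rec,
    network_events,
    bands: dict[str, tuple[float, float]] | None = None,
    cfg: SpectrogramConfig | None = None,
    total: tuple[float, float] = TOTAL_BAND,
) -> pd.DataFrame:
    """Band-power table for detected events.

    For each network event, each participating channel's trace over
    ``[onset, offset]`` is analyzed and the absolute and percent band powers
    are averaged across channels. Columns: event_id, label, band,
    abs_power_per_s, pct_total.
    """
    bands = bands or DEFAULT_BANDS
    cfg = cfg or SpectrogramConfig()
    names = list(bands) + ["total"]
    rows = []
    for ev in network_events:
        abs_acc = {n: [] for n in names}
        pct_acc = {n: [] for n in bands}
        i0 = int(np.floor(ev.onset * rec.fs))
        i1 = min(rec.n_samples, int(np.ceil(ev.offset * rec.fs)) + 1)
        for cid in ev.channel_ids:
            seg = rec.channel(cid)[i0:i1]
            if seg.size < int(round(cfg.window * rec.fs)):
                continue
            top_edge = max(hi for _, hi in bands.values())
            for name, band in bands.items():
                abs_acc[name].append(
                    band_power(seg, rec.fs, band, cfg, include_upper=(band[1] == top_edge))
                )
            abs_acc["total"].append(band_power(seg, rec.fs, total, cfg, include_upper=True))
            for name, pct in percent_total_power(seg, rec.fs, bands, cfg, total).items():
                pct_acc[name].append(pct)
        for name in names:
            rows.append(
                {
                    "event_id": ev.event_id,
                    "label": ev.label,
                    "band": name,
                    "abs_power_per_s": float(np.mean(abs_acc[name])) if abs_acc[name] else np.nan,
                    "pct_total": float(np.mean(pct_acc[name])) if name in pct_acc and pct_acc[name] else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["event_id", "label", "band", "abs_power_per_s", "pct_total"])
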