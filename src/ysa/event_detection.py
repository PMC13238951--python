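"""Per-channel detection and classification of seizure-like activity.

The detector runs on every channel independently in three steps:

1. **Baseline** — find a quiet 2-minute reference stretch (fewest robust
   threshold crossings) and take its voltage mean/SD plus the distribution of
   1-s sub-window variances.
2. **Discharge points** — flag samples deviating from the baseline mean by
   more than ``k_v`` baseline SDs, and confirm each only if the variance of
   the 1-s window centered on it also exceeds the reference variance by
   ``k_var`` of its SDs.
3. **Events** — group discharge points closer than 2 s into events, then
   label by duration: > 5 min → status-epilepticus-like (SE), > 10 s →
   self-limiting seizure-like event (SLSLE), otherwise discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mea_io import Recording

LABEL_SE = "SE"
LABEL_SLSLE = "SLSLE"
LABEL_DISCARDED = "discarded"


@dataclass
class DetectionConfig:
    """Detector thresholds and windows (defaults are the analysis defaults)."""

    k_v: float = 3.0              # voltage threshold, baseline SD units
    k_var: float = 3.0            # variance threshold, reference-variance SD units
    group_gap: float = 2.0        # s, max gap between discharges in one event
    slsle_min: float = 10.0       # s, events longer than this are SLSLE
    se_min: float = 300.0         # s, events longer than this are SE
    baseline_window: float = 120.0  # s
    baseline_step: float = 10.0   # s, stride of the baseline search
    variance_window: float = 1.0  # s, window for the variance confirmation

    def __post_init__(self) -> None:
        for name in ("k_v", "k_var", "group_gap", "slsle_min", "se_min",
                     "baseline_window", "baseline_step", "variance_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.se_min <= self.slsle_min:
            raise ValueError("se_min must exceed slsle_min")


@dataclass
class Baseline:
    channel_id: int
    start: float          # s
    end: float            # s
    mean: float           # µV
    sd: float             # µV
    var_mean: float       # µV², mean of 1-s sub-window variances
    var_sd: float         # µV², SD of 1-s sub-window variances
    whole_record: bool = False  # true when the recording was shorter than the window

    @property
    def degenerate(self) -> bool:
        return self.sd == 0


@dataclass
class ChannelEvent:
    channel_id: int
    onset: float
    offset: float
    times: np.ndarray     # member discharge-point times, s
    label: str
    truncated: bool = False

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def n_points(self) -> int:
        return len(self.times)


@dataclass
class ChannelEventSet:
    """All events detected on one recording, with the per-channel baselines."""

    events: list[ChannelEvent] = field(default_factory=list)
    baselines: dict[int, Baseline] = field(default_factory=dict)

    def kept(self) -> list[ChannelEvent]:
        """Classified (non-discarded) events."""
        return [e for e in self.events if e.label != LABEL_DISCARDED]


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def find_baseline(x: np.ndarray, fs: float, cfg: DetectionConfig | None = None,
                  channel_id: int = 0) -> Baseline:
    """Locate the quietest baseline window of one channel.

    Candidate windows (length ``baseline_window``, stride ``baseline_step``)
    are scored by how many samples deviate from the global median by more
    than ``k_v`` × the global robust SD (1.4826·MAD); the window with the
    fewest such crossings wins, with ties broken by smaller variance, then
    earlier start. Recordings shorter than the window fall back to the whole
    record with a warning.
    """
    cfg = cfg or DetectionConfig()
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("signal too short for a baseline")
    win = int(round(cfg.baseline_window * fs))
    step = max(1, int(round(cfg.baseline_step * fs)))
    whole = n < win
    if whole:
        warnings.warn(
            f"recording shorter than the {cfg.baseline_window:g}-s baseline "
            "window; using the whole record as baseline",
            stacklevel=2,
        )
        start = 0
        win = n
    else:
        med = np.median(x)
        rsd = _robust_sd(x)
        crossing = (np.abs(x - med) > cfg.k_v * rsd).astype(np.int64) if rsd > 0 else np.zeros(n, dtype=np.int64)
        c_cross = np.concatenate([[0], np.cumsum(crossing)])
        c1 = np.concatenate([[0.0], np.cumsum(x)])
        c2 = np.concatenate([[0.0], np.cumsum(x * x)])
        starts = np.arange(0, n - win + 1, step)
        scores = c_cross[starts + win] - c_cross[starts]
        means = (c1[starts + win] - c1[starts]) / win
        variances = (c2[starts + win] - c2[starts]) / win - means**2
        # ties: fewest crossings, then smallest variance, then earliest
        order = np.lexsort((starts, variances, scores))
        start = int(starts[order[0]])

    seg = x[start:start + win]
    w1 = max(2, int(round(cfg.variance_window * fs)))
    k = max(1, win // w1)
    sub = seg[: k * w1].reshape(k, w1)
    sub_var = sub.var(axis=1)
    return Baseline(
        channel_id=channel_id,
        start=start / fs,
        end=(start + win) / fs,
        mean=float(seg.mean()),
        sd=float(seg.std()),
        var_mean=float(sub_var.mean()),
        var_sd=float(sub_var.std()),
        whole_record=whole,
    )


def _centered_rolling_variance(x: np.ndarray, w: int) -> np.ndarray:
    """Variance of the length-``w`` window centered on each sample (edge-clipped)."""
    n = x.size
    half = w // 2
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx - half + w, 0, n)
    lo = np.minimum(lo, hi - 1)
    cnt = hi - lo
    m = (c1[hi] - c1[lo]) / cnt
    v = (c2[hi] - c2[lo]) / cnt - m**2
    return np.maximum(v, 0.0)


def detect_discharge_points(x: np.ndarray, fs: float, bl: Baseline,
                            cfg: DetectionConfig | None = None) -> np.ndarray:
    """Times (s) of confirmed discharge points on one channel.

    A sample is a candidate when its voltage deviates from the baseline mean
    by more than ``k_v`` baseline SDs; it is confirmed only if the variance
    of the ``variance_window`` centered on it exceeds the baseline reference
    variance by ``k_var`` of the reference variance SD. A degenerate baseline
    (SD = 0) yields no discharges.
    """
    cfg = cfg or DetectionConfig()
    x = np.asarray(x, dtype=float)
    if bl.sd == 0:
        return np.empty(0)
    candidates = np.abs(x - bl.mean) > cfg.k_v * bl.sd
    if not candidates.any():
        return np.empty(0)
    w = max(2, int(round(cfg.variance_window * fs)))
    var = _centered_rolling_variance(x, w)
    confirmed = candidates & (var > bl.var_mean + cfg.k_var * bl.var_sd)
    return np.flatnonzero(confirmed) / fs


def group_into_events(points: np.ndarray, gap: float = 2.0) -> list[tuple[float, float, np.ndarray]]:
    """Partition sorted discharge times into maximal runs with gaps ≤ ``gap``.

    The gap comparison is inclusive ("within 2 s"). Returns
    ``(onset, offset, member_times)`` triples in time order.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        return []
    if np.any(np.diff(points) < 0):
        raise ValueError("discharge times must be sorted ascending")
    breaks = np.flatnonzero(np.diff(points) > gap) + 1
    out = []
    for chunk in np.split(points, breaks):
        out.append((float(chunk[0]), float(chunk[-1]), chunk))
    return out


def classify_event(duration: float, cfg: DetectionConfig | None = None) -> str:
    """Duration-based label: > 5 min → SE, > 10 s → SLSLE, else discarded.

    Both thresholds are strict, so a 10.0-s event is discarded and a 300-s
    event is an SLSLE; SE takes precedence.
    """
    cfg = cfg or DetectionConfig()
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if duration > cfg.se_min:
        return LABEL_SE
    if duration > cfg.slsle_min:
        return LABEL_SLSLE
    return LABEL_DISCARDED


def detect_channel_events(rec: Recording, cfg: DetectionConfig | None = None) -> ChannelEventSet:
    """Run the three-step detector on every channel of a recording.

    Discarded (sub-10-s) events are retained with their label for audit;
    summaries downstream ignore them. Events reaching the end of the record
    (within one grouping gap) are flagged truncated.
    """
    cfg = cfg or DetectionConfig()
    result = ChannelEventSet()
    for i, cid in enumerate(rec.channel_ids):
        x = rec.data[i]
        bl = find_baseline(x, rec.fs, cfg, channel_id=int(cid))
        result.baselines[int(cid)] = bl
        pts = detect_discharge_points(x, rec.fs, bl, cfg)
        for onset, offset, members in group_into_events(pts, cfg.group_gap):
            label = classify_event(offset - onset, cfg)
            truncated = (rec.duration - offset) <= cfg.group_gap
            result.events.append(
                ChannelEvent(int(cid), onset, offset, members, label, truncated)
            )
    return result


def events_dataframe(evset: ChannelEventSet):
    """Flatten a ChannelEventSet to the events CSV schema."""
    import pandas as pd

    rows = [
        {
            "channel_id": e.channel_id,
            "onset_s": e.onset,
            "offset_s": e.offset,
            "duration_s": e.duration,
            "n_points": e.n_points,
            "label": e.label,
            "truncated": e.truncated,
        }
        for e in evset.events
    ]
    return pd.DataFrame(
        rows,
        columns=["channel_id", "onset_s", "offset_s", "duration_s", "n_points", "label", "truncated"],
    )
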