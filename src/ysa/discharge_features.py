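"""Per-event feature quantification, table export, and raster matrices.

Detection yields per-channel events and tracking yields grid-level discharge
trajectories; this module joins the two. Per-channel SLSLE/SE events that
overlap in time (within the grouping gap) are merged into one network-level
event, classified on the merged span, and each trajectory is assigned to the
event whose span contains its start time. The exported table carries, per
event: duration, mean discharge duration (spread of onset times within one
discharge), mean inter-discharge interval, discharge count, and mean
propagation path length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .event_detection import (
    ChannelEventSet,
    DetectionConfig,
    LABEL_DISCARDED,
    classify_event,
)

FEATURE_COLUMNS = [
    "event_id", "label", "onset_s", "offset_s", "duration_s", "n_channels",
    "n_discharges", "mean_discharge_duration_s", "mean_idi_s", "mean_path_len_um",
]


def discharge_duration(onsets) -> float:
    """Time between the first and last detected onsets within one discharge."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("discharge has no onsets")
    return float(onsets.max() - onsets.min())


def interdischarge_intervals(onsets) -> np.ndarray:
    """First differences of sorted discharge onset times within one event."""
    onsets = np.sort(np.asarray(onsets, dtype=float))
    if onsets.size < 2:
        return np.empty(0)
    return np.diff(onsets)


@dataclass
class NetworkEvent:
    """Per-channel events merged across the array by temporal overlap."""

    event_id: int
    label: str
    onset: float
    offset: float
    channel_ids: list[int] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def contains(self, t: float) -> bool:
        return self.onset <= t <= self.offset


def merge_channel_events(events_df: pd.DataFrame, cfg: DetectionConfig | None = None) -> list[NetworkEvent]:
    """Merge per-channel SLSLE/SE events into network-level events.

    Events (rows of the detection CSV schema) whose intervals overlap or lie
    within the grouping gap of each other are unioned; the merged span is
    re-classified by duration. Discarded events never participate.
    """
    cfg = cfg or DetectionConfig()
    kept = events_df[events_df["label"] != LABEL_DISCARDED].sort_values("onset_s")
    merged: list[NetworkEvent] = []
    for row in kept.itertuples(index=False):
        if merged and row.onset_s <= merged[-1].offset + cfg.group_gap:
            ev = merged[-1]
            ev.offset = max(ev.offset, float(row.offset_s))
            ev.channel_ids.append(int(row.channel_id))
        else:
            merged.append(
                NetworkEvent(
                    event_id=len(merged),
                    label="",
                    onset=float(row.onset_s),
                    offset=float(row.offset_s),
                    channel_ids=[int(row.channel_id)],
                )
            )
    for ev in merged:
        ev.channel_ids = sorted(set(ev.channel_ids))
        ev.label = classify_event(ev.duration, cfg)
    return [ev for ev in merged if ev.label != LABEL_DISCARDED]


def event_discharge_count(event: NetworkEvent, discharges_df: pd.DataFrame) -> int:
    """Number of tracked discharges whose start time falls inside the event."""
    starts = discharges_df["start_s"].to_numpy(dtype=float)
    return int(np.count_nonzero((starts >= event.onset) & (starts <= event.offset)))


def summarize_events(
    events_df: pd.DataFrame,
    discharges_df: pd.DataFrame,
    cfg: DetectionConfig | None = None,
) -> pd.DataFrame:
    """Build the per-event feature table from detection and tracking outputs.

    ``events_df`` follows the events CSV schema; ``discharges_df`` the
    discharges CSV schema (one row per trajectory). One output row per
    merged SLSLE/SE event; all within-event aggregates are means.
    """
    cfg = cfg or DetectionConfig()
    rows = []
    for ev in merge_channel_events(events_df, cfg):
        starts = discharges_df["start_s"].to_numpy(dtype=float)
        inside = (starts >= ev.onset) & (starts <= ev.offset)
        sub = discharges_df[inside]
        idis = interdischarge_intervals(sub["start_s"].to_numpy()) if len(sub) >= 2 else np.empty(0)
        rows.append(
            {
                "event_id": ev.event_id,
                "label": ev.label,
                "onset_s": ev.onset,
                "offset_s": ev.offset,
                "duration_s": ev.duration,
                "n_channels": len(ev.channel_ids),
                "n_discharges": int(len(sub)),
                "mean_discharge_duration_s": float(sub["discharge_duration_s"].mean()) if len(sub) else np.nan,
                "mean_idi_s": float(idis.mean()) if idis.size else np.nan,
                "mean_path_len_um": float(sub["path_len_um"].mean()) if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


@dataclass
class RasterMatrix:
    """Channels × time-bins count matrix of detected activity points."""

    matrix: np.ndarray
    bin_size: float
    channel_ids: list[int]
    overlays: list[tuple[str, float, float]] = field(default_factory=list)  # (label, onset, offset)


def raster_matrix(
    points_by_channel: dict[int, np.ndarray],
    bin_size: float,
    duration: float | None = None,
    groups: dict[int, str] | None = None,
    order_by_group: bool = False,
    overlays: list[tuple[str, float, float]] | None = None,
) -> RasterMatrix:
    """Bin per-channel activity times into a channels × bins count matrix.

    Rows follow the input channel order, or are sorted by group label (then
    channel id) when ``order_by_group`` is set. Event spans may be attached
    as overlay metadata for downstream plotting.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    channels = list(points_by_channel)
    if order_by_group:
        groups = groups or {}
        unknown = [c for c in groups if c not in channels]
        if unknown:
            raise KeyError(f"group map refers to unknown channels: {unknown}")
        channels.sort(key=lambda c: (groups.get(c, "~"), c))
    if duration is None:
        all_t = [t for ts in points_by_channel.values() for t in np.atleast_1d(ts)]
        duration = (max(all_t) + bin_size) if all_t else bin_size
    n_bins = int(np.ceil(duration / bin_size))
    mat = np.zeros((len(channels), n_bins), dtype=int)
    for i, c in enumerate(channels):
        ts = np.atleast_1d(np.asarray(points_by_channel[c], dtype=float))
        for t in ts:
            b = int(np.floor(t / bin_size))
            if 0 <= b < n_bins:
                mat[i, b] += 1
    return RasterMatrix(mat, float(bin_size), [int(c) for c in channels], overlays or [])
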