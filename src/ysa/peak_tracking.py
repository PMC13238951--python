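"""Discharge peak detection and spatiotemporal propagation tracking.

Each discharge appears as a sharp LFP deflection that sweeps across the
electrode grid. Per channel, peaks are local maxima of the absolute
deviation from the mean exceeding ``k_p`` robust SDs, thinned to a minimum
inter-peak distance; the discharge *onset* is the largest single-step
voltage change in the window preceding each peak. Onsets are then binned in
time (default 0.0133 s), active electrodes in each bin are clustered with
DBSCAN (epsilon = 4.8 grid units, MinPts = 4 by default), and cluster
centroids are linked bin-to-bin into trajectories. A trajectory ends after
three consecutive bins without a linked cluster; its propagation path
length is the summed Euclidean distance between consecutive centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from sklearn.cluster import DBSCAN

from .mea_io import Recording, compute_snr

DEFAULT_BIN_S = 0.0133


@dataclass
class PeakConfig:
    k_p: float = 4.0            # peak threshold, robust SD units
    min_distance: int = 30      # samples, minimum inter-peak distance
    window: int = 20            # samples, onset search window before a peak
    snr_threshold: float = 35.0
    bin_size: float = DEFAULT_BIN_S  # s

    def __post_init__(self) -> None:
        if min(self.k_p, self.min_distance, self.window, self.snr_threshold, self.bin_size) <= 0:
            raise ValueError("all PeakConfig fields must be positive")


@dataclass
class ClusterConfig:
    epsilon: float = 4.8        # grid-index units (1 = one electrode pitch)
    min_pts: int = 4
    max_link_distance: float | None = None  # defaults to 2 × epsilon
    patience: int = 3           # empty bins before a trajectory closes

    def __post_init__(self) -> None:
        if self.epsilon < 1:
            raise ValueError("epsilon must be at least the electrode-to-electrode distance (1)")
        if self.min_pts < 1:
            raise ValueError("min_pts must be ≥ 1")
        if self.max_link_distance is None:
            self.max_link_distance = 2 * self.epsilon
        if self.patience < 1:
            raise ValueError("patience must be ≥ 1")


@dataclass
class Peak:
    channel_id: int
    peak_index: int
    peak_time: float
    onset_index: int
    onset_time: float
    amplitude: float   # |x − mean| at the peak, µV
    row: int
    col: int


@dataclass
class Cluster:
    centroid: np.ndarray        # (row, col), float
    indices: np.ndarray         # indices into the input point list


@dataclass
class DischargeTrajectory:
    """Time-ordered centroid track of one propagating discharge."""

    discharge_id: int
    bins: list[int] = field(default_factory=list)
    centroids: list[np.ndarray] = field(default_factory=list)
    members: list[list[int]] = field(default_factory=list)       # channel ids per bin
    onset_times: list[list[float]] = field(default_factory=list)  # member onsets per bin
    bin_size: float = DEFAULT_BIN_S

    @property
    def start_time(self) -> float:
        return self.bins[0] * self.bin_size

    @property
    def end_time(self) -> float:
        return (self.bins[-1] + 1) * self.bin_size

    @property
    def initiation_channels(self) -> list[int]:
        """Electrodes in the first cluster — where the discharge started."""
        return list(self.members[0])

    def all_onset_times(self) -> np.ndarray:
        return np.sort(np.concatenate([np.asarray(t) for t in self.onset_times]))

    def centroid_array(self) -> np.ndarray:
        return np.vstack(self.centroids)


def detect_peaks(x: np.ndarray, cfg: PeakConfig | None = None) -> np.ndarray:
    """Indices of discharge peaks on one trace.

    Peaks are local maxima of ``|x − mean(x)|`` exceeding ``k_p`` robust SDs
    (1.4826·MAD, so large events do not suppress their own detection). Among
    peaks closer than ``min_distance`` samples the larger wins; ties go to
    the earlier peak.
    """
    cfg = cfg or PeakConfig()
    x = np.asarray(x, dtype=float)
    dev = np.abs(x - x.mean())
    mad = np.median(np.abs(x - np.median(x)))
    rsd = 1.4826 * float(mad)
    if rsd == 0:
        return np.empty(0, dtype=int)
    cand, _ = _signal.find_peaks(dev, height=cfg.k_p * rsd)
    if cand.size == 0:
        return cand
    # greedy suppression: larger amplitude first, earlier on ties
    order = sorted(range(cand.size), key=lambda i: (-dev[cand[i]], cand[i]))
    kept: list[int] = []
    for i in order:
        c = cand[i]
        if all(abs(c - k) >= cfg.min_distance for k in kept):
            kept.append(int(c))
    return np.array(sorted(kept), dtype=int)


def locate_onset(x: np.ndarray, peak_idx: int, window: int) -> int:
    """Discharge onset: the largest single-step voltage change before a peak.

    Searches steps ``t → t+1`` for ``t`` in ``[max(0, peak − window), peak)``
    and returns the index just after the earliest maximal step.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if peak_idx < 1:
        raise ValueError("peak index must be ≥ 1")
    x = np.asarray(x, dtype=float)
    lo = max(0, peak_idx - window)
    steps = np.abs(np.diff(x[lo:peak_idx + 1]))
    return lo + int(np.argmax(steps)) + 1


def detect_all_peaks(rec: Recording, cfg: PeakConfig | None = None) -> list[Peak]:
    """Peak + onset detection across all channels passing the SNR screen."""
    cfg = cfg or PeakConfig()
    report = compute_snr(rec, cfg.snr_threshold)
    excluded = set(report.excluded)
    peaks: list[Peak] = []
    for i, cid in enumerate(rec.channel_ids):
        if int(cid) in excluded:
            continue
        x = rec.data[i]
        dev = np.abs(x - x.mean())
        for p in detect_peaks(x, cfg):
            if p < 1:
                continue
            o = locate_onset(x, int(p), cfg.window)
            peaks.append(
                Peak(
                    channel_id=int(cid),
                    peak_index=int(p),
                    peak_time=p / rec.fs,
                    onset_index=o,
                    onset_time=o / rec.fs,
                    amplitude=float(dev[p]),
                    row=int(rec.coords[i, 0]),
                    col=int(rec.coords[i, 1]),
                )
            )
    return peaks


def bin_onsets(peaks: list[Peak], bin_size: float = DEFAULT_BIN_S) -> dict[int, list[Peak]]:
    """Group peaks by the half-open time bin containing their onset.

    Bin ``b`` covers ``[b·bin_size, (b+1)·bin_size)``. Each electrode appears
    at most once per bin (first peak wins).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    out: dict[int, list[Peak]] = {}
    for pk in sorted(peaks, key=lambda p: p.onset_time):
        b = int(np.floor(pk.onset_time / bin_size))
        bucket = out.setdefault(b, [])
        if any(q.channel_id == pk.channel_id for q in bucket):
            continue
        bucket.append(pk)
    return out


def dbscan_clusters(points: np.ndarray, epsilon: float, min_pts: int) -> tuple[list[Cluster], np.ndarray]:
    """DBSCAN over electrode (row, col) positions in grid-index units.

    Points are sorted lexicographically before clustering so border-point
    assignment (first core cluster to reach them in scan order) is
    deterministic. Returns clusters in order of first appearance plus the
    indices of noise points, both referring to the *input* order.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if points.shape[0] == 0:
        return [], np.empty(0, dtype=int)
    order = np.lexsort((points[:, 1], points[:, 0]))
    sorted_pts = points[order]
    labels = DBSCAN(eps=epsilon, min_samples=min_pts).fit(sorted_pts).labels_
    clusters: list[Cluster] = []
    for lab in range(labels.max() + 1):
        member_sorted = np.flatnonzero(labels == lab)
        idx = order[member_sorted]
        clusters.append(Cluster(centroid=points[idx].mean(axis=0), indices=np.sort(idx)))
    noise = np.sort(order[np.flatnonzero(labels == -1)])
    return clusters, noise


def track_discharges(
    peaks: list[Peak],
    ccfg: ClusterConfig | None = None,
    bin_size: float = DEFAULT_BIN_S,
) -> list[DischargeTrajectory]:
    """Link per-bin DBSCAN clusters into discharge trajectories.

    Within each bin, every cluster links to the open trajectory whose last
    centroid is nearest (greedy by distance, at most one cluster per
    trajectory per bin) and within ``max_link_distance``; otherwise it seeds
    a new trajectory. A trajectory closes after ``patience`` consecutive
    bins without a linked cluster.
    """
    ccfg = ccfg or ClusterConfig()
    binned = bin_onsets(peaks, bin_size)
    if not binned:
        return []
    open_trajs: list[tuple[DischargeTrajectory, int]] = []  # (traj, misses)
    done: list[DischargeTrajectory] = []
    next_id = 0
    last_bin: int | None = None
    for b in sorted(binned):
        if last_bin is not None:
            gap = b - last_bin - 1
            if gap > 0:
                still = []
                for traj, misses in open_trajs:
                    if misses + gap >= ccfg.patience:
                        done.append(traj)
                    else:
                        still.append((traj, misses + gap))
                open_trajs = still
        bucket = binned[b]
        pts = np.array([[p.row, p.col] for p in bucket], dtype=float)
        clusters, _ = dbscan_clusters(pts, ccfg.epsilon, ccfg.min_pts)
        # greedy nearest linking of clusters to open trajectories
        pairs = []
        for ci, cl in enumerate(clusters):
            for ti, (traj, _) in enumerate(open_trajs):
                d = float(np.linalg.norm(cl.centroid - traj.centroids[-1]))
                if d <= ccfg.max_link_distance:
                    pairs.append((d, ci, ti))
        pairs.sort()
        cl_assigned: dict[int, int] = {}
        traj_taken: set[int] = set()
        for d, ci, ti in pairs:
            if ci in cl_assigned or ti in traj_taken:
                continue
            cl_assigned[ci] = ti
            traj_taken.add(ti)
        new_open: list[tuple[DischargeTrajectory, int]] = []
        for ti, (traj, misses) in enumerate(open_trajs):
            if ti in traj_taken:
                new_open.append((traj, 0))
            elif misses + 1 >= ccfg.patience:
                done.append(traj)
            else:
                new_open.append((traj, misses + 1))
        for ci, cl in enumerate(clusters):
            member_ids = [bucket[i].channel_id for i in cl.indices]
            onsets = [bucket[i].onset_time for i in cl.indices]
            if ci in cl_assigned:
                traj = open_trajs[cl_assigned[ci]][0]
            else:
                traj = DischargeTrajectory(discharge_id=next_id, bin_size=bin_size)
                next_id += 1
                new_open.append((traj, 0))
            traj.bins.append(b)
            traj.centroids.append(cl.centroid)
            traj.members.append(member_ids)
            traj.onset_times.append(onsets)
        open_trajs = new_open
        last_bin = b
    done.extend(traj for traj, _ in open_trajs)
    done.sort(key=lambda t: t.start_time)
    for i, traj in enumerate(done):
        traj.discharge_id = i
    return done


def path_length(traj: "DischargeTrajectory | np.ndarray", pitch: float = 60.0) -> tuple[float, float]:
    """Propagation path length: summed Euclidean distance between consecutive
    centroids, in grid units and µm (grid value × pitch)."""
    if isinstance(traj, DischargeTrajectory):
        cents = traj.centroid_array()
    else:
        cents = np.asarray(traj, dtype=float).reshape(-1, 2)
    if cents.shape[0] == 0:
        raise ValueError("trajectory has no centroids")
    grid = float(np.sum(np.linalg.norm(np.diff(cents, axis=0), axis=1)))
    return grid, grid * pitch


def trajectories_dataframe(trajs: list[DischargeTrajectory], pitch: float = 60.0):
    """Flatten trajectories to the discharges CSV schema."""
    import pandas as pd

    rows = []
    for t in trajs:
        grid, um = path_length(t, pitch)
        onsets = t.all_onset_times()
        rows.append(
            {
                "discharge_id": t.discharge_id,
                "start_s": t.start_time,
                "end_s": t.end_time,
                "n_centroids": len(t.centroids),
                "path_len_grid": grid,
                "path_len_um": um,
                "discharge_duration_s": float(onsets[-1] - onsets[0]),
                "initiation_channels": ";".join(str(c) for c in t.initiation_channels),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "discharge_id", "start_s", "end_s", "n_centroids",
            "path_len_grid", "path_len_um", "discharge_duration_s", "initiation_channels",
        ],
    )


def centroids_dataframe(trajs: list[DischargeTrajectory]):
    import pandas as pd

    rows = []
    for t in trajs:
        for b, c, m in zip(t.bins, t.centroids, t.members):
            rows.append(
                {
                    "discharge_id": t.discharge_id,
                    "bin": b,
                    "t_s": b * t.bin_size,
                    "row": c[0],
                    "col": c[1],
                    "n_members": len(m),
                }
            )
    return pd.DataFrame(rows, columns=["discharge_id", "bin", "t_s", "row", "col", "n_members"])
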