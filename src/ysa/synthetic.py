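"""Synthetic HD-MEA recordings with planted, analytically known ground truth.

The generator emulates the phenomenology the analysis pipeline targets:
Gaussian background noise per electrode, dead channels, and epileptiform
events built from trains of discharges. Each discharge is a traveling
wavefront — a disc of configurable radius whose center moves at constant
velocity from an origin electrode until it exits the grid — and every
electrode it passes receives a biphasic LFP-like transient (sharp ~50 ms
deflection followed by a slower opposite-sign recovery) at the moment the
front reaches it. Event types follow the duration taxonomy used in
detection: blips (< 10 s, should be discarded), SLSLE trains (10 s–5 min)
and SE episodes (> 5 min).

Because the wavefront geometry is analytic, the ground truth is exact: the
true per-channel event intervals, each discharge's onset time and origin,
and its path length (speed × traversal time = distance from origin to grid
exit) are all known in closed form.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mea_io import Recording

EVENT_KINDS = ("blip", "SLSLE", "SE")

#: duration of the synthetic biphasic discharge waveform (s)
WAVEFORM_DURATION = 0.2


@dataclass
class EventSpec:
    """One planted event: a train of propagating discharges."""

    kind: str                      # blip | SLSLE | SE
    start: float                   # s
    duration: float                # s (taxonomy-checked against kind)
    discharge_interval: float = 1.5  # s between discharge onsets (≤ 2 s keeps
                                     # a train one event under the 2-s grouping gap)
    amplitude: float = 8.0         # discharge amplitude in noise-SD multiples
    origin: tuple[float, float] = (8.0, 0.0)   # (row, col) wave origin
    direction: tuple[float, float] = (0.0, 1.0)  # propagation direction
    speed: float = 75.0            # grid units / s; default ≈ one electrode
                                   # pitch per 0.0133-s tracking bin, so the
                                   # front advances one column per bin

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"kind must be one of {EVENT_KINDS}")
        if self.kind == "blip" and not self.duration < 10:
            raise ValueError("blip duration must be < 10 s")
        if self.kind == "SLSLE" and not (10 < self.duration <= 300):
            raise ValueError("SLSLE duration must lie in (10, 300] s")
        if self.kind == "SE" and not self.duration > 300:
            raise ValueError("SE duration must exceed 300 s")
        if self.discharge_interval <= 0 or self.speed <= 0:
            raise ValueError("discharge_interval and speed must be positive")
        d = np.asarray(self.direction, dtype=float)
        if np.linalg.norm(d) == 0:
            raise ValueError("direction must be nonzero")

    @property
    def end(self) -> float:
        return self.start + self.duration

    def discharge_onsets(self) -> np.ndarray:
        """Onset times of the discharges in this train."""
        return self.start + np.arange(0.0, self.duration, self.discharge_interval)


@dataclass
class SynthConfig:
    """Study conditions for one synthetic recording. ``seed`` is mandatory."""

    seed: int
    duration: float = 600.0        # s
    grid: tuple[int, int] = (16, 16)
    fs: float = 100.0              # Hz — the analysis rate after downsampling
    noise_sd: float = 10.0         # µV
    events: list[EventSpec] = field(default_factory=list)
    dead_fraction: float = 0.05
    wave_radius: float = 2.0       # grid units, half-width of the wavefront disc
    pitch: float = 60.0            # µm

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0 or self.noise_sd <= 0:
            raise ValueError("duration, fs and noise_sd must be positive")
        if not 0 <= self.dead_fraction < 1:
            raise ValueError("dead_fraction must lie in [0, 1)")
        spans = sorted((e.start, e.end + WAVEFORM_DURATION) for e in self.events)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("planted events overlap in time; ground truth would be ambiguous")
        for e in self.events:
            if e.end + WAVEFORM_DURATION > self.duration:
                raise ValueError("event extends beyond the recording")


@dataclass
class GroundTruth:
    """Exact per-channel event intervals and per-discharge wave parameters."""

    events: pd.DataFrame       # channel_id, onset_s, offset_s, label
    discharges: pd.DataFrame   # event_id, discharge_id, onset_s, origin_row,
                               # origin_col, speed, path_len_grid, path_len_um
    dead_channels: list[int]
    config: SynthConfig


def _exit_distance(origin: np.ndarray, direction: np.ndarray, grid: tuple[int, int]) -> float:
    """Distance the wave center travels from origin until it leaves the grid."""
    lo = np.zeros(2)
    hi = np.array([grid[0] - 1, grid[1] - 1], dtype=float)
    s_max = np.inf
    for k in range(2):
        if direction[k] > 0:
            s_max = min(s_max, (hi[k] - origin[k]) / direction[k])
        elif direction[k] < 0:
            s_max = min(s_max, (lo[k] - origin[k]) / direction[k])
    return float(max(s_max, 0.0))


def discharge_waveform(fs: float, amplitude: float) -> np.ndarray:
    """Biphasic transient with a steep leading edge, as epileptiform LFP
    spikes have: an abrupt deflection to ``amplitude`` decaying over ~50 ms,
    then a slower 150-ms opposite-sign recovery at 30% height. The sharp
    onset makes the true onset sample unambiguous for ground truth."""
    t1 = np.arange(int(round(0.05 * fs))) / fs
    t2 = np.arange(int(round(0.15 * fs))) / fs
    main = amplitude * np.cos(0.5 * np.pi * t1 / 0.05)
    recovery = -0.3 * amplitude * np.sin(np.pi * t2 / 0.15)
    return np.concatenate([main, recovery])


def _channel_activations(spec: EventSpec, coords: np.ndarray, grid: tuple[int, int],
                         radius: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-channel wavefront delay for one discharge.

    Returns (channel_indices, delays_s, exit_distance): channels within
    ``radius`` of the propagation line whose along-track projection lies in
    [0, exit_distance], with the delay at which the front passes each.
    """
    origin = np.asarray(spec.origin, dtype=float)
    d = np.asarray(spec.direction, dtype=float)
    d = d / np.linalg.norm(d)
    s_exit = _exit_distance(origin, d, grid)
    rel = coords.astype(float) - origin
    proj = rel @ d
    perp = np.abs(rel @ np.array([-d[1], d[0]]))
    hit = (perp <= radius) & (proj >= 0) & (proj <= s_exit)
    return np.flatnonzero(hit), proj[hit] / spec.speed, s_exit


def generate_recording(cfg: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Render a synthetic recording and its exact ground truth.

    Identical seeds give bit-identical recordings; the planted event and
    discharge timings depend only on the config, never on the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid
    n_ch = rows * cols
    n = int(round(cfg.duration * cfg.fs))
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=int)
    data = rng.normal(0.0, cfg.noise_sd, size=(n_ch, n))
    n_dead = int(round(cfg.dead_fraction * n_ch))
    dead = sorted(rng.choice(n_ch, size=n_dead, replace=False).tolist()) if n_dead else []
    data[dead] = 0.0
    dead_set = set(dead)

    event_rows = []
    discharge_rows = []
    wf_cache: dict[float, np.ndarray] = {}
    d_id = 0
    for e_id, spec in enumerate(cfg.events):
        amp = spec.amplitude * cfg.noise_sd
        wf = wf_cache.setdefault(amp, discharge_waveform(cfg.fs, amp))
        chans, delays, s_exit = _channel_activations(spec, coords, cfg.grid, cfg.wave_radius)
        first_act = np.full(n_ch, np.inf)
        last_act = np.full(n_ch, -np.inf)
        for t0 in spec.discharge_onsets():
            discharge_rows.append(
                {
                    "event_id": e_id,
                    "discharge_id": d_id,
                    "onset_s": t0,
                    "origin_row": spec.origin[0],
                    "origin_col": spec.origin[1],
                    "speed": spec.speed,
                    "path_len_grid": s_exit,
                    "path_len_um": s_exit * cfg.pitch,
                }
            )
            d_id += 1
            for ch, delay in zip(chans, delays):
                if ch in dead_set:
                    continue
                t_act = t0 + delay
                i0 = int(round(t_act * cfg.fs))
                i1 = min(n, i0 + wf.size)
                if i0 < n:
                    data[ch, i0:i1] += wf[: i1 - i0]
                first_act[ch] = min(first_act[ch], t_act)
                last_act[ch] = max(last_act[ch], t_act)
        for ch in chans:
            if ch in dead_set or not np.isfinite(first_act[ch]):
                continue
            event_rows.append(
                {
                    "channel_id": int(ch),
                    "onset_s": float(first_act[ch]),
                    "offset_s": float(last_act[ch] + WAVEFORM_DURATION),
                    "label": spec.kind,
                }
            )

    rec = Recording(data, cfg.fs, coords, pitch=cfg.pitch)
    gt = GroundTruth(
        events=pd.DataFrame(event_rows, columns=["channel_id", "onset_s", "offset_s", "label"]),
        discharges=pd.DataFrame(
            discharge_rows,
            columns=["event_id", "discharge_id", "onset_s", "origin_row", "origin_col",
                     "speed", "path_len_grid", "path_len_um"],
        ),
        dead_channels=[int(c) for c in dead],
        config=cfg,
    )
    return rec, gt


def export_truth(gt: GroundTruth, out_dir: str | os.PathLike) -> tuple[str, str]:
    """Write the truth tables (events, discharges) as CSV; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    events_path = os.path.join(out_dir, "truth_events.csv")
    discharges_path = os.path.join(out_dir, "truth_discharges.csv")
    gt.events.to_csv(events_path, index=False)
    gt.discharges.to_csv(discharges_path, index=False)
    return events_path, discharges_path


def standard_fixture(seed: int, include_se: bool = True) -> SynthConfig:
    """The canonical test recording: a quiet baseline stretch, one 30-s
    SLSLE train at 140 s and (optionally) one 360-s SE train at 200 s on a
    16×16 grid at 100 Hz, 600 s total (300 s without the SE train)."""
    events = [EventSpec(kind="SLSLE", start=140.0, duration=30.0)]
    duration = 300.0
    if include_se:
        events.append(EventSpec(kind="SE", start=200.0, duration=360.0))
        duration = 600.0
    return SynthConfig(seed=seed, duration=duration, events=events)
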