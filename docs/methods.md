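# Methods

This note documents the models and procedures implemented in `ysa`, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic-data tests do and do not establish about real
recordings.

## Data model

A recording is a channels × samples voltage matrix (µV) with a sampling
rate, per-channel integer `(row, col)` positions on an electrode grid
(≤ 64 × 64), and an electrode pitch (default 60 µm). All spatial
computations run in grid-index units (1 = one pitch) and convert to µm
only for reporting, so geometry is independent of the physical pitch.
The HDF5 container stores `/data`, `/coords`, optional `/groups` and
`/channel_ids`, and root attributes `fs`, `pitch_um`, `voltage_scale`;
`ysa convert` maps foreign HDF5 layouts into it.

Temporal downsampling (typically 2 kHz acquisition → 100 Hz analysis rate)
uses Fourier-domain resampling: the spectrum is truncated at the target
Nyquist frequency before reconstruction, so anti-aliasing is implicit.
Sub-Nyquist amplitudes are preserved to well under 1% and content above
the new Nyquist is attenuated to numerical zero.

### SNR channel screen

No formula for the channel SNR is standard in this setting; we use a
robust peak-over-noise ratio

    SNR = max|x − median(x)| / (1.4826 · MAD(x)),

with SNR := 0 when MAD = 0 (dead channel). The denominator estimates the
noise SD robustly, so large discharges do not inflate the noise term; the
numerator is the largest deflection. The default exclusion threshold is
35, appropriate for recordings whose discharges are tens of noise SDs
tall. Like every tracking parameter, it is expected to be tuned per
recording: on the synthetic fixtures, whose discharges are 8 noise SDs,
pipeline runs use a threshold of 6 — above the ≈4.5 that the extreme-value
statistics of a pure-noise channel reach at these record lengths, and
comfortably below the ≈8.5 of a discharge-bearing channel.

## Event detection

Detection is strictly per channel, in three steps.

1. **Baseline.** A 2-minute window (stride 10 s) minimizing the count of
   samples beyond 3 robust SDs from the global median is selected; ties go
   to the window with smaller variance, then the earlier one. The window
   provides the reference voltage mean/SD and, from its non-overlapping
   1-s sub-windows, the reference variance mean/SD. Recordings shorter
   than 2 min fall back to the whole record with a warning. A flat
   baseline (SD = 0) is flagged degenerate and yields no detections.
2. **Discharge points.** Samples with |x − mean| > k_v·SD (k_v = 3) are
   candidates; each is confirmed only if the variance of the 1-s window
   centered on it (clipped at record edges) exceeds the reference variance
   mean by k_var (= 3) reference-variance SDs. The variance window length
   is a design choice; 1 s matches the sub-window length used to build the
   reference distribution, which is what makes "3 SD from the reference
   variance" well defined.
3. **Events.** Discharge points with gaps ≤ 2 s (inclusive) form one
   event. Labels are assigned on strict thresholds: duration > 300 s → SE,
   > 10 s → SLSLE, otherwise discarded. A 10.0-s event is discarded and a
   300-s event is an SLSLE. Discarded events are kept, labeled, for audit;
   all summaries ignore them. Events ending within one grouping gap of the
   record end are flagged truncated and classified on observed duration.

## Discharge tracking

Per channel (after the SNR screen), peaks are local maxima of
|x − mean(x)| exceeding k_p (= 4) robust SDs — robust (1.4826·MAD) so that
dense discharge trains do not suppress their own detection. Among peaks
closer than 30 samples the larger wins (ties → earlier). The onset of each
discharge is the sample following the largest single-step voltage change
within the 20 samples preceding the peak (earliest maximal step on ties).

Onsets are binned into half-open 0.0133-s windows (≈ 75 Hz). Within each
bin, active electrode positions are clustered with DBSCAN (ε = 4.8 grid
units, MinPts = 4; scikit-learn implementation). Input points are sorted
lexicographically by (row, col) first, which makes border-point assignment
deterministic: a border point joins the first core cluster to reach it in
scan order. Cluster centroids are arithmetic means of member coordinates.

Trajectory building iterates bins in order. Each cluster links to the open
trajectory whose last centroid is nearest, greedily by distance, if within
the maximum linking distance (2ε by default; linking is otherwise
unconstrained, so the simplest deterministic rule is used, and at most
one cluster links per trajectory per bin); unlinked clusters seed new
trajectories. A trajectory closes after 3 consecutive bins without a
linked cluster. Its initiation electrodes are the members of its first
cluster; its propagation path length is the summed Euclidean distance
between consecutive centroids (grid units; × pitch for µm).

## Event features

Detection yields per-channel events; tracking yields grid-level
trajectories. For the exported feature table, per-channel SLSLE/SE events
that overlap in time (within the grouping gap) are merged into one
network-level event, re-classified on the merged span. Each trajectory is
assigned to the network event whose span contains its start time. Per
event the table reports: duration, number of participating channels,
discharge count, mean discharge duration (spread between first and last
member onset within one trajectory), mean inter-discharge interval (first
differences of sorted trajectory start times) and mean path length. All
within-event aggregates are means.

Raster matrices count per-channel activity points in fixed bins; rows can
be ordered by user-defined region groups, and event spans ride along as
overlay metadata.

## Spectral analysis

Band power is reported per unit time: the Welch PSD (1-s Hann windows, 50%
overlap, density scaling) integrated over the band. This equals band
energy divided by segment duration, so stationary segments of different
lengths are directly comparable. The mean is removed once globally rather
than per Welch segment: per-segment detrending leaks into the 1 Hz bin
through the window response and visibly biases the delta band.

Bands are delta [1, 4), theta [4, 8), alpha [8, 12), beta [12, 30),
low-gamma [30, 50] Hz; all half-open except the top band, so the five
bands tile the total 1–50 Hz range exactly and percent-of-total values sum
to 100 by construction. Event-level spectra are computed per participating
channel over the event span and averaged across channels (a per-channel
table is available by passing single-channel events).

## Benchmarking

Predicted and annotated event intervals are rasterized to per-sample
boolean masks (event present/absent; sub-type labels collapse to binary),
compared element-wise, pooled across channels by summing raw counts, and
scored once on the pooled counts with the five standard formulas. Metrics
with zero denominators are reported as missing, never coerced to 0 or 1.

## Synthetic recordings

The generator plants analytically known activity in seeded Gaussian noise
(default σ = 10 µV, 16×16 grid, 100 Hz, 5% dead channels):

- **Discharge waveform**: a biphasic transient with a steep leading edge —
  an abrupt deflection to the configured amplitude decaying over 50 ms,
  then a 150-ms opposite-sign recovery at 30% height. Epileptiform LFP
  spikes have steep onsets, and the sharp edge makes the true onset sample
  exact for ground truth.
- **Propagation**: each discharge is a wavefront disc (radius 2 grid
  units) moving at constant velocity from an origin until its center exits
  the grid; a channel within the disc's track receives the waveform when
  the front passes it. True path length is therefore speed × traversal
  time, in closed form. The default speed is 75 grid units/s ≈ one
  electrode pitch per 0.0133-s tracking bin: the front advances one
  column per bin, so the planted wave is properly sampled at the tracker's
  bin rate. (A slower front leaves empty bins between active columns; if
  dead channels then push a column below MinPts, gaps can reach the 3-bin
  termination patience and split a trajectory — an observability limit of
  bin-based tracking, not a detector bug.)
- **Events** are discharge trains: blips (< 10 s), SLSLE (10 s–5 min) and
  SE (> 5 min), with a default inter-discharge interval of 1.5 s — chosen
  below the detector's 2-s grouping gap so a train is one event, as in the
  biological recordings where discharges within an event recur every
  second or two. Default amplitude is 8 noise SDs. Events may not overlap
  in time, keeping ground truth unambiguous.

The standard fixture is 600 s: quiet noise until 140 s (providing the
2-minute baseline), a 30-s SLSLE train at 140 s, and a 360-s SE train at
200 s.

What the generator does *not* emulate: 1/f background spectra, baseline
drift, electrode-coupling artifacts, spatially varying noise, waveform
variability between discharges, and curved or accelerating propagation.
Passing the recovery tests therefore shows the pipeline is correct under
its own assumptions (additive transients on stationary Gaussian noise),
not that it attains the same scores on biological recordings.

## Numerical choices and problem sizes

- Robust SD is always 1.4826·MAD; deviations use |x − reference|
  (both polarities), since slice discharges can deflect either way.
- Ties are always broken deterministically (earliest in time, smallest
  variance, lexicographic scan order), so every run is reproducible; the
  pipeline manifest records config and seed.
- Tests and the acceptance script use the 16×16 / 600-s fixture (15.4 M
  samples) and small 8×8 variants, sizes chosen so the whole suite runs in
  well under a minute per module on one core; the full 64×64 grid is
  supported by the same code paths.
- The spectral comparison between event types plants a denser (2×-rate)
  SE train at equal amplitude rather than a higher-amplitude one: with a
  shared waveform the percent-of-total band profile is preserved while
  absolute power scales, which is the direction the analysis is meant to
  resolve. Changing amplitude instead shifts the waveform/noise mixture
  and with it the percent profile — a property of synthetic mixtures, not
  of the estimator.

## Known limitations

- Detection assumes a quiet 2-minute stretch exists; recordings that are
  ictal throughout will get a poor baseline (the minimum-crossing window)
  and a warning only when the record is shorter than the window.
- Trajectory linking is greedy nearest-centroid; crossing or merging
  wavefronts within one linking radius may be joined or swapped.
- The SNR screen keys on the single largest deflection; a single large
  artifact can rescue an otherwise dead-quiet channel.
- Network-event merging is purely temporal; two spatially disjoint events
  overlapping in time would merge into one table row.
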