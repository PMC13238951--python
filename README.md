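# ysa — seizure-like event analysis for HD-MEA recordings

High-density multielectrode arrays (HD-MEAs) record local field potentials
(LFPs) from thousands of electrodes on a regular grid, which makes them
ideal for studying how epileptiform activity starts and spreads through
brain-slice networks — and painful to analyze by hand. `ysa` is a headless
Python library + CLI for that analysis: it detects seizure-like activity
per channel, tracks individual discharges as they propagate across the
electrode grid, quantifies per-event features, computes spectral band
power, and benchmarks detector output sample-by-sample against annotated
ground truth. A seeded synthetic-recording generator with exact ground
truth makes the whole pipeline testable without lab data.

It is intended for electrophysiologists and analysis engineers working
with slice HD-MEA data (e.g. low-Mg²⁺ seizure models) who want a scriptable,
reproducible pipeline rather than a GUI.

## The analysis in brief

**Detection** runs per channel in three steps. A quiet 2-minute baseline
window is located (fewest robust-threshold crossings); samples deviating
from the baseline mean by more than 3 SD *and* whose surrounding 1-s
variance exceeds the baseline reference variance by 3 SD are discharge
points; points within 2 s of each other are grouped into one event. Events
are labeled by duration *d*:

- *d* > 5 min → **SE** (status-epilepticus-like activity)
- 10 s < *d* ≤ 5 min → **SLSLE** (self-limiting seizure-like event)
- *d* ≤ 10 s → discarded (kept in the output for audit)

**Tracking** finds discharge peaks per channel (|x − mean| > 4 robust SD,
minimum inter-peak distance 30 samples), marks each discharge onset at the
largest single-step voltage change in the 20 samples before the peak, bins
onsets into 0.0133-s windows, clusters active electrodes per bin with
DBSCAN (ε = 4.8 electrode pitches, MinPts = 4), and links cluster centroids
across bins into trajectories; a trajectory ends after 3 consecutive empty
bins. The propagation path length is Σ‖cᵢ₊₁ − cᵢ‖₂ over consecutive
centroids (× 60 µm pitch for physical units).

**Features** per event: duration, discharge count, mean discharge duration,
mean inter-discharge interval, mean path length — exported as CSV.

**Spectra**: absolute band power normalized to time (Welch PSD integral)
and percent-of-total over delta 1–4, theta 4–8, alpha 8–12, beta 12–30 and
low-gamma 30–50 Hz (total 1–50 Hz).

**Benchmark**: sample-wise TP/TN/FP/FN pooled across channels, scored as
accuracy, precision, recall, specificity and F1.

## Worked example

Simulate a recording with one 30-s SLSLE and one 360-s SE train of
discharges sweeping a 16×16 grid, then run the full pipeline:

```sh
cat > synth.yaml <<EOF
seed: 1
duration: 600.0
events:
  - {kind: SLSLE, start: 140.0, duration: 30.0}
  - {kind: SE, start: 200.0, duration: 360.0}
EOF
cat > run.yaml <<EOF
peaks: {snr_threshold: 6.0}   # tuned to the fixture's 8-sigma discharges
EOF

ysa simulate --config synth.yaml --out rec.h5 --truth truth/
ysa run rec.h5 --config run.yaml --outdir out/
ysa benchmark --pred out/events.csv --truth truth/truth_events.csv \
    --fs 100 --duration 600 --out scores.csv
```

The pipeline prints

```
simulated 256 channels × 600 s → rec.h5
pipeline complete: 2 events → out/
accuracy=0.9995 precision=0.9996 recall=0.9996 specificity=0.9992 f1=0.9996
```

`out/event_features.csv` then contains one row per detected event
(floats abbreviated):

```
event_id,label,onset_s,offset_s,duration_s,n_channels,n_discharges,mean_discharge_duration_s,mean_idi_s,mean_path_len_um
0,SLSLE,139.72,169.21,29.49,77,20,0.200,1.5001,890.40
1,SE,199.73,561.11,361.38,77,240,0.200,1.5000,890.70
```

Read: the detector recovered both planted events with the correct labels;
each contains exactly its planted discharges (one every 1.5 s, recovered
as mean_idi_s ≈ 1.500), and tracking recovered the waves' 900-µm planted
propagation path within ~1%. The benchmark line shows sample-wise
agreement with the ground-truth annotations.
Other commands (`convert`, `resample`, `select`, `detect`, `track`,
`features`, `raster`, `spectra`, `snr`) expose the individual stages;
`ysa run` writes a `manifest.json` so any run can be reproduced exactly.

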