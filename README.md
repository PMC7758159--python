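# nervequant

Quantification pipeline for peripheral nerve multi-unit recordings: band-pass
and notch filtering, rectified leaky integration, noise-floor-referenced spike
detection, burst-ensemble counting, stimulation-protocol scheduling, group
statistics (pooled t test, two-way ANOVA with a Tukey–Kramer post hoc) and
intermodes-threshold area quantification for stained-tissue images. A
synthetic-data module generates ground-truthed recordings, summary tables and
bimodal test images so every stage is verifiable without animal data.

## Analysis chains

* **Spike chain (SSNA)** — 300–1000 Hz band-pass + 50 Hz notch; spikes are
  local maxima of the filtered magnitude above `k ×` the baseline noise floor
  (MAD of a post-mortem segment, scaled to the Gaussian sd); firing frequency
  is reported as spikes per 10-minute bin and amplitude gain as the mean
  spike-peak / noise-floor ratio per bin.
* **Burst chain (CVNA)** — stricter 300–550 Hz band-pass; full-wave
  rectification followed by a leaky integrator with a 0.1 s decay; envelope
  peaks above a post-mortem envelope reference are merged into activation
  bursts (default merge gap 0.3 s) and counted per 10-minute bin.
* **Stimulation** — 5 Hz, 0.3 mA monophasic pulses on alternate minutes
  within a 10-minute window; sham keeps the stimulator off; both arms share
  the 10–20 min analysis window.
* **Imaging** — 256-bin histogram smoothed with a 3-bin mean until exactly
  two modes survive; threshold at the mode midpoint; stained-area fraction is
  the proportion of pixels above it, averaged per animal over fields of view.

## CLI

```sh
# simulate a ground-truthed session (activity + annotated post-mortem tail)
nervequant simulate --kind session --duration-s 600 --seed 1 --out session.csv

# run the burst-chain quantification
nervequant run --input session.csv --mode cvna --out-dir out/

# stimulation schedule and analysis window
nervequant stim-schedule --mode vns --out schedule.json

# group statistics over a tidy per-animal table
nervequant stats --input summaries.csv --test auto --out results.json

# stained-area quantification over fields of view
nervequant quantify-image field1.png field2.png --out area.csv
```

Recordings are delimited text (`time,<channel>...` in seconds / μV / mmHg)
with optional `.annotations.csv` (label, start, end) and `.meta.json`
sidecars. Pipeline parameters live in a YAML config (see
`nervequant.config.PipelineConfig`; unknown keys are rejected). Exit codes:
0 success, 2 configuration error, 3 data error.

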