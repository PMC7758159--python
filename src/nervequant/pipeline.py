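"""End-to-end workflows: spike-chain (SSNA) and burst-chain (CVNA)
quantification of a recording, and group statistics over summary tables.

Every output file embeds the configuration hash and seed, and serialisation
is deterministic, so identical invocations are reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import bursts as _bursts
from . import preprocess as _pp
from . import spikes as _spikes
from .config import PipelineConfig, config_hash
from .errors import DataError, ParameterError
from .io_timeseries import Recording, read_recording, write_recording
from .stats import GroupDesign, TestResult, t_test_two_sample, two_way_anova_tukey

__all__ = ["run_pipeline", "run_group_stats", "PipelineResult"]


@dataclasses.dataclass
class PipelineResult:
    mode: str
    noise_floor: float
    bins: list[_spikes.BinSummary]
    spikes: list[_spikes.SpikeEvent]
    bursts: list[_bursts.BurstEvent]
    out_files: dict[str, Path]


def _dump_json(path: Path, payload: Any) -> None:
    path.write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def _analysis_span(rec: Recording, cfg: PipelineConfig) -> tuple[float, float]:
    """Analysable span: the recording minus a trailing post-mortem segment."""
    try:
        pm = rec.annotation(cfg.postmortem_label)
    except DataError:
        return (0.0, rec.duration)
    if pm.t_start > 0 and pm.t_end >= rec.duration - 0.5 / rec.fs:
        return (0.0, pm.t_start)
    return (0.0, rec.duration)


def run_pipeline(
    config: PipelineConfig,
    mode: str,
    rec: Recording | None = None,
    out_dir: str | Path | None = None,
    write_traces: bool = True,
) -> PipelineResult:
    """Run the full quantification chain on one recording.

    mode="ssna": band-pass + notch, noise-floor spike detection, per-bin
    firing frequency and amplitude gain.  mode="cvna": strict band-pass,
    rectified leaky integration, envelope peak detection, burst merging and
    per-bin burst counts.

    The recording must carry a post-mortem annotation (the noise reference);
    its absence is an error naming the missing label.  ``write_traces=False``
    skips the (large) filtered/integrated trace exports and keeps only events
    and summaries.
    """
    if mode not in ("ssna", "cvna"):
        raise ParameterError(f"mode must be 'ssna' or 'cvna', got {mode!r}")
    if rec is None:
        if config.input is None:
            raise ParameterError("no recording given and config.input is unset")
        rec = read_recording(config.input)

    # Validate filter designs before any heavy processing.
    chain = config.ssna if mode == "ssna" else config.cvna
    spec = _pp.FilterSpec(
        kind="bandpass", low_hz=chain.band[0], high_hz=chain.band[1], order=chain.order
    )
    _pp.bandpass_sos(rec.fs, spec)

    try:
        pm = rec.annotation(config.postmortem_label)
    except DataError:
        raise DataError(
            f"recording has no {config.postmortem_label!r} annotation; "
            "a post-mortem segment is required to estimate the noise floor"
        ) from None

    nerve = rec.channel(config.nerve_channel)
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    meta = {"config_hash": chash, "seed": config.seed, "mode": mode}
    span = _analysis_span(rec, config)
    out_files: dict[str, Path] = {}

    # Baseline noise floor from the raw post-mortem segment (pre-filter),
    # so the k*floor threshold refers to the recording's baseline noise.
    noise = _spikes.estimate_noise_floor(nerve, rec.fs, pm)

    if mode == "ssna":
        filt = _pp.bandpass_filter(nerve, rec.fs, spec)
        filt = _pp.notch_filter(filt, rec.fs, chain.notch_hz, chain.notch_q)
        spike_events = _spikes.detect_spikes(
            filt, rec.fs, noise, k=chain.k, refractory_s=chain.refractory_s
        )
        spike_events = [s for s in spike_events if span[0] <= s.t < span[1]]
        bins = _spikes.bin_firing_frequency(spike_events, span, config.bin_s)
        for b in bins:
            in_bin = [s for s in spike_events
                      if b.bin_start <= s.t < b.bin_start + b.bin_len]
            b.amplitude_gain = _spikes.amplitude_gain(in_bin, noise)
        burst_events: list[_bursts.BurstEvent] = []

        if write_traces:
            out_files["filtered"] = write_recording(
                Recording(
                    channels={config.nerve_channel: filt},
                    fs=rec.fs,
                    t0=rec.t0,
                    annotations=list(rec.annotations),
                    units={config.nerve_channel: "uV"},
                ),
                out / "filtered_ssna.csv",
            )
        _dump_json(
            out / "spikes.json",
            {**meta, "noise_floor_uv": noise.floor,
             "spikes": [{"t": s.t, "peak": s.peak} for s in spike_events]},
        )
        out_files["spikes"] = out / "spikes.json"
    else:
        filt = _pp.bandpass_filter(nerve, rec.fs, spec)
        env = _pp.rectify_integrate(filt, rec.fs, tau=chain.tau_s)
        i0, i1 = int(round(pm.t_start * rec.fs)), int(round(pm.t_end * rec.fs))
        pm_env = _pp.IntegratedTrace(env.samples[i0:i1], rec.fs, chain.tau_s)
        noise_env = _bursts.envelope_noise_level(pm_env)
        if noise_env <= 0:
            raise DataError("post-mortem envelope noise level is 0")
        peaks = _bursts.detect_integrated_peaks(
            env, noise_env, k=chain.env_k, min_separation_s=chain.min_separation_s
        )
        peaks = [p for p in peaks if span[0] <= p[0] < span[1]]
        burst_events = _bursts.merge_peaks_to_bursts(peaks, chain.merge_gap_s)
        counts = _bursts.bin_burst_count(burst_events, span, config.bin_s)
        bins = _spikes.bin_firing_frequency([], span, config.bin_s)
        for b, c in zip(bins, counts):
            b.n_bursts = c
        spike_events = []

        if write_traces:
            out_files["integrated"] = write_recording(
                Recording(
                    channels={config.nerve_channel: env.samples},
                    fs=rec.fs,
                    t0=rec.t0,
                    annotations=list(rec.annotations),
                    units={config.nerve_channel: "uV"},
                ),
                out / "integrated_cvna.csv",
            )
        _dump_json(
            out / "bursts.json",
            {**meta, "envelope_noise_uv": noise_env,
             "bursts": [{"t_start": b.t_start, "t_end": b.t_end,
                         "peak": b.peak, "n_peaks": b.n_peaks}
                        for b in burst_events]},
        )
        out_files["bursts"] = out / "bursts.json"

    summary_rows = [
        {
            "bin_start": b.bin_start,
            "bin_len": b.bin_len,
            "n_spikes": b.n_spikes,
            "firing_frequency": b.firing_frequency,
            "amplitude_gain": b.amplitude_gain,
            "n_bursts": b.n_bursts,
        }
        for b in bins
    ]
    _dump_json(out / "summary.json", {**meta, "noise_floor_uv": noise.floor,
                                      "bins": summary_rows})
    pd.DataFrame(summary_rows).to_csv(out / "summary.csv", index=False)
    out_files["summary_json"] = out / "summary.json"
    out_files["summary_csv"] = out / "summary.csv"

    if config.bp_channel and config.bp_channel in rec.channels:
        bp = _pp.bp_bin_summary(rec.channel(config.bp_channel), rec.fs, config.bin_s)
        pd.DataFrame(bp, columns=["mean_mmhg", "sd_mmhg"]).to_csv(
            out / "bp_summary.csv", index=False
        )
        out_files["bp_summary"] = out / "bp_summary.csv"

    return PipelineResult(
        mode=mode,
        noise_floor=noise.floor,
        bins=bins,
        spikes=spike_events,
        bursts=burst_events,
        out_files=out_files,
    )


def run_group_stats(
    table: pd.DataFrame,
    test: str = "auto",
    out_path: str | Path | None = None,
) -> list[TestResult]:
    """Group statistics over a tidy per-animal summary table.

    With columns ``group``/``value`` and two groups: pooled two-sample t
    test.  With columns ``value``/``factor_a``/``factor_b``: two-way ANOVA
    cells with the Tukey-Kramer post hoc.  ``test`` may force "t" or "tukey".
    """
    cols = set(table.columns)
    if test == "auto":
        test = "tukey" if {"factor_a", "factor_b"} <= cols else "t"
    if test == "t":
        if not {"group", "value"} <= cols:
            raise DataError("t test needs 'group' and 'value' columns")
        groups = {g: sub["value"].to_numpy() for g, sub in table.groupby("group")}
        if len(groups) != 2:
            raise DataError(f"t test needs exactly 2 groups, got {len(groups)}")
        (la, xa), (lb, xb) = sorted(groups.items())
        for label, v in ((la, xa), (lb, xb)):
            if v.size < 2:
                raise DataError(f"group {label!r} has n < 2")
        results = [t_test_two_sample(xa, xb, labels=(la, lb))]
    elif test == "tukey":
        if not {"value", "factor_a", "factor_b"} <= cols:
            raise DataError("tukey needs 'value', 'factor_a' and 'factor_b' columns")
        design = GroupDesign(
            values=table["value"].to_numpy(),
            factor_a=[str(v) for v in table["factor_a"]],
            factor_b=[str(v) for v in table["factor_b"]],
        )
        results = two_way_anova_tukey(design)
    else:
        raise ParameterError(f"unknown test {test!r}")

    if out_path is not None:
        out_path = Path(out_path)
        rows = [
            {"comparison": " vs ".join(r.comparison), "kind": r.kind,
             "statistic": r.statistic, "df": r.df, "p": r.p}
            for r in results
        ]
        if out_path.suffix == ".json":
            _dump_json(out_path, rows)
        else:
            pd.DataFrame(rows).to_csv(out_path, index=False)
    return results
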