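"""Ground-truthed synthetic data: recordings, noise segments, group tables,
bimodal images.

Every generator is a pure function of its configuration and seed, so each
analysis stage can be verified end-to-end without animal data.  The recording
model is deliberately simple: bursts arrive as a homogeneous Poisson process,
each carrying a Poisson number of biphasic spike templates at a fixed
intra-burst rate, on top of white Gaussian background noise plus a 50 Hz
mains sine.  It is a test harness, not a physiological claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .io_timeseries import Annotation, Recording

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "spike_template",
    "simulate_recording",
    "simulate_postmortem",
    "simulate_session",
    "simulate_group_summaries",
    "simulate_if_image",
]


@dataclass(frozen=True)
class SynthConfig:
    fs: float = 4000.0
    duration_s: float = 600.0
    burst_rate: float = 20.0  # bursts per 600 s
    spikes_per_burst: float = 10.0  # Poisson mean
    intra_burst_rate: float = 150.0  # Hz within a burst
    spike_peak: float = 40.0  # uV
    spike_width_ms: float = 2.0
    noise_sd: float = 5.0  # uV
    mains_amp: float = 2.0  # uV
    mains_hz: float = 50.0
    tonic_rate: float = 0.0  # optional tonic (out-of-burst) spikes, Hz
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("burst_rate", "spikes_per_burst", "intra_burst_rate",
                     "noise_sd", "mains_amp", "tonic_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ParameterError("fs and duration_s must be > 0")
        if self.spike_peak <= 0 or self.spike_width_ms <= 0:
            raise ParameterError("spike_peak and spike_width_ms must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    spike_times: list[float]
    burst_intervals: list[tuple[float, float]]
    tonic_spike_times: list[float] = field(default_factory=list)


def spike_template(fs: float, peak: float, width_ms: float) -> np.ndarray:
    """One-cycle biphasic sinusoid: zero net area, analytic peak amplitude."""
    n = max(4, int(round(width_ms / 1000.0 * fs)))
    tpl = np.sin(2 * np.pi * np.arange(n) / n)
    return peak * tpl / np.max(np.abs(tpl))


def _add_template(sig: np.ndarray, tpl: np.ndarray, i0: int) -> None:
    n = sig.size
    j0, j1 = max(i0, 0), min(i0 + tpl.size, n)
    if j0 < j1:
        sig[j0:j1] += tpl[j0 - i0 : j1 - i0]


def _background(cfg: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    t = np.arange(n) / cfg.fs
    bg = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else np.zeros(n)
    if cfg.mains_amp > 0:
        bg += cfg.mains_amp * np.sin(2 * np.pi * cfg.mains_hz * t)
    return bg


def simulate_recording(cfg: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Simulate a nerve recording with known spike times and burst intervals.

    Burst onsets follow a homogeneous Poisson process at ``burst_rate`` per
    600 s; each burst carries ``Poisson(spikes_per_burst)`` spikes with
    exponential inter-spike intervals at ``intra_burst_rate``.  A drawn burst
    with zero spikes produces no signal and is omitted from the ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    sig = _background(cfg, rng, n)
    tpl = spike_template(cfg.fs, cfg.spike_peak, cfg.spike_width_ms)
    width_s = tpl.size / cfg.fs

    rate_per_s = cfg.burst_rate / 600.0
    n_bursts = rng.poisson(rate_per_s * cfg.duration_s)
    onsets = np.sort(rng.uniform(0.0, cfg.duration_s, n_bursts))

    spike_times: list[float] = []
    burst_intervals: list[tuple[float, float]] = []
    for onset in onsets:
        n_sp = rng.poisson(cfg.spikes_per_burst)
        if n_sp == 0:
            continue
        if cfg.intra_burst_rate > 0 and n_sp > 1:
            gaps = rng.exponential(1.0 / cfg.intra_burst_rate, n_sp - 1)
            times = onset + np.concatenate([[0.0], np.cumsum(gaps)])
        else:
            times = np.array([onset])
        times = times[times < cfg.duration_s - width_s]
        if times.size == 0:
            continue
        for t in times:
            _add_template(sig, tpl, int(round(t * cfg.fs)))
        spike_times.extend(float(t) for t in times)
        burst_intervals.append((float(times[0]), float(times[-1] + width_s)))

    tonic_times: list[float] = []
    if cfg.tonic_rate > 0:
        n_tonic = rng.poisson(cfg.tonic_rate * cfg.duration_s)
        for t in np.sort(rng.uniform(0.0, cfg.duration_s - width_s, n_tonic)):
            _add_template(sig, tpl, int(round(t * cfg.fs)))
            tonic_times.append(float(t))

    rec = Recording(
        channels={"nerve": sig},
        fs=cfg.fs,
        units={"nerve": "uV"},
    )
    return rec, GroundTruth(
        spike_times=sorted(spike_times + tonic_times),
        burst_intervals=burst_intervals,
        tonic_spike_times=tonic_times,
    )


def simulate_postmortem(cfg: SynthConfig) -> Recording:
    """Spike-free segment (noise + mains only), annotated "postmortem"."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    sig = _background(cfg, rng, n)
    return Recording(
        channels={"nerve": sig},
        fs=cfg.fs,
        annotations=[Annotation("postmortem", 0.0, cfg.duration_s)],
        units={"nerve": "uV"},
    )


def simulate_session(
    cfg: SynthConfig, postmortem_s: float = 60.0
) -> tuple[Recording, GroundTruth]:
    """Activity recording followed by an annotated post-mortem noise tail.

    This is the shape the end-to-end pipeline expects: one recording whose
    noise floor can be estimated from its own "postmortem" annotation.
    """
    if postmortem_s < 1.0:
        raise ParameterError("postmortem_s must be >= 1 s")
    rec, truth = simulate_recording(cfg)
    rng = np.random.default_rng([cfg.seed, 0x706D])  # independent stream for the tail
    n_pm = int(round(postmortem_s * cfg.fs))
    tail = rng.normal(0.0, cfg.noise_sd, n_pm) if cfg.noise_sd > 0 else np.zeros(n_pm)
    if cfg.mains_amp > 0:
        t = (np.arange(n_pm) + rec.n_samples) / cfg.fs
        tail += cfg.mains_amp * np.sin(2 * np.pi * cfg.mains_hz * t)
    sig = np.concatenate([rec.channel("nerve"), tail])
    session = Recording(
        channels={"nerve": sig},
        fs=cfg.fs,
        annotations=[Annotation("postmortem", cfg.duration_s, cfg.duration_s + postmortem_s)],
        units={"nerve": "uV"},
    )
    return session, truth


def simulate_group_summaries(
    design: list[tuple[str, int, float, float]],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-animal Gaussian summary values for a list of (label, n, mean, sd).

    Returns a tidy frame with columns ``group``, ``animal`` and ``value``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, n, mean, sd in design:
        if n < 2:
            raise ParameterError(f"group {label!r}: need n >= 2, got {n}")
        if sd < 0:
            raise ParameterError(f"group {label!r}: sd must be >= 0")
        values = mean + sd * rng.standard_normal(n) if sd > 0 else np.full(n, float(mean))
        rows.extend(
            {"group": label, "animal": f"{label}_{i + 1}", "value": float(v)}
            for i, v in enumerate(values)
        )
    return pd.DataFrame(rows, columns=["group", "animal", "value"])


def simulate_if_image(
    width: int,
    height: int,
    target_fraction: float,
    fg_mean: float,
    bg_mean: float,
    noise_sd: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Grayscale image with a blob-shaped foreground of known area fraction.

    A smoothed Gaussian random field is thresholded at the quantile matching
    ``target_fraction``, giving organically shaped blobs whose true mask
    fraction is exact up to pixel quantisation.  Returns ``(image, mask)``
    with the image as float64 and the mask boolean.
    """
    if not 0 < target_fraction < 1:
        raise ParameterError("target_fraction must be in (0, 1)")
    if fg_mean <= bg_mean:
        raise ParameterError("fg_mean must exceed bg_mean")
    if width < 8 or height < 8:
        raise ParameterError("image must be at least 8x8 for the blob model")
    rng = np.random.default_rng(seed)
    blob_field = ndimage.gaussian_filter(
        rng.standard_normal((height, width)), sigma=min(height, width) / 10.0
    )
    thr = np.quantile(blob_field, 1.0 - target_fraction)
    mask = blob_field > thr
    img = np.where(mask, fg_mean, bg_mean).astype(float)
    if noise_sd > 0:
        img += noise_sd * rng.standard_normal(img.shape)
    return img, mask
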