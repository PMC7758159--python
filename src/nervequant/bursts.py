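"""Peak detection on the integrated envelope and burst-ensemble counting.

An activation ensemble shows up as a cluster of envelope peaks; peaks closer
than the merge gap are combined and counted once.  The default merge gap of
0.3 s (three integrator time constants) lets ensembles within the
integrator's memory merge naturally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .errors import DataError, ParameterError
from .preprocess import IntegratedTrace

__all__ = [
    "BurstEvent",
    "envelope_noise_level",
    "detect_integrated_peaks",
    "merge_peaks_to_bursts",
    "bin_burst_count",
    "DEFAULT_ENV_K",
    "DEFAULT_MIN_SEPARATION_S",
    "DEFAULT_MERGE_GAP_S",
]

DEFAULT_ENV_K = 2.0
DEFAULT_MIN_SEPARATION_S = 0.2
DEFAULT_MERGE_GAP_S = 0.3


@dataclass(frozen=True)
class BurstEvent:
    t_start: float
    t_end: float
    peak: float  # uV, max member-peak envelope value
    n_peaks: int

    def __post_init__(self) -> None:
        if self.t_start > self.t_end:
            raise ParameterError("t_start must be <= t_end")
        if self.n_peaks < 1:
            raise ParameterError("a burst has at least one member peak")


def envelope_noise_level(postmortem_env: IntegratedTrace) -> float:
    """Envelope-domain noise reference: median of the integrated post-mortem
    segment.  Keeps the envelope threshold consistent with the spike-domain
    noise floor (both derive from the same spike-free data)."""
    return float(np.median(postmortem_env.samples))


def detect_integrated_peaks(
    env: IntegratedTrace,
    noise_env: float,
    k: float = DEFAULT_ENV_K,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
) -> list[tuple[float, float]]:
    """Local maxima of the envelope above ``k * noise_env``.

    Peaks closer than ``min_separation_s`` are collapsed to the larger one.
    A flat plateau at a maximum is reported at its earliest sample.
    """
    if noise_env <= 0:
        raise DataError(f"noise_env must be > 0, got {noise_env}")
    if k <= 0:
        raise ParameterError("k must be > 0")
    if min_separation_s < 0:
        raise ParameterError("min_separation_s must be >= 0")
    x = env.samples
    thr = k * noise_env
    distance = max(1, int(round(min_separation_s * env.fs)))
    idx, props = _signal.find_peaks(x, height=thr, distance=distance, plateau_size=1)
    left = props["left_edges"]  # earliest plateau sample (tie-break convention)
    heights = props["peak_heights"]
    keep = heights > thr
    return [
        (float(i / env.fs), float(h)) for i, h in zip(left[keep], heights[keep])
    ]


def merge_peaks_to_bursts(
    peaks: list[tuple[float, float]],
    merge_gap_s: float = DEFAULT_MERGE_GAP_S,
) -> list[BurstEvent]:
    """Combine runs of peaks with inter-peak gap <= ``merge_gap_s`` into bursts.

    The burst peak is the maximum member peak; ``t_start``/``t_end`` span the
    first and last member.  Input must be time-sorted.
    """
    if merge_gap_s < 0:
        raise ParameterError("merge_gap_s must be >= 0")
    times = [t for t, _ in peaks]
    if any(b < a for a, b in zip(times, times[1:])):
        raise DataError("peaks must be sorted by time")
    bursts: list[BurstEvent] = []
    group: list[tuple[float, float]] = []
    for p in peaks:
        if group and p[0] - group[-1][0] > merge_gap_s:
            bursts.append(_close_group(group))
            group = []
        group.append(p)
    if group:
        bursts.append(_close_group(group))
    return bursts


def _close_group(group: list[tuple[float, float]]) -> BurstEvent:
    return BurstEvent(
        t_start=group[0][0],
        t_end=group[-1][0],
        peak=max(v for _, v in group),
        n_peaks=len(group),
    )


def bin_burst_count(
    bursts: list[BurstEvent],
    t_span: tuple[float, float],
    bin_s: float = 600.0,
) -> list[int]:
    """Burst counts per complete half-open bin; assignment by onset time.

    A burst straddling a bin boundary is counted once, in the bin containing
    its ``t_start``.
    """
    if bin_s <= 0:
        raise ParameterError("bin_s must be > 0")
    t0, t1 = t_span
    if not t0 < t1:
        raise ParameterError(f"invalid t_span {t_span}")
    n_bins = int(np.floor((t1 - t0) / bin_s + 1e-9))
    counts = [0] * n_bins
    for b in bursts:
        i = int(np.floor((b.t_start - t0) / bin_s))
        if 0 <= i < n_bins:
            counts[i] += 1
    return counts
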