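"""Spike detection and cluster segmentation.

The baseline (4 pA set point) is shifted to zero; every contiguous excursion
whose apex exceeds 15 pA above baseline is a signal peak; peaks are grouped
into capture clusters by summing unit-height Gaussian windows (4096-sample
full width) centred at each apex and cutting the summed envelope at 0.1;
finally, local maxima inside a cluster span with amplitude below the
detection threshold (but above a noise floor) are harvested as sub-threshold
spikes, since cluster features are computed from all member spikes.

All indices are 0-based; peak and cluster intervals are half-open.
Threshold comparisons are strict (``>``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import ConfigError, EVENT_COLUMNS, PipelineConfig, TraceRecord


@dataclass
class Peak:
    start_index: int
    apex_index: int
    end_index: int
    amplitude: float
    width_samples: int
    subthreshold_flag: bool = False

    def __post_init__(self) -> None:
        if not (self.start_index <= self.apex_index < self.end_index):
            raise ValueError("apex must lie inside the half-open peak interval")


@dataclass
class Cluster:
    cluster_id: int
    peaks: list[Peak]
    start_index: int
    end_index: int
    envelope_max: float
    rejected: bool = False
    rejection_reason: str = ""
    zpiezo_r: float = field(default=float("nan"))

    @property
    def span(self) -> tuple[int, int]:
        return self.start_index, self.end_index


def shift_baseline(trace: TraceRecord | np.ndarray,
                   baseline: float = 4.0) -> np.ndarray:
    """Subtract the constant current set point so the baseline sits at zero."""
    if not math.isfinite(baseline):
        raise ValueError("baseline must be finite")
    x = trace.samples_current if isinstance(trace, TraceRecord) else np.asarray(trace, float)
    return x - baseline


def detect_peaks(shifted: np.ndarray, threshold: float = 15.0) -> list[Peak]:
    """One peak per contiguous excursion whose apex exceeds ``threshold``.

    Excursion boundaries extend outward from the above-threshold run to the
    nearest zero-crossing or local-minimum valley on each side; the apex is
    the maximum sample (earliest index on ties); amplitude is the apex value.
    """
    if not threshold > 0:
        raise ConfigError("threshold must be positive")
    x = np.asarray(shifted, dtype=float)
    if x.size == 0:
        return []
    above = x > threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))

    peaks: list[Peak] = []
    for rs, re in zip(run_starts, run_ends):
        # walk left to zero-crossing or valley
        s = rs
        while s > 0 and x[s - 1] > 0 and x[s - 1] <= x[s]:
            s -= 1
        e = re
        while e < x.size and x[e] > 0 and x[e] <= x[e - 1]:
            e += 1
        seg = x[rs:re]
        apex_local = int(np.argmax(seg))  # argmax returns earliest tie
        apex = rs + apex_local
        amplitude = float(x[apex])
        half = amplitude / 2.0
        width = int(np.count_nonzero(x[s:e] > half))
        peaks.append(Peak(int(s), int(apex), int(e), amplitude, width, False))
    return peaks


def gaussian_sigma(window_full_width: int) -> float:
    """The Gaussian window spans ``window_full_width`` samples at +-3 sigma."""
    return window_full_width / 6.0


def cluster_envelope(apexes: np.ndarray, trace_length: int,
                     window_full_width: int = 4096) -> np.ndarray:
    """Sum of unit-height Gaussians centred at each apex (direct form)."""
    sigma = gaussian_sigma(window_full_width)
    env = np.zeros(trace_length)
    idx = np.arange(trace_length)
    for a in apexes:
        env += np.exp(-((idx - a) ** 2) / (2.0 * sigma ** 2))
    return env


def segment_clusters(peaks: list[Peak], trace_length: int,
                     window_full_width: int = 4096,
                     sum_threshold: float = 0.1) -> list[Cluster]:
    """Group peaks into clusters by the summed-Gaussian envelope rule.

    Equivalent to direct summation (``cluster_envelope``) but computed by
    convolving the apex impulse train with a truncated Gaussian kernel, which
    scales to multi-million-sample traces.
    """
    if window_full_width <= 0:
        raise ConfigError("window_full_width must be positive")
    if not peaks:
        return []
    apexes = np.array(sorted(p.apex_index for p in peaks))
    sigma = gaussian_sigma(window_full_width)
    # truncate the kernel where its tail is 1e-9 of the threshold: the
    # truncation error cannot move a threshold crossing by even one sample
    half = int(math.ceil(sigma * math.sqrt(
        2.0 * math.log(1.0 / (sum_threshold * 1e-9))))) + 1
    k = np.arange(-half, half + 1)
    kernel = np.exp(-(k ** 2) / (2.0 * sigma ** 2))
    env = np.zeros(trace_length)
    for a in apexes:
        lo, hi = a - half, a + half + 1
        klo = max(0, -lo)
        khi = kernel.size - max(0, hi - trace_length)
        env[max(lo, 0):min(hi, trace_length)] += kernel[klo:khi]

    above = env > sum_threshold
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))

    clusters: list[Cluster] = []
    sorted_peaks = sorted(peaks, key=lambda p: p.apex_index)
    for cid, (s, e) in enumerate(zip(starts, ends)):
        members = [p for p in sorted_peaks if s <= p.apex_index < e]
        if not members:
            continue
        clusters.append(Cluster(cid, members, int(s), int(e),
                                float(env[s:e].max())))
    return clusters


def harvest_subthreshold_peaks(cluster: Cluster, shifted: np.ndarray,
                               threshold: float = 15.0,
                               noise_floor: float = 5.0) -> Cluster:
    """Append sub-threshold local maxima inside the cluster span.

    Local maxima with amplitude in ``(noise_floor, threshold]`` that do not
    fall inside an already-detected peak interval are added with
    ``subthreshold_flag=True``.  A prominence of at least half the noise
    floor is required so that baseline-noise wiggles riding on spike tails
    are not counted as spikes.  Supra-threshold peaks are unchanged and
    harvested peaks never feed back into cluster segmentation.
    """
    s, e = cluster.span
    seg = np.asarray(shifted, float)[s:e]
    if seg.size < 3:
        return cluster
    locs, _ = find_peaks(seg, height=(noise_floor, None),
                         prominence=noise_floor / 2.0)
    existing = [(p.start_index, p.end_index) for p in cluster.peaks]
    new_peaks = []
    for loc in locs:
        g = s + int(loc)
        amp = float(seg[loc])
        if amp > threshold:
            continue
        if any(a <= g < b for a, b in existing):
            continue
        # boundaries: walk out to zero-crossing or valley
        lo = g
        while lo > s and shifted[lo - 1] > 0 and shifted[lo - 1] <= shifted[lo]:
            lo -= 1
        hi = g + 1
        while hi < e and shifted[hi] > 0 and shifted[hi] <= shifted[hi - 1]:
            hi += 1
        half = amp / 2.0
        width = int(np.count_nonzero(shifted[lo:hi] > half))
        new_peaks.append(Peak(int(lo), g, int(hi), amp, width, True))
    if new_peaks:
        cluster.peaks = sorted(cluster.peaks + new_peaks,
                               key=lambda p: p.apex_index)
    return cluster


def detect_events(trace: TraceRecord,
                  config: PipelineConfig | None = None
                  ) -> tuple[list[Cluster], np.ndarray]:
    """Full detection chain for one trace: shift, detect, segment, harvest.

    Returns the cluster list and the baseline-shifted current.
    """
    config = config or PipelineConfig()
    shifted = shift_baseline(trace, config.baseline)
    peaks = detect_peaks(shifted, config.amplitude_threshold)
    clusters = segment_clusters(peaks, trace.n_samples,
                                config.cluster_window,
                                config.cluster_sum_threshold)
    for cl in clusters:
        harvest_subthreshold_peaks(cl, shifted,
                                   config.amplitude_threshold,
                                   config.subthreshold_floor)
    return clusters, shifted


def clusters_to_event_table(clusters: list[Cluster], trace: TraceRecord
                            ) -> pd.DataFrame:
    """Flatten clusters into the tabular event schema."""
    rows = []
    for cl in clusters:
        for pid, p in enumerate(cl.peaks):
            rows.append((trace.junction_id, trace.run_id, cl.cluster_id, pid,
                         p.start_index, p.apex_index, p.end_index,
                         p.amplitude, p.subthreshold_flag,
                         cl.rejected, cl.rejection_reason))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
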