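"""Peak detection and Gaussian-sum cluster segmentation contracts."""

from __future__ import annotations

import math

import numpy as np
import pytest

from rtpipe import PipelineConfig, detect_events
from rtpipe.detection import (Cluster, Peak, cluster_envelope, detect_peaks,
                              gaussian_sigma, harvest_subthreshold_peaks,
                              segment_clusters, shift_baseline)


def _spike_trace(apexes, amp=30.0, n=20000, width=6):
    x = np.zeros(n)
    for a in apexes:
        for k in range(-width, width + 1):
            x[a + k] = amp * math.exp(-0.5 * (k / (width / 2)) ** 2)
    return x


def test_shift_baseline():
    x = np.full(10, 4.0)
    assert np.allclose(shift_baseline(x, 4.0), 0.0)


def test_threshold_is_strict():
    x = np.zeros(100)
    x[50] = 15.0  # exactly at threshold: not detected
    assert detect_peaks(x, 15.0) == []
    x[50] = 15.0 + 1e-9
    assert len(detect_peaks(x, 15.0)) == 1


def test_peak_boundaries_and_amplitude():
    x = _spike_trace([100], amp=40.0, n=300)
    peaks = detect_peaks(x, 15.0)
    assert len(peaks) == 1
    p = peaks[0]
    assert p.apex_index == 100
    assert p.amplitude == pytest.approx(40.0)
    assert p.start_index <= 100 < p.end_index
    # width counts samples above half maximum
    assert p.width_samples == int(np.sum(x > 20.0))


def test_two_separated_peaks():
    x = _spike_trace([100, 200], n=400)
    peaks = detect_peaks(x, 15.0)
    assert [p.apex_index for p in peaks] == [100, 200]


def test_gaussian_sigma_convention():
    assert gaussian_sigma(4096) == pytest.approx(4096 / 6)


def test_single_peak_cluster_halfspan_closed_form():
    """A lone peak's cluster extends sigma*sqrt(2 ln 10) each side."""
    x = _spike_trace([10000], n=20000)
    peaks = detect_peaks(x, 15.0)
    clusters = segment_clusters(peaks, len(x), window_full_width=4096, sum_threshold=0.1)
    assert len(clusters) == 1
    sigma = 4096 / 6
    half = sigma * math.sqrt(2 * math.log(10.0))
    c = clusters[0]
    assert c.start_index == pytest.approx(10000 - half, abs=2)
    assert c.end_index == pytest.approx(10000 + half, abs=2)


def test_segmentation_matches_bruteforce_oracle(rng):
    """Sparse kernel summation equals the direct dense Gaussian sum."""
    n = 100_000
    apexes = np.sort(rng.choice(np.arange(500, n - 500), size=40,
                                replace=False))
    x = np.zeros(n)
    x[apexes] = 30.0
    peaks = detect_peaks(x, 15.0)
    assert len(peaks) == len(apexes)
    window, thr = 4096, 0.1
    clusters = segment_clusters(peaks, n, window_full_width=window, sum_threshold=thr)

    # brute force: dense unit-height Gaussian at every apex
    sigma = gaussian_sigma(window)
    t = np.arange(n, dtype=float)
    dense = np.zeros(n)
    for a in apexes:
        dense += np.exp(-0.5 * ((t - a) / sigma) ** 2)
    above = dense > thr
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = edges[::2] + 1 if above[0] is np.True_ else None
    # recover intervals from the boolean mask directly
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    seg_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    seg_ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    # keep only intervals containing at least one apex (oracle clusters)
    keep = [(s, e) for s, e in zip(seg_starts, seg_ends)
            if np.any((apexes >= s) & (apexes < e))]
    assert len(clusters) == len(keep)
    for c, (s, e) in zip(clusters, keep):
        assert abs(c.start_index - s) <= 2
        assert abs(c.end_index - e) <= 2


def test_envelope_matches_definition():
    apexes = np.array([5000, 5500])
    env = cluster_envelope(apexes, 20000, window_full_width=4096)
    sigma = gaussian_sigma(4096)
    t = np.arange(20000, dtype=float)
    dense = sum(np.exp(-0.5 * ((t - a) / sigma) ** 2) for a in apexes)
    np.testing.assert_allclose(env, dense, atol=1e-6)


def test_more_peaks_never_fewer_clusters_span():
    """Adding a peak inside a cluster can only extend, never shrink it."""
    x1 = _spike_trace([10000], n=30000)
    x2 = _spike_trace([10000, 10400], n=30000)
    c1 = segment_clusters(detect_peaks(x1, 15.0), 30000, 4096, 0.1)[0]
    c2 = segment_clusters(detect_peaks(x2, 15.0), 30000, 4096, 0.1)[0]
    assert c2.start_index <= c1.start_index
    assert c2.end_index >= c1.end_index


def test_subthreshold_harvest():
    x = _spike_trace([10000], amp=40.0, n=30000)
    # a clear sub-threshold spike inside the cluster span
    x[10300:10310] += 10.0 * np.exp(
        -0.5 * ((np.arange(10) - 5) / 2.0) ** 2)
    peaks = detect_peaks(x, 15.0)
    clusters = segment_clusters(peaks, len(x), 4096, 0.1)
    cl = harvest_subthreshold_peaks(clusters[0], x, threshold=15.0,
                                    noise_floor=5.0)
    extra = [p for p in cl.peaks if p.subthreshold_flag]
    assert any(10300 <= p.apex_index < 10310 for p in extra)
    assert all(p.amplitude <= 15.0 for p in extra)
    # the original supra-threshold peak is untouched
    assert any(p.apex_index == 10000 and not p.subthreshold_flag
               for p in cl.peaks)


def test_detect_events_recovers_planted_clusters(small_trace, pipe_cfg):
    trace, truth = small_trace
    clusters, shifted = detect_events(trace, pipe_cfg)
    n_true = truth["cluster_index"].nunique()
    assert len(clusters) == pytest.approx(n_true, abs=max(2, 0.5 * n_true))
    # every planted above-threshold apex falls inside some cluster span
    strong = truth[truth["amplitude_pA"] > 20.0]
    covered = 0
    for apex in strong["apex_index"]:
        if any(c.start_index <= apex < c.end_index for c in clusters):
            covered += 1
    assert covered >= 0.9 * len(strong)


def test_peak_invariant_enforced():
    with pytest.raises(ValueError):
        Peak(start_index=10, apex_index=9, end_index=12, amplitude=20.0,
             width_samples=1)
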