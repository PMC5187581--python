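"""The 264-feature registry and per-spike feature extraction.

Each detected spike receives a vector of 264 named features: 81 time-domain
features (21 per-peak shape/timing descriptors and 60 per-cluster
aggregates, replicated onto each member spike) and 183 spectral features
(10-bin peak FFT, 61-bin cluster FFT, 51-bin whole-cluster FFT variant, and
61-bin cepstrum of the cluster).  Spectra are computed on mean-removed
segments with a rectangular window and down-sampled by averaging the
magnitude within equal-width frequency bins from 0 to the Nyquist frequency
(25 kHz at the default 20 μs sampling).  The cepstrum is the magnitude of
the Fourier transform of the cluster's power spectrum.

Feature columns are finally standardized per column to mean 0 / s.d. 1 over
a reference row set (training rows in the honest protocol), so classifiers
see scale-free inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .detection import Cluster, Peak
from .io import FEATURE_META_COLUMNS, PipelineConfig, TraceRecord

log = logging.getLogger("rtpipe")


# ---------------------------------------------------------------------------
# Registry

@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    scope: str    # "peak" | "cluster"
    domain: str   # "time" | "frequency" | "cepstrum"


_PEAK_TIME = [
    "peak_amplitude", "peak_width_half_max", "peak_duration", "peak_area",
    "peak_rise_time", "peak_fall_time", "peak_asymmetry", "peak_roughness",
    "peak_mean", "peak_median", "peak_sd", "peak_skew", "peak_kurtosis",
    "peak_energy", "peak_max_slope_rise", "peak_max_slope_fall",
    "peak_half_width_fraction", "peak_apex_frac_in_cluster",
    "peak_preceding_interval", "peak_following_interval",
    "peak_is_subthreshold",
]

_MEMBER_PROPS = ["amplitude", "width", "duration", "area", "rise", "fall",
                 "roughness", "interval"]
_MEMBER_STATS = ["mean", "sd", "min", "max", "skew"]

_CLUSTER_EXTRA = [
    "cluster_n_peaks", "cluster_n_subthreshold",
    "cluster_subthreshold_fraction", "cluster_span_duration",
    "cluster_peak_rate", "cluster_envelope_max", "cluster_total_area",
    "cluster_current_mean", "cluster_current_sd", "cluster_current_skew",
    "cluster_current_kurtosis", "cluster_current_max",
    "cluster_occupancy_threshold", "cluster_occupancy_half_threshold",
    "cluster_on_time", "cluster_duty_cycle",
    "cluster_first_peak_offset_frac", "cluster_last_peak_offset_frac",
    "cluster_interval_cv", "cluster_amplitude_cv",
]

N_PEAK_FFT_BINS = 10
N_CLUSTER_FFT_BINS = 61
N_WHOLE_FFT_BINS = 51
N_CEPSTRUM_BINS = 61


def _build_registry() -> list[FeatureDescriptor]:
    reg: list[FeatureDescriptor] = []
    for name in _PEAK_TIME:
        reg.append(FeatureDescriptor(name, "peak", "time"))
    for prop in _MEMBER_PROPS:
        for stat in _MEMBER_STATS:
            reg.append(FeatureDescriptor(f"cluster_{prop}_{stat}",
                                         "cluster", "time"))
    for name in _CLUSTER_EXTRA:
        reg.append(FeatureDescriptor(name, "cluster", "time"))
    for i in range(N_PEAK_FFT_BINS):
        reg.append(FeatureDescriptor(f"peak_fft_{i:02d}", "peak", "frequency"))
    for i in range(N_CLUSTER_FFT_BINS):
        reg.append(FeatureDescriptor(f"cluster_fft_{i:02d}", "cluster", "frequency"))
    for i in range(N_WHOLE_FFT_BINS):
        reg.append(FeatureDescriptor(f"whole_fft_{i:02d}", "cluster", "frequency"))
    for i in range(N_CEPSTRUM_BINS):
        reg.append(FeatureDescriptor(f"cepstrum_{i:02d}", "cluster", "cepstrum"))
    return reg


FEATURE_REGISTRY: list[FeatureDescriptor] = _build_registry()
FEATURE_NAMES: list[str] = [d.name for d in FEATURE_REGISTRY]
assert len(FEATURE_REGISTRY) == 264, "feature registry must total 264 entries"
assert len(set(FEATURE_NAMES)) == 264, "feature names must be unique"


class AssemblyError(ValueError):
    """A spike is missing a registry feature at table-assembly time."""


# ---------------------------------------------------------------------------
# Helpers

def _moment_stats(x: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mean, sd, min, max, skew) with degenerate inputs mapped to 0."""
    x = np.asarray(x, float)
    if x.size == 0:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else 0.0
    skew = float(sstats.skew(x)) if (x.size >= 3 and np.ptp(x) > 0) else 0.0
    return mean, sd, float(np.min(x)), float(np.max(x)), skew


def _safe_skew(x: np.ndarray) -> float:
    return float(sstats.skew(x)) if (x.size >= 3 and np.ptp(x) > 0) else 0.0


def _safe_kurt(x: np.ndarray) -> float:
    return float(sstats.kurtosis(x)) if (x.size >= 4 and np.ptp(x) > 0) else 0.0


# ---------------------------------------------------------------------------
# Spectral features

def binned_spectrum(segment: np.ndarray, n_bins: int,
                    sample_interval: float = 20e-6) -> np.ndarray:
    """Mean FFT magnitude in ``n_bins`` equal-width bands over [0, Nyquist].

    The segment mean is removed first (no taper); empty bins are 0; bin i
    covers frequencies in [i, i+1) * Nyquist/n_bins, the last bin closed at
    the Nyquist frequency.
    """
    x = np.asarray(segment, float)
    if x.size < 2:
        log.warning("segment of %d samples: all-zero spectral bins", x.size)
        return np.zeros(n_bins)
    mags = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(x.size, d=sample_interval)
    nyquist = 0.5 / sample_interval
    which = np.minimum((freqs / nyquist * n_bins).astype(int), n_bins - 1)
    out = np.zeros(n_bins)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=mags, minlength=n_bins)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def spectral_features(segment: np.ndarray, scope: str,
                      sample_interval: float = 20e-6) -> np.ndarray:
    """Binned magnitude spectrum: 10 bins for peaks, 61 for clusters,
    51 for the whole-cluster variant."""
    n_bins = {"peak": N_PEAK_FFT_BINS, "cluster": N_CLUSTER_FFT_BINS,
              "whole": N_WHOLE_FFT_BINS}[scope]
    return binned_spectrum(segment, n_bins, sample_interval)


def cepstrum_features(segment: np.ndarray,
                      n_bins: int = N_CEPSTRUM_BINS) -> np.ndarray:
    """Magnitude of the Fourier transform of the power spectrum, averaged
    into ``n_bins`` equal quefrency bins."""
    x = np.asarray(segment, float)
    if x.size < 4:
        log.warning("segment of %d samples: all-zero cepstrum bins", x.size)
        return np.zeros(n_bins)
    power = np.abs(np.fft.rfft(x - x.mean())) ** 2
    ceps = np.abs(np.fft.rfft(power))
    if ceps.size < 2:
        return np.zeros(n_bins)
    which = np.minimum(
        (np.arange(ceps.size) / ceps.size * n_bins).astype(int), n_bins - 1)
    out = np.zeros(n_bins)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=ceps, minlength=n_bins)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


# ---------------------------------------------------------------------------
# Time-domain features

def peak_time_features(peak: Peak, shifted: np.ndarray,
                       sample_interval: float = 20e-6,
                       cluster_span: tuple[int, int] | None = None,
                       preceding_interval: float = 0.0,
                       following_interval: float = 0.0) -> dict[str, float]:
    """Shape and timing descriptors of one spike.

    Roughness is the standard deviation of the samples strictly above half
    of the apex value — the spike-top texture measure.
    """
    seg = np.asarray(shifted, float)[peak.start_index:peak.end_index]
    dt = sample_interval
    amp = peak.amplitude
    above_half = seg[seg > amp / 2.0]
    roughness = float(np.std(above_half)) if above_half.size else 0.0
    rise = (peak.apex_index - peak.start_index) * dt
    fall = (peak.end_index - 1 - peak.apex_index) * dt
    dur = (peak.end_index - peak.start_index) * dt
    diffs = np.diff(seg) if seg.size >= 2 else np.zeros(1)
    if cluster_span is not None and cluster_span[1] > cluster_span[0]:
        apex_frac = ((peak.apex_index - cluster_span[0])
                     / (cluster_span[1] - cluster_span[0]))
    else:
        apex_frac = 0.0
    return {
        "peak_amplitude": amp,
        "peak_width_half_max": peak.width_samples * dt,
        "peak_duration": dur,
        "peak_area": float(seg.sum()) * dt,
        "peak_rise_time": rise,
        "peak_fall_time": fall,
        "peak_asymmetry": rise / (rise + fall) if (rise + fall) > 0 else 0.0,
        "peak_roughness": roughness,
        "peak_mean": float(seg.mean()) if seg.size else 0.0,
        "peak_median": float(np.median(seg)) if seg.size else 0.0,
        "peak_sd": float(np.std(seg, ddof=1)) if seg.size >= 2 else 0.0,
        "peak_skew": _safe_skew(seg),
        "peak_kurtosis": _safe_kurt(seg),
        "peak_energy": float(np.sum(seg ** 2)) * dt,
        "peak_max_slope_rise": float(diffs.max()) / dt if diffs.size else 0.0,
        "peak_max_slope_fall": float(-diffs.min()) / dt if diffs.size else 0.0,
        "peak_half_width_fraction": (peak.width_samples * dt / dur) if dur > 0 else 0.0,
        "peak_apex_frac_in_cluster": float(apex_frac),
        "peak_preceding_interval": preceding_interval,
        "peak_following_interval": following_interval,
        "peak_is_subthreshold": 1.0 if peak.subthreshold_flag else 0.0,
    }


def cluster_time_features(cluster: Cluster, shifted: np.ndarray,
                          sample_interval: float = 20e-6,
                          amplitude_threshold: float = 15.0
                          ) -> dict[str, float]:
    """Aggregate burst descriptors shared by every spike in the cluster."""
    if not cluster.peaks:
        raise ValueError("cluster has no peaks")
    dt = sample_interval
    s, e = cluster.span
    seg = np.asarray(shifted, float)[s:e]
    peaks = sorted(cluster.peaks, key=lambda p: p.apex_index)
    apexes = np.array([p.apex_index for p in peaks], float)
    intervals = np.diff(apexes) * dt if len(peaks) >= 2 else np.array([])

    props = {
        "amplitude": np.array([p.amplitude for p in peaks]),
        "width": np.array([p.width_samples for p in peaks]) * dt,
        "duration": np.array([(p.end_index - p.start_index) for p in peaks]) * dt,
        "area": np.array([float(shifted[p.start_index:p.end_index].sum()) * dt
                          for p in peaks]),
        "rise": np.array([(p.apex_index - p.start_index) for p in peaks]) * dt,
        "fall": np.array([(p.end_index - 1 - p.apex_index) for p in peaks]) * dt,
        "roughness": np.array([
            float(np.std(shifted[p.start_index:p.end_index][
                shifted[p.start_index:p.end_index] > p.amplitude / 2.0]))
            if np.any(shifted[p.start_index:p.end_index] > p.amplitude / 2.0)
            else 0.0
            for p in peaks]),
        "interval": intervals,
    }
    out: dict[str, float] = {}
    for prop, values in props.items():
        mean, sd, mn, mx, skew = _moment_stats(values)
        out[f"cluster_{prop}_mean"] = mean
        out[f"cluster_{prop}_sd"] = sd
        out[f"cluster_{prop}_min"] = mn
        out[f"cluster_{prop}_max"] = mx
        out[f"cluster_{prop}_skew"] = skew

    n = len(peaks)
    n_sub = sum(p.subthreshold_flag for p in peaks)
    span_dur = (e - s) * dt
    amps = props["amplitude"]
    on_samples = int(np.count_nonzero(seg > amplitude_threshold))
    out.update({
        "cluster_n_peaks": float(n),
        "cluster_n_subthreshold": float(n_sub),
        "cluster_subthreshold_fraction": n_sub / n,
        "cluster_span_duration": span_dur,
        "cluster_peak_rate": n / span_dur if span_dur > 0 else 0.0,
        "cluster_envelope_max": cluster.envelope_max,
        "cluster_total_area": float(seg.sum()) * dt,
        "cluster_current_mean": float(seg.mean()) if seg.size else 0.0,
        "cluster_current_sd": float(np.std(seg, ddof=1)) if seg.size >= 2 else 0.0,
        "cluster_current_skew": _safe_skew(seg),
        "cluster_current_kurtosis": _safe_kurt(seg),
        "cluster_current_max": float(seg.max()) if seg.size else 0.0,
        "cluster_occupancy_threshold": on_samples / seg.size if seg.size else 0.0,
        "cluster_occupancy_half_threshold":
            float(np.count_nonzero(seg > amplitude_threshold / 2.0)) / seg.size
            if seg.size else 0.0,
        "cluster_on_time": on_samples * dt,
        "cluster_duty_cycle":
            sum((p.end_index - p.start_index) for p in peaks) * dt / span_dur
            if span_dur > 0 else 0.0,
        "cluster_first_peak_offset_frac":
            (apexes[0] - s) / (e - s) if e > s else 0.0,
        "cluster_last_peak_offset_frac":
            (apexes[-1] - s) / (e - s) if e > s else 0.0,
        "cluster_interval_cv":
            (float(np.std(intervals, ddof=1)) / float(np.mean(intervals)))
            if intervals.size >= 2 and np.mean(intervals) > 0 else 0.0,
        "cluster_amplitude_cv":
            (float(np.std(amps, ddof=1)) / float(np.mean(amps)))
            if amps.size >= 2 and np.mean(amps) > 0 else 0.0,
    })
    return out


# ---------------------------------------------------------------------------
# Assembly & normalization

def extract_features(trace: TraceRecord, clusters: list[Cluster],
                     shifted: np.ndarray,
                     config: PipelineConfig | None = None) -> pd.DataFrame:
    """Assemble the feature table for one trace: one row per spike, 264
    registry columns plus metadata, cluster-scope values replicated onto
    member rows."""
    config = config or PipelineConfig()
    dt = trace.sample_interval
    rows: list[dict] = []
    for cl in clusters:
        cfeat = cluster_time_features(cl, shifted, dt,
                                      config.amplitude_threshold)
        cseg = shifted[cl.start_index:cl.end_index]
        cluster_fft = spectral_features(cseg, "cluster", dt)
        whole_fft = spectral_features(cseg, "whole", dt)
        ceps = cepstrum_features(cseg)
        for i, v in enumerate(cluster_fft):
            cfeat[f"cluster_fft_{i:02d}"] = float(v)
        for i, v in enumerate(whole_fft):
            cfeat[f"whole_fft_{i:02d}"] = float(v)
        for i, v in enumerate(ceps):
            cfeat[f"cepstrum_{i:02d}"] = float(v)

        peaks = sorted(cl.peaks, key=lambda p: p.apex_index)
        apexes = [p.apex_index for p in peaks]
        for pid, p in enumerate(peaks):
            prev_iv = (apexes[pid] - apexes[pid - 1]) * dt if pid > 0 else 0.0
            next_iv = (apexes[pid + 1] - apexes[pid]) * dt \
                if pid + 1 < len(peaks) else 0.0
            row = dict(cfeat)
            row.update(peak_time_features(p, shifted, dt, cl.span,
                                          prev_iv, next_iv))
            pseg = shifted[p.start_index:p.end_index]
            for i, v in enumerate(spectral_features(pseg, "peak", dt)):
                row[f"peak_fft_{i:02d}"] = float(v)
            row.update({
                "junction_id": trace.junction_id,
                "run_id": trace.run_id,
                "cluster_id": cl.cluster_id,
                "peak_id": pid,
                "label": trace.label,
            })
            rows.append(row)

    table = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=FEATURE_META_COLUMNS + FEATURE_NAMES)
    return assemble_feature_table(table)


def assemble_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate completeness and fix the column order to the registry order."""
    missing = [n for n in FEATURE_NAMES if n not in table.columns]
    if missing:
        raise AssemblyError(f"missing registry features: {missing[:5]}"
                            f"{'...' if len(missing) > 5 else ''}")
    meta = [c for c in FEATURE_META_COLUMNS if c in table.columns]
    ordered = table[meta + FEATURE_NAMES]
    if len(ordered) and ordered[FEATURE_NAMES].isna().any().any():
        bad = ordered[FEATURE_NAMES].isna().any()
        raise AssemblyError(
            f"NaN feature values in columns: {list(bad[bad].index)[:5]}")
    return ordered


def normalize_features(table: pd.DataFrame,
                       reference: pd.DataFrame | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize feature columns to mean 0 / s.d. 1 over a reference set.

    Returns the transformed table and a (mean, sd) frame that can be applied
    to held-out rows with :func:`apply_normalization`.  Constant columns map
    to 0 with a logged warning.
    """
    reference = table if reference is None else reference
    if len(reference) == 0:
        raise ValueError("normalization reference must be non-empty")
    mean = reference[FEATURE_NAMES].mean()
    sd = reference[FEATURE_NAMES].std(ddof=1).fillna(0.0)
    n_const = int((sd == 0).sum())
    if n_const:
        log.warning("%d constant feature columns map to 0 after scaling",
                    n_const)
    stats = pd.DataFrame({"mean": mean, "sd": sd})
    return apply_normalization(table, stats), stats


def apply_normalization(table: pd.DataFrame, stats: pd.DataFrame
                        ) -> pd.DataFrame:
    """Apply stored (mean, sd) column statistics to a (possibly held-out)
    table; columns whose reference s.d. was 0 map to 0."""
    out = table.copy()
    sd = stats["sd"].replace(0.0, np.nan)
    out[FEATURE_NAMES] = ((table[FEATURE_NAMES] - stats["mean"]) / sd).fillna(0.0)
    return out


def concat_feature_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-trace feature tables with a stable schema."""
    tables = [t for t in tables if len(t)]
    if not tables:
        return pd.DataFrame(columns=FEATURE_META_COLUMNS + FEATURE_NAMES)
    return pd.concat(tables, ignore_index=True)
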