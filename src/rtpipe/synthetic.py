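"""Synthetic recognition-tunnelling trace generator.

Emulates the statistical structure of STM recognition-tunnelling data so the
whole analysis chain can be exercised without an instrument: spikes arrive in
Poisson-distributed capture clusters; within a cluster the current follows
two-state (telegraph) on/off switching with exponential dwells; spike
amplitudes are lognormal above a 4 pA baseline; class identity is encoded
jointly in amplitude, dwell kinetics and within-spike spectral shape; a
water/contamination class is mixed into analyte runs; a configurable fraction
of clusters carries a component injected into both the current and the
z-piezo channel (servo artifact); and capture rates follow a Langmuir
isotherm in concentration.

Every generated spike has a ground-truth record (class, cluster, junction,
contamination flag) so detection, filtering and classification can be scored
against the truth.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import ClassProfile, ConfigError, GeneratorConfig, TraceRecord

GROUND_TRUTH_COLUMNS = [
    "junction_id", "run_id", "cluster_index", "spike_index", "class_name",
    "contaminated", "apex_index", "start_index", "end_index", "amplitude_pA",
]

#: margin (in Gaussian-window sigmas) by which a detected cluster span
#: extends beyond its outermost spike apex: exp(-x^2/2sigma^2) = 0.1
_SPAN_SIGMAS = math.sqrt(2.0 * math.log(10.0))


def _empty_ground_truth() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        GROUND_TRUTH_COLUMNS,
        [str, str, int, int, str, bool, int, int, int, float])})


def _cluster_class_probabilities(config: GeneratorConfig,
                                 class_mixture: Mapping[str, float]
                                 ) -> tuple[list[ClassProfile], np.ndarray]:
    """Per-cluster class probabilities that realize the configured
    spike-level mixture: analyte classes share ``1 - water_fraction`` of
    spikes in proportion to mixture weight x capture_weight; the water class
    contributes ``water_fraction``.  Spike-level targets are converted to
    cluster-level probabilities by dividing by the class's mean cluster
    length."""
    if any(w < 0 for w in class_mixture.values()):
        raise ConfigError("mixture weights must be non-negative")
    weighted = {name: w * config.class_by_name(name).capture_weight
                for name, w in class_mixture.items() if w > 0}
    spike_fractions: dict[str, float] = {}
    if "water" in weighted:
        # an explicit water weight (e.g. a buffer-only control run) takes the
        # mixture at face value instead of applying water_fraction on top
        total = sum(weighted.values())
        spike_fractions = {name: w / total for name, w in weighted.items()}
    elif weighted:
        total = sum(weighted.values())
        for name, w in weighted.items():
            spike_fractions[name] = (1.0 - config.water_fraction) * w / total
        if config.water_fraction > 0:
            spike_fractions["water"] = config.water_fraction
    else:
        if config.water_fraction == 0:
            return [], np.array([])
        spike_fractions["water"] = 1.0
    profiles = [config.class_by_name(name) for name in spike_fractions]
    probs = np.array([spike_fractions[p.name] / p.cluster_len_mean
                      for p in profiles])
    probs /= probs.sum()
    return profiles, probs


def _one_pole_lowpass(x: np.ndarray, corner_hz: float, dt: float) -> np.ndarray:
    """First-order low-pass smoothing the telegraph edges."""
    from scipy.signal import lfilter

    a = math.exp(-2.0 * math.pi * corner_hz * dt)
    return lfilter([1.0 - a], [1.0, -a], x)


def generate_trace(config: GeneratorConfig,
                   junction_id: str = "j0",
                   class_mixture: Optional[Mapping[str, float]] = None,
                   seed: int = 0,
                   *,
                   run_id: str = "r0",
                   label: Optional[str] = None,
                   concentration: Optional[float] = None,
                   junction_effect: Optional[float] = None,
                   ) -> tuple[TraceRecord, pd.DataFrame]:
    """Generate one two-channel trace and its ground-truth spike table.

    ``class_mixture`` gives relative weights over analyte classes; the water
    class is mixed in at ``config.water_fraction`` on top of it.  If
    ``concentration`` is given, the cluster arrival rate follows the Langmuir
    law ``lambda_max * (c/kd)/(1 + c/kd)``; otherwise the saturated rate
    ``lambda_max`` is used.  ``junction_effect`` is a multiplicative
    amplitude/rate factor; when None one lognormal realization is drawn.
    Identical (config, arguments, seed) reproduce the trace bit-for-bit.
    """
    if not config.classes:
        raise ConfigError("config has no classes")
    if class_mixture is None:
        analyte_names = [c.name for c in config.classes if c.name != "water"]
        class_mixture = {name: 1.0 for name in analyte_names}

    rng = np.random.default_rng(seed)
    dt = config.sample_interval
    n = int(round(config.duration / dt))
    current = rng.normal(0.0, config.noise_sd, size=n)
    # z channel: slow actuator drift + white readout noise
    t = np.arange(n) * dt
    zpiezo = rng.normal(0.0, 1.0, size=n)
    for _ in range(3):
        freq = rng.uniform(0.2, 1.0)
        zpiezo += rng.uniform(0.5, 2.0) * np.sin(
            2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))

    if junction_effect is None:
        junction_effect = float(rng.lognormal(0.0, config.junction_effect_sd)) \
            if config.junction_effect_sd > 0 else 1.0

    rate = config.lambda_max
    if concentration is not None:
        x = concentration / config.kd_true
        rate = config.lambda_max * x / (1.0 + x)
    rate *= junction_effect

    profiles, probs = _cluster_class_probabilities(config, class_mixture)
    n_clusters = rng.poisson(rate * config.duration) if profiles else 0
    cluster_starts = np.sort(rng.uniform(0, n, size=n_clusters)).astype(int)

    records: list[tuple] = []
    for ci, start in enumerate(cluster_starts):
        profile = profiles[rng.choice(len(profiles), p=probs)]
        contaminated = bool(rng.random() < config.zpiezo_contam_fraction)
        n_spikes = 1 + rng.poisson(max(profile.cluster_len_mean - 1.0, 0.0))

        # build the telegraph waveform for this cluster on a local buffer
        on_samp = np.maximum(
            rng.exponential(profile.on_dwell_mean / dt, size=n_spikes), 2.0
        ).astype(int)
        off_samp = np.maximum(
            rng.exponential(profile.off_dwell_mean / dt, size=n_spikes), 1.0
        ).astype(int)
        amps = rng.lognormal(profile.amp_log_mean, profile.amp_log_sd,
                             size=n_spikes) * junction_effect
        length = int(on_samp.sum() + off_samp.sum()) + 8
        local = np.zeros(length)
        spike_bounds = []
        pos = 4
        for k in range(n_spikes):
            s, e = pos, pos + on_samp[k]
            seg = np.full(on_samp[k], amps[k])
            # within-spike fluctuation, low-pass shaped at the class corner
            seg += _one_pole_lowpass(
                rng.normal(0.0, 0.08 * amps[k], size=on_samp[k]),
                profile.spectral_corner, dt)
            local[s:e] = seg
            spike_bounds.append((s, e))
            pos = e + off_samp[k]
        local = _one_pole_lowpass(local, profile.spectral_corner, dt)

        end = min(start + length, n)
        if end <= start:
            continue
        current[start:end] += local[: end - start]

        first_apex = last_apex = None
        for k, (s, e) in enumerate(spike_bounds):
            gs, ge = start + s, min(start + e, n)
            if ge <= gs:
                continue
            apex_local = int(np.argmax(local[s: s + (ge - gs)]))
            apex = gs + apex_local
            realized_amp = float(local[s + apex_local])
            records.append((junction_id, run_id, ci, k, profile.name,
                            contaminated, apex, gs, ge, realized_amp))
            first_apex = apex if first_apex is None else first_apex
            last_apex = apex

        if contaminated and first_apex is not None:
            # servo artifact: within this cluster the z actuator tracks the
            # low-passed current excursion, so current and z-piezo become
            # strongly correlated over the cluster span while the current
            # channel itself is untouched
            response = _one_pole_lowpass(local[: end - start], 800.0, dt)
            sd = float(np.std(response))
            if sd > 0:
                zpiezo[start:end] += 3.0 * response / sd

    current += config.baseline_current
    trace = TraceRecord(current, zpiezo, sample_interval=dt,
                        junction_id=junction_id, run_id=run_id, label=label,
                        concentration=concentration,
                        setpoint=config.baseline_current)
    truth = pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS) \
        if records else _empty_ground_truth()
    return trace, truth


def junction_effects(config: GeneratorConfig, seed: int = 0) -> np.ndarray:
    """One multiplicative lognormal amplitude/rate effect per junction."""
    rng = np.random.default_rng(seed)
    if config.junction_effect_sd > 0:
        return rng.lognormal(0.0, config.junction_effect_sd,
                             size=config.n_junctions)
    return np.ones(config.n_junctions)


def generate_junction_dataset(config: GeneratorConfig,
                              labels: Sequence[str],
                              seed: int = 0,
                              runs_per_label: int = 1,
                              effects: np.ndarray | None = None,
                              ) -> list[tuple[TraceRecord, pd.DataFrame]]:
    """Generate ``n_junctions x labels x runs_per_label`` labelled traces.

    Each junction draws a single lognormal effect applied to every run it
    hosts, emulating junction-to-junction variability of freshly prepared
    probe/substrate pairs.  Passing ``effects`` explicitly lets separate
    datasets (e.g. calibration standards and analyte runs) share the same
    physical junctions.  A run labelled ``water`` is a buffer-only control
    (all clusters from the water class).
    """
    if config.n_junctions < 2:
        raise ConfigError("n_junctions must be >= 2")
    known = {c.name for c in config.classes}
    unknown = set(labels) - known
    if unknown:
        raise ConfigError(f"labels not in config.classes: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    if effects is None:
        effects = junction_effects(config, seed)
        rng = np.random.default_rng(seed + 1)  # keep run seeds independent
    if len(effects) != config.n_junctions:
        raise ConfigError("effects length must equal n_junctions")
    out = []
    for j in range(config.n_junctions):
        for label in labels:
            for r in range(runs_per_label):
                run_seed = int(rng.integers(0, 2**31 - 1))
                mixture: Mapping[str, float] = {label: 1.0}
                trace, truth = generate_trace(
                    config, junction_id=f"j{j}", class_mixture=mixture,
                    seed=run_seed, run_id=f"j{j}_{label}_r{r}", label=label,
                    junction_effect=float(effects[j]))
                out.append((trace, truth))
    return out


def langmuir_rate(concentration: np.ndarray | float, lambda_max: float,
                  kd: float) -> np.ndarray | float:
    """Expected cluster arrival rate lambda(c) = lambda_max * (c/kd)/(1+c/kd)."""
    x = np.asarray(concentration, dtype=float) / kd
    return lambda_max * x / (1.0 + x)


def generate_concentration_series(config: GeneratorConfig,
                                  concentrations: Sequence[float],
                                  seed: int = 0,
                                  duration: Optional[float] = None,
                                  mode: str = "counts",
                                  ) -> pd.DataFrame | list[tuple[TraceRecord, pd.DataFrame]]:
    """Simulate a titration: capture rates follow the Langmuir isotherm.

    ``mode='counts'`` (fast, the default) returns a table of Poisson event
    counts per concentration; ``mode='traces'`` generates full traces.
    """
    concentrations = list(concentrations)
    if len(concentrations) < 2:
        raise ConfigError("need at least 2 concentrations")
    if any(c <= 0 for c in concentrations):
        raise ConfigError("concentrations must be positive")
    duration = config.duration if duration is None else duration
    rng = np.random.default_rng(seed)

    if mode == "traces":
        out = []
        for c in concentrations:
            run_seed = int(rng.integers(0, 2**31 - 1))
            out.append(generate_trace(config, seed=run_seed,
                                      run_id=f"c{c:g}", concentration=c))
        return out
    if mode != "counts":
        raise ConfigError(f"unknown mode {mode!r}")

    rates = np.asarray(langmuir_rate(np.array(concentrations),
                                     config.lambda_max, config.kd_true))
    counts = rng.poisson(rates * duration)
    return pd.DataFrame({
        "concentration_M": concentrations,
        "duration_s": duration,
        "expected_rate_hz": rates,
        "count": counts,
    })
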