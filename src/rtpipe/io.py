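"""File formats, domain containers and configuration for the RT pipeline.

Traces are stored as self-describing text files: ``# key=value`` header
lines followed by a two-column numeric body (current in pA, z-piezo
displacement).  Large traces can alternatively be stored in an HDF5
container with the same schema.  Event and feature tables are
tab-delimited text with a header row.  All indices are 0-based and all
intervals half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("rtpipe")

# ---------------------------------------------------------------------------
# Errors

class FormatError(ValueError):
    """A file violates the trace/table format contract."""


class SchemaError(ValueError):
    """A table carries columns not in the feature registry / schema."""


class ConfigError(ValueError):
    """A configuration value is missing or out of range."""


# ---------------------------------------------------------------------------
# Trace container

@dataclass
class TraceRecord:
    """A two-channel sampled time series from one tunnel-junction run.

    ``samples_current`` is the tunnel current in pA; ``samples_zpiezo`` is
    the servo (vertical actuator) displacement in arbitrary units.  The
    default acquisition metadata mirror a typical STM recognition-tunnelling
    run: 20 μs per point, 0.5 V bias, 4 pA current set point.
    """

    samples_current: np.ndarray
    samples_zpiezo: np.ndarray
    sample_interval: float = 20e-6
    junction_id: str = "j0"
    run_id: str = "r0"
    label: Optional[str] = None
    concentration: Optional[float] = None
    bias: float = 0.5
    setpoint: float = 4.0

    def __post_init__(self) -> None:
        self.samples_current = np.asarray(self.samples_current, dtype=float)
        self.samples_zpiezo = np.asarray(self.samples_zpiezo, dtype=float)
        if self.samples_current.shape != self.samples_zpiezo.shape:
            raise FormatError(
                f"channel length mismatch: current has "
                f"{self.samples_current.size} samples, z-piezo has "
                f"{self.samples_zpiezo.size}"
            )
        if not self.sample_interval > 0:
            raise FormatError("sample_interval must be positive")
        if self.samples_current.size and not np.all(np.isfinite(self.samples_current)):
            raise FormatError("current channel contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return int(self.samples_current.size)

    @property
    def duration(self) -> float:
        return self.n_samples * self.sample_interval


_TRACE_META_FIELDS = (
    "sample_interval", "junction_id", "run_id", "label",
    "concentration", "bias", "setpoint",
)
_TRACE_FLOAT_META = {"sample_interval", "concentration", "bias", "setpoint"}


def write_trace(path: str | Path, trace: TraceRecord) -> None:
    """Write a trace as header + two-column text (or HDF5 if path ends .h5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_trace_h5(path, trace)
        return
    with open(path, "w") as fh:
        for key in _TRACE_META_FIELDS:
            value = getattr(trace, key)
            if value is None:
                continue
            fh.write(f"# {key}={value!r}\n" if isinstance(value, str)
                     else f"# {key}={value}\n")
        fh.write("# columns=current_pA,zpiezo\n")
        np.savetxt(fh, np.column_stack([trace.samples_current,
                                        trace.samples_zpiezo]),
                   fmt="%.9g", delimiter="\t")


def read_trace(path: str | Path) -> TraceRecord:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_trace_h5(path)
    meta: dict = {}
    current: list[float] = []
    zpiezo: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    continue
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            current.append(float(parts[0]))
            zpiezo.append(float(parts[1]))
    if "sample_interval" not in meta:
        raise FormatError(f"{path}: missing required header key 'sample_interval'")
    kwargs: dict = {}
    for key in _TRACE_META_FIELDS:
        if key not in meta:
            continue
        value = meta[key]
        if key in _TRACE_FLOAT_META:
            kwargs[key] = float(value)
        else:
            kwargs[key] = value.strip("'\"")
    return TraceRecord(np.array(current), np.array(zpiezo), **kwargs)


def _write_trace_h5(path: Path, trace: TraceRecord) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("current_pA", data=trace.samples_current)
        fh.create_dataset("zpiezo", data=trace.samples_zpiezo)
        for key in _TRACE_META_FIELDS:
            value = getattr(trace, key)
            if value is not None:
                fh.attrs[key] = value


def _read_trace_h5(path: Path) -> TraceRecord:
    import h5py

    with h5py.File(path, "r") as fh:
        if "sample_interval" not in fh.attrs:
            raise FormatError(f"{path}: missing required attribute 'sample_interval'")
        kwargs = {k: fh.attrs[k] for k in _TRACE_META_FIELDS if k in fh.attrs}
        for key in list(kwargs):
            if key in _TRACE_FLOAT_META:
                kwargs[key] = float(kwargs[key])
            else:
                kwargs[key] = str(kwargs[key])
        return TraceRecord(fh["current_pA"][:], fh["zpiezo"][:], **kwargs)


# ---------------------------------------------------------------------------
# Event / feature tables

EVENT_COLUMNS = [
    "junction_id", "run_id", "cluster_id", "peak_id",
    "start_index", "apex_index", "end_index", "amplitude_pA",
    "subthreshold_flag", "rejected_flag", "rejection_reason",
]

#: metadata columns a feature table carries alongside registry features
FEATURE_META_COLUMNS = ["junction_id", "run_id", "cluster_id", "peak_id", "label"]


def empty_event_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        EVENT_COLUMNS,
        [str, str, int, int, int, int, int, float, bool, bool, str])})


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write an event or feature table as tab-delimited text."""
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | Path, kind: str = "event") -> pd.DataFrame:
    """Read a table, validating its schema.

    ``kind='event'`` checks the event-table columns; ``kind='feature'``
    checks every non-metadata column against the 264-feature registry.
    """
    table = pd.read_csv(path, sep="\t")
    if kind == "event":
        missing = [c for c in EVENT_COLUMNS if c not in table.columns]
        if missing:
            raise SchemaError(f"event table missing columns: {missing}")
        if len(table) == 0:
            table = table.astype({
                "start_index": int, "apex_index": int, "end_index": int,
                "amplitude_pA": float})
    elif kind == "feature":
        from .features import FEATURE_REGISTRY
        known = {d.name for d in FEATURE_REGISTRY} | set(FEATURE_META_COLUMNS)
        unknown = [c for c in table.columns if c not in known]
        if unknown:
            raise SchemaError(f"unknown feature columns: {unknown}")
    else:
        raise ValueError(f"unknown table kind {kind!r}")
    return table


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class ClassProfile:
    """Statistical profile of one analyte (or control) class.

    Spike amplitudes above baseline are lognormal with log-space parameters
    ``amp_log_mean``/``amp_log_sd`` (pA); on/off dwell times of the telegraph
    process are exponential with the given means (seconds); within-spike
    fluctuations are low-pass shaped at ``spectral_corner`` (Hz);
    ``cluster_len_mean`` is the mean number of spikes per capture cluster and
    ``capture_weight`` a relative capture-frequency multiplier.
    """

    name: str
    amp_log_mean: float
    amp_log_sd: float
    on_dwell_mean: float
    off_dwell_mean: float
    spectral_corner: float
    cluster_len_mean: float = 5.0
    capture_weight: float = 1.0

    def __post_init__(self) -> None:
        for fld in ("amp_log_sd", "on_dwell_mean", "off_dwell_mean",
                    "spectral_corner", "cluster_len_mean", "capture_weight"):
            if not getattr(self, fld) > 0:
                raise ConfigError(f"class {self.name!r}: {fld} must be positive")


def default_classes() -> list[ClassProfile]:
    """Default class profiles for two sugar anomers plus the water/control
    class.  Classes overlap in any single property but differ jointly in
    amplitude, dwell kinetics and spectral shape, while the control class is
    well separated so the common-class filter has a learnable target."""
    return [
        ClassProfile("alphaMGlu", amp_log_mean=np.log(48.0), amp_log_sd=0.35,
                     on_dwell_mean=1.0e-3, off_dwell_mean=1.5e-3,
                     spectral_corner=3000.0, cluster_len_mean=5.0,
                     capture_weight=1.8),
        ClassProfile("betaMGlu", amp_log_mean=np.log(40.0), amp_log_sd=0.35,
                     on_dwell_mean=1.6e-3, off_dwell_mean=2.2e-3,
                     spectral_corner=2000.0, cluster_len_mean=5.0,
                     capture_weight=1.0),
        ClassProfile("water", amp_log_mean=np.log(34.0), amp_log_sd=0.22,
                     on_dwell_mean=0.4e-3, off_dwell_mean=0.6e-3,
                     spectral_corner=8000.0, cluster_len_mean=5.0,
                     capture_weight=1.0),
    ]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic trace generator.

    Defaults mirror the acquisition conditions the analysis assumes:
    20 μs sampling, 4 pA baseline shifted to zero before detection, a
    Gaussian noise floor of 1 pA so the 15 pA threshold sits far above
    electronic noise, half of all spikes from a chemically-insensitive
    water/contamination class, and ~10% of clusters carrying
    servo-correlated distortion.
    """

    sample_interval: float = 20e-6
    baseline_current: float = 4.0
    noise_sd: float = 1.0
    classes: list[ClassProfile] = field(default_factory=default_classes)
    n_junctions: int = 4
    junction_effect_sd: float = 0.2
    water_fraction: float = 0.5
    zpiezo_contam_fraction: float = 0.1
    lambda_max: float = 0.5
    kd_true: float = 0.74e-6
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.water_fraction < 1:
            raise ConfigError("water_fraction must be in [0, 1)")
        if not 0 <= self.zpiezo_contam_fraction < 1:
            raise ConfigError("zpiezo_contam_fraction must be in [0, 1)")
        if not self.sample_interval > 0:
            raise ConfigError("sample_interval must be positive")
        if not self.duration > 0:
            raise ConfigError("duration must be positive")
        names = [c.name for c in self.classes]
        if len(names) != len(set(names)):
            raise ConfigError("class names must be unique")

    def class_by_name(self, name: str) -> ClassProfile:
        for profile in self.classes:
            if profile.name == name:
                return profile
        raise ConfigError(f"no class named {name!r} in config")


@dataclass
class PipelineConfig:
    """Analysis-stage thresholds; defaults are the documented method values."""

    baseline: float = 4.0                 # pA shifted to zero
    amplitude_threshold: float = 15.0     # pA above baseline, strict >
    subthreshold_floor: float = 5.0       # pA floor for in-cluster harvest
    cluster_window: int = 4096            # Gaussian window full width, samples
    cluster_sum_threshold: float = 0.1    # envelope sum, strict >
    correlation_prune: float = 0.7        # |r| pruning, strict >
    zpiezo_threshold: float = 0.1         # |r| with servo channel, strict >
    posterior_threshold: float = 0.7      # water-class posterior cutoff
    train_fraction: float = 0.10          # optimistic-protocol training share
    histogram_bins: int = 50              # fluctuation-ranking histograms
    subset_tolerance: float = 0.5         # pp slack when picking subset size

    def __post_init__(self) -> None:
        positive = ("amplitude_threshold", "cluster_window",
                    "cluster_sum_threshold", "histogram_bins")
        for fld in positive:
            if not getattr(self, fld) > 0:
                raise ConfigError(f"{fld} must be positive")
        for fld in ("correlation_prune", "zpiezo_threshold",
                    "posterior_threshold"):
            if not 0 <= getattr(self, fld) <= 1:
                raise ConfigError(f"{fld} must be in [0, 1]")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must be in (0, 1)")


def load_config(path: str | Path | None = None,
                overrides: dict | None = None
                ) -> tuple[GeneratorConfig, PipelineConfig]:
    """Load generator + pipeline configuration from a YAML file.

    The file has two optional sections, ``generator`` and ``pipeline``;
    every threshold has a documented default, so an empty file (or no file)
    yields the standard parameter set.  Overrides are logged.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        for section, values in overrides.items():
            data.setdefault(section, {}).update(values)

    gen_kwargs = dict(data.get("generator") or {})
    if "classes" in gen_kwargs:
        gen_kwargs["classes"] = [ClassProfile(**c) for c in gen_kwargs["classes"]]
    pipe_kwargs = dict(data.get("pipeline") or {})

    known_gen = {f.name for f in dataclasses.fields(GeneratorConfig)}
    known_pipe = {f.name for f in dataclasses.fields(PipelineConfig)}
    for kwargs, known, section in ((gen_kwargs, known_gen, "generator"),
                                   (pipe_kwargs, known_pipe, "pipeline")):
        unknown = set(kwargs) - known
        if unknown:
            raise ConfigError(f"unknown {section} keys: {sorted(unknown)}")

    generator = GeneratorConfig(**gen_kwargs)
    pipeline = PipelineConfig(**pipe_kwargs)
    for key, value in {**gen_kwargs, **pipe_kwargs}.items():
        log.info("config override: %s=%r", key, value)
    log.debug("loaded generator config: %s", generator)
    log.debug("loaded pipeline config: %s", pipeline)
    return generator, pipeline
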