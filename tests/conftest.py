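"""Shared fixtures: one small synthetic dataset reused across test modules.

Session scope keeps total generation cost low; individual tests must not
mutate fixture objects in place (copy first).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rtpipe import (GeneratorConfig, PipelineConfig, concat_feature_tables,
                    detect_events, extract_features, filter_zpiezo,
                    generate_junction_dataset, generate_trace)


@pytest.fixture(scope="session")
def gen_cfg() -> GeneratorConfig:
    return GeneratorConfig(duration=10.0, n_junctions=2)


@pytest.fixture(scope="session")
def pipe_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_trace(gen_cfg):
    """One analyte trace plus its ground truth."""
    trace, truth = generate_trace(gen_cfg, "j0", {"alphaMGlu": 1.0},
                                  seed=11, label="alphaMGlu")
    return trace, truth


@pytest.fixture(scope="session")
def anomer_dataset(gen_cfg):
    """Two junctions x two labels x two runs of short traces."""
    return generate_junction_dataset(gen_cfg, ["alphaMGlu", "betaMGlu"],
                                     seed=2, runs_per_label=2)


@pytest.fixture(scope="session")
def feature_table(anomer_dataset, pipe_cfg) -> pd.DataFrame:
    """Assembled 264-feature table over the whole small dataset."""
    tables = []
    for trace, _ in anomer_dataset:
        clusters, shifted = detect_events(trace, pipe_cfg)
        clusters, _ = filter_zpiezo(clusters, trace,
                                    pipe_cfg.zpiezo_threshold)
        tables.append(extract_features(trace, clusters, shifted, pipe_cfg))
    table = concat_feature_tables(tables)
    assert len(table) > 50, "fixture dataset unexpectedly sparse"
    return table


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
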