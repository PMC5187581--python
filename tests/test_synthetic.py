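"""Generator contracts: determinism, ground truth, mixing, rate law."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy import stats as sstats

from rtpipe import (GeneratorConfig, generate_concentration_series,
                    generate_junction_dataset, generate_trace)
from rtpipe.synthetic import (GROUND_TRUTH_COLUMNS, junction_effects,
                              langmuir_rate)


def test_determinism_same_seed(gen_cfg):
    a, ta = generate_trace(gen_cfg, "j0", {"alphaMGlu": 1.0}, seed=5)
    b, tb = generate_trace(gen_cfg, "j0", {"alphaMGlu": 1.0}, seed=5)
    np.testing.assert_array_equal(a.samples_current, b.samples_current)
    np.testing.assert_array_equal(a.samples_zpiezo, b.samples_zpiezo)
    assert ta.equals(tb)


def test_different_seeds_differ(gen_cfg):
    a, _ = generate_trace(gen_cfg, "j0", {"alphaMGlu": 1.0}, seed=5)
    b, _ = generate_trace(gen_cfg, "j0", {"alphaMGlu": 1.0}, seed=6)
    assert not np.array_equal(a.samples_current, b.samples_current)


def test_trace_shape_and_baseline(small_trace, gen_cfg):
    trace, _ = small_trace
    n = round(gen_cfg.duration / gen_cfg.sample_interval)
    assert len(trace.samples_current) == n
    assert len(trace.samples_zpiezo) == n
    # the quiet-region median sits at the 4 pA baseline
    assert np.median(trace.samples_current) == pytest.approx(
        gen_cfg.baseline_current, abs=0.5)


def test_ground_truth_schema_and_consistency(small_trace):
    trace, truth = small_trace
    assert list(truth.columns) == GROUND_TRUTH_COLUMNS
    assert len(truth) > 0
    assert (truth["start_index"] <= truth["apex_index"]).all()
    assert (truth["apex_index"] < truth["end_index"]).all()
    assert (truth["end_index"] <= len(trace.samples_current)).all()
    assert (truth["amplitude_pA"] > 0).all()
    # the planted apex really carries the planted amplitude above baseline
    shifted = trace.samples_current - 4.0
    apex_vals = shifted[truth["apex_index"].to_numpy()]
    assert np.median(apex_vals / truth["amplitude_pA"]) == pytest.approx(
        1.0, abs=0.35)


def test_water_fraction_binomial():
    """Fraction of water clusters matches water_fraction statistically."""
    cfg = GeneratorConfig(duration=40.0, water_fraction=0.5,
                          zpiezo_contam_fraction=0.0)
    _, truth = generate_trace(cfg, "j0", {"alphaMGlu": 1.0}, seed=9)
    clusters = truth.drop_duplicates("cluster_index")
    n = len(clusters)
    k = int((clusters["class_name"] == "water").sum())
    assert n >= 10
    # exact binomial two-sided test at alpha=1e-3: must not reject p=0.5
    p = sstats.binomtest(k, n, 0.5).pvalue
    assert p > 1e-3, f"water fraction {k}/{n} inconsistent with 0.5"


def test_explicit_water_mixture_is_pure_control():
    cfg = GeneratorConfig(duration=30.0)
    _, truth = generate_trace(cfg, "j0", {"water": 1.0}, seed=3)
    assert len(truth) > 0
    assert (truth["class_name"] == "water").all()


def test_contaminated_fraction_and_z_channel():
    cfg = GeneratorConfig(duration=60.0, zpiezo_contam_fraction=0.5)
    trace, truth = generate_trace(cfg, "j0", {"alphaMGlu": 1.0}, seed=21)
    clusters = truth.drop_duplicates("cluster_index")
    frac = clusters["contaminated"].mean()
    p = sstats.binomtest(int(clusters["contaminated"].sum()),
                         len(clusters), 0.5).pvalue
    assert p > 1e-3, f"contaminated fraction {frac:.2f} inconsistent with 0.5"
    # contaminated cluster spans show current/z correlation; clean ones not
    z = trace.samples_zpiezo
    x = trace.samples_current
    spans = truth.groupby("cluster_index").agg(
        s=("start_index", "min"), e=("end_index", "max"),
        contaminated=("contaminated", "first"))
    r_contam, r_clean = [], []
    for _, row in spans.iterrows():
        s, e = int(row["s"]), int(row["e"])
        r = abs(np.corrcoef(x[s:e], z[s:e])[0, 1])
        (r_contam if row["contaminated"] else r_clean).append(r)
    assert np.median(r_contam) > 0.3
    assert np.median(r_clean) < 0.1


def test_junction_dataset_layout(anomer_dataset, gen_cfg):
    assert len(anomer_dataset) == gen_cfg.n_junctions * 2 * 2
    labels = {t.label for t, _ in anomer_dataset}
    assert labels == {"alphaMGlu", "betaMGlu"}
    junctions = {t.junction_id for t, _ in anomer_dataset}
    assert len(junctions) == gen_cfg.n_junctions
    run_ids = [t.run_id for t, _ in anomer_dataset]
    assert len(set(run_ids)) == len(run_ids)


def test_shared_effects_reproduce_amplitude_scaling():
    cfg = GeneratorConfig(duration=10.0, n_junctions=2,
                          junction_effect_sd=0.5)
    eff = junction_effects(cfg, seed=4)
    assert eff.shape == (2,)
    data = generate_junction_dataset(cfg, ["alphaMGlu"], seed=4, effects=eff)
    data2 = generate_junction_dataset(cfg, ["alphaMGlu"], seed=4,
                                      effects=eff)
    np.testing.assert_array_equal(data[0][0].samples_current,
                                  data2[0][0].samples_current)


def test_langmuir_rate_saturation():
    kd = 0.74e-6
    assert langmuir_rate(kd, 2.0, kd) == pytest.approx(1.0)
    assert langmuir_rate(1e3 * kd, 2.0, kd) == pytest.approx(2.0, rel=1e-2)
    assert langmuir_rate(0.0, 2.0, kd) == 0.0


def test_concentration_series_counts_follow_rate_law():
    cfg = GeneratorConfig(duration=60.0, water_fraction=0.0)
    concs = np.array([0.01, 0.1, 1.0, 10.0, 100.0]) * 1e-6
    frames = [generate_concentration_series(cfg, concs, seed=s,
                                            duration=600.0)
              for s in range(8)]
    counts = np.mean([f["count"].to_numpy() for f in frames], axis=0)
    expected = langmuir_rate(concs, cfg.lambda_max, cfg.kd_true) * 600.0
    # Poisson means over 8 replicates: allow 5 sigma of the averaged count
    sigma = np.sqrt(np.maximum(expected, 1.0) / 8)
    assert np.all(np.abs(counts - expected) < 5 * sigma + 1.0)


def test_concentration_series_rejects_bad_inputs(gen_cfg):
    with pytest.raises(Exception):
        generate_concentration_series(gen_cfg, [1e-6], seed=0)
    with pytest.raises(Exception):
        generate_concentration_series(gen_cfg, [0.0, 1e-6], seed=0)
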