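"""Correlation pruning, fluctuation ranking, subset choice contracts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rtpipe.selection import (SelectionReport, fluctuation_ranking,
                              prune_correlated, run_selection, select_subset)


def _toy_table(rng, n=200):
    a = rng.normal(size=n)
    return pd.DataFrame({
        "f_a": a,
        "f_b": a * 2.0 + 1.0,              # r = 1 with f_a
        "f_c": rng.normal(size=n),          # independent
        "f_d": -a + rng.normal(0, 0.01, n),  # r ~ -1 with f_a
    })


def test_prune_collapses_correlated_group(rng):
    table = _toy_table(rng)
    names = ["f_a", "f_b", "f_c", "f_d"]
    report = SelectionReport()
    kept = prune_correlated(table, 0.7, feature_names=names, report=report)
    # {f_a, f_b, f_d} is one component; one representative survives
    assert "f_c" in kept
    assert len(kept) == 2
    rep = [k for k in kept if k != "f_c"][0]
    assert set(report.dropped_correlated.values()) == {rep}
    assert set(report.dropped_correlated) == {"f_a", "f_b", "f_d"} - {rep}


def test_prune_idempotent(rng):
    table = _toy_table(rng)
    names = ["f_a", "f_b", "f_c", "f_d"]
    kept1 = prune_correlated(table, 0.7, feature_names=names)
    kept2 = prune_correlated(table, 0.7, feature_names=kept1)
    assert kept1 == kept2


def test_prune_threshold_strict(rng):
    n = 5000
    a = rng.normal(size=n)
    # build b with |r| very close to, but below, 0.7
    b = 0.7 * a + np.sqrt(1 - 0.49) * rng.normal(size=n)
    r = np.corrcoef(a, b)[0, 1]
    table = pd.DataFrame({"x": a, "y": b})
    kept = prune_correlated(table, max(abs(r) + 1e-6, 0.7),
                            feature_names=["x", "y"])
    assert kept == ["x", "y"]


def test_prune_constant_column_survives(rng):
    table = pd.DataFrame({"x": rng.normal(size=50), "k": np.ones(50)})
    kept = prune_correlated(table, 0.7, feature_names=["x", "k"])
    assert kept == ["x", "k"]


def test_fluctuation_ranking_hand_computed_toy():
    """4-bin toy where the L1 distances can be written down by hand.

    Feature 'good': label A values all in bin 0, label B all in bin 3, and
    the two runs of each label identical -> in-group L1 = 0 per run... but
    in-group 0 gives inf score; we offset one run slightly to keep it
    finite and check out-group = 2 exactly (disjoint histograms).
    """
    # 8 values per label, 2 runs x 4 values; range [0, 4) split into 4 bins
    vals_good = np.array([0.1, 0.2, 0.3, 0.4, 0.1, 0.2, 0.3, 0.4,   # A
                          3.1, 3.2, 3.3, 3.4, 3.1, 3.2, 3.3, 3.4])  # B
    # 'bad': identical distribution for both labels
    vals_bad = np.tile([0.5, 1.5, 2.5, 3.5], 4)
    labels = ["A"] * 8 + ["B"] * 8
    runs = (["r1"] * 4 + ["r2"] * 4) * 2
    table = pd.DataFrame({"good": vals_good, "bad": vals_bad})
    scores = fluctuation_ranking(table, labels, runs,
                                 feature_names=["good", "bad"], n_bins=4)
    s = scores.set_index("feature")
    # good: each run's histogram equals its label's accumulated histogram
    assert s.loc["good", "in_group"] == pytest.approx(0.0)
    # disjoint label histograms: L1 distance = 2 (maximum)
    assert s.loc["good", "out_group"] == pytest.approx(2.0)
    assert np.isinf(s.loc["good", "score"])
    # bad: labels indistinguishable -> out-group 0
    assert s.loc["bad", "out_group"] == pytest.approx(0.0)
    assert scores.iloc[0]["feature"] == "good"


def test_fluctuation_ranking_label_permutation_kills_signal(rng):
    """Permuting labels destroys out-group separation for a strong feature."""
    n = 400
    labels = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    runs = np.tile(["r1", "r2"], n // 2)
    x = np.where(labels == "A", 0.0, 5.0) + rng.normal(0, 0.5, n)
    table = pd.DataFrame({"x": x})
    true_score = fluctuation_ranking(table, labels, runs,
                                     feature_names=["x"]).loc[0, "score"]
    perm = rng.permutation(labels)
    perm_score = fluctuation_ranking(table, perm, runs,
                                     feature_names=["x"]).loc[0, "score"]
    assert true_score > 5 * perm_score


def test_fluctuation_ranking_requires_two_runs_per_label():
    table = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(ValueError):
        fluctuation_ranking(table, ["A", "A", "B", "B"],
                            ["r1", "r1", "r2", "r2"], feature_names=["x"])


def test_select_subset_smallest_within_tolerance():
    accs = {1: 80.0, 2: 90.0, 4: 90.4, 8: 90.5}
    chosen = select_subset(["a", "b", "c", "d", "e", "f", "g", "h"],
                           lambda s: accs[len(s)], k_grid=[1, 2, 4, 8],
                           tolerance=0.5)
    assert chosen == ["a", "b"]  # 90.0 >= 90.5 - 0.5


def test_select_subset_empty_rejected():
    with pytest.raises(ValueError):
        select_subset([], lambda s: 0.0)


def test_run_selection_on_fixture(feature_table):
    from rtpipe.features import normalize_features
    norm, _ = normalize_features(feature_table)
    report = run_selection(norm, top_k=8)
    assert 0 < len(report.kept) < 264
    assert len(report.chosen_subset) == 8
    assert report.scores is not None
    # ranking is sorted by score descending
    sc = report.scores["score"].to_numpy()
    assert np.all(np.diff(sc[np.isfinite(sc)]) <= 1e-12)
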