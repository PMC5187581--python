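"""Feature selection: correlation pruning, fluctuation ranking, subset choice.

Starting from the 264-feature table, (1) features whose absolute Pearson
correlation exceeds 0.7 are replaced by one representative per correlated
group; (2) survivors are scored by comparing, per feature, the run-to-run
histogram variability within an analyte (in-group fluctuation) against the
histogram difference between analytes (out-group fluctuation), and ranked by
the out/in ratio so chemically discriminating, run-stable features come
first; (3) nested top-k subsets along the ranking are evaluated by a
caller-supplied accuracy callback and the smallest subset within a tolerance
of the best accuracy is chosen.

Histogram distance is the L1 norm between normalized histograms on shared
equal-width bins over the pooled feature range (maximum distance 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

log = logging.getLogger("rtpipe")


@dataclass
class SelectionReport:
    """Book-keeping of what happened to every starting feature."""

    kept: list[str] = field(default_factory=list)
    dropped_correlated: dict[str, str] = field(default_factory=dict)  # dropped -> representative
    scores: pd.DataFrame | None = None      # in/out fluctuation + ratio per kept feature
    ranked: list[str] = field(default_factory=list)
    chosen_subset: list[str] = field(default_factory=list)
    accuracy_trace: list[tuple[int, float]] = field(default_factory=list)


def prune_correlated(table: pd.DataFrame, r_threshold: float = 0.7,
                     feature_names: Sequence[str] | None = None,
                     report: SelectionReport | None = None) -> list[str]:
    """Collapse groups of features with |Pearson r| strictly above threshold.

    Features are grouped into connected components of the |r| > threshold
    graph; within each component the member with the highest mean |r| to the
    other members is kept (ties broken by registry order) and the rest are
    dropped with a mapping recorded in the report.
    """
    names = list(feature_names) if feature_names is not None else list(FEATURE_NAMES)
    if len(table) < 2:
        raise ValueError("need at least 2 rows to compute correlations")
    X = table[names].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # constant columns correlate as 0
    acorr = np.abs(corr)
    np.fill_diagonal(acorr, 0.0)
    adj = acorr > r_threshold

    # connected components by simple traversal
    n = len(names)
    comp = -np.ones(n, dtype=int)
    ncomp = 0
    for i in range(n):
        if comp[i] >= 0:
            continue
        stack = [i]
        comp[i] = ncomp
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[u]):
                if comp[v] < 0:
                    comp[v] = ncomp
                    stack.append(v)
        ncomp += 1

    kept: list[str] = []
    for c in range(ncomp):
        members = np.flatnonzero(comp == c)
        if members.size == 1:
            kept.append(names[members[0]])
            continue
        sub = acorr[np.ix_(members, members)]
        mean_r = sub.sum(axis=1) / (members.size - 1)
        rep = members[int(np.argmax(mean_r))]  # argmax: earliest tie = registry order
        kept.append(names[rep])
        if report is not None:
            for m in members:
                if m != rep:
                    report.dropped_correlated[names[m]] = names[rep]
    kept.sort(key=names.index)
    if report is not None:
        report.kept = kept
    log.info("correlation pruning: %d -> %d features", n, len(kept))
    return kept


def _histogram(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    h, _ = np.histogram(values, bins=edges)
    total = h.sum()
    return h / total if total > 0 else h.astype(float)


def fluctuation_ranking(table: pd.DataFrame, labels: Sequence,
                        run_ids: Sequence,
                        feature_names: Sequence[str] | None = None,
                        n_bins: int = 50) -> pd.DataFrame:
    """Score each feature by out-group / in-group histogram fluctuation.

    In-group fluctuation: mean L1 distance between each run's normalized
    histogram and the accumulated histogram of that run's analyte.
    Out-group fluctuation: mean L1 distance between the accumulated
    histograms of each analyte pair.  Higher out/in = more discriminating
    relative to its run-to-run variability.
    """
    names = list(feature_names) if feature_names is not None else list(FEATURE_NAMES)
    labels = np.asarray(labels)
    run_ids = np.asarray(run_ids)
    uniq_labels = sorted(set(labels.tolist()))
    if len(uniq_labels) < 2:
        raise ValueError("need at least 2 labels")
    for lab in uniq_labels:
        runs = set(run_ids[labels == lab].tolist())
        if len(runs) < 2:
            raise ValueError(
                f"label {lab!r} has {len(runs)} run(s); in-group fluctuation "
                f"needs at least 2 runs per label")

    rows = []
    for name in names:
        values = table[name].to_numpy(dtype=float)
        lo, hi = float(np.min(values)), float(np.max(values))
        if hi <= lo:
            rows.append((name, 0.0, 0.0, 0.0))
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        label_hist = {lab: _histogram(values[labels == lab], edges)
                      for lab in uniq_labels}
        in_terms = []
        for lab in uniq_labels:
            for run in sorted(set(run_ids[labels == lab].tolist())):
                mask = (labels == lab) & (run_ids == run)
                in_terms.append(np.abs(_histogram(values[mask], edges)
                                       - label_hist[lab]).sum())
        in_fluct = float(np.mean(in_terms))
        out_terms = [np.abs(label_hist[a] - label_hist[b]).sum()
                     for a, b in combinations(uniq_labels, 2)]
        out_fluct = float(np.mean(out_terms))
        score = out_fluct / in_fluct if in_fluct > 0 else (
            np.inf if out_fluct > 0 else 0.0)
        rows.append((name, in_fluct, out_fluct, score))
    scores = pd.DataFrame(rows, columns=["feature", "in_group", "out_group",
                                         "score"])
    # stable sort keeps registry order among ties
    return scores.sort_values("score", ascending=False,
                              kind="stable").reset_index(drop=True)


def select_subset(ranked_features: Sequence[str],
                  evaluate: Callable[[list[str]], float],
                  k_grid: Sequence[int] | None = None,
                  tolerance: float = 0.5,
                  report: SelectionReport | None = None) -> list[str]:
    """Pick the smallest top-k prefix whose accuracy is within ``tolerance``
    percentage points of the best observed accuracy.

    ``evaluate`` maps a feature subset to a (cross-validated) accuracy in
    percent and must be deterministic for reproducible selection.
    """
    ranked = list(ranked_features)
    if not ranked:
        raise ValueError("empty feature ranking")
    if k_grid is None:
        k_grid = sorted({k for k in (1, 2, 4, 8, 16, 32, 64, 128, len(ranked))
                         if k <= len(ranked)})
    trace = []
    for k in k_grid:
        acc = float(evaluate(ranked[:k]))
        trace.append((k, acc))
    best = max(acc for _, acc in trace)
    chosen_k = min(k for k, acc in trace if acc >= best - tolerance)
    subset = ranked[:chosen_k]
    if report is not None:
        report.accuracy_trace = trace
        report.chosen_subset = subset
        report.ranked = ranked
    log.info("subset selection: k=%d of %d (best accuracy %.2f%%)",
             chosen_k, len(ranked), best)
    return subset


def run_selection(table: pd.DataFrame,
                  evaluate: Callable[[list[str]], float] | None = None,
                  r_threshold: float = 0.7,
                  n_bins: int = 50,
                  tolerance: float = 0.5,
                  top_k: int | None = None) -> SelectionReport:
    """Full selection chain: prune -> rank -> (optionally) accuracy sweep.

    Without an evaluation callback the chosen subset is the top ``top_k``
    ranked features (default: all survivors).
    """
    report = SelectionReport()
    kept = prune_correlated(table, r_threshold, report=report)
    scores = fluctuation_ranking(table, table["label"], table["run_id"],
                                 feature_names=kept, n_bins=n_bins)
    report.scores = scores
    ranked = scores["feature"].tolist()
    report.ranked = ranked
    if evaluate is not None:
        select_subset(ranked, evaluate, tolerance=tolerance, report=report)
    else:
        report.chosen_subset = ranked[:top_k] if top_k else ranked
    return report
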