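"""Kernel-SVM classification of individual spikes under two protocols.

*Optimistic* protocol: a stratified random 10% of all spikes (drawn across
every junction) trains the classifier and the remaining 90% is scored — an
upper bound corresponding to calibrating a device with standards before use.
*Predictive* protocol: leave-one-junction-out — train on all junctions but
one, score the held-out junction, with normalization statistics (and, when
requested, feature selection) computed inside the training fold only, so the
held-out junction contributes nothing to model building.

The SVM uses a radial-basis kernel; C and gamma are chosen by grid search
over stratified cross-validation folds, ties resolved toward the smallest C
then the smallest gamma.  Posterior probabilities come from Platt scaling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .features import FEATURE_NAMES, apply_normalization, normalize_features

log = logging.getLogger("rtpipe")

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (1e-3, 1e-2, 1e-1, 1.0, 10.0)


@dataclass
class SvmModelSpec:
    """A trained classifier plus everything needed to reproduce it."""

    estimator: SVC
    classes: list[str]
    feature_subset: list[str]
    norm_stats: pd.DataFrame
    C: float
    gamma: float
    train_junctions: list[str] = field(default_factory=list)
    train_runs: list[str] = field(default_factory=list)
    seed: int = 0
    calibration: str = "platt"


@dataclass
class EvaluationResult:
    protocol: str                       # "optimistic" | "predictive"
    accuracy: float                     # overall, percent
    per_class: dict[str, float]         # percent per true class
    confusion: pd.DataFrame             # rows: true, cols: predicted
    held_out: Optional[str] = None      # junction id for predictive folds
    n_test: int = 0


def _confusion(y_true: np.ndarray, y_pred: np.ndarray,
               classes: Sequence[str]) -> pd.DataFrame:
    mat = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    return mat


def _result(protocol: str, y_true: np.ndarray, y_pred: np.ndarray,
            classes: Sequence[str], held_out: str | None = None
            ) -> EvaluationResult:
    acc = 100.0 * float(np.mean(y_true == y_pred)) if len(y_true) else 0.0
    per_class = {}
    for c in classes:
        mask = y_true == c
        if mask.any():
            per_class[c] = 100.0 * float(np.mean(y_pred[mask] == c))
    return EvaluationResult(protocol, acc, per_class,
                            _confusion(y_true, y_pred, classes),
                            held_out, int(len(y_true)))


def train_svm(table: pd.DataFrame,
              feature_subset: Sequence[str] | None = None,
              label_col: str = "label",
              c_grid: Sequence[float] = DEFAULT_C_GRID,
              gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
              cv_folds: int = 3,
              seed: int = 0,
              normalized: bool = True) -> SvmModelSpec:
    """Grid-searched RBF SVM on a (normalized) feature table.

    ``normalized=False`` standardizes the table internally and stores the
    statistics on the model for application to held-out data.
    """
    features = list(feature_subset) if feature_subset is not None \
        else list(FEATURE_NAMES)
    y = table[label_col].to_numpy()
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("training needs at least 2 classes")

    if normalized:
        norm_stats = pd.DataFrame({"mean": 0.0, "sd": 1.0},
                                  index=pd.Index(FEATURE_NAMES))
        work = table
    else:
        work, norm_stats = normalize_features(table)
    X = work[features].to_numpy(dtype=float)

    n_folds = min(cv_folds, min(np.bincount(pd.factorize(y)[0])))
    best: tuple[float, float, float] | None = None  # (acc, C, gamma)
    if n_folds >= 2 and (len(c_grid) > 1 or len(gamma_grid) > 1):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed)
        splits = list(skf.split(X, y))
        for C in sorted(c_grid):
            for gamma in sorted(gamma_grid):
                accs = []
                for tr, te in splits:
                    clf = SVC(kernel="rbf", C=C, gamma=gamma)
                    clf.fit(X[tr], y[tr])
                    accs.append(np.mean(clf.predict(X[te]) == y[te]))
                acc = float(np.mean(accs))
                if best is None or acc > best[0] + 1e-12:
                    best = (acc, C, gamma)
        C, gamma = best[1], best[2]
        log.info("grid search: C=%g gamma=%g (cv accuracy %.2f%%)",
                 C, gamma, 100 * best[0])
    else:
        C, gamma = c_grid[0], gamma_grid[0]

    clf = SVC(kernel="rbf", C=C, gamma=gamma, probability=True,
              random_state=seed)
    with warnings.catch_warnings():
        # SVC(probability=True) is deprecated in favour of
        # CalibratedClassifierCV but remains the stable Platt route here
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(X, y)
    junctions = sorted(set(table["junction_id"])) if "junction_id" in table else []
    runs = sorted(set(table["run_id"])) if "run_id" in table else []
    return SvmModelSpec(clf, classes, features, norm_stats, C, gamma,
                        junctions, runs, seed)


def classify_spikes(model: SvmModelSpec, table: pd.DataFrame,
                    normalized: bool = True
                    ) -> tuple[np.ndarray, pd.DataFrame]:
    """Predicted class and posterior vector per spike.

    Returns (labels, posterior frame with one column per class).  The
    posterior rows sum to 1.  ``normalized=False`` applies the model's
    stored normalization first.
    """
    missing = [f for f in model.feature_subset if f not in table.columns]
    if missing:
        raise ValueError(f"table is missing model features: {missing[:5]}")
    work = table if normalized else apply_normalization(table, model.norm_stats)
    X = work[model.feature_subset].to_numpy(dtype=float)
    labels = model.estimator.predict(X)
    proba = pd.DataFrame(model.estimator.predict_proba(X),
                         columns=list(model.estimator.classes_),
                         index=table.index)
    return labels, proba


def class_composition(labels: np.ndarray) -> pd.Series:
    """Fraction of spikes assigned to each class (mixture quantification)."""
    s = pd.Series(labels).value_counts(normalize=True).sort_index()
    s.name = "fraction"
    return s


Selector = Callable[[pd.DataFrame], list[str]]


def evaluate_optimistic(table: pd.DataFrame,
                        train_fraction: float = 0.10,
                        feature_subset: Sequence[str] | None = None,
                        selector: Selector | None = None,
                        seed: int = 0,
                        label_col: str = "label",
                        max_redraws: int = 10,
                        **svm_kwargs) -> EvaluationResult:
    """Train on a stratified random fraction of all spikes, test on the rest.

    Normalization statistics (and feature selection, when a ``selector`` is
    given) are computed on the training split only.
    """
    y = table[label_col].to_numpy()
    classes = sorted(set(y.tolist()))
    rng = np.random.default_rng(seed)
    for attempt in range(max_redraws):
        split_seed = int(rng.integers(0, 2**31 - 1))
        tr_idx, te_idx = train_test_split(
            np.arange(len(table)), train_size=train_fraction,
            random_state=split_seed, stratify=y)
        if set(y[tr_idx]) == set(classes):
            break
        log.warning("training split missing a class; redrawing (%d)", attempt)
    train, test = table.iloc[tr_idx], table.iloc[te_idx]

    train_norm, stats = normalize_features(train)
    test_norm = apply_normalization(test, stats)
    subset = selector(train_norm) if selector is not None else feature_subset
    model = train_svm(train_norm, feature_subset=subset, seed=seed,
                      label_col=label_col, **svm_kwargs)
    model.norm_stats = stats
    pred, _ = classify_spikes(model, test_norm)
    return _result("optimistic", test[label_col].to_numpy(), pred, classes)


def evaluate_predictive(table: pd.DataFrame,
                        feature_subset: Sequence[str] | None = None,
                        selector: Selector | None = None,
                        seed: int = 0,
                        label_col: str = "label",
                        **svm_kwargs) -> list[EvaluationResult]:
    """Leave-one-junction-out evaluation: one result per held-out junction."""
    junctions = sorted(set(table["junction_id"]))
    if len(junctions) < 2:
        raise ValueError("predictive protocol needs >= 2 junctions")
    classes = sorted(set(table[label_col].tolist()))
    results = []
    for j in junctions:
        train = table[table["junction_id"] != j]
        test = table[table["junction_id"] == j]
        fold_classes = sorted(set(test[label_col]))
        if set(fold_classes) != set(classes):
            log.warning("junction %s lacks classes %s; per-class report "
                        "restricted", j, set(classes) - set(fold_classes))
        train_norm, stats = normalize_features(train)
        test_norm = apply_normalization(test, stats)
        subset = selector(train_norm) if selector is not None else feature_subset
        model = train_svm(train_norm, feature_subset=subset, seed=seed,
                          label_col=label_col, **svm_kwargs)
        model.norm_stats = stats
        pred, _ = classify_spikes(model, test_norm)
        results.append(_result("predictive", test[label_col].to_numpy(),
                               pred, classes, held_out=j))
    return results


def pooled_accuracy(results: list[EvaluationResult]) -> float:
    """Spike-weighted accuracy pooled over predictive folds, percent."""
    n = sum(r.n_test for r in results)
    if n == 0:
        return 0.0
    return sum(r.accuracy * r.n_test for r in results) / n
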