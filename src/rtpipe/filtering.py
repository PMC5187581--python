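"""Removal of chemically-insensitive signals.

Two independent filters run before classification: (1) clusters whose
current is correlated with the z-piezo servo displacement (|Pearson r| over
the cluster span strictly above 0.1) are rejected wholesale, since such
excursions track tip motion rather than chemistry; (2) spikes that the
control-trained SVM assigns to the water/common class with posterior
probability above 0.7 are rejected, removing contamination events shared
between different samples.  At the documented defaults these remove roughly
10% and 50% of peaks respectively.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classify import SvmModelSpec, classify_spikes
from .detection import Cluster
from .io import TraceRecord

log = logging.getLogger("rtpipe")


def zpiezo_correlation(cluster: Cluster, trace: TraceRecord) -> float:
    """Pearson correlation of current vs z-piezo over the cluster span.

    Returns a signed value in [-1, 1]; the filter statistic is |r|.
    A constant channel within the span yields 0 by convention.
    """
    s, e = cluster.span
    if not (0 <= s < e <= trace.n_samples):
        raise ValueError("cluster span outside trace")
    x = trace.samples_current[s:e]
    z = trace.samples_zpiezo[s:e]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(z) == 0:
        log.debug("constant channel in cluster %d: correlation 0",
                  cluster.cluster_id)
        return 0.0
    r = float(np.corrcoef(x, z)[0, 1])
    return 0.0 if not np.isfinite(r) else r


def filter_zpiezo(clusters: list[Cluster], trace: TraceRecord,
                  threshold: float = 0.1
                  ) -> tuple[list[Cluster], list[Cluster]]:
    """Reject clusters with |r| strictly above ``threshold``.

    Rejection is wholesale: every member peak of a rejected cluster is
    discarded.  Returns (retained, rejected); rejected clusters carry the
    reason ``"zpiezo"`` and their correlation value.
    """
    retained, rejected = [], []
    for cl in clusters:
        r = zpiezo_correlation(cl, trace)
        cl.zpiezo_r = r
        if abs(r) > threshold:
            cl.rejected = True
            cl.rejection_reason = "zpiezo"
            rejected.append(cl)
        else:
            retained.append(cl)
    n_rej = sum(len(c.peaks) for c in rejected)
    n_all = n_rej + sum(len(c.peaks) for c in retained)
    if n_all:
        log.info("z-piezo filter: rejected %d/%d peaks (%.1f%%)",
                 n_rej, n_all, 100.0 * n_rej / n_all)
    return retained, rejected


def filter_common_class(table: pd.DataFrame, control_model: SvmModelSpec,
                        posterior_threshold: float = 0.7,
                        water_class: str = "water",
                        normalized: bool = True
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reject spikes the control-trained SVM calls water/common.

    A spike is rejected when its posterior probability for the water class
    exceeds ``posterior_threshold``.  Returns (retained, rejected) feature
    tables; rejected rows gain a ``rejection_reason`` column.
    """
    if water_class not in control_model.classes:
        raise ValueError(
            f"control model has no {water_class!r} class; classes are "
            f"{control_model.classes}")
    _, proba = classify_spikes(control_model, table, normalized=normalized)
    reject_mask = proba[water_class].to_numpy() > posterior_threshold
    retained = table.loc[~reject_mask].copy()
    rejected = table.loc[reject_mask].copy()
    rejected["rejection_reason"] = "common_class"
    log.info("common-class filter: rejected %d/%d spikes (%.1f%%)",
             len(rejected), len(table),
             100.0 * len(rejected) / max(len(table), 1))
    return retained, rejected
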