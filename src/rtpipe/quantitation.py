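"""Langmuir-isotherm quantitation of capture rates.

The frequency of capture clusters saturates with analyte concentration
following the Langmuir form f(x) = a·(b·x)/(1 + b·x), where b (M^-1) is the
association constant and K_d = 1/b the dissociation constant.  Peak
frequencies are normalized to the highest-concentration rate, fitted by
Levenberg–Marquardt nonlinear least squares, and reported with standard
errors (delta method for K_d) plus an optional bootstrap interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy import stats as sstats

log = logging.getLogger("rtpipe")


def langmuir(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """f(x) = a * (b*x) / (1 + b*x); x in M, b in 1/M."""
    return a * (b * x) / (1.0 + b * x)


@dataclass
class IsothermFit:
    a: float                      # saturation amplitude (normalized units)
    b: float                      # association constant, 1/M
    kd: float                     # dissociation constant, M (= 1/b)
    r_squared: float
    a_se: float
    b_se: float
    kd_se: float                  # delta method: se(1/b) = se(b)/b^2
    n_points: int
    converged: bool = True
    kd_ci95: tuple[float, float] = field(default=(np.nan, np.nan))
    bootstrap_kd_ci: Optional[tuple[float, float]] = None


class FitError(RuntimeError):
    """Langmuir fit failed to converge or produced invalid parameters."""


def count_rates(counts: Sequence[int] | pd.DataFrame,
                durations: Sequence[float] | None = None,
                concentrations: Sequence[float] | None = None
                ) -> pd.DataFrame:
    """Per-concentration absolute and normalized peak frequencies.

    Accepts either the frame produced by the generator's concentration
    series or parallel count/duration/concentration sequences.  Replicate
    rows at the same concentration are averaged with an s.d. column.
    Frequencies are normalized by the rate at the highest concentration.
    """
    if isinstance(counts, pd.DataFrame):
        frame = counts.rename(columns={"concentration_M": "concentration",
                                       "duration_s": "duration"})
    else:
        frame = pd.DataFrame({"concentration": list(concentrations),
                              "duration": list(durations),
                              "count": list(counts)})
    if (frame["duration"] <= 0).any():
        raise ValueError("durations must be positive")
    frame["rate_hz"] = frame["count"] / frame["duration"]
    agg = frame.groupby("concentration", as_index=False).agg(
        rate_hz=("rate_hz", "mean"), rate_sd=("rate_hz", "std"),
        n_replicates=("rate_hz", "size"))
    top = agg.loc[agg["concentration"].idxmax(), "rate_hz"]
    if top <= 0:
        raise ValueError("zero events at the highest concentration; "
                         "cannot normalize")
    agg["normalized"] = agg["rate_hz"] / top
    return agg


def fit_langmuir(concentrations: Sequence[float],
                 normalized: Sequence[float],
                 weights: Sequence[float] | None = None,
                 init: tuple[float, float] | None = None,
                 n_bootstrap: int = 0,
                 seed: int = 0) -> IsothermFit:
    """Levenberg–Marquardt fit of the Langmuir isotherm.

    Initialization defaults to a0 = max(y), b0 = 1/median(x).  Returns the
    fitted (a, b), K_d = 1/b with a delta-method standard error and normal
    95% CI, and an optional nonparametric bootstrap CI over the points.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(normalized, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("concentrations and frequencies must be finite")
    p0 = init if init is not None else (float(np.max(y)),
                                        1.0 / float(np.median(x)))
    sigma = None if weights is None else 1.0 / np.asarray(weights, float)
    try:
        popt, pcov = curve_fit(langmuir, x, y, p0=p0, sigma=sigma,
                               method="lm", maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"Langmuir fit did not converge: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    if a <= 0 or b <= 0:
        raise FitError(f"invalid parameter estimates a={a:g}, b={b:g}")
    resid = y - langmuir(x, a, b)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    a_se, b_se = (float(np.sqrt(pcov[i, i])) if np.isfinite(pcov[i, i])
                  else np.nan for i in (0, 1))
    kd = 1.0 / b
    kd_se = b_se / b ** 2
    # t-based 95% interval with n - 2 degrees of freedom, as standard for
    # nonlinear least squares with few points
    tq = float(sstats.t.ppf(0.975, max(len(x) - 2, 1)))
    ci = (kd - tq * kd_se, kd + tq * kd_se)

    boot_ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        kds = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(x), size=len(x))
            if len(np.unique(x[idx])) < 3:
                continue
            try:
                bp, _ = curve_fit(langmuir, x[idx], y[idx], p0=(a, b),
                                  method="lm", maxfev=10000)
                if bp[1] > 0:
                    kds.append(1.0 / bp[1])
            except RuntimeError:
                continue
        if len(kds) >= 10:
            boot_ci = tuple(np.percentile(kds, [2.5, 97.5]))

    return IsothermFit(a, b, kd, r2, a_se, b_se, kd_se, len(x),
                       converged=True, kd_ci95=ci, bootstrap_kd_ci=boot_ci)


def two_site_kd_bound(kd_single: float) -> float:
    """Upper bound on K_d for simultaneous two-site binding.

    If one recognition contact binds with dissociation constant K_d (in M),
    doubling the binding free energy (equal-entropy assumption) squares the
    molar value: e.g. 4 mM single-site → (4e-3)^2 = 1.6e-5 M = 16 μM.
    """
    if kd_single <= 0:
        raise ValueError("kd must be positive")
    return kd_single ** 2


def dynamic_range_report(rates: pd.DataFrame,
                         floor_per_minute: float = 1.0) -> dict:
    """Concentration span with detectable counts.

    Reports the lowest concentration whose absolute rate exceeds the
    counts-per-minute floor, the highest concentration, and the decade span
    between them.  Empty when nothing clears the floor.
    """
    detectable = rates[rates["rate_hz"] * 60.0 > floor_per_minute]
    if len(detectable) == 0:
        log.warning("no concentration clears the %.2g counts/min floor",
                    floor_per_minute)
        return {"lowest": None, "highest": None, "decades": 0.0}
    lo = float(detectable["concentration"].min())
    hi = float(detectable["concentration"].max())
    return {"lowest": lo, "highest": hi,
            "decades": float(np.log10(hi / lo)) if lo > 0 else 0.0}
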