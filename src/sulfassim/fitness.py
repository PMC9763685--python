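"""Colony-grid relative-fitness pipeline.

Fixed processing order: border removal -> outlier filter (unscaled MAD)
-> normalization against the reference strain's per-plate, per-time median
-> either per-time summaries or loess resampling + logistic fit + AUC
-> Kruskal-Wallis statistics and median-difference effect sizes.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import chi2, rankdata

from .synth import PlateLayout, logistic_size

logger = logging.getLogger("sulfassim")


@dataclasses.dataclass
class GrowthFit:
    """Logistic fit of one colony's (resampled) growth series."""

    key: str
    K: float
    r: float
    N0: float
    auc: float
    n_points: int
    fallback: bool = False  # empirical trapezoid AUC used (fit not converged)


@dataclasses.dataclass
class FitnessResult:
    strain_pair: tuple[str, str]
    effect_size: float
    statistic: float  # Kruskal-Wallis H with tie correction
    p_value: float
    p_permutation: float | None  # exact (includes the observed point's mass)
    n_per_group: tuple[int, int]
    p_permutation_mid: float | None = None  # mid-p: half the observed mass


def remove_border(records: pd.DataFrame, layout: PlateLayout) -> pd.DataFrame:
    """Drop records at border positions; interior records keep their order."""
    pos = list(zip(records["row"], records["col"]))
    for r, c in pos:
        if not (1 <= r <= layout.n_rows and 1 <= c <= layout.n_cols):
            raise ValueError(f"record position ({r}, {c}) outside the grid")
    keep = [p not in layout.border_mask for p in pos]
    return records.loc[keep].reset_index(drop=True)


def mad_outlier_filter(values: Sequence[float], k: float = 2.0) -> np.ndarray:
    """Keep x with |x - median| <= k * MAD, MAD unscaled.

    When MAD is zero (more than half the values tied at the median) only the
    median value itself survives, which removes gross outliers from otherwise
    constant groups.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x[x == med]
    return x[np.abs(x - med) <= k * mad]


def _mad_mask(x: np.ndarray, k: float) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x == med
    return np.abs(x - med) <= k * mad


def filter_outliers(
    records: pd.DataFrame, k: float = 2.0, pool: str = "plate_time"
) -> pd.DataFrame:
    """Apply the MAD filter per strain within the chosen pooling stratum.

    ``pool='plate_time'`` (default) pools sizes per strain per plate per time
    point; ``pool='plate'`` pools across time points within a plate.
    """
    if pool == "plate_time":
        keys = ["strain", "plate", "time_h"]
    elif pool == "plate":
        keys = ["strain", "plate"]
    else:
        raise ValueError(f"unknown pooling {pool!r}")
    mask = np.zeros(len(records), dtype=bool)
    for _, idx in records.groupby(keys).groups.items():
        sub = records.loc[idx, "size_px"].to_numpy()
        mask[records.index.get_indexer(idx)] = _mad_mask(sub, k)
    return records.loc[mask].reset_index(drop=True)


def relative_colony_size(records: pd.DataFrame, reference_strain: str) -> pd.DataFrame:
    """Normalize sizes by the reference strain's median per plate per time.

    Strata without the reference strain are dropped with a logged warning;
    a zero reference median is an error.
    """
    out = []
    for (plate, t), sub in records.groupby(["plate", "time_h"]):
        ref = sub.loc[sub["strain"] == reference_strain, "size_px"]
        if ref.empty:
            logger.warning("stratum (%s, t=%s) lacks reference %s; dropped",
                           plate, t, reference_strain)
            continue
        med = float(ref.median())
        if med == 0:
            raise ValueError(f"reference median 0 in stratum ({plate}, t={t})")
        sub = sub.copy()
        sub["relative_size"] = sub["size_px"] / med
        out.append(sub)
    if not out:
        raise ValueError("no stratum contains the reference strain")
    return pd.concat(out, ignore_index=True)


def loess_resample(
    times: Sequence[float],
    sizes: Sequence[float],
    n_out: int = 100,
    degree: int = 2,
    span: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """Locally weighted polynomial smoothing onto an equally spaced grid.

    At each output point a weighted polynomial of the given degree is fitted
    to the nearest ``ceil(span * n)`` observations with tricube weights. The
    output grid runs from min(times) to max(times) with exactly ``n_out``
    points. A degree-2 input polynomial with span 1 is reproduced exactly.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(sizes, dtype=float)
    if len(np.unique(t)) < degree + 2:
        raise ValueError(f"need at least {degree + 2} distinct times")
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    order = np.argsort(t)
    t, y = t[order], y[order]
    grid = np.linspace(t.min(), t.max(), n_out)
    q = max(int(np.ceil(span * len(t))), degree + 1)
    out = np.empty(n_out)
    for i, x in enumerate(grid):
        d = np.abs(t - x)
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx[0]]
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-12)  # keep design nonsingular at window edges
        coeffs = np.polyfit(t[idx] - x, y[idx], degree, w=np.sqrt(w))
        out[i] = coeffs[-1]
    return grid, out


class LogisticGrowthModel:
    """Least-squares logistic growth model size(t) = K/(1+((K-N0)/N0)e^{-rt})."""

    def __init__(self, times, sizes, key: str = "colony"):
        self.t = np.asarray(times, dtype=float)
        self.y = np.asarray(sizes, dtype=float)
        self.key = key
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite sizes")
        if self.t.shape != self.y.shape:
            raise ValueError("times and sizes must have equal length")

    def fit(self, n_points: int = 100) -> GrowthFit:
        t, y = self.t, self.y
        span = t.max() - t.min()
        ymax = y.max()
        if ymax <= 0 or span <= 0 or np.ptp(y) == 0:
            # flat series: AUC is the exact trapezoid of the data
            auc = float(np.trapezoid(y, t))
            return GrowthFit(self.key, float(ymax), 0.0, float(ymax), auc,
                             n_points, fallback=True)
        K0 = ymax * 1.05
        N00 = max(y[np.argmin(t)], ymax * 1e-3)
        r0 = max(4.0 / span, 1e-3)
        try:
            popt, _ = curve_fit(
                logistic_size, t, y, p0=[K0, r0, N00],
                bounds=([1e-9, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            K, r, N0 = map(float, popt)
            grid = np.linspace(t.min(), t.max(), n_points)
            auc = float(np.trapezoid(logistic_size(grid, K, r, N0), grid))
            return GrowthFit(self.key, K, r, N0, auc, n_points)
        except RuntimeError:
            auc = float(np.trapezoid(y, t))
            return GrowthFit(self.key, float("nan"), float("nan"), float("nan"),
                             auc, n_points, fallback=True)


def fit_growth_curve(times, sizes, key: str = "colony", n_points: int = 100) -> GrowthFit:
    """Fit the logistic model; AUC is the trapezoid of the fitted curve over
    the observed time range (empirical trapezoid, flagged, on non-convergence)."""
    return LogisticGrowthModel(times, sizes, key=key).fit(n_points=n_points)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (df = k - 1).

    Unlike scipy's implementation this returns H = 0, p = 1 when every value
    is identical rather than raising.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n) if n > 1 else 1.0
    if tie == 0:
        return 0.0, 1.0
    h /= tie
    p = float(chi2.sf(h, df=len(groups) - 1))
    return float(h), p


def permutation_kw_pvalue(a, b, max_exhaustive: int = 200000,
                          mid_p: bool = False) -> float:
    """Exact two-group permutation p for the Kruskal-Wallis H statistic.

    Enumerates every assignment of the pooled values into groups of the
    observed sizes (feasible for the small n used here) and reports the
    fraction with H at least as large as observed. With ``mid_p=True`` only
    half the probability mass at the observed H is counted — the standard
    correction when comparing a discrete permutation distribution with a
    continuous approximation such as the chi-square.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    from math import comb

    if comb(n, na) > max_exhaustive:
        raise ValueError("too many assignments for exhaustive enumeration")
    h_obs, _ = kruskal_wallis(a, b)
    greater = equal = total = 0
    idx = np.arange(n)
    for combo in itertools.combinations(idx, na):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        h, _ = kruskal_wallis(pooled[mask], pooled[~mask])
        if h > h_obs + 1e-12:
            greater += 1
        elif h >= h_obs - 1e-12:
            equal += 1
        total += 1
    if mid_p:
        return (greater + 0.5 * equal) / total
    return (greater + equal) / total


def effect_size_and_test(
    groupA,
    groupB,
    reference_median: float,
    permutation_max_n: int = 10,
) -> FitnessResult:
    """Median-difference effect size and Kruskal-Wallis test for two strains.

    effect_size = (median(A) - median(B)) / reference_median. The H statistic
    uses mid-ranks with tie correction; p comes from the chi-square
    approximation, plus an exact permutation p when both groups have at most
    ``permutation_max_n`` observations.
    """
    a = np.asarray(groupA, dtype=float)
    b = np.asarray(groupB, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if reference_median == 0:
        raise ValueError("reference median must be nonzero")
    effect = (np.median(a) - np.median(b)) / reference_median
    h, p = kruskal_wallis(a, b)
    p_perm = p_mid = None
    if a.size <= permutation_max_n and b.size <= permutation_max_n:
        p_perm = permutation_kw_pvalue(a, b)
        p_mid = permutation_kw_pvalue(a, b, mid_p=True)
    return FitnessResult(("A", "B"), float(effect), h, p, p_perm,
                         (a.size, b.size), p_mid)


def relative_fitness_at_saturation(
    records: pd.DataFrame,
    layout: PlateLayout,
    reference_strain: str,
    k_mad: float = 2.0,
    pool: str = "plate_time",
    saturation_times: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Full pipeline to per-strain median relative colony size at saturation.

    Saturation defaults to the final three observed time points. The
    distribution entering the per-strain medians is the median relative size
    per plate per replicate, and the returned frame carries one row per
    strain with its median and observation count.
    """
    interior = remove_border(records, layout)
    filtered = filter_outliers(interior, k=k_mad, pool=pool)
    norm = relative_colony_size(filtered, reference_strain)
    if saturation_times is None:
        times = np.sort(norm["time_h"].unique())
        saturation_times = times[-3:] if times.size >= 3 else times
    sat = norm[norm["time_h"].isin(saturation_times)]
    per_rep = (
        sat.groupby(["strain", "plate", "replicate"])["relative_size"]
        .median()
        .reset_index()
    )
    out = (
        per_rep.groupby("strain")["relative_size"]
        .agg(median_relative_size="median", n="size")
        .reset_index()
    )
    return out
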