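"""De-trending and de-totaling of monthly count series.

De-trending subtracts a Gaussian-kernel Nadaraya-Watson estimate of each
code's secular trend; the bandwidth defaults to Silverman's normal-reference
rule applied to the count-weighted month positions, with a floor that keeps
the smoother broad enough to pass seasonal (<= 18 month) frequencies.
Months within two bandwidths of either end of the series are trimmed, as
the kernel estimate is unreliable there.

De-totaling then removes the shared seasonal hospitalization component: the
summed series over all codes is de-trended the same way, scaled to each
code's mean level, and subtracted.  A code that is a fixed proportion of
the total is thereby flattened to noise, which is exactly the confound this
step exists to remove.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

import pandas as pd

from .ingest import MonthlyCounts

__all__ = [
    "AdjustedSeries",
    "SharedSeasonal",
    "silverman_bandwidth",
    "smooth_series",
    "detrend_series",
    "build_shared_seasonal",
    "detotal_series",
    "TrendAdjuster",
    "adjust_counts",
]

#: Default lower bound on the kernel bandwidth, months.  A narrower kernel
#: would start absorbing the sub-annual periodicities the scan is meant to
#: detect; 9 months attenuates a 12-month cosine's contribution to the trend
#: to exp(-(2*pi*9/12)**2 / 2) ~ 1e-5, i.e. the seasonal signal survives
#: de-trending essentially intact.
DEFAULT_BANDWIDTH_FLOOR = 9.0

MIN_SERIES_MONTHS = 24


@dataclass
class AdjustedSeries:
    """One code's series after trend (and optionally total) adjustment.

    All arrays share the trimmed month axis; ``time`` is in decimal years.
    ``bandwidth`` is in months; ``trim`` is the number of months removed
    from each end of the original axis.
    """

    code: str
    time: np.ndarray
    raw: np.ndarray
    trend: np.ndarray
    detrended: np.ndarray
    bandwidth: float
    trim: int
    detotaled: np.ndarray | None = None

    def series(self, stage: str) -> np.ndarray:
        if stage == "detotaled" and self.detotaled is None:
            raise ValueError(f"code {self.code}: detotaled stage not computed")
        return getattr(self, stage)


@dataclass
class SharedSeasonal:
    """De-trended total-visit series plus per-code mean-scale factors."""

    time: np.ndarray
    total_detrended: np.ndarray
    scale: Mapping[str, float]  # mean(code) / mean(total) on the trimmed axis
    bandwidth: float
    trim: int


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(np.interp(q * cw[-1], cw, x[order]))


def silverman_bandwidth(time_months: np.ndarray, counts: np.ndarray) -> float:
    """Normal-reference bandwidth for count-weighted month positions.

    Treats each counted event as an observation at its month's position, so
    n is the total count and the spread statistics are count-weighted.
    Returns NaN for degenerate (all-zero or single-month) series.
    """
    w = np.asarray(counts, float)
    n = w.sum()
    if n <= 0:
        return float("nan")
    t = np.asarray(time_months, float)
    mu = np.average(t, weights=w)
    sigma = math.sqrt(np.average((t - mu) ** 2, weights=w))
    iqr = _weighted_quantile(t, w, 0.75) - _weighted_quantile(t, w, 0.25)
    spread = min(s for s in (sigma, iqr / 1.34) if s > 0) if max(sigma, iqr) > 0 else 0.0
    if spread == 0:
        return float("nan")
    return 0.9 * spread * n ** (-0.2)


def smooth_series(
    counts: np.ndarray,
    time: np.ndarray,
    bandwidth: float | None = None,
    bandwidth_floor: float = DEFAULT_BANDWIDTH_FLOOR,
) -> tuple[np.ndarray, float]:
    """Gaussian-kernel Nadaraya-Watson trend evaluated at every month.

    Parameters
    ----------
    counts
        Non-negative monthly values, length >= 24.
    time
        Numeric axis in decimal years (evenly spaced months).
    bandwidth
        Kernel bandwidth in months; ``None`` selects Silverman's rule on the
        count-weighted month positions, floored at ``bandwidth_floor``.

    Returns
    -------
    (trend, bandwidth_months)
    """
    y = np.asarray(counts, float)
    t = np.asarray(time, float)
    if y.size != t.size:
        raise ValueError("counts and time must have equal length")
    if y.size < MIN_SERIES_MONTHS:
        raise ValueError(f"series too short ({y.size} < {MIN_SERIES_MONTHS} months)")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    tm = (t - t[0]) * 12.0  # months since series start
    if not y.any():
        return np.zeros_like(y), float("nan")
    if bandwidth is None:
        h = silverman_bandwidth(tm, y)
        h = bandwidth_floor if math.isnan(h) else max(h, bandwidth_floor)
    else:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        h = float(bandwidth)
    k = np.exp(-0.5 * ((tm[:, None] - tm[None, :]) / h) ** 2)
    trend = (k @ y) / k.sum(axis=1)
    return trend, h


def detrend_series(
    counts: np.ndarray,
    time: np.ndarray,
    code: str = "",
    bandwidth: float | None = None,
    trim: int | None = None,
    bandwidth_floor: float = DEFAULT_BANDWIDTH_FLOOR,
) -> AdjustedSeries:
    """Subtract the kernel trend and trim the unreliable edges.

    ``trim`` defaults to ``ceil(2 * bandwidth)`` months removed from each
    end; pass an explicit value (>= the default) to align several codes on
    a common axis.
    """
    y = np.asarray(counts, float)
    t = np.asarray(time, float)
    trend, h = smooth_series(y, t, bandwidth=bandwidth, bandwidth_floor=bandwidth_floor)
    own_trim = 0 if math.isnan(h) else math.ceil(2 * h)
    trim = own_trim if trim is None else int(trim)
    if y.size - 2 * trim < MIN_SERIES_MONTHS:
        raise ValueError(
            f"trimming {trim} months per end leaves fewer than "
            f"{MIN_SERIES_MONTHS} of {y.size} months"
        )
    sl = slice(trim, y.size - trim if trim else None)
    return AdjustedSeries(
        code=code,
        time=t[sl].copy(),
        raw=y[sl].copy(),
        trend=trend[sl],
        detrended=y[sl] - trend[sl],
        bandwidth=h,
        trim=trim,
    )


def build_shared_seasonal(
    counts: MonthlyCounts,
    bandwidth: float | None = None,
    trim: int | None = None,
    bandwidth_floor: float = DEFAULT_BANDWIDTH_FLOOR,
) -> SharedSeasonal:
    """De-trend the summed series over all codes and compute scale factors.

    The per-code scale factor mean(code)/mean(total), taken on the trimmed
    axis, is the proportion of total visits the code represents; scaling the
    de-trended total by it predicts the code's counts under the null that
    the code is a fixed fraction of hospital traffic.
    """
    if len(counts.codes) < 2:
        raise ValueError("de-totaling requires at least 2 codes")
    total = counts.values.sum(axis=0)
    adj = detrend_series(
        total, counts.time_axis, code="<total>", bandwidth=bandwidth,
        trim=trim, bandwidth_floor=bandwidth_floor,
    )
    sl = slice(adj.trim, len(total) - adj.trim if adj.trim else None)
    mean_total = counts.values[:, sl].sum(axis=0).mean()
    scale = {
        code: counts.values[i, sl].mean() / mean_total
        for i, code in enumerate(counts.codes)
    }
    return SharedSeasonal(
        time=adj.time,
        total_detrended=adj.detrended,
        scale=scale,
        bandwidth=adj.bandwidth,
        trim=adj.trim,
    )


def detotal_series(adj: AdjustedSeries, shared: SharedSeasonal) -> AdjustedSeries:
    """Subtract the mean-scaled de-trended total from a de-trended series."""
    if adj.time.size != shared.time.size or not np.allclose(
        adj.time, shared.time, atol=1e-9
    ):
        raise ValueError(
            f"code {adj.code}: time axis does not match the shared seasonal axis"
        )
    if adj.code not in shared.scale:
        raise KeyError(f"no scale factor for code {adj.code}")
    out = replace(adj)
    out.detotaled = adj.detrended - shared.scale[adj.code] * shared.total_detrended
    return out


class TrendAdjuster(BaseEstimator, TransformerMixin):
    """Transformer applying de-trending and de-totaling to a counts matrix.

    All codes are trimmed to a common month axis (the widest trim implied by
    any code's bandwidth, or by the total's), so the shared seasonal series
    aligns with every code and the output is a rectangular matrix.

    Parameters
    ----------
    bandwidth : float or None, default None
        Kernel bandwidth in months for every code; ``None`` selects
        Silverman's rule per code (floored at ``bandwidth_floor``).
    bandwidth_floor : float, default 9.0
        Lower bound on automatic bandwidths, months.
    detotal : bool, default True
        Whether ``transform`` returns the de-totaled stage (otherwise the
        de-trended stage).

    Attributes
    ----------
    adjusted_ : dict of code -> AdjustedSeries
    shared_ : SharedSeasonal
    trim_ : int, months removed from each end of the common axis
    bandwidths_ : dict of code -> bandwidth in months
    time_ : ndarray, trimmed axis in decimal years
    months_ : pandas.PeriodIndex of the trimmed axis
    """

    def __init__(
        self,
        bandwidth: float | None = None,
        bandwidth_floor: float = DEFAULT_BANDWIDTH_FLOOR,
        detotal: bool = True,
    ):
        self.bandwidth = bandwidth
        self.bandwidth_floor = bandwidth_floor
        self.detotal = detotal

    def fit(self, X: MonthlyCounts, y=None) -> "TrendAdjuster":
        counts = X if isinstance(X, MonthlyCounts) else MonthlyCounts(X)
        time = counts.time_axis
        values = counts.values
        n_codes = len(counts.codes)
        if n_codes < 1:
            raise ValueError("empty counts matrix")

        bandwidths: dict[str, float] = {}
        for i, code in enumerate(counts.codes):
            _, h = smooth_series(
                values[i], time, bandwidth=self.bandwidth,
                bandwidth_floor=self.bandwidth_floor,
            )
            bandwidths[code] = h
        shared = None
        trims = [0 if math.isnan(h) else math.ceil(2 * h) for h in bandwidths.values()]
        if self.detotal:
            if n_codes < 2:
                raise ValueError("de-totaling requires at least 2 codes")
            _, h_tot = smooth_series(
                values.sum(axis=0), time, bandwidth=self.bandwidth,
                bandwidth_floor=self.bandwidth_floor,
            )
            trims.append(math.ceil(2 * h_tot))
        trim = max(trims)

        if self.detotal:
            shared = build_shared_seasonal(
                counts, bandwidth=self.bandwidth, trim=trim,
                bandwidth_floor=self.bandwidth_floor,
            )
        adjusted: dict[str, AdjustedSeries] = {}
        for i, code in enumerate(counts.codes):
            adj = detrend_series(
                values[i], time, code=code,
                bandwidth=self.bandwidth if self.bandwidth is not None
                else (None if math.isnan(bandwidths[code]) else bandwidths[code]),
                trim=trim, bandwidth_floor=self.bandwidth_floor,
            )
            if shared is not None:
                adj = detotal_series(adj, shared)
            adjusted[code] = adj

        self.adjusted_ = adjusted
        self.shared_ = shared
        self.trim_ = trim
        self.bandwidths_ = bandwidths
        self.time_ = time[trim: len(time) - trim if trim else None]
        self.months_ = counts.months[trim: len(counts.months) - trim if trim else None]
        return self

    def transform(self, X=None) -> pd.DataFrame:
        """Adjusted matrix (codes x trimmed months) at the configured stage."""
        stage = "detotaled" if self.detotal else "detrended"
        data = {c: a.series(stage) for c, a in self.adjusted_.items()}
        return pd.DataFrame.from_dict(data, orient="index", columns=self.months_)

    def to_long_frame(self) -> pd.DataFrame:
        """Long per-code table: code, month, raw, trend, detrended[, detotaled]."""
        rows = []
        for code, a in self.adjusted_.items():
            d = {
                "code": code,
                "month": [str(m) for m in self.months_],
                "time": a.time,
                "raw": a.raw,
                "trend": a.trend,
                "detrended": a.detrended,
            }
            if a.detotaled is not None:
                d["detotaled"] = a.detotaled
            rows.append(pd.DataFrame(d))
        return pd.concat(rows, ignore_index=True)


def adjust_counts(
    counts: MonthlyCounts,
    bandwidth: float | None = None,
    bandwidth_floor: float = DEFAULT_BANDWIDTH_FLOOR,
    detotal: bool = True,
) -> TrendAdjuster:
    """Fit a :class:`TrendAdjuster` on a counts matrix and return it."""
    return TrendAdjuster(
        bandwidth=bandwidth, bandwidth_floor=bandwidth_floor, detotal=detotal
    ).fit(counts)
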