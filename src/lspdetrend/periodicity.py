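"""Lomb-Scargle periodogram scan with exponential false-alarm significance.

The periodogram is the classical normalized (Press) form

    P(w) = 1/(2 s^2) * { [sum (y - ybar) cos w(t - tau)]^2 / sum cos^2 w(t - tau)
                       + [sum (y - ybar) sin w(t - tau)]^2 / sum sin^2 w(t - tau) }

with tan(2 w tau) = sum sin(2 w t) / sum cos(2 w t) and s^2 the sample
variance (N-1 denominator).  Under Gaussian white noise P at a fixed
frequency is exponentially distributed with mean 1, so the false-alarm
probability of the maximum over M effectively independent frequencies is
1 - (1 - exp(-z))^M.

Best periods longer than 18 months (1.5 years) are forced non-significant:
with only a decade or so of monthly data such periods are poorly supported
and rarely interpretable as seasonality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .detrend import AdjustedSeries

__all__ = [
    "PeriodogramResult",
    "lomb_scargle",
    "false_alarm_p",
    "bh_adjust",
    "period_grid",
    "scan_series",
    "scan_all",
    "PeriodicityScanner",
]

DEFAULT_MIN_PERIOD = 2.0  # months (monthly Nyquist)
DEFAULT_MAX_PERIOD = 60.0  # months
DEFAULT_OVERSAMPLE = 4
MAX_SIGNIFICANT_PERIOD = 18.0  # months; the 1.5-year admissibility rule


@dataclass
class PeriodogramResult:
    """Periodogram of one series with its best period and false-alarm p."""

    code: str
    frequencies: np.ndarray  # cycles/month
    power: np.ndarray
    best_period: float  # months
    best_power: float
    p_value: float
    n_indep: float

    @property
    def periods(self) -> np.ndarray:
        return 1.0 / self.frequencies


def lomb_scargle(
    values: np.ndarray, time: np.ndarray, frequencies: np.ndarray
) -> np.ndarray:
    """Normalized Lomb-Scargle power on a frequency grid.

    ``frequencies`` are in cycles per unit of ``time``.  The estimate is
    invariant to adding a constant to ``values`` and to shifting the time
    origin.  Raises on constant input (zero variance).
    """
    y = np.asarray(values, float)
    t = np.asarray(time, float)
    f = np.asarray(frequencies, float)
    if y.size != t.size:
        raise ValueError("values and time must have equal length")
    if y.size < 24:
        raise ValueError(f"need >= 24 points, got {y.size}")
    if (f <= 0).any():
        raise ValueError("frequencies must be positive")
    var = y.var(ddof=1)
    if var <= 0:
        raise ValueError("constant series has no periodogram (zero variance)")
    yc = y - y.mean()
    t = t - t[0]  # numerical conditioning; result is shift-invariant anyway
    w = 2 * np.pi * f[:, None]
    wt = w * t[None, :]
    tau_arg = 0.5 * np.arctan2(np.sin(2 * wt).sum(axis=1), np.cos(2 * wt).sum(axis=1))
    arg = wt - tau_arg[:, None]
    c = np.cos(arg)
    s = np.sin(arg)
    power = ((c @ yc) ** 2 / (c * c).sum(axis=1) + (s @ yc) ** 2 / (s * s).sum(axis=1))
    return power / (2 * var)


def false_alarm_p(best_power: float, n_indep: float) -> float:
    """P(max of M iid Exp(1) powers >= z) = 1 - (1 - e^-z)^M, stably."""
    z = float(best_power)
    m = float(n_indep)
    if z < 0:
        raise ValueError("power must be >= 0")
    if m < 1:
        raise ValueError("n_indep must be >= 1")
    if z == 0:
        return 1.0
    # -expm1(M log1p(-e^-z)) reduces to M e^-z in the small-p regime
    p = -math.expm1(m * math.log1p(-math.exp(-z))) if z < 700 else m * math.exp(-z)
    return min(max(p, 0.0), 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotonized, order-preserving)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def period_grid(
    time_months: np.ndarray,
    min_period: float = DEFAULT_MIN_PERIOD,
    max_period: float = DEFAULT_MAX_PERIOD,
    oversample: int = DEFAULT_OVERSAMPLE,
) -> np.ndarray:
    """Frequency grid (cycles/month) spanning periods [min_period, max_period].

    Spacing is 1/(oversample * span) so adjacent grid points differ by
    1/oversample cycles over the observation span.
    """
    span = float(time_months[-1] - time_months[0])
    if span <= 0:
        raise ValueError("time axis must span a positive interval")
    df = 1.0 / (oversample * span)
    return np.arange(1.0 / max_period, 1.0 / min_period + df / 2, df)


def scan_series(
    values: np.ndarray,
    time_months: np.ndarray,
    min_period: float = DEFAULT_MIN_PERIOD,
    max_period: float = DEFAULT_MAX_PERIOD,
    oversample: int = DEFAULT_OVERSAMPLE,
    max_sig_period: float = MAX_SIGNIFICANT_PERIOD,
    n_indep: float | None = None,
    code: str = "",
) -> PeriodogramResult:
    """Periodogram + false-alarm p for one series (time in months)."""
    f = period_grid(time_months, min_period, max_period, oversample)
    power = lomb_scargle(values, time_months, f)
    # Press's convention: a grid of n_out frequencies built with oversampling
    # factor `ofac` carries ~2 n_out / ofac effectively independent
    # frequencies (= N when the grid runs from ~0 to the Nyquist frequency).
    m = float(n_indep) if n_indep is not None else max(2.0 * f.size / oversample, 1.0)
    i = int(np.argmax(power))
    best_period = 1.0 / f[i]
    best_power = float(power[i])
    p = 1.0 if best_period > max_sig_period else false_alarm_p(best_power, m)
    return PeriodogramResult(
        code=code, frequencies=f, power=power, best_period=best_period,
        best_power=best_power, p_value=p, n_indep=m,
    )


def _iter_series(
    adjusted, stage: str
) -> Iterable[tuple[str, np.ndarray, np.ndarray]]:
    """Yield (code, values, time_months) from the accepted input shapes."""
    if isinstance(adjusted, pd.DataFrame):
        if isinstance(adjusted.columns, pd.PeriodIndex):
            months = adjusted.columns
            t = np.asarray(months.year + (months.month - 0.5) / 12.0, float) * 12.0
        else:
            t = np.asarray(adjusted.columns, float)
        for code, row in adjusted.iterrows():
            yield str(code), row.to_numpy(float), t
        return
    if isinstance(adjusted, Mapping):
        adjusted = adjusted.values()
    for a in adjusted:
        if not isinstance(a, AdjustedSeries):
            raise TypeError(f"expected AdjustedSeries, got {type(a).__name__}")
        yield a.code, a.series(stage), a.time * 12.0


def scan_all(
    adjusted,
    stage: str = "detotaled",
    min_period: float = DEFAULT_MIN_PERIOD,
    max_period: float = DEFAULT_MAX_PERIOD,
    oversample: int = DEFAULT_OVERSAMPLE,
    max_sig_period: float = MAX_SIGNIFICANT_PERIOD,
    p_threshold: float = 0.01,
    n_indep: float | None = None,
) -> pd.DataFrame:
    """Scan every series and control FDR across codes.

    ``adjusted`` may be a matrix (codes x months, as produced by
    :meth:`TrendAdjuster.transform`), a mapping of code -> AdjustedSeries,
    or an iterable of AdjustedSeries.

    Returns a frame with columns code, best_period, best_power, p_value,
    bh_q, significant — sorted by p-value.
    """
    rows = []
    for code, values, tm in _iter_series(adjusted, stage):
        r = scan_series(
            values, tm, min_period=min_period, max_period=max_period,
            oversample=oversample, max_sig_period=max_sig_period,
            n_indep=n_indep, code=code,
        )
        rows.append((code, r.best_period, r.best_power, r.p_value))
    if not rows:
        raise ValueError("no series to scan")
    out = pd.DataFrame(rows, columns=["code", "best_period", "best_power", "p_value"])
    out["bh_q"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = (out["p_value"] < p_threshold) & (
        out["best_period"] <= max_sig_period
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


class PeriodicityScanner(BaseEstimator):
    """Estimator wrapper for the per-code periodicity scan.

    Parameters mirror :func:`scan_all`.  After ``fit``, ``results_`` holds
    the per-code scan table and ``n_significant_`` the number of codes
    flagged at ``p_threshold`` within the admissible period range.
    """

    def __init__(
        self,
        stage: str = "detotaled",
        min_period: float = DEFAULT_MIN_PERIOD,
        max_period: float = DEFAULT_MAX_PERIOD,
        oversample: int = DEFAULT_OVERSAMPLE,
        max_sig_period: float = MAX_SIGNIFICANT_PERIOD,
        p_threshold: float = 0.01,
        n_indep: float | None = None,
    ):
        self.stage = stage
        self.min_period = min_period
        self.max_period = max_period
        self.oversample = oversample
        self.max_sig_period = max_sig_period
        self.p_threshold = p_threshold
        self.n_indep = n_indep

    def fit(self, X, y=None) -> "PeriodicityScanner":
        self.results_ = scan_all(
            X, stage=self.stage, min_period=self.min_period,
            max_period=self.max_period, oversample=self.oversample,
            max_sig_period=self.max_sig_period, p_threshold=self.p_threshold,
            n_indep=self.n_indep,
        )
        self.n_significant_ = int(self.results_["significant"].sum())
        return self

    def significant_codes(self) -> list[str]:
        return list(self.results_.loc[self.results_["significant"], "code"])
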