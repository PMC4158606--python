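"""Synthetic EHR generators with the statistical structure of hospital data.

Two confounds dominate real monthly diagnosis-count series: a multi-year
secular growth in total events, and a shared ~6-month oscillation in total
hospital visits (spring and fall admission peaks).  The matrix generator
reproduces both, lets callers plant per-code periodic signals of known
period/phase/amplitude, and can generate "chronic" codes that are a fixed
proportion of the total — the mechanism by which shared hospital seasonality
masquerades as disease seasonality.

Counts are sampled first and events materialized from them afterwards, so
the truth table is exact and aggregation round-trips are testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import MonthlyCounts

__all__ = [
    "PlantedSignal",
    "SimConfig",
    "SimOutput",
    "simulate_counts",
    "simulate_comorbidity_cohort",
]


@dataclass(frozen=True)
class PlantedSignal:
    """A per-code periodic incidence signal.

    amplitude is the fractional modulation of the mean (0.3 means +/-30%);
    phase is in months (peak shifted right by ``phase``).
    """

    code_index: int
    period: float  # months
    phase: float = 0.0  # months
    amplitude: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.amplitude < 1:
            raise ValueError("amplitude must be in [0, 1)")
        if self.period < 2:
            raise ValueError("period must be >= 2 months")


@dataclass
class SimConfig:
    """Configuration for the monthly-count simulator.

    Defaults emulate the study conditions the package targets: a 13-year
    monthly axis (1997-2009), total events roughly doubling over 12 years,
    and a 6-month oscillation of ~10% amplitude shared by all codes through
    the total-visits factor.
    """

    n_codes: int = 10
    months: int = 156
    start: str = "1997-01"
    baseline_rates: float | Sequence[float] = 100.0
    growth_doubling_years: float | None = 12.0  # None disables growth
    total_season_amplitude: float = 0.1
    total_season_period: float = 6.0
    total_season_phase: float = 0.0  # months
    planted_signals: Sequence[PlantedSignal] = field(default_factory=tuple)
    chronic_fraction: Mapping[int, float] = field(default_factory=dict)
    patient_reuse: float = 0.0  # prob. of a duplicate same-month event per patient
    seed: int = 0

    def __post_init__(self) -> None:
        rates = np.broadcast_to(np.asarray(self.baseline_rates, float), (self.n_codes,))
        if (rates <= 0).any():
            raise ValueError("baseline_rates must be > 0")
        if not 0 <= self.total_season_amplitude < 1:
            raise ValueError("total_season_amplitude must be in [0, 1)")
        if self.total_season_period < 2:
            raise ValueError("total_season_period must be >= 2 months")
        planted = {s.code_index for s in self.planted_signals}
        chronic = set(self.chronic_fraction)
        if planted & chronic:
            raise ValueError(
                f"codes {sorted(planted & chronic)} are both planted and chronic"
            )
        for idx in planted | chronic:
            if not 0 <= idx < self.n_codes:
                raise ValueError(f"code index {idx} out of range")
        for frac in self.chronic_fraction.values():
            if not 0 < frac < 1:
                raise ValueError("chronic fractions must be in (0, 1)")

    @property
    def rates(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.baseline_rates, float), (self.n_codes,)
        ).copy()

    @property
    def code_labels(self) -> list[str]:
        return [f"C{i:04d}" for i in range(self.n_codes)]


@dataclass
class SimOutput:
    events: pd.DataFrame | None  # patient_id, code, date; None if not materialized
    truth: pd.DataFrame  # per-code planted period/phase/amplitude or kind marker
    counts: MonthlyCounts  # exact aggregation of events
    means: np.ndarray  # noiseless Poisson means, codes x months


def _cos(t: np.ndarray, period: float, phase: float, amplitude: float) -> np.ndarray:
    return 1.0 + amplitude * np.cos(2 * np.pi * (t - phase) / period)


def expected_means(config: SimConfig) -> np.ndarray:
    """Noiseless per-code monthly means implied by the configuration."""
    t = np.arange(config.months, dtype=float)
    growth = np.ones_like(t)
    if config.growth_doubling_years is not None:
        growth = 1.0 + t / (12.0 * config.growth_doubling_years)
    shared = _cos(
        t,
        config.total_season_period,
        config.total_season_phase,
        config.total_season_amplitude,
    )
    mu = np.outer(config.rates, growth * shared)
    for sig in config.planted_signals:
        mu[sig.code_index] *= _cos(t, sig.period, sig.phase, sig.amplitude)
    chronic = sorted(config.chronic_fraction)
    if chronic:
        others = np.ones(config.n_codes, bool)
        others[chronic] = False
        base_total = mu[others].sum(axis=0)
        for idx in chronic:
            mu[idx] = config.chronic_fraction[idx] * base_total
    if (mu < 0).any():
        raise ValueError("implied means are negative; amplitudes too large")
    return mu


def _materialize_events(
    config: SimConfig, values: np.ndarray, months: pd.PeriodIndex, rng: np.random.Generator
) -> pd.DataFrame:
    codes = config.code_labels
    recs: list[tuple[str, str, str]] = []
    for ci, code in enumerate(codes):
        for mi, month in enumerate(months):
            k = int(values[ci, mi])
            if k == 0:
                continue
            days = rng.integers(0, month.days_in_month, size=k) + 1
            dup = rng.random(k) < config.patient_reuse
            for j in range(k):
                pid = f"P{ci}_{mi}_{j}"
                date = f"{month}-{days[j]:02d}"
                recs.append((pid, code, date))
                if dup[j]:  # duplicate same-month event: count must not change
                    d2 = int(rng.integers(0, month.days_in_month)) + 1
                    recs.append((pid, code, f"{month}-{d2:02d}"))
    return pd.DataFrame(recs, columns=["patient_id", "code", "date"])


def simulate_counts(config: SimConfig, materialize_events: bool = True) -> SimOutput:
    """Draw a code x month count matrix (and optionally its event table).

    Monthly counts are Poisson with mean
    ``baseline * growth(t) * (1 + A_tot cos) * (1 + A_code cos)``;
    chronic-fraction codes instead get ``fraction * (sum of other codes'
    means)`` so they track the total exactly up to Poisson noise.
    """
    rng = np.random.default_rng(config.seed)
    mu = expected_means(config)
    values = rng.poisson(mu)
    months = pd.period_range(config.start, periods=config.months, freq="M")
    counts = MonthlyCounts(
        pd.DataFrame(values, index=config.code_labels, columns=months)
    )

    kind = np.array(["none"] * config.n_codes, dtype=object)
    period = np.full(config.n_codes, np.nan)
    phase = np.full(config.n_codes, np.nan)
    amplitude = np.full(config.n_codes, np.nan)
    for sig in config.planted_signals:
        kind[sig.code_index] = "planted"
        period[sig.code_index] = sig.period
        phase[sig.code_index] = sig.phase
        amplitude[sig.code_index] = sig.amplitude
    for idx in config.chronic_fraction:
        kind[idx] = "chronic"
    truth = pd.DataFrame(
        {"code": config.code_labels, "kind": kind, "period": period,
         "phase": phase, "amplitude": amplitude}
    ).set_index("code")

    events = None
    if materialize_events:
        events = _materialize_events(config, values, months, rng)
    return SimOutput(events=events, truth=truth, counts=counts, means=mu)


def simulate_comorbidity_cohort(
    n_cases: int,
    n_controls: int,
    conditions: Sequence[str],
    effect: Mapping[str, tuple[float, float]],
    window_days: int = 60,
    seed: int = 0,
    exact: bool = False,
    query_code: str = "Q",
    control_code: str = "CTRL",
    index_start: str = "2005-01-01",
    index_span_days: int = 730,
) -> pd.DataFrame:
    """Event table for a case/control comorbidity screen with known effects.

    Each case patient gets one index event of ``query_code`` and each control
    one of ``control_code``; for every candidate condition, patients acquire
    one event uniformly placed in the ``window_days`` days before their index
    date, with per-arm probabilities from ``effect`` (case, control).  With
    ``exact=True`` exactly ``round(p * n)`` patients per arm get the
    condition, making downstream counts deterministic.
    """
    rng = np.random.default_rng(seed)
    for cond in conditions:
        p_case, p_ctrl = effect.get(cond, (0.0, 0.0))
        if not (0 <= p_case <= 1 and 0 <= p_ctrl <= 1):
            raise ValueError(f"incidences for {cond} must be in [0, 1]")
    start = pd.Timestamp(index_start)
    recs: list[tuple[str, str, str]] = []

    def _arm(prefix: str, n: int, arm_code: str, which: int) -> list[pd.Timestamp]:
        idx_dates = []
        offsets = rng.integers(0, index_span_days, size=n)
        for i in range(n):
            pid = f"{prefix}{i:05d}"
            d = start + pd.Timedelta(days=int(offsets[i]))
            idx_dates.append(d)
            recs.append((pid, arm_code, d.date().isoformat()))
        for cond in conditions:
            p = effect.get(cond, (0.0, 0.0))[which]
            if exact:
                hit = np.zeros(n, bool)
                hit[: int(round(p * n))] = True
            else:
                hit = rng.random(n) < p
            lags = rng.integers(1, window_days + 1, size=n)
            for i in np.flatnonzero(hit):
                d = idx_dates[i] - pd.Timedelta(days=int(lags[i]))
                recs.append((f"{prefix}{i:05d}", cond, d.date().isoformat()))
        return idx_dates

    _arm("CASE", n_cases, query_code, 0)
    _arm("CTRL", n_controls, control_code, 1)
    return pd.DataFrame(recs, columns=["patient_id", "code", "date"])
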