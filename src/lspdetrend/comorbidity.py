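"""Windowed case/control comorbidity screen.

Given a query diagnosis (e.g. an acute exacerbation code) and one or more
control diagnoses chosen to be clinically unrelated, the screen asks which
other conditions occur disproportionately in the 60 days *before* a
patient's first query event, relative to the same window before control
patients' index events.  The reported effect size is the incidence ratio

    (case patients with condition / case cohort size)
    / (control patients with condition / control cohort size)

with a -1 sentinel when the control count is zero, and a two-sided Fisher
exact test on the 2x2 table for significance.  Screens against multiple
controls are intersected: a condition must be significant against every
control to survive, which guards against artifacts of any one control's
patient mix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.base import BaseEstimator

from .ingest import events_frame, _parse_dates
from .periodicity import bh_adjust

__all__ = [
    "CohortSpec",
    "incidence_ratio",
    "build_cohorts",
    "screen",
    "intersect_controls",
    "ComorbidityScreen",
]


@dataclass(frozen=True)
class CohortSpec:
    """Query/control codes and the look-back window in days."""

    query: str
    controls: tuple[str, ...]
    window_days: int = 60

    def __post_init__(self) -> None:
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")
        if not self.controls:
            raise ValueError("at least one control code is required")
        if self.query in self.controls:
            raise ValueError("query code cannot also be a control")


def incidence_ratio(a: int, n1: int, b: int, n2: int) -> float:
    """Case/control incidence ratio with the -1 sentinel for b == 0."""
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValueError("counts must satisfy 0 <= a <= n1 and 0 <= b <= n2")
    if b == 0:
        return -1.0
    return (a / n1) / (b / n2)


def _first_occurrence(events: pd.DataFrame, code: str) -> pd.Series:
    """patient_id -> date of first event with ``code``."""
    sub = events.loc[events["code"] == code]
    return sub.groupby("patient_id")["_date"].min()


def build_cohorts(
    events, spec: CohortSpec
) -> tuple[pd.Series, list[pd.Series]]:
    """Index dates (first query/control occurrence) per patient.

    Patients appearing in both the case cohort and a control cohort are
    removed from the control.  Returns (case index dates, list of control
    index dates), each a Series mapping patient_id -> Timestamp.
    """
    ev = events_frame(events)
    ev = ev.assign(_date=_parse_dates(ev))
    case = _first_occurrence(ev, spec.query)
    if case.empty:
        raise ValueError(f"no patients with query code {spec.query}")
    controls = []
    for ctrl in spec.controls:
        idx = _first_occurrence(ev, ctrl)
        idx = idx.drop(index=case.index, errors="ignore")
        if idx.empty:
            raise ValueError(f"no patients left in control cohort {ctrl}")
        controls.append(idx)
    return case, controls


def _window_counts(
    ev: pd.DataFrame, index_dates: pd.Series, window_days: int
) -> pd.Series:
    """condition code -> distinct patients with an event in [index-w, index)."""
    sub = ev.loc[ev["patient_id"].isin(index_dates.index)].copy()
    sub["_index"] = sub["patient_id"].map(index_dates)
    delta = (sub["_index"] - sub["_date"]).dt.days
    # half-open window: events on the index day are consequences, not antecedents
    hit = sub.loc[(delta > 0) & (delta <= window_days)]
    return hit.groupby("code")["patient_id"].nunique()


def screen(
    events,
    case_index: pd.Series,
    control_index: pd.Series,
    spec: CohortSpec,
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-condition co-occurrence table for one case/control pair.

    Columns: condition, a, n1, inc_case, b, n2, inc_ctrl, ratio, p, bh_q —
    sorted by Fisher exact p ascending.
    """
    if case_index.empty or control_index.empty:
        raise ValueError("cohorts must be non-empty")
    ev = events_frame(events)
    ev = ev.assign(_date=_parse_dates(ev))
    skip = {spec.query, *spec.controls, *exclude}
    ev = ev.loc[~ev["code"].isin(skip)]
    n1, n2 = len(case_index), len(control_index)
    a_counts = _window_counts(ev, case_index, spec.window_days)
    b_counts = _window_counts(ev, control_index, spec.window_days)
    conditions = sorted(set(a_counts.index) | set(b_counts.index))
    rows = []
    for cond in conditions:
        a = int(a_counts.get(cond, 0))
        b = int(b_counts.get(cond, 0))
        table = [[a, n1 - a], [b, n2 - b]]
        p = fisher_exact(table, alternative="two-sided")[1]
        rows.append(
            (cond, a, n1, a / n1, b, n2, b / n2, incidence_ratio(a, n1, b, n2), p)
        )
    out = pd.DataFrame(
        rows,
        columns=["condition", "a", "n1", "inc_case", "b", "n2", "inc_ctrl",
                 "ratio", "p"],
    )
    out["bh_q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def intersect_controls(
    results: Sequence[pd.DataFrame], p_threshold: float = 0.05, report: int = 0
) -> pd.DataFrame:
    """Conditions significant against every control.

    The returned rows carry the statistics of ``results[report]`` (the
    first-listed control by default).
    """
    if len(results) < 2:
        raise ValueError("intersection needs at least 2 control screens")
    keep = set(results[0].loc[results[0]["p"] < p_threshold, "condition"])
    for res in results[1:]:
        keep &= set(res.loc[res["p"] < p_threshold, "condition"])
    if not keep:
        warnings.warn("no condition is significant against every control", stacklevel=2)
    ref = results[report]
    return ref.loc[ref["condition"].isin(keep)].reset_index(drop=True)


class ComorbidityScreen(BaseEstimator):
    """Estimator form of the windowed comorbidity screen.

    Parameters
    ----------
    query : str
        Index-event diagnosis code.
    controls : sequence of str
        Control diagnosis codes (>= 1); results are intersected across them.
    window_days : int, default 60
        Look-back window before the index event.
    p_threshold : float, default 0.05
        Per-control significance cut used for the intersection.
    exclude : sequence of str, default ()
        Condition codes to drop from the candidate list (e.g. known direct
        consequences of the query condition).

    Attributes
    ----------
    case_index_ : Series patient_id -> index date
    control_indices_ : list of Series
    per_control_ : list of per-control screen tables
    results_ : intersection table (statistics of the first control)
    """

    def __init__(
        self,
        query: str,
        controls: Sequence[str] = (),
        window_days: int = 60,
        p_threshold: float = 0.05,
        exclude: Sequence[str] = (),
    ):
        self.query = query
        self.controls = controls
        self.window_days = window_days
        self.p_threshold = p_threshold
        self.exclude = exclude

    def fit(self, X, y=None) -> "ComorbidityScreen":
        spec = CohortSpec(
            query=self.query, controls=tuple(self.controls),
            window_days=self.window_days,
        )
        case, controls = build_cohorts(X, spec)
        self.case_index_ = case
        self.control_indices_ = controls
        self.per_control_ = [
            screen(X, case, ctrl, spec, exclude=self.exclude) for ctrl in controls
        ]
        if len(self.per_control_) >= 2:
            self.results_ = intersect_controls(
                self.per_control_, p_threshold=self.p_threshold
            )
        else:
            only = self.per_control_[0]
            self.results_ = only.loc[only["p"] < self.p_threshold].reset_index(
                drop=True
            )
        return self
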