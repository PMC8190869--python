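"""Liver-metastasis-free survival: Kaplan–Meier curves and log-rank tests.

Times are follow-up days from surgery; the event is the first liver
metastasis, and patients without one are right-censored at their last
follow-up.  Estimation and testing are delegated to lifelines; this module
wraps them in the small containers the rest of the pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from ._errors import ValidationError

DAYS_PER_YEAR = 365.0


@dataclass
class SurvivalCurve:
    """Product-limit estimate with its risk table."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    median: float

    def rate_at(self, t: float) -> float:
        """Right-continuous step evaluation S(t)."""
        if t < 0:
            raise ValidationError("time must be non-negative")
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "at_risk": self.at_risk,
            "events": self.events,
            "survival": self.survival,
        })


def kaplan_meier(times, events) -> SurvivalCurve:
    """Kaplan–Meier estimate of event-free survival.

    ``events`` is 1 for an observed event, 0 for censoring; ties at a time
    are simultaneous events, with censoring at the same time processed after
    the events.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t < 0).any():
        raise ValidationError("negative follow-up time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    surv = kmf.survival_function_at_times(ev.index.to_numpy()).to_numpy()
    median = float(kmf.median_survival_time_)
    return SurvivalCurve(
        event_times=ev.index.to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        events=ev["observed"].to_numpy(dtype=int),
        survival=surv,
        median=median,
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float, bool]:
    """Two-group log-rank test; returns (chi_square, p, degenerate).

    With no events in either group the test is undefined: p = 1 with the
    degenerate flag set.
    """
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if len(ea) == 0 or len(eb) == 0:
        raise ValidationError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return 0.0, 1.0, True
    res = _ll_logrank(
        np.asarray(times_a, float), np.asarray(times_b, float),
        event_observed_A=ea, event_observed_B=eb,
    )
    return float(res.test_statistic), float(res.p_value), False


def survival_rate_at(curve: SurvivalCurve, t: float) -> float:
    """S(t) of a fitted curve (right-continuous step function)."""
    return curve.rate_at(t)


def lim_free_survival(
    samples: pd.DataFrame,
    groups: pd.Series | None = None,
) -> dict:
    """LIM-free survival summary for one primary-tumor sample per patient.

    Uses the ``followup_days``/``lim_event`` sample-sheet fields.  When
    ``groups`` (sample_id -> bool, e.g. predicted LIM-positive) is given,
    also fits per-group curves and the log-rank comparison.
    """
    prim = samples[(samples["tissue"] == "primary")
                   & samples["followup_days"].notna()
                   & samples["lim_event"].notna()]
    t = prim["followup_days"].to_numpy(dtype=float)
    e = prim["lim_event"].astype(bool).to_numpy().astype(int)
    out = {"overall": kaplan_meier(t, e), "n": len(prim)}
    if groups is not None:
        g = groups.reindex(prim["sample_id"]).astype(bool).to_numpy()
        if g.all() or not g.any():
            out["logrank"] = (np.nan, np.nan, True)
        else:
            out["curve_pos"] = kaplan_meier(t[g], e[g])
            out["curve_neg"] = kaplan_meier(t[~g], e[~g])
            out["logrank"] = logrank_test(t[g], e[g], t[~g], e[~g])
    return out
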