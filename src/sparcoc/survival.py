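"""Survival analysis: Kaplan-Meier curves and the two-group log-rank test.

The Kaplan-Meier fit is delegated to lifelines; the log-rank statistic is
computed directly from the observed-minus-expected event counts with the
hypergeometric variance at each distinct event time, and referred to a
chi-square distribution with one degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats


@dataclass
class SurvivalTable:
    """Right-censored follow-up for a set of samples.

    ``time`` is follow-up in months (any consistent unit works); ``event`` is
    1 if death was observed at ``time`` and 0 if the subject was censored.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if not (len(self.sample_ids) == self.time.size == self.event.size):
            raise ValueError("sample_ids, time and event must have equal length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in survival table")
        if not np.all(np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValueError("survival times must be finite and nonnegative")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return self.time.size

    def select(self, mask: np.ndarray) -> "SurvivalTable":
        mask = np.asarray(mask, dtype=bool)
        return SurvivalTable(
            [s for s, keep in zip(self.sample_ids, mask) if keep],
            self.time[mask],
            self.event[mask],
        )


def truncate_survival(table: SurvivalTable, horizon: float) -> SurvivalTable:
    """Administratively censor follow-up at ``horizon``.

    Subjects with follow-up beyond the horizon are censored at the horizon;
    e.g. ``horizon=60`` turns overall survival into 5-year survival when time
    is in months.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    time = np.minimum(table.time, horizon)
    event = np.where(table.time > horizon, 0, table.event)
    return SurvivalTable(list(table.sample_ids), time, event)


@dataclass
class KaplanMeierCurve:
    """Right-continuous product-limit survival estimate S(t).

    ``times`` are the distinct event times; ``survival`` the value of S just
    after each of them.  Callable: ``curve(t)`` evaluates the step function.
    """

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate([[1.0], self.survival])
        out = padded[idx]
        return float(out) if out.ndim == 0 else out


def km_estimate(table: SurvivalTable) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator of the survival function."""
    if len(table) == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(table.time, event_observed=table.event)
    event_times = np.unique(table.time[table.event == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    return KaplanMeierCurve(times=event_times, survival=surv)


def logrank_test(table: SurvivalTable, group_labels: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank test.

    At every distinct event time t the number of events in group 1 is
    compared with its expectation under the null (events distributed
    proportionally to the numbers at risk), and the hypergeometric variance
    is accumulated.  The statistic (sum O-E)^2 / (sum V) is referred to
    chi-square with 1 df.

    Returns ``(chi2_statistic, p_value)``.  If the data contain no events at
    all the test is undefined; ``(0.0, 1.0)`` is returned with a warning.
    """
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"need exactly two groups, got {groups.size}")
    in1 = labels == groups[0]
    if table.event.sum() == 0:
        warnings.warn("no events observed; log-rank test undefined, returning p=1")
        return 0.0, 1.0

    event_times = np.unique(table.time[table.event == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = table.time >= t
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        died = (table.time == t) & (table.event == 1)
        d = died.sum()
        d1 = (died & in1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        warnings.warn("zero log-rank variance; returning p=1")
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
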