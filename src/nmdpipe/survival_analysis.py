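"""Lifespan assay statistics: Kaplan-Meier curves, log-rank (Mantel-Cox) test.

Censored animals (crawled off, ruptured, bagged, burrowed) stay in the risk
set through their censoring day: when deaths and censorings share a day,
deaths are processed first. Days are nonnegative; integer days are the norm
(animals scored on transfer days) but fractional input is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

EVENT_DEATH = "death"
EVENT_CENSORED = "censored"


@dataclass(frozen=True)
class SurvivalRecord:
    animal_id: str
    group: str
    day: float
    event: str  # "death" or "censored"

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"{self.animal_id}: negative day {self.day}")
        if self.event not in (EVENT_DEATH, EVENT_CENSORED):
            raise ValueError(f"{self.animal_id}: event must be 'death' or 'censored'")


@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival estimate at each distinct death time."""

    group: str
    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    events: tuple[int, ...]


@dataclass(frozen=True)
class LogRankResult:
    chi2: Optional[float]
    df: int
    p: Optional[float]
    observed: dict
    expected: dict


@dataclass(frozen=True)
class LifespanSummary:
    group: str
    mean_lifespan: Optional[float]
    sem: Optional[float]
    n_deaths: int
    n_censored: int
    pct_change: Optional[float]


def _group_arrays(
    records: Iterable[SurvivalRecord], group: str
) -> tuple[np.ndarray, np.ndarray]:
    rows = [(r.day, r.event == EVENT_DEATH) for r in records if r.group == group]
    if not rows:
        raise ValueError(f"no records for group {group!r}")
    days = np.array([d for d, _ in rows], dtype=float)
    died = np.array([e for _, e in rows], dtype=bool)
    return days, died


def km_estimate(records: Iterable[SurvivalRecord], group: str) -> KmCurve:
    """Kaplan-Meier product-limit estimate for one group.

    Censored animals leave the risk set after their day (they remain at risk
    for same-day deaths).
    """
    days, died = _group_arrays(records, group)
    death_times = np.unique(days[died])
    times, survival, at_risk, events = [], [], [], []
    s = 1.0
    for t in death_times:
        n_risk = int(np.sum(days >= t))  # same-day censorings still at risk
        d = int(np.sum(died & (days == t)))
        s *= 1.0 - d / n_risk
        times.append(float(t))
        survival.append(s)
        at_risk.append(n_risk)
        events.append(d)
    return KmCurve(
        group=group,
        times=tuple(times),
        survival=tuple(survival),
        at_risk=tuple(at_risk),
        events=tuple(events),
    )


def logrank_statistic(
    days_a: np.ndarray, died_a: np.ndarray, days_b: np.ndarray, died_b: np.ndarray
) -> tuple[Optional[float], float, float]:
    """Mantel-Cox chi-square for two groups from raw day/event arrays.

    At each distinct death time the expected deaths in group A come from the
    hypergeometric model on the pooled risk set; the statistic is
    (sum(O_A - E_A))^2 / sum(V). Returns ``(chi2, observed_a, expected_a)``;
    chi2 is None when there are no deaths.
    """
    all_days = np.concatenate([days_a, days_b])
    all_died = np.concatenate([died_a, died_b])
    death_times, d = np.unique(all_days[all_died], return_counts=True)
    if death_times.size == 0:
        return None, 0.0, 0.0
    d = d.astype(float)
    sorted_all = np.sort(all_days)
    sorted_a = np.sort(days_a)
    # risk-set sizes just before each death time (same-day censorings included)
    n_at = len(all_days) - np.searchsorted(sorted_all, death_times, side="left")
    na_at = len(days_a) - np.searchsorted(sorted_a, death_times, side="left")
    d_a = np.zeros(death_times.size)
    times_a, counts_a = np.unique(days_a[died_a], return_counts=True)
    d_a[np.searchsorted(death_times, times_a)] = counts_a
    frac_a = na_at / n_at
    e_a = d * frac_a
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(
            n_at > 1, d * frac_a * (1 - frac_a) * (n_at - d) / (n_at - 1), 0.0
        )
    observed_a = float(d_a.sum())
    expected_a = float(e_a.sum())
    var = float(v.sum())
    if var == 0.0:
        return 0.0, observed_a, expected_a
    return float((d_a - e_a).sum() ** 2 / var), observed_a, expected_a


def logrank_test(
    records: Iterable[SurvivalRecord], group_a: str, group_b: str
) -> LogRankResult:
    """Two-group log-rank (Mantel-Cox) test; two-sided p from chi-square(1)."""
    records = list(records)
    days_a, died_a = _group_arrays(records, group_a)
    days_b, died_b = _group_arrays(records, group_b)
    total_deaths = int(died_a.sum() + died_b.sum())
    if total_deaths == 0:
        return LogRankResult(
            chi2=None, df=1, p=None,
            observed={group_a: 0, group_b: 0}, expected={group_a: 0.0, group_b: 0.0},
        )
    chi2, obs_a, exp_a = logrank_statistic(days_a, died_a, days_b, died_b)
    p = float(stats.chi2.sf(chi2, 1)) if chi2 is not None else None
    return LogRankResult(
        chi2=chi2,
        df=1,
        p=p,
        observed={group_a: float(obs_a), group_b: float(total_deaths - obs_a)},
        expected={group_a: float(exp_a), group_b: float(total_deaths - exp_a)},
    )


def summarize_lifespan(
    records: Iterable[SurvivalRecord],
    group: str,
    reference_group: Optional[str] = None,
) -> LifespanSummary:
    """Mean lifespan over death events only; censored animals counted separately."""
    records = list(records)
    days, died = _group_arrays(records, group)
    deaths = days[died]
    n_deaths = int(died.sum())
    n_censored = int((~died).sum())
    if n_deaths == 0:
        return LifespanSummary(group, None, None, 0, n_censored, None)
    mean = float(deaths.mean())
    sem = float(deaths.std(ddof=1) / np.sqrt(n_deaths)) if n_deaths > 1 else None
    pct = None
    if reference_group is not None:
        ref_days, ref_died = _group_arrays(records, reference_group)
        if ref_died.any():
            ref_mean = float(ref_days[ref_died].mean())
            pct = 100.0 * (mean - ref_mean) / ref_mean
    return LifespanSummary(group, mean, sem, n_deaths, n_censored, pct)


def records_from_arrays(
    days: Sequence[float], died: Sequence[bool], group: str, prefix: str = "w"
) -> list[SurvivalRecord]:
    """Convenience constructor used by simulations and tests."""
    return [
        SurvivalRecord(
            animal_id=f"{group}-{prefix}{i}",
            group=group,
            day=float(d),
            event=EVENT_DEATH if e else EVENT_CENSORED,
        )
        for i, (d, e) in enumerate(zip(days, died))
    ]
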