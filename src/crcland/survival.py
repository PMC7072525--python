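"""Product-limit survival estimation and nonparametric group comparison.

The Kaplan-Meier estimate is computed through lifelines'
``KaplanMeierFitter`` (Greenwood variance, log(-log) confidence bands).
Median overall survival follows the standard convention: the smallest time
at which the estimated survival function reaches 0.5 or below; it is
``None`` when the curve never gets there. Censored subjects remain at risk
at their own time (censored-after-events-at-equal-times convention).

The two-group comparison is the Mantel-Haenszel log-rank test; the tally
of observed and expected events per group also yields the O/E hazard
ratio (O1/E1)/(O2/E2) with a log-scale 95% interval. The multivariate Cox
model is deliberately not re-implemented here; use lifelines' CoxPHFitter
directly for adjusted hazard ratios.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .records import ClinicalRecord

__all__ = [
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "logrank_test",
    "compare_strata",
]


@dataclass
class KMCurve:
    """A fitted product-limit curve for one stratum."""

    event_times: np.ndarray        # distinct event times, ascending
    at_risk: np.ndarray            # subjects at risk just before each time
    events: np.ndarray             # deaths at each time
    survival: np.ndarray           # S(t) just after each event time
    median_os: float | None        # months; None if S never reaches 0.5
    ci_lower: np.ndarray           # pointwise 95% band (Greenwood/log-log)
    ci_upper: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t."""
        s = 1.0
        for time, surv in zip(self.event_times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s


def km_estimate(records: Sequence[tuple[float, bool]] | Sequence[ClinicalRecord]) -> KMCurve:
    """Kaplan-Meier estimate from (time, event) pairs or clinical records."""
    if len(records) == 0:
        raise ValueError("km_estimate needs at least one record")
    if isinstance(records[0], ClinicalRecord):
        times = np.array([r.os_months for r in records], dtype=float)
        events = np.array([r.event for r in records], dtype=bool)
    else:
        times = np.array([t for t, _ in records], dtype=float)
        events = np.array([e for _, e in records], dtype=bool)
    if np.any(times < 0):
        raise ValueError("survival times must be >= 0")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    mask = table["observed"].to_numpy() > 0
    event_times = table.index.to_numpy(dtype=float)[mask]
    at_risk = table["at_risk"].to_numpy(dtype=float)[mask]
    d = table["observed"].to_numpy(dtype=float)[mask]
    surv_fn = kmf.survival_function_["KM_estimate"]
    survival = np.array([surv_fn.loc[t] for t in event_times], dtype=float)
    ci = kmf.confidence_interval_
    lo = np.array([ci.iloc[:, 0].loc[t] for t in event_times], dtype=float)
    hi = np.array([ci.iloc[:, 1].loc[t] for t in event_times], dtype=float)
    med = kmf.median_survival_time_
    median_os = None if not np.isfinite(med) else float(med)
    return KMCurve(
        event_times=event_times,
        at_risk=at_risk,
        events=d,
        survival=survival,
        median_os=median_os,
        ci_lower=lo,
        ci_upper=hi,
        n=len(times),
    )


@dataclass
class LogRankResult:
    observed: tuple[float, float]   # (O1, O2)
    expected: tuple[float, float]   # (E1, E2)
    chi_square: float
    p_value: float
    hazard_ratio: float             # (O1/E1)/(O2/E2)
    hr_ci: tuple[float, float]      # log-scale 95% interval
    label_a: str = "A"
    label_b: str = "B"


def _oev(times: np.ndarray, events: np.ndarray, group: np.ndarray) -> tuple[float, float, float]:
    """Observed and expected events in group 1 and the hypergeometric
    variance, tallied over distinct event times."""
    o1 = e1 = v = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & group).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o1, e1, v


def logrank_test(
    group_a: Sequence[tuple[float, bool]],
    group_b: Sequence[tuple[float, bool]],
    label_a: str = "A",
    label_b: str = "B",
) -> LogRankResult:
    """Mantel-Haenszel log-rank comparison of two samples of
    (time, event) pairs, with the O/E hazard ratio of A versus B."""
    ta = np.array([t for t, _ in group_a], dtype=float)
    ea = np.array([e for _, e in group_a], dtype=bool)
    tb = np.array([t for t, _ in group_b], dtype=float)
    eb = np.array([e for _, e in group_b], dtype=bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups need at least one subject")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])

    o1, e1, v = _oev(times, events, group)
    o_total = float(events.sum())
    o2, e2 = o_total - o1, o_total - e1
    if v > 0:
        chi2 = (o1 - e1) ** 2 / v
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0
    if e1 > 0 and e2 > 0 and o1 > 0 and o2 > 0:
        hr = (o1 / e1) / (o2 / e2)
        se = math.sqrt(1.0 / e1 + 1.0 / e2)
        ci = (hr * math.exp(-1.959964 * se), hr * math.exp(1.959964 * se))
    elif e1 > 0 and e2 > 0:
        hr = (o1 / e1) / (o2 / e2) if o2 > 0 else math.inf
        ci = (math.nan, math.nan)
    else:
        hr, ci = math.nan, (math.nan, math.nan)
    return LogRankResult(
        observed=(float(o1), float(o2)),
        expected=(float(e1), float(e2)),
        chi_square=float(chi2),
        p_value=p,
        hazard_ratio=float(hr),
        hr_ci=ci,
        label_a=label_a,
        label_b=label_b,
    )


def compare_strata(
    records: Iterable[ClinicalRecord],
    risk_by_sample: Mapping[str, str] | None = None,
    by: Sequence[str] = ("country", "treatment", "risk"),
) -> tuple[dict[tuple, KMCurve], list[LogRankResult]]:
    """Per-stratum KM curves plus all pairwise log-rank comparisons.

    Strata are the observed combinations of the requested keys; ``risk``
    requires ``risk_by_sample`` (sample id -> "high"/"low"). Empty strata
    simply do not appear; strata with subjects but no information still get
    a curve and enter the pairwise tests.
    """
    groups: dict[tuple, list[tuple[float, bool]]] = {}
    for rec in records:
        key_parts = []
        for k in by:
            if k == "risk":
                if risk_by_sample is None:
                    raise ValueError("stratifying by risk needs risk_by_sample")
                key_parts.append(risk_by_sample.get(rec.sample_id, "NA"))
            else:
                key_parts.append(getattr(rec, k))
        groups.setdefault(tuple(key_parts), []).append((rec.os_months, rec.event))
    curves = {key: km_estimate(g) for key, g in sorted(groups.items())}
    tests = [
        logrank_test(groups[a], groups[b],
                     label_a="/".join(map(str, a)), label_b="/".join(map(str, b)))
        for a, b in itertools.combinations(sorted(groups), 2)
    ]
    return curves, tests
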