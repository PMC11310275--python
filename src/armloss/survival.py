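"""Kaplan-Meier estimation, the two-group log-rank test, and Harrell's c-index.

These are first-principles implementations (the package's analyses depend on
the exact tie conventions, which established libraries vary on), checked in
the test suite against independent oracles.

Conventions:

* Kaplan-Meier ties: events precede censorings at the same time, the
  textbook product-limit definition.
* The survival median is the smallest event time t with S(t) <= 0.5; when
  the curve plateaus above 0.5 it is undefined (None), not infinity.
* Harrell's concordance: a pair with distinct observed times is comparable
  iff the earlier time is an event; pairs with tied times are omitted
  unless exactly one is censored, in which case the event subject is
  treated as failing first.  Score ties among comparable pairs count 0.5.
* Log-rank p-values are upper-tail chi-square(1), no continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "KmCurve",
    "LogrankResult",
    "ConcordanceResult",
    "km_fit",
    "km_median_difference",
    "logrank_test",
    "harrell_cindex",
]

logger = logging.getLogger(__name__)


def _as_time_event(time: Sequence[float], event: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if t.size == 0:
        raise ValueError("empty input: at least one subject required")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and non-negative")
    if not np.all(np.isin(e, (0, 1))):
        raise ValueError("event indicators must be 0 or 1")
    return t, e


@dataclass
class KmCurve:
    """Product-limit survival estimate.

    ``event_times`` are the distinct times with at least one event, ascending;
    ``survival_prob[i]`` is S(event_times[i]); ``at_risk[i]`` and
    ``n_events[i]`` are the risk-set size and event count at that time.
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_subjects: int

    @property
    def median(self) -> float | None:
        """Smallest event time with S <= 0.5, or None if never reached."""
        below = self.survival_prob <= 0.5 + 1e-12
        if not below.any():
            return None
        return float(self.event_times[np.argmax(below)])

    def survival_at(self, times: Sequence[float]) -> np.ndarray:
        """Evaluate the step function S(t) (right-continuous) at given times."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        out = np.ones_like(t)
        mask = idx >= 0
        out[mask] = self.survival_prob[idx[mask]]
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival_prob,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


def km_fit(time: Sequence[float], event: Sequence[int]) -> KmCurve:
    """Kaplan-Meier product-limit fit: S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    Censored subjects leave the risk set after their time (events precede
    censorings at tied times).
    """
    t, e = _as_time_event(time, event)
    n = t.size
    order = np.lexsort((1 - e, t))  # by time; events (e=1) before censorings at ties
    t_sorted, e_sorted = t[order], e[order]

    event_times: list[float] = []
    surv: list[float] = []
    at_risk: list[int] = []
    n_events: list[int] = []
    s = 1.0
    i = 0
    while i < n:
        ti = t_sorted[i]
        j = i
        d = 0
        while j < n and t_sorted[j] == ti:
            d += e_sorted[j]
            j += 1
        if d > 0:
            n_i = n - i  # subjects with time >= ti still at risk
            s *= 1.0 - d / n_i
            event_times.append(ti)
            surv.append(s)
            at_risk.append(n_i)
            n_events.append(d)
        i = j
    return KmCurve(
        event_times=np.asarray(event_times),
        survival_prob=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_events, dtype=int),
        n_subjects=n,
    )


def km_median_difference(group_a: KmCurve, group_b: KmCurve) -> float | None:
    """|median_a - median_b| in years; None when either median is undefined."""
    ma, mb = group_a.median, group_b.median
    if ma is None or mb is None:
        return None
    return abs(ma - mb)


@dataclass
class LogrankResult:
    """Two-group log-rank test: chi-square statistic with 1 df and its p-value."""

    statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "p_value": self.p_value, "df": 1}


def logrank_test(
    time_a: Sequence[float],
    event_a: Sequence[int],
    time_b: Sequence[float],
    event_b: Sequence[int],
) -> LogrankResult:
    """Standard two-group log-rank test.

    At each distinct event time the observed group-a events are compared to
    the hypergeometric expectation given the pooled risk sets; the statistic
    is (sum(O_a - E_a))^2 / sum(V), referred to chi-square(1).
    """
    ta, ea = _as_time_event(time_a, event_a)
    tb, eb = _as_time_event(time_b, event_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event overall")

    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    groups = np.concatenate([np.zeros_like(ta), np.ones_like(tb)])

    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n_tot = int(at_risk.sum())
        n_a = int((at_risk & (groups == 0)).sum())
        dying = (times == t) & (events == 1)
        d_tot = int(dying.sum())
        d_a = int((dying & (groups == 0)).sum())
        if n_tot < 2:
            continue
        e_a = d_tot * n_a / n_tot
        v = d_tot * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d_tot) / (n_tot - 1)
        o_minus_e += d_a - e_a
        var += v
    if var <= 0:
        logger.warning("log-rank: zero variance (no comparable structure); statistic set to 0")
        return LogrankResult(statistic=0.0, p_value=1.0)
    stat = o_minus_e**2 / var
    p = float(stats.chi2.sf(stat, df=1))
    return LogrankResult(statistic=float(stat), p_value=max(p, np.finfo(float).tiny))


@dataclass
class ConcordanceResult:
    """Harrell concordance-index pair counts and the resulting c-index."""

    c_index: float
    n_concordant: int
    n_discordant: int
    n_tied_score: int
    n_comparable: int

    def to_dict(self) -> dict:
        return {
            "c_index": self.c_index,
            "n_concordant": self.n_concordant,
            "n_discordant": self.n_discordant,
            "n_tied_score": self.n_tied_score,
            "n_comparable": self.n_comparable,
        }


def harrell_cindex(
    time: Sequence[float], event: Sequence[int], score: Sequence[float]
) -> ConcordanceResult:
    """Harrell's concordance index for a risk score (higher = riskier).

    c = (concordant + 0.5 * score-ties) / comparable over all comparable
    pairs; see the module docstring for the comparability and tie rules.
    Raises if no pair is comparable.
    """
    t, e = _as_time_event(time, event)
    s = np.asarray(score, dtype=float)
    if s.shape != t.shape:
        raise ValueError("score must match time/event in length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")

    # Broadcast pair matrices; the (i, j) entry refers to the ordered pair in
    # which i is the candidate "fails first" subject.
    ti, tj = t[:, None], t[None, :]
    ei = e[:, None].astype(bool)
    ej = e[None, :].astype(bool)
    si, sj = s[:, None], s[None, :]

    # i fails strictly first and is an event; or times tied with i the only event
    first = (ti < tj) & ei
    tied_time = (ti == tj) & ei & ~ej
    comparable = first | tied_time
    np.fill_diagonal(comparable, False)

    conc = int(np.sum(comparable & (si > sj)))
    disc = int(np.sum(comparable & (si < sj)))
    ties = int(np.sum(comparable & (si == sj)))
    n_comp = conc + disc + ties
    if n_comp == 0:
        raise ValueError("c-index undefined: no comparable pairs")
    c = (conc + 0.5 * ties) / n_comp
    return ConcordanceResult(
        c_index=float(c),
        n_concordant=conc,
        n_discordant=disc,
        n_tied_score=ties,
        n_comparable=n_comp,
    )
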