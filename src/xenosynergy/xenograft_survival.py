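"""Engraftment time courses -> event times, EFS, growth delay and synergy.

Event-free survival (EFS) of a xenografted mouse is the number of days from
randomization until the %huCD45+ fraction in peripheral blood reaches 25%,
or until leukemia-unrelated morbidity (censored).  The leukemia growth delay
(LGD) of a treated cohort is its median EFS minus the control median EFS.
Under the log-kill additivity rule, a combination is synergistic when its
LGD exceeds the sum of the single-agent LGDs.

Kaplan-Meier estimation is delegated to :mod:`lifelines`; the exact
permutation log-rank test is implemented here (full enumeration for small
cohorts, seeded Monte-Carlo otherwise); the exact Mann-Whitney test uses
:func:`scipy.stats.mannwhitneyu` and the 2x2 outcome-stratification test the
exact conditional (hypergeometric) test, since cohort sizes of ~10 rule out
asymptotic chi-square.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.stats import fisher_exact, mannwhitneyu

from .bounded import BoundedValue, as_float

__all__ = [
    "MouseTimecourse",
    "EventRecord",
    "SynergyCall",
    "KMCurve",
    "event_time",
    "km_curve",
    "median_efs",
    "compute_lgd",
    "additivity_call",
    "exact_logrank",
    "mann_whitney_exact",
    "cutoff_contingency",
]


@dataclass(frozen=True)
class MouseTimecourse:
    """One animal's %huCD45+ series (days counted from randomization)."""

    mouse_id: str
    arm: str
    days: Sequence[float]
    values: Sequence[float]
    censor_day: float | None = None
    censor_cause: str | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.days, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if d.size != v.size:
            raise ValueError(f"{self.mouse_id}: days/values length mismatch")
        if d.size and np.any(np.diff(d) <= 0):
            raise ValueError(f"{self.mouse_id}: sample days must be increasing")
        if v.size and (v.min() < 0 or v.max() > 100):
            raise ValueError(f"{self.mouse_id}: %huCD45+ outside [0, 100]")


@dataclass(frozen=True)
class EventRecord:
    """Leukemia event (or censoring) time for one mouse."""

    mouse_id: str
    arm: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"{self.mouse_id}: negative event time")


@dataclass(frozen=True)
class SynergyCall:
    """Combination LGD versus the additive (summed single-agent) prediction.

    ``excess`` is the signed difference combination - sum(singles); it is a
    lower bound whenever the combination LGD is censored.
    """

    combo_lgd: BoundedValue
    single_lgds: tuple[BoundedValue, ...]
    additive_prediction: float
    excess: float
    excess_is_lower_bound: bool
    verdict: str


def event_time(
    tc: MouseTimecourse,
    threshold: float = 25.0,
    mode: str = "interpolate",
) -> EventRecord:
    """Convert one time course to an event record at the %huCD45+ threshold.

    ``mode="interpolate"`` places the crossing by linear interpolation
    between the bracketing samples (exact sample day when a sample equals
    the threshold, or when the first sample already exceeds it);
    ``mode="first_sample"`` uses the first sampling day at or above the
    threshold.  Series that never cross are censored at the last sample day
    (or the stated leukemia-unrelated censoring day, if earlier).
    """
    if mode not in ("interpolate", "first_sample"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    days = np.asarray(tc.days, dtype=float)
    vals = np.asarray(tc.values, dtype=float)
    if days.size == 0:
        raise ValueError(f"{tc.mouse_id}: empty %huCD45+ series")
    crossing: float | None = None
    for i, (d, v) in enumerate(zip(days, vals)):
        if v >= threshold:
            if mode == "first_sample" or v == threshold or i == 0:
                crossing = float(d)
            else:
                d0, v0 = days[i - 1], vals[i - 1]
                crossing = float(d0 + (d - d0) * (threshold - v0) / (v - v0))
            break
    if crossing is not None:
        if tc.censor_day is not None and tc.censor_day < crossing:
            return EventRecord(tc.mouse_id, tc.arm, float(tc.censor_day), False)
        return EventRecord(tc.mouse_id, tc.arm, crossing, True)
    end = float(days[-1])
    if tc.censor_day is not None:
        end = min(end, float(tc.censor_day))
    return EventRecord(tc.mouse_id, tc.arm, end, False)


@dataclass(frozen=True)
class KMCurve:
    """Right-continuous product-limit survival step function."""

    times: tuple[float, ...]        # event times where the curve steps
    survival: tuple[float, ...]     # S(t) just after each step
    last_observed: float            # end of follow-up (max time in the data)

    def __call__(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def km_curve(events: Sequence[EventRecord]) -> KMCurve:
    """Product-limit estimator for one arm (censoring shrinks the risk set)."""
    if not events:
        raise ValueError("km_curve needs at least one event record")
    times = np.array([e.time for e in events])
    flags = np.array([e.event for e in events], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=flags)
    sf = kmf.survival_function_
    step_t, step_s = [], []
    prev = 1.0
    for t, s in zip(sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float)):
        if s < prev:
            step_t.append(float(t))
            step_s.append(float(s))
            prev = s
    return KMCurve(tuple(step_t), tuple(step_s), float(times.max()))


def median_efs(curve: KMCurve) -> BoundedValue:
    """Smallest time with S(t) <= 0.5; a lower bound if never reached."""
    for t, s in zip(curve.times, curve.survival):
        if s <= 0.5 + 1e-12:
            return BoundedValue(t)
    return BoundedValue(curve.last_observed, is_lower_bound=True)


def compute_lgd(treated: BoundedValue, control: BoundedValue) -> BoundedValue:
    """LGD = treated median EFS - control median EFS, floored at zero.

    A censored (lower-bound) treated median propagates its bound; a
    lower-bound control median leaves the difference undefined and is
    rejected.
    """
    treated = BoundedValue.parse(treated)
    control = BoundedValue.parse(control)
    if control.is_lower_bound:
        raise ValueError("LGD is undefined when the control median is censored")
    return BoundedValue(max(0.0, treated.value - control.value),
                        is_lower_bound=treated.is_lower_bound)


def additivity_call(
    combo_lgd: BoundedValue,
    single_lgds: Sequence[BoundedValue],
    tolerance: float = 0.0,
) -> SynergyCall:
    """Log-kill additivity: synergy iff combination LGD exceeds the sum.

    ``tolerance`` (days) widens the additive verdict band; the default 0 is
    the strict summation rule.  A lower-bound combination LGD yields a
    lower-bound excess.
    """
    combo = BoundedValue.parse(combo_lgd)
    singles = tuple(BoundedValue.parse(s) for s in single_lgds)
    if any(s.is_lower_bound for s in singles):
        raise ValueError("additive prediction undefined with censored "
                         "single-agent LGDs")
    additive = sum(s.value for s in singles)
    excess = combo.value - additive
    if excess > tolerance:
        verdict = "synergy"
    elif excess < -tolerance:
        # a censored combination LGD below the sum cannot rule out synergy
        verdict = "indeterminate" if combo.is_lower_bound else "antagonism"
    else:
        verdict = "additive"
    return SynergyCall(combo_lgd=combo, single_lgds=singles,
                       additive_prediction=additive, excess=excess,
                       excess_is_lower_bound=combo.is_lower_bound,
                       verdict=verdict)


# --------------------------------------------------------------------------
# nonparametric tests
# --------------------------------------------------------------------------

def _logrank_stat_matrix(times: np.ndarray, flags: np.ndarray,
                         masks: np.ndarray) -> np.ndarray:
    """|O_A - E_A| for each row of ``masks`` (boolean membership of arm A)."""
    event_times = np.unique(times[flags])
    # subjects x event-times indicators
    at_risk = times[:, None] >= event_times[None, :]
    died = (times[:, None] == event_times[None, :]) & flags[:, None]
    n_t = at_risk.sum(axis=0).astype(float)
    d_t = died.sum(axis=0).astype(float)
    m = masks.astype(float)
    n_a = m @ at_risk                 # perms x event-times
    o_a = (m @ died).sum(axis=1)
    e_a = (d_t * n_a / n_t).sum(axis=1)
    return np.abs(o_a - e_a)


def exact_logrank(
    arm_a: Sequence[EventRecord],
    arm_b: Sequence[EventRecord],
    seed: int = 0,
    max_enumeration: int = 16,
    n_mc: int = 100_000,
) -> float:
    """Two-sided exact permutation log-rank p-value.

    The statistic is |observed - expected| events in arm A.  All
    ``C(n, n_A)`` group assignments are enumerated when the pooled size is
    at most ``max_enumeration``; otherwise a seeded Monte-Carlo sample of
    permutations is used with the add-one estimator.
    """
    if not arm_a or not arm_b:
        raise ValueError("both arms must be non-empty")
    if (len(arm_a) == len(arm_b) == 1
            and arm_a[0].time == arm_b[0].time
            and arm_a[0].event == arm_b[0].event):
        raise ValueError("identical single-record arms carry no information")
    pooled = list(arm_a) + list(arm_b)
    times = np.array([e.time for e in pooled])
    flags = np.array([e.event for e in pooled], dtype=bool)
    if not flags.any():
        return 1.0
    n, n_a = len(pooled), len(arm_a)
    obs_mask = np.zeros((1, n), dtype=bool)
    obs_mask[0, :n_a] = True
    t_obs = _logrank_stat_matrix(times, flags, obs_mask)[0]
    eps = 1e-9
    if n <= max_enumeration:
        combos = list(itertools.combinations(range(n), n_a))
        masks = np.zeros((len(combos), n), dtype=bool)
        for i, idx in enumerate(combos):
            masks[i, list(idx)] = True
        stats = _logrank_stat_matrix(times, flags, masks)
        return float(np.mean(stats >= t_obs - eps))
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_mc, n), dtype=bool)
    for i in range(n_mc):
        masks[i, rng.choice(n, size=n_a, replace=False)] = True
    stats = _logrank_stat_matrix(times, flags, masks)
    return float((1 + np.sum(stats >= t_obs - eps)) / (1 + n_mc))


def mann_whitney_exact(
    x: Sequence[BoundedValue | float],
    y: Sequence[BoundedValue | float],
) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test (no cross-group ties allowed).

    Lower-bound values participate at their bound, which is valid for the
    rank test whenever every bound exceeds the values it is compared to.
    """
    xv = np.array([as_float(BoundedValue.parse(v)) for v in x])
    yv = np.array([as_float(BoundedValue.parse(v)) for v in y])
    if np.intersect1d(xv, yv).size:
        raise ValueError("cross-group ties: the exact U null is undefined")
    res = mannwhitneyu(xv, yv, alternative="two-sided", method="exact")
    return float(res.statistic), float(res.pvalue)


def cutoff_contingency(
    lgds: Sequence[BoundedValue | float],
    outcomes: Sequence[str],
    cutoff: float = 55.0,
) -> tuple[np.ndarray, float]:
    """2x2 outcome-vs-cutoff table with the exact conditional two-sided p.

    Rows are outcome groups in first-appearance order, columns are
    (LGD > cutoff, LGD <= cutoff); lower-bound LGDs classify by their bound.
    The exact conditional (hypergeometric / Fisher) test replaces asymptotic
    chi-square, which is invalid at these cohort sizes.
    """
    if len(lgds) != len(outcomes):
        raise ValueError("lgds and outcomes must align")
    groups = list(dict.fromkeys(outcomes))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 outcome groups, got {groups}")
    table = np.zeros((2, 2), dtype=int)
    for lgd, outc in zip(lgds, outcomes):
        v = as_float(BoundedValue.parse(lgd))
        table[groups.index(outc), 0 if v > cutoff else 1] += 1
    _, p = fisher_exact(table, alternative="two-sided")
    return table, float(p)
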