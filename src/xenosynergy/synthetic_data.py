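"""Synthetic study generators with known ground truth.

Three generators emulate the designs every analysis stage consumes, so that
each stage has a parameter-recovery test with no external data:

* fixed-ratio cytotoxicity plates (single agents + combination, logit-normal
  replicate noise, a potency-shift factor ``phi`` on each drug's median-effect
  dose inside the combination: ``phi < 1`` means synergy and is exactly the CI
  the downstream analysis should recover);
* xenograft engraftment cohorts (exponential leukemic-burden growth measured
  as %huCD45+ of a fixed host leukocyte pool, log-kill during a dosing
  window, weekly sampling, morbidity censoring);
* sparse destructively-sampled PK datasets (one terminal plasma sample per
  animal, 3 animals per time point, single-agent vs combination arms with a
  clearance multiplier ``theta_cl``).

All generators are deterministic for a fixed seed, and their zero-noise
output matches the closed forms exposed here (``true_*`` helpers) to
round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .median_effect import DoseResponsePoint
from .pk_models import PKObservation, StructuralModel, predict_concentration
from .xenograft_survival import MouseTimecourse

__all__ = [
    "InVitroTruth",
    "InVivoTruth",
    "PKTruth",
    "gen_dose_response",
    "gen_xenograft_cohort",
    "gen_pk_dataset",
    "true_single_fa",
    "true_combo_fa",
    "true_event_time",
    "arm_kill_rate",
]


# --------------------------------------------------------------------------
# in vitro
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InVitroTruth:
    """Ground truth for fixed-ratio plates.

    ``m`` and ``dm`` are per-drug median-effect slope and 50%-effect dose
    (drug-specific units); ``ratio`` is the fixed dose ratio (dose of drug j
    at scale 1); ``phi`` shifts every ``Dm`` inside the combination
    (``phi < 1`` = synergy, and equals the CI under Loewe-type combination of
    the shifted curves); ``noise_sd`` is replicate noise on the logit of
    fractional survival; ``n_reps`` replicates per condition.
    """

    m: Mapping[str, float]
    dm: Mapping[str, float]
    ratio: Mapping[str, float]
    phi: float = 1.0
    noise_sd: float = 0.1
    n_reps: int = 12

    def __post_init__(self) -> None:
        if set(self.m) != set(self.dm) or set(self.m) != set(self.ratio):
            raise ValueError("m, dm and ratio must cover the same drugs")
        for name, vals in (("m", self.m), ("dm", self.dm), ("ratio", self.ratio)):
            for drug, v in vals.items():
                if v <= 0:
                    raise ValueError(f"{name}[{drug!r}] must be > 0, got {v}")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self.m)


def true_single_fa(truth: InVitroTruth, drug: str, dose: float) -> float:
    """Closed-form affected fraction for one drug alone."""
    odds = (dose / truth.dm[drug]) ** truth.m[drug]
    return odds / (1.0 + odds)


def true_combo_fa(truth: InVitroTruth, level: float) -> float:
    """Affected fraction of the fixed-ratio combination at scale ``level``.

    The combination responds as the Loewe-additive mixture of the single
    curves with each ``Dm_j`` replaced by ``phi * Dm_j``: ``fa`` solves

        sum_j (level * r_j) / (phi * Dm_j * (fa/fu)**(1/m_j)) = 1.

    With equal slopes the solution is closed-form; otherwise it is found by
    bisection on the log-odds.
    """
    slopes = [truth.m[d] for d in truth.drugs]
    s = sum(
        level * truth.ratio[d] / (truth.phi * truth.dm[d]) for d in truth.drugs
    )
    if np.allclose(slopes, slopes[0]):
        odds = s ** slopes[0]
        return odds / (1.0 + odds)

    log_terms = np.array([
        math.log10(level * truth.ratio[d] / (truth.phi * truth.dm[d]))
        for d in truth.drugs
    ])
    inv_m = np.array([1.0 / truth.m[d] for d in truth.drugs])

    def excess(log_odds: float) -> float:
        # exponents clipped to keep the sum finite while preserving sign
        return float(np.sum(10.0 ** np.clip(log_terms - log_odds * inv_m,
                                            -300.0, 300.0))) - 1.0

    lo = brentq(excess, -300.0, 300.0, xtol=1e-13, rtol=8.9e-16)
    odds = 10.0 ** lo
    return odds / (1.0 + odds)


def _noisy_survival(rng: np.random.Generator, s_true: float, sd: float,
                    n: int) -> np.ndarray:
    """Replicates with logit-normal noise, staying strictly inside (0, 1)."""
    if sd == 0.0:
        return np.full(n, s_true)
    s = min(max(s_true, 1e-12), 1.0 - 1e-12)
    return expit(logit(s) + rng.normal(0.0, sd, size=n))


def gen_dose_response(
    truth: InVitroTruth,
    dose_levels: Sequence[float],
    seed: int,
) -> list[DoseResponsePoint]:
    """Single-agent and combination plate conditions at each ratio scale."""
    for lam in dose_levels:
        if lam <= 0:
            raise ValueError(f"dose level {lam} is not strictly positive")
    rng = np.random.default_rng(seed)
    points: list[DoseResponsePoint] = []
    for drug in truth.drugs:
        for lam in dose_levels:
            dose = lam * truth.ratio[drug]
            fa = true_single_fa(truth, drug, dose)
            points.append(DoseResponsePoint(
                condition=drug,
                doses={drug: dose},
                survival=tuple(_noisy_survival(rng, 1.0 - fa, truth.noise_sd,
                                               truth.n_reps)),
            ))
    for lam in dose_levels:
        fa = true_combo_fa(truth, lam)
        points.append(DoseResponsePoint(
            condition="combination",
            doses={d: lam * truth.ratio[d] for d in truth.drugs},
            survival=tuple(_noisy_survival(rng, 1.0 - fa, truth.noise_sd,
                                           truth.n_reps)),
            scale=lam,
        ))
    return points


# --------------------------------------------------------------------------
# in vivo
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InVivoTruth:
    """Ground truth for xenograft engraftment cohorts.

    Leukemic burden grows as ``B(t) = B0 * 10**(g*t - K(t))`` against a fixed
    host leukocyte pool; the observed readout is ``%huCD45+ = 100*B/(B+H)``.
    ``K(t)`` accumulates log10 cell kill at rate ``sum_j k_j`` (+ ``k_int``
    when >=2 components are active) while ``t`` is inside ``window``.
    Time origin is the randomization day (treatment starts at day 6); ``f0``
    is the leukemic fraction at randomization (the 1% randomization trigger).
    """

    g: float = 0.1                      # log10 cells/day net growth
    f0: float = 1.0                     # %huCD45+ at randomization
    kills: Mapping[str, float] = field(
        default_factory=lambda: {"VCR": 0.07, "DEX": 0.012, "ASP": 0.012})
    k_int: float = 0.0                  # extra log10/day when combined
    window: tuple[float, float] = (6.0, 34.0)
    cv_g: float = 0.15                  # between-mouse lognormal CV on g
    cv_f0: float = 0.25                 # between-mouse lognormal CV on f0
    noise_sd: float = 0.15              # measurement noise, logit scale
    sample_interval: float = 7.0        # days between bleeds
    morbidity_hazard: float = 0.0       # per-day leukemia-unrelated hazard

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("growth rate g must be > 0")
        if not (0.0 < self.f0 < 25.0):
            raise ValueError("f0 must lie in (0, 25)")
        for drug, k in self.kills.items():
            if k < 0:
                raise ValueError(f"kill rate for {drug!r} must be >= 0")
        if self.k_int < 0:
            raise ValueError("k_int must be >= 0")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if self.window[1] <= self.window[0]:
            raise ValueError("dosing window must have positive length")
        if min(self.cv_g, self.cv_f0, self.noise_sd, self.morbidity_hazard) < 0:
            raise ValueError("dispersion parameters must be >= 0")


def arm_kill_rate(truth: InVivoTruth, components: frozenset[str] | set[str]) -> float:
    """Total log10/day kill rate for an arm's active component set."""
    unknown = set(components) - set(truth.kills)
    if unknown:
        raise ValueError(f"unknown treatment components: {sorted(unknown)}")
    k = sum(truth.kills[c] for c in components)
    if len(components) >= 2:
        k += truth.k_int
    return k


def _burden_exponent(t: float, g: float, k: float,
                     window: tuple[float, float]) -> float:
    exposure = min(max(t - window[0], 0.0), window[1] - window[0])
    return g * t - k * exposure


def true_event_time(
    truth: InVivoTruth,
    components: frozenset[str] | set[str] = frozenset(),
    threshold: float = 25.0,
) -> float:
    """Analytic day the noiseless %huCD45+ curve crosses ``threshold``.

    Solves ``g*t - K(t) = C`` piecewise, where
    ``C = log10(thr/(100-thr) * (100-f0)/f0)``.  Returns ``inf`` if the
    burden never reaches the threshold (possible when kill rate >= growth
    rate and the window is long enough only for bounded t — here growth
    always wins after the window, so the crossing is always finite).
    """
    k = arm_kill_rate(truth, components)
    g, (t0, t1) = truth.g, truth.window
    c = math.log10(threshold / (100.0 - threshold)
                   * (100.0 - truth.f0) / truth.f0)
    if g * t0 >= c:                      # crosses before treatment starts
        return c / g
    if g - k > 0:
        t = (c - k * t0) / (g - k)       # candidate crossing inside window
        if t <= t1:
            return t
    return (c + k * (t1 - t0)) / g       # crossing after window end


def gen_xenograft_cohort(
    truth: InVivoTruth,
    arms: Sequence[tuple[str, frozenset[str] | set[str]]],
    n_mice: int,
    followup: float,
    seed: int,
) -> list[MouseTimecourse]:
    """Per-mouse weekly %huCD45+ series for each treatment arm.

    An empty component set is a vehicle control.  Mice are censored at a
    leukemia-unrelated morbidity day drawn from the stated exponential
    hazard; otherwise follow-up ends at ``followup`` days.
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    if followup <= truth.window[1]:
        raise ValueError(
            f"followup ({followup} d) must exceed the dosing window end "
            f"({truth.window[1]} d)"
        )
    rng = np.random.default_rng(seed)
    days = np.arange(0.0, followup + 1e-9, truth.sample_interval)
    cohort: list[MouseTimecourse] = []
    for label, components in arms:
        k = arm_kill_rate(truth, components)
        for i in range(n_mice):
            g_i = truth.g * _lognormal(rng, truth.cv_g)
            f0_i = min(truth.f0 * _lognormal(rng, truth.cv_f0), 24.9)
            b0 = f0_i / (100.0 - f0_i)          # host pool H = 1
            expo = np.array([_burden_exponent(t, g_i, k, truth.window)
                             for t in days])
            burden = b0 * np.power(10.0, expo)
            frac = 100.0 * burden / (burden + 1.0)
            if truth.noise_sd > 0:
                frac = 100.0 * expit(logit(np.clip(frac / 100.0, 1e-12,
                                                   1.0 - 1e-12))
                                     + rng.normal(0.0, truth.noise_sd,
                                                  size=frac.shape))
            censor_day = None
            cause = None
            if truth.morbidity_hazard > 0:
                t_m = rng.exponential(1.0 / truth.morbidity_hazard)
                if t_m < followup:
                    censor_day = float(t_m)
                    cause = "morbidity"
            keep = days <= (censor_day if censor_day is not None else followup)
            cohort.append(MouseTimecourse(
                mouse_id=f"{label}-{i + 1:02d}",
                arm=label,
                days=tuple(days[keep]),
                values=tuple(np.clip(frac[keep], 0.0, 100.0)),
                censor_day=censor_day,
                censor_cause=cause,
            ))
    return cohort


def _lognormal(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0.0:
        return 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2)))


# --------------------------------------------------------------------------
# pharmacokinetics
# --------------------------------------------------------------------------

#: Destructive-sampling design: terminal samples at these hours post-dose.
PK_SAMPLING_TIMES: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 12.0, 24.0)


@dataclass(frozen=True)
class PKTruth:
    """Ground truth for a sparse destructively-sampled PK study.

    Apparent (per-bioavailability) parameters for extravascular dosing:
    ``cl`` = CL/F (mL/h/kg), ``v`` = V/F (mL/kg), ``ka`` (1/h); two-compartment
    models add ``q`` = Q/F and ``v2`` = V2/F.  ``theta_cl`` multiplies CL in
    the combination arm (``theta_cl < 1`` = higher combination exposure).
    Assay error is proportional-plus-additive: ``C_obs = C*(1+b*e1) + a*e2``.
    """

    n_compartments: int = 1
    ka: float = 25.0
    cl: float = 1525.0       # DEX-like: 5 mg/kg dose -> AUC ~3.3 ug*h/mL
    v: float = 2800.0
    q: float | None = None
    v2: float | None = None
    dose: float = 5.0e6      # ng/kg (5 mg/kg)
    theta_cl: float = 1.0
    prop_sd: float = 0.15    # b
    add_sd: float = 0.0      # a, concentration units
    times: tuple[float, ...] = PK_SAMPLING_TIMES
    n_per_time: int = 3

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        for name in ("ka", "cl", "v", "dose"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_compartments == 2 and (self.q is None or self.v2 is None):
            raise ValueError("two-compartment truth needs q and v2")
        if self.theta_cl <= 0:
            raise ValueError("theta_cl must be > 0")
        if self.add_sd < 0 or self.prop_sd < 0:
            raise ValueError("error sds must be >= 0")
        if self.add_sd + self.prop_sd == 0:
            raise ValueError("at least one error component must be > 0")
        if self.n_per_time < 1:
            raise ValueError("n_per_time must be >= 1")

    @property
    def model(self) -> StructuralModel:
        return StructuralModel(self.n_compartments)

    def params(self, arm: str) -> dict[str, float]:
        cl = self.cl * (self.theta_cl if arm == "combination" else 1.0)
        p = {"ka": self.ka, "cl": cl, "v": self.v}
        if self.n_compartments == 2:
            p.update(q=self.q, v2=self.v2)
        return p


def gen_pk_dataset(
    truth: PKTruth,
    arms: Sequence[str] = ("single", "combination"),
    seed: int = 0,
    drug: str = "drug",
) -> list[PKObservation]:
    """One concentration per animal, ``n_per_time`` animals per time point.

    Pre-dose (t = 0) samples are recorded as exactly zero (extravascular
    dosing); later samples get proportional-plus-additive noise truncated
    at zero.
    """
    for arm in arms:
        if arm not in ("single", "combination"):
            raise ValueError(f"unknown arm {arm!r}")
    rng = np.random.default_rng(seed)
    obs: list[PKObservation] = []
    counter = 0
    for arm in arms:
        params = truth.params(arm)
        for t in truth.times:
            pred = predict_concentration(truth.model, params, truth.dose, t)
            for _ in range(truth.n_per_time):
                counter += 1
                if t == 0.0:
                    conc = 0.0
                else:
                    conc = pred * (1.0 + truth.prop_sd * rng.normal()) \
                        + truth.add_sd * rng.normal()
                    conc = max(conc, 0.0)
                obs.append(PKObservation(
                    animal_id=f"{arm}-{counter:03d}", arm=arm, drug=drug,
                    time_h=float(t), conc=float(conc), dose=truth.dose,
                ))
    return obs
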