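"""Median-effect dose-response fitting and multi-drug Combination Indices.

The median-effect equation relates dose ``D`` to affected fraction ``fa``
(``fu = 1 - fa``)::

    log(fa / fu) = m * log(D) - m * log(Dm)

with slope ``m`` and 50%-effect dose ``Dm``.  For drugs combined at a fixed
dose ratio, the Combination Index at effect level ``fa`` is

    CI = sum_j d_j / Dx_j

where ``d_j`` is drug ``j``'s dose in the combination and ``Dx_j`` the dose of
drug ``j`` alone producing the same effect (mutually-exclusive form, the
classic fixed-ratio CI).  CI < 1 indicates synergy, CI = 1 additivity, CI > 1
antagonism; a nine-band vocabulary refines this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DoseResponsePoint",
    "MedianEffectFit",
    "CIResult",
    "FitError",
    "affected_fraction",
    "fit_median_effect",
    "predict_affected_fraction",
    "dose_for_effect",
    "combination_index",
    "classify_ci",
    "CI_BANDS",
]


class FitError(ValueError):
    """Raised when a median-effect fit is impossible for a condition."""


@dataclass(frozen=True)
class DoseResponsePoint:
    """One plate condition: doses applied and fractional-survival replicates.

    ``doses`` maps drug name -> dose (drug-specific units).  For fixed-ratio
    combination conditions ``scale`` holds the ratio scale factor (the dose
    variable the combination curve is fitted against); single-agent points
    leave it ``None`` and are fitted against their single dose.
    """

    condition: str
    doses: Mapping[str, float]
    survival: Sequence[float] = field(default_factory=tuple)
    scale: float | None = None

    def __post_init__(self) -> None:
        if len(self.survival) < 1:
            raise ValueError(f"condition {self.condition!r}: needs >=1 replicate")
        for s in self.survival:
            if not (0.0 <= s <= 1.0):
                raise ValueError(
                    f"condition {self.condition!r}: survival {s} outside [0, 1]"
                )

    @property
    def dose_value(self) -> float:
        """Scalar dose used in the median-effect regression."""
        if self.scale is not None:
            return float(self.scale)
        if len(self.doses) != 1:
            raise ValueError(
                f"condition {self.condition!r}: multi-drug point without a scale"
            )
        return float(next(iter(self.doses.values())))


@dataclass(frozen=True)
class MedianEffectFit:
    """Fitted median-effect parameters for one condition."""

    condition: str
    m: float
    dm: float
    r: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.m > 0 and self.dm > 0):
            raise ValueError(f"{self.condition!r}: m and Dm must be positive")
        if self.n_points < 2:
            raise ValueError(f"{self.condition!r}: fit needs >=2 points")


@dataclass(frozen=True)
class CIResult:
    """Combination Index at one fixed-ratio dose level."""

    doses: Mapping[str, float]
    fa: float
    alone_doses: Mapping[str, float]
    ci: float
    classification: str


def affected_fraction(survival: float) -> float:
    """Affected fraction ``fa = 1 - fractional survival``."""
    if not (0.0 <= survival <= 1.0):
        raise ValueError(f"fractional survival {survival} outside [0, 1]")
    return 1.0 - survival


# Levels whose mean affected fraction is this close to 0 or 1 are excluded
# from the log-odds regression (log-odds undefined/unstable at the bounds).
FA_EXCLUSION = 0.005


def fit_median_effect(points: Sequence[DoseResponsePoint]) -> MedianEffectFit:
    """Fit the median-effect line for one condition by OLS on the log-odds.

    Replicates are averaged arithmetically per dose level, levels with mean
    ``fa <= 0.005`` or ``>= 0.995`` are dropped, and ``log10(fa/fu)`` is
    regressed on ``log10(dose)``.  Returns slope ``m``, median-effect dose
    ``Dm = 10**(-intercept/m)`` and the linear correlation ``r``.
    """
    if not points:
        raise FitError("no dose-response points supplied")
    condition = points[0].condition
    doses, fas = [], []
    for p in points:
        if p.condition != condition:
            raise FitError(
                f"mixed conditions in one fit: {condition!r} vs {p.condition!r}"
            )
        d = p.dose_value
        if d <= 0:  # explicit zero-dose control carries no log-dose information
            continue
        fa = affected_fraction(float(np.mean(np.asarray(p.survival, dtype=float))))
        if fa <= FA_EXCLUSION or fa >= 1.0 - FA_EXCLUSION:
            continue
        doses.append(d)
        fas.append(fa)
    if len(doses) < 2:
        raise FitError(
            f"condition {condition!r}: fewer than 2 usable dose levels after "
            f"exclusion (got {len(doses)})"
        )
    x = np.log10(np.asarray(doses))
    y = np.log10(np.asarray(fas) / (1.0 - np.asarray(fas)))
    m, intercept = np.polyfit(x, y, 1)
    if m <= 0:
        raise FitError(f"condition {condition!r}: non-positive fitted slope {m:.4g}")
    dm = 10.0 ** (-intercept / m)
    if len(x) == 2 or np.allclose(y, y.mean()):
        r = 1.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return MedianEffectFit(condition=condition, m=float(m), dm=float(dm), r=r,
                           n_points=len(doses))


def predict_affected_fraction(fit: MedianEffectFit, dose: float) -> float:
    """Forward median-effect prediction ``fa`` at a dose (or ratio scale)."""
    if dose <= 0:
        raise ValueError(f"dose must be positive, got {dose}")
    odds = (dose / fit.dm) ** fit.m
    return odds / (1.0 + odds)


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Invert the median-effect curve: dose producing affected fraction ``fa``."""
    if not (0.0 < fa < 1.0):
        raise ValueError(f"fa must lie strictly in (0, 1), got {fa}")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


# Nine CalcuSyn-style interpretation bands, lower-inclusive at each printed
# boundary: CI < 0.3 strong synergy, 0.3-0.7 synergy, 0.7-0.85 moderate
# synergy, 0.85-0.9 slight synergy, 0.9-1.1 additivity, 1.1-1.2 slight
# antagonism, 1.2-1.45 moderate antagonism, 1.45-3.3 antagonism, > 3.3
# strong antagonism.
CI_BANDS: tuple[tuple[float, str], ...] = (
    (0.3, "strong synergy"),
    (0.7, "synergy"),
    (0.85, "moderate synergy"),
    (0.9, "slight synergy"),
    (1.1, "additivity"),
    (1.2, "slight antagonism"),
    (1.45, "moderate antagonism"),
    (3.3, "antagonism"),
    (math.inf, "strong antagonism"),
)


def classify_ci(ci: float) -> str:
    """Map a Combination Index to its nine-band interpretation label."""
    if ci <= 0:
        raise ValueError(f"CI must be positive, got {ci}")
    for upper, label in CI_BANDS:
        if ci < upper:
            return label
        if ci == upper and upper == 3.3:
            return label  # printed top band is 1.45-3.3 inclusive
    return CI_BANDS[-1][1]


def combination_index(
    single_fits: Mapping[str, MedianEffectFit],
    combo_fit: MedianEffectFit,
    ratio: Mapping[str, float],
    level: float,
    fa: float | None = None,
) -> CIResult:
    """Combination Index at ratio scale ``level`` (mutually-exclusive form).

    ``fa`` defaults to the combination fit's smoothed prediction at ``level``
    (CalcuSyn behavior); pass an observed affected fraction to override.
    """
    if level <= 0:
        raise ValueError(f"dose level must be positive, got {level}")
    missing = set(ratio) - set(single_fits)
    if missing:
        raise ValueError(f"missing single-agent fits for drugs: {sorted(missing)}")
    if fa is None:
        fa = predict_affected_fraction(combo_fit, level)
    if not (0.0 < fa < 1.0):
        raise ValueError(f"affected fraction {fa} outside (0, 1)")
    doses = {drug: level * r for drug, r in ratio.items()}
    alone = {drug: dose_for_effect(single_fits[drug], fa) for drug in ratio}
    ci = sum(doses[d] / alone[d] for d in ratio)
    return CIResult(doses=doses, fa=fa, alone_doses=alone, ci=ci,
                    classification=classify_ci(ci))
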