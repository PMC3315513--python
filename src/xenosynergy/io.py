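"""CSV readers/writers for the three dataset shapes.

All tables are UTF-8 CSV with "." decimal.  Censored values use the
canonical ``">x"`` notation (see :class:`~xenosynergy.bounded.BoundedValue`).

Plate CSV (one row per condition x dose level):
    ``condition, scale, dose_<DRUG>..., rep1..repN``
    (``scale`` empty for single-agent rows; empty dose cells mean the drug
    is absent from that condition).

Cohort CSV (long format, one row per bleed):
    ``mouse, arm, day, hucd45_pct, censor_day, censor_cause``

PK CSV (one row per animal):
    ``animal, arm, drug, time_h, conc, dose_per_kg``
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .median_effect import DoseResponsePoint
from .pk_models import PKObservation
from .xenograft_survival import MouseTimecourse

__all__ = [
    "write_plates", "read_plates",
    "write_cohort", "read_cohort",
    "write_pk", "read_pk",
]


def write_plates(points: Sequence[DoseResponsePoint], path) -> None:
    drugs = sorted({d for p in points for d in p.doses})
    n_rep = max(len(p.survival) for p in points)
    rows = []
    for p in points:
        row: dict = {"condition": p.condition, "scale": p.scale}
        for d in drugs:
            row[f"dose_{d}"] = p.doses.get(d)
        for i in range(n_rep):
            row[f"rep{i + 1}"] = p.survival[i] if i < len(p.survival) else None
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_plates(path) -> list[DoseResponsePoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    dose_cols = [c for c in df.columns if c.startswith("dose_")]
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    points = []
    for _, row in df.iterrows():
        doses = {c[5:]: float(row[c]) for c in dose_cols
                 if not _isna(row[c])}
        survival = tuple(float(row[c]) for c in rep_cols if not _isna(row[c]))
        scale = None if _isna(row.get("scale")) else float(row["scale"])
        points.append(DoseResponsePoint(condition=str(row["condition"]),
                                        doses=doses, survival=survival,
                                        scale=scale))
    return points


def write_cohort(cohort: Sequence[MouseTimecourse], path) -> None:
    rows = []
    for tc in cohort:
        for day, val in zip(tc.days, tc.values):
            rows.append({"mouse": tc.mouse_id, "arm": tc.arm, "day": day,
                         "hucd45_pct": val, "censor_day": tc.censor_day,
                         "censor_cause": tc.censor_cause})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> list[MouseTimecourse]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for (mouse, arm), grp in df.groupby(["mouse", "arm"], sort=False):
        grp = grp.sort_values("day")
        cd = grp["censor_day"].iloc[0]
        cc = grp["censor_cause"].iloc[0]
        out.append(MouseTimecourse(
            mouse_id=str(mouse), arm=str(arm),
            days=tuple(grp["day"].astype(float)),
            values=tuple(grp["hucd45_pct"].astype(float)),
            censor_day=None if _isna(cd) else float(cd),
            censor_cause=None if _isna(cc) else str(cc),
        ))
    return out


def write_pk(observations: Sequence[PKObservation], path) -> None:
    pd.DataFrame([{
        "animal": o.animal_id, "arm": o.arm, "drug": o.drug,
        "time_h": o.time_h, "conc": o.conc, "dose_per_kg": o.dose,
    } for o in observations]).to_csv(path, index=False, float_format="%.17g")


def read_pk(path) -> list[PKObservation]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [PKObservation(animal_id=str(r.animal), arm=str(r.arm),
                          drug=str(r.drug), time_h=float(r.time_h),
                          conc=float(r.conc), dose=float(r.dose_per_kg))
            for r in df.itertuples()]


def _isna(x) -> bool:
    if x is None:
        return True
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return False
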