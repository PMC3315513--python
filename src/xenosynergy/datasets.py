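"""Bundled reference tables used by the worked examples and reports.

Two small CSVs summarize a pediatric ALL xenograft combination-therapy
study: per-cohort median event-free survival (with ``">x"`` censored-median
notation) and growth delays for the VXL +/- ABT-737 and VXL +/- arsenic
trioxide experiments, together with the donor patient's clinical outcome;
and the per-drug compartmental exposure estimates (AUC0-inf, Cmax, Tmax)
for single-agent versus combination dosing.  They serve as arithmetic and
stratification inputs — the underlying raw time courses are not public, so
synthetic cohorts stand in wherever raw data are needed.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .bounded import BoundedValue

__all__ = [
    "load_xenograft_summary",
    "load_pk_summary",
    "vxl_lgds_by_outcome",
]


def _data_path(name: str):
    return files("xenosynergy.data").joinpath(name)


def load_xenograft_summary() -> pd.DataFrame:
    """Median EFS / LGD summary per (study, xenograft, treatment) cohort.

    ``median_efs`` and ``lgd`` columns are strings in the canonical bound
    notation; parse with :meth:`BoundedValue.parse`.  Rows whose printed LGD
    is arithmetically inconsistent with the medians carry
    ``flag == "lgd-discrepant"``.
    """
    with _data_path("xenograft_response_summary.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"median_efs": str, "lgd": str, "flag": str})
    return df


def load_pk_summary() -> pd.DataFrame:
    """Per-drug exposure estimates, single-agent vs combination arm."""
    with _data_path("pk_parameter_summary.csv").open() as fh:
        return pd.read_csv(fh)


def vxl_lgds_by_outcome() -> dict[str, list[BoundedValue]]:
    """VXL-treatment LGDs grouped by donor patient outcome (alive / dod)."""
    df = load_xenograft_summary()
    sel = df[(df.study == "abt737") & (df.treatment == "VXL")]
    out: dict[str, list[BoundedValue]] = {}
    for _, row in sel.iterrows():
        out.setdefault(row.outcome, []).append(BoundedValue.parse(row.lgd))
    return out
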