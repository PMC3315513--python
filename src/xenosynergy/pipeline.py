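"""Configuration-driven orchestration of the three analysis stages.

A :class:`StudyConfig` (usually loaded from YAML) names, per stage, either a
CSV dataset or a synthetic-truth block, plus per-stage options and a global
seed.  :func:`run_study` executes the enabled stages in order (synthesize ->
in vitro CI -> in vivo EFS/LGD -> PK -> outcome stratification), writes CSV
report tables plus a JSON run manifest, and is byte-identical for identical
config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__, datasets, io, median_effect as me
from .bounded import BoundedValue, as_float
from .pk_models import StructuralModel, covariate_lrt, derived_metrics
from .synthetic_data import (InVitroTruth, InVivoTruth, PKTruth,
                             gen_dose_response, gen_pk_dataset,
                             gen_xenograft_cohort)
from .xenograft_survival import (additivity_call, compute_lgd, event_time,
                                 exact_logrank, km_curve, median_efs,
                                 cutoff_contingency, mann_whitney_exact)

log = logging.getLogger("xenosynergy")

__all__ = ["StudyConfig", "ReportBundle", "run_study", "stratify_by_outcome",
           "load_config"]


class _Stage(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InVitroStage(_Stage):
    path: Optional[str] = None
    truth: Optional[dict] = None
    dose_levels: list[float] = [0.5, 1.0, 2.5, 5.0, 10.0]
    raw_fa: bool = False        # use observed means instead of the combo fit

    @model_validator(mode="after")
    def _one_source(self):
        if (self.path is None) == (self.truth is None):
            raise ValueError("invitro: exactly one of path/truth required")
        return self


class InVivoStage(_Stage):
    path: Optional[str] = None
    truth: Optional[dict] = None
    arms: Optional[dict[str, list[str]]] = None     # label -> components
    n_mice: int = 8
    followup: float = 160.0
    control_arm: str = "control"
    combination_arm: Optional[str] = None
    single_arms: list[str] = []
    threshold: float = 25.0
    interpolation: Literal["interpolate", "first_sample"] = "interpolate"
    tolerance: float = 0.0

    @model_validator(mode="after")
    def _one_source(self):
        if (self.path is None) == (self.truth is None):
            raise ValueError("invivo: exactly one of path/truth required")
        if self.truth is not None and self.arms is None:
            raise ValueError("invivo: synthetic cohorts need an arms block")
        return self


class PKStage(_Stage):
    path: Optional[str] = None
    truth: Optional[dict] = None
    n_compartments: Literal[1, 2] = 1
    multistart: int = 20

    @model_validator(mode="after")
    def _one_source(self):
        if (self.path is None) == (self.truth is None):
            raise ValueError("pk: exactly one of path/truth required")
        return self


class StratificationStage(_Stage):
    source: str = "bundled"     # "bundled" or a CSV path with lgd,outcome
    cutoff: float = 55.0


class StudyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    invitro: Optional[InVitroStage] = None
    invivo: Optional[InVivoStage] = None
    pk: Optional[PKStage] = None
    stratification: Optional[StratificationStage] = None


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        return StudyConfig.model_validate(yaml.safe_load(fh) or {})


@dataclass
class ReportBundle:
    """All report tables produced by one study run."""

    ci_table: Optional[pd.DataFrame]
    efs_table: Optional[pd.DataFrame]
    pk_table: Optional[pd.DataFrame]
    covariate_test: Optional[dict]
    synergy: Optional[dict]
    stratification: Optional[dict]
    manifest: dict


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _run_invitro(cfg: InVitroStage, seed: int) -> pd.DataFrame:
    if cfg.truth is not None:
        truth = InVitroTruth(**cfg.truth)
        points = gen_dose_response(truth, cfg.dose_levels, seed)
    else:
        points = io.read_plates(cfg.path)
    conditions: dict[str, list] = {}
    for p in points:
        conditions.setdefault(p.condition, []).append(p)
    combo_pts = conditions.pop("combination", None)
    if combo_pts is None:
        raise RuntimeError("in vitro stage needs a 'combination' condition")
    singles = {c: me.fit_median_effect(pts) for c, pts in conditions.items()}
    combo_fit = me.fit_median_effect(combo_pts)
    rows = []
    for p in sorted(combo_pts, key=lambda q: q.scale):
        ratio = {d: dose / p.scale for d, dose in p.doses.items()}
        fa = None
        if cfg.raw_fa:
            fa = me.affected_fraction(float(np.mean(p.survival)))
        res = me.combination_index(singles, combo_fit, ratio, p.scale, fa=fa)
        row = {f"dose_{d}": p.doses[d] for d in sorted(p.doses)}
        row.update(scale=p.scale, fa=res.fa, ci=res.ci,
                   classification=res.classification)
        rows.append(row)
    return pd.DataFrame(rows)


def _run_invivo(cfg: InVivoStage, seed: int):
    if cfg.truth is not None:
        truth = InVivoTruth(**cfg.truth)
        arms = [(label, frozenset(comps)) for label, comps in cfg.arms.items()]
        cohort = gen_xenograft_cohort(truth, arms, cfg.n_mice, cfg.followup,
                                      seed)
    else:
        cohort = io.read_cohort(cfg.path)
    by_arm: dict[str, list] = {}
    for tc in cohort:
        by_arm.setdefault(tc.arm, []).append(
            event_time(tc, threshold=cfg.threshold, mode=cfg.interpolation))
    if cfg.control_arm not in by_arm:
        raise RuntimeError(f"control arm {cfg.control_arm!r} absent from data")
    medians = {arm: median_efs(km_curve(evs)) for arm, evs in by_arm.items()}
    control = medians[cfg.control_arm]
    rows = []
    lgds: dict[str, BoundedValue] = {}
    for arm, evs in by_arm.items():
        rec = {"arm": arm, "n_mice": len(evs),
               "median_efs": str(medians[arm]), "lgd": "", "p_vs_control": "",
               "p_vs_backbone": ""}
        if arm != cfg.control_arm:
            lgds[arm] = compute_lgd(medians[arm], control)
            rec["lgd"] = str(lgds[arm])
            rec["p_vs_control"] = exact_logrank(evs, by_arm[cfg.control_arm],
                                                seed=seed)
            backbone = cfg.combination_arm
            if backbone and backbone in by_arm and arm != backbone:
                rec["p_vs_backbone"] = exact_logrank(evs, by_arm[backbone],
                                                     seed=seed)
        rows.append(rec)
    synergy = None
    if cfg.combination_arm and cfg.single_arms:
        call = additivity_call(lgds[cfg.combination_arm],
                               [lgds[a] for a in cfg.single_arms],
                               tolerance=cfg.tolerance)
        synergy = {
            "combination_arm": cfg.combination_arm,
            "combination_lgd": str(call.combo_lgd),
            "additive_prediction": call.additive_prediction,
            "excess": call.excess,
            "excess_is_lower_bound": call.excess_is_lower_bound,
            "verdict": call.verdict,
        }
    return pd.DataFrame(rows), synergy, lgds


def _run_pk(cfg: PKStage, seed: int):
    if cfg.truth is not None:
        truth = PKTruth(**cfg.truth)
        obs = gen_pk_dataset(truth, seed=seed)
        model = truth.model
    else:
        obs = io.read_pk(cfg.path)
        model = StructuralModel(cfg.n_compartments)
    res = covariate_lrt(obs, model, multistart=cfg.multistart, seed=seed)
    fit = res.covariate_fit if res.significant else res.base_fit
    metrics = derived_metrics(fit, obs)
    rows = []
    for pname in ("auc_model", "auc_nca", "cmax_observed", "tmax_observed",
                  "cmax_model", "tmax_model"):
        rows.append({"parameter": pname,
                     "single_agent": metrics["single"][pname],
                     "combination": metrics["combination"][pname]})
    for pname, val in fit.params.items():
        rows.append({"parameter": pname, "single_agent": val,
                     "combination": val * (fit.theta_cl if pname == "cl"
                                           else 1.0)})
    test = {"base_ofv": res.base_ofv, "covariate_ofv": res.covariate_ofv,
            "delta_ofv": res.delta_ofv, "threshold": res.threshold,
            "significant": bool(res.significant), "theta_cl": res.theta_cl}
    return pd.DataFrame(rows), test


def stratify_by_outcome(
    lgds,
    outcomes,
    cutoff: float = 55.0,
) -> dict:
    """Group medians, exact Mann-Whitney p and cutoff contingency.

    ``lgds`` may contain :class:`BoundedValue`; bounds rank at their value.
    With fewer than 2 members in a group only the medians are reported.
    """
    lgds = [BoundedValue.parse(v) for v in lgds]
    groups = list(dict.fromkeys(outcomes))
    by_group = {g: [v for v, o in zip(lgds, outcomes) if o == g]
                for g in groups}
    out: dict = {"medians": {
        g: float(np.median([as_float(v) for v in vs]))
        for g, vs in by_group.items()
    }}
    if len(groups) == 2 and all(len(v) >= 2 for v in by_group.values()):
        u, p = mann_whitney_exact(by_group[groups[0]], by_group[groups[1]])
        table, p_cont = cutoff_contingency(lgds, outcomes, cutoff=cutoff)
        out.update(mann_whitney_u=u, mann_whitney_p=p, cutoff=cutoff,
                   contingency_table=table.tolist(), contingency_p=p_cont)
    else:
        warnings.warn("a group has <2 members; tests skipped", stacklevel=2)
    return out


def _run_stratification(cfg: StratificationStage) -> dict:
    if cfg.source == "bundled":
        grouped = datasets.vxl_lgds_by_outcome()
        lgds = [v for vs in grouped.values() for v in vs]
        outcomes = [g for g, vs in grouped.items() for _ in vs]
    else:
        df = pd.read_csv(cfg.source, dtype={"lgd": str})
        lgds = [BoundedValue.parse(v) for v in df["lgd"]]
        outcomes = list(df["outcome"])
    return stratify_by_outcome(lgds, outcomes, cutoff=cfg.cutoff)


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def run_study(config: StudyConfig, outdir) -> ReportBundle:
    """Execute the enabled stages and write reports under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_json = config.model_dump_json()
    manifest = {
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {"xenosynergy": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
    }
    ci = efs = pk_table = None
    synergy = covariate = strat = None
    if config.invitro is not None:
        log.info("stage invitro: median-effect fits and CI table")
        ci = _run_invitro(config.invitro, config.seed)
        ci.to_csv(outdir / "ci_table.csv", index=False)
    if config.invivo is not None:
        log.info("stage invivo: EFS/LGD table")
        efs, synergy, _ = _run_invivo(config.invivo, config.seed)
        efs.to_csv(outdir / "efs_table.csv", index=False)
        if synergy is not None:
            (outdir / "synergy.json").write_text(json.dumps(synergy, indent=2))
    if config.pk is not None:
        log.info("stage pk: compartmental fit and covariate test")
        pk_table, covariate = _run_pk(config.pk, config.seed)
        pk_table.to_csv(outdir / "pk_table.csv", index=False)
        (outdir / "covariate_test.json").write_text(
            json.dumps(covariate, indent=2))
    if config.stratification is not None:
        log.info("stage stratification: outcome analysis")
        strat = _run_stratification(config.stratification)
        (outdir / "stratification.json").write_text(
            json.dumps(strat, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ReportBundle(ci_table=ci, efs_table=efs, pk_table=pk_table,
                        covariate_test=covariate, synergy=synergy,
                        stratification=strat, manifest=manifest)
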