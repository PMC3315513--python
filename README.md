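# xenosynergy

Synergy scoring for preclinical combination therapy in pediatric acute
lymphoblastic leukemia (ALL) models. The package re-implements, as a tested
and reusable pipeline, the three analyses used to optimize an induction-type
triple regimen — vincristine (VCR) + dexamethasone (DEX) + l-asparaginase
(ASP), "VXL" — and to screen new agents against it:

1. **In vitro fixed-ratio synergy** (`xenosynergy.median_effect`).
   Fractional-survival dose-response data are fitted to the median-effect
   equation `log(fa/fu) = m·log(D) − m·log(Dm)` and drug interaction is
   scored by the Combination Index at each fixed-ratio level,
   `CI = Σ_j d_j / Dx_j`, where `d_j` is drug *j*'s dose in the combination
   and `Dx_j` the single-agent dose producing the same affected fraction
   `fa`. CI < 1 means synergy; a nine-band vocabulary (CI < 0.3 = strong
   synergy … > 3.3 = strong antagonism) refines the call.
2. **In vivo leukemia growth delay** (`xenosynergy.xenograft_survival`).
   Per-mouse %huCD45⁺ engraftment time courses are converted to event-free
   survival (event = 25% leukemic cells in peripheral blood), summarized by
   Kaplan–Meier medians, and differenced against the control arm to give a
   leukemia growth delay (LGD, days). Under the log-kill additivity rule a
   combination is synergistic when its LGD exceeds the sum of the
   single-agent LGDs. Cohorts are compared with an exact permutation
   log-rank test; LGDs stratified by donor-patient outcome are compared with
   the exact Mann–Whitney test and an exact 2×2 cutoff contingency test.
3. **Compartmental pharmacokinetics** (`xenosynergy.pk_models`).
   One- and two-compartment models with first-order absorption are fitted to
   sparse, destructively sampled plasma concentrations (one terminal sample
   per animal) by pooled maximum likelihood with a combined
   additive + proportional error. A drug-combination effect on apparent
   clearance CL/F is tested by refitting with `CL_combination = CL·θ_CL` and
   declaring significance when the objective function (−2 log L) drops by
   ≥ 3.8 units. Exposure is reported as `AUC0-∞ = Dose/(CL/F)`, Cmax and
   Tmax (model-based and observed), with a noncompartmental AUC cross-check.

A synthetic-data module (`xenosynergy.synthetic_data`) generates all three
dataset shapes with known ground truth — fixed-ratio plates with a potency
shift φ (the CI the analysis should recover), engraftment cohorts following
`B(t) = B0·10^(g·t − K(t))` with log-kill during a dosing window, and
destructively sampled PK studies — so every stage has parameter-recovery
tests with no external data. Two small bundled CSVs
(`xenosynergy/data/*.csv`) carry the reference study's printed cohort
medians and PK estimates for the arithmetic worked examples.

## Worked example

The bundled demo config runs every stage on synthetic data in one command:

```bash
xenosynergy report --config configs/demo_study.yaml --out results/demo
```

`results/demo/ci_table.csv` (in vitro; generator truth φ = 0.25):

```
dose_ASP,dose_DEX,dose_VCR,scale,fa,ci,classification
1.0,50.0,0.5,1.0,0.796…,0.2504…,strong synergy
2.5,125.0,1.25,2.5,0.912…,0.2446…,strong synergy
5.0,250.0,2.5,5.0,0.956…,0.2420…,strong synergy
10.0,500.0,5.0,10.0,0.979…,0.2408…,strong synergy
```

The CI ≈ 0.25 at every level recovers the generator's potency shift — a
strongly synergistic triple combination.

`results/demo/efs_table.csv` (in vivo; 8 mice/arm, weekly bleeds):

```
arm,n_mice,median_efs,lgd,p_vs_control,p_vs_backbone
control,8,15.7095,,,
VCR,8,22.854,7.1445,0.00078,0.00031
DEX,8,15.171,0,0.87,0.00016
ASP,8,16.7774,1.0679,0.18,0.00062
VXL,8,43.1887,27.4792,0.00078,
```

The combination LGD (27.5 d) exceeds the additive prediction (8.2 d) by
19.3 d → verdict `synergy` (`synergy.json`). Note the excess is larger
than the generator's interaction kill alone: single agents whose kill rate
is below the growth rate progress *during* treatment, so their single-agent
LGDs understate their contribution inside the combination — the same
mechanism by which individually inactive DEX/ASP doses synergize with VCR
in vivo.

`results/demo/covariate_test.json` (PK; generator truth θ_CL = 0.48):

```json
{"base_ofv": 526.12, "covariate_ofv": 417.49, "delta_ofv": 108.63,
 "threshold": 3.8, "significant": true, "theta_cl": 0.485}
```

The clearance covariate is detected (ΔOFV ≫ 3.8) and θ_CL is recovered;
the combination arm's model AUC is `1/θ_CL ≈ 2.1×` the single-agent AUC,
mirroring the reference study's 2-fold DEX exposure increase.

`results/demo/stratification.json` reproduces the outcome stratification of
the bundled reference LGDs: survivor-derived xenografts median 99.7 d vs
46.2 d for patients who died of disease, exact Mann–Whitney p = 0.0159,
and Fisher p = 0.0476 for the 55-day cutoff table `[[5,0],[1,4]]`.

Each stage is also available separately (`xenosynergy synth|ci|efs|pk`),
reading/writing the CSV schemas documented in `xenosynergy/io.py`.

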