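# Methods

## In vitro: median-effect fits and Combination Indices

Fractional survival `S` of drug-exposed cells relative to untreated controls
is converted to an affected fraction `fa = 1 − S`. For each condition
(single agent or fixed-ratio combination) replicates are averaged
arithmetically per dose level, levels with mean `fa ≤ 0.005` or `≥ 0.995`
are excluded (the log-odds is undefined or numerically unstable at the
bounds), and the median-effect line

    log10(fa / (1 − fa)) = m · log10(D) − m · log10(Dm)

is fitted by ordinary least squares. `m` is the sigmoidicity (slope) and
`Dm` the 50%-effect dose; for combinations the dose variable is the ratio
scale factor λ, so the combination `Dm` is in units of λ. The fit reports
the linear correlation `r` of the median-effect plot as a quality
diagnostic.

The Combination Index at level λ uses the mutually-exclusive (classic
fixed-ratio) form without a cross-product term:

    CI(λ) = Σ_j (λ·r_j) / Dx_j,   Dx_j = Dm_j · (fa/(1−fa))^(1/m_j)

with `fa` taken from the *fitted* combination curve at λ (smoothed, the
conventional behavior of fixed-ratio CI software); a flag substitutes the
raw observed mean instead. Because each drug's dose enters as the ratio
`d_j / Dx_j`, CI is invariant to each drug's dose units. Classification
uses nine lower-inclusive bands: < 0.3 strong synergy, 0.3–0.7 synergy,
0.7–0.85 moderate synergy, 0.85–0.9 slight synergy, 0.9–1.1 additivity,
1.1–1.2 slight antagonism, 1.2–1.45 moderate antagonism, 1.45–3.3
antagonism, > 3.3 strong antagonism.

The synthetic plate generator parameterizes interaction as a potency shift
φ applied to every `Dm_j` inside the combination; the combination's
affected fraction solves the Loewe-type mixture equation
`Σ_j λ·r_j / (φ·Dm_j·(fa/fu)^(1/m_j)) = 1` (closed form for equal slopes,
bisection on the log-odds otherwise). Under this construction the true CI
equals φ at every level, giving an analytic recovery target. Replicate
noise is logit-normal on survival so generated values stay strictly inside
(0, 1).

## In vivo: EFS, leukemia growth delay, and LGD-summation synergy

The readout is the percentage of human CD45⁺ cells among circulating
human + murine leukocytes (%huCD45⁺). Time zero is the randomization day
(median cohort engraftment 1%); treatment runs during a dosing window,
default days 6–34 (start 6 days after randomization, 4-week schedules).
An event is the first crossing of 25% huCD45⁺; crossings are placed by
linear interpolation between the bracketing weekly samples (exact sample
day when a sample equals the threshold or the first sample already exceeds
it). A first-sampling-day mode is provided because visual read-off versus
interpolation cannot be distinguished from published summaries; linear
interpolation is the default as the conservative choice. Mice whose series
never crosses are censored at end of follow-up; leukemia-unrelated
morbidity censors at its day.

Event-free survival (EFS) per arm is summarized by the Kaplan–Meier
product-limit median — the smallest time with S(t) ≤ 0.5, reported as a
lower bound ">t_last" when survival never reaches 0.5 (estimation is
delegated to lifelines). The leukemia growth delay is

    LGD = median EFS(treated) − median EFS(control)

floored at 0 (a treated median below control prints as 0), with the
censoring bound propagated from the treated arm; LGD is undefined when the
control median is censored. Synergy follows the log-kill summation rule: a
combination is synergistic when its LGD exceeds the sum of the single-agent
LGDs (strict inequality by default; a tolerance in days is configurable).
A censored combination LGD below the additive sum yields an
"indeterminate" verdict since the bound cannot exclude synergy.

Arms are compared by an exact permutation log-rank test on the score
statistic |O_A − E_A| (observed minus expected events in one arm summed
over event times). All C(n, n_A) group assignments are enumerated for
pooled sizes ≤ 16; larger problems use seeded Monte-Carlo permutation
(default 10⁵ draws) with the add-one estimator. The score statistic is
used rather than the studentized chi-square form because its permutation
null is directly enumerable and the variance term of the studentized form
varies with the assignment. Outcome stratification uses the exact
Mann–Whitney U test (no cross-group ties permitted; censored LGD bounds
rank at their value, valid here because every bound exceeds all exact
values it is compared with) and an exact conditional (hypergeometric) test
for the 2×2 table of LGD above/below a 55-day cutoff by donor outcome —
the asymptotic chi-square is invalid at cohort sizes near 10.

The synthetic cohort generator models leukemic burden as
`B(t) = B0 · 10^(g·t − K(t))` against a fixed host leukocyte pool H (only
the leukemic compartment grows — the simplest model consistent with a
monotone %huCD45⁺ rise in controls), with `%huCD45⁺ = 100·B/(B+H)` and
`B0` set so the fraction at randomization equals `f0` (default 1%).
`K(t)` accumulates log10 kill inside the dosing window at rate
`Σ_j k_j (+ k_int when ≥ 2 components are active)`; `k_int = 0` makes the
combination exactly additive in log-kill. Defaults: `g = 0.1` log10/day
(control events ~2 weeks after randomization, matching the reference
cohorts), kill rates per drug 0.07/0.012/0.012 log10/day, weekly sampling,
logit-normal measurement noise (sd 0.15), between-mouse lognormal CV of
15% on `g` and 25% on `f0` (magnitudes not published; stated here as
package defaults, not claims about the source data), and an optional
exponential leukemia-unrelated morbidity hazard. Analytic crossing times
are exposed for oracle tests.

One property of this model worth flagging: LGD summation equals log-kill
additivity only when events occur after the dosing window. A single agent
whose kill rate is below the growth rate progresses *during* treatment, so
its single-agent LGD understates its contribution inside a combination,
and a combination of individually "inactive" agents can show a large
LGD excess without any interaction kill. The generator reproduces this
(visible in the demo study); recovery tests of the additivity rule
therefore use kill rates above the growth rate so that all arms cross
after the window.

## Pharmacokinetics: pooled ML, covariate test, exposure metrics

With destructive sampling (one terminal sample per animal, 3 animals per
time point at 0, 0.5, 1, 2, 4, 6, 12, 24 h) between-animal variability is
not separable from assay error, so a mixed-effects analysis reduces to a
naive-pooled fit: a single residual error `σ_i = a + b·f_i` (additive +
proportional) absorbs both sources, and both treatment arms are fitted
simultaneously. The objective function is OFV = −2 log-likelihood with
constants included (they cancel in ΔOFV).

Structural models are the standard extravascular closed forms. One
compartment:

    C(t) = D·ka / (V·(ka − ke)) · (e^(−ke·t) − e^(−ka·t)),  ke = CL/V

(continuous limit when ka → ke); two compartments: the tri-exponential
with micro-constants `k10 = CL/V`, `k12 = Q/V`, `k21 = Q/V2`. Only
apparent (per-bioavailability) parameters CL/F, V/F, Q/F, V2/F are
identifiable from intraperitoneal dosing, and C(0) = 0. ASP "concentration"
is enzyme activity (U/mL) handled by identical machinery with linear
elimination.

Fitting maximizes the pooled likelihood over log-transformed parameters
(positivity) with multistart local search: a moment-based start (NCA-style
CL and V, Tmax-based ka) plus a seeded Latin-hypercube over data-scaled
bounds, L-BFGS-B per start, and a derivative-free Nelder–Mead polish of
the best optimum. Pre-dose (t = 0) zero concentrations are included in the
likelihood; because a zero-residual point with σ → 0 makes the combined-
error likelihood unbounded, the additive component is floored at 0.1% of
the maximum observed concentration whenever any fitted observation is
zero. One-compartment fits are reported on the canonical branch ka > ke:
the extravascular curve is invariant under the flip-flop swap
(ka ↔ ke, V → CL/ka), and early observed Tmax under this design is
consistent with absorption faster than elimination.

The combination effect on clearance is tested by refitting with
`CL_combination = CL·θ_CL` (θ_CL estimated on the log scale, warm-started
from the base fit so the nested-model OFV ordering is preserved) and
comparing objective functions: significant when
`ΔOFV = OFV_base − OFV_covariate ≥ 3.8`, the conventional one-parameter
criterion (the χ²₁ 0.95 quantile is 3.84; the threshold 3.8 is used
verbatim as in the reference analysis, whose accompanying "(p>0.05)"
annotation appears to be a typo for p<0.05 and is not reinterpreted here).
Simulation at the reference design gives a type-I error near the nominal
5% (slightly anticonservative, as expected for an ML likelihood-ratio test
at n = 48) and power ≈ 1 at θ_CL = 0.5 with 15% proportional error.

Exposure per arm: model `AUC0-∞ = Dose/(CL/F)` (so the
combination/single AUC ratio is exactly 1/θ_CL); model Cmax/Tmax from the
closed form (`Tmax = ln(ka/ke)/(ka − ke)` for one compartment, numeric
maximization for two); observed Cmax/Tmax from per-time-point mean
concentrations (observed Tmax is therefore constrained to the sampling
grid, while model Tmax is not — both are reported). A noncompartmental
AUC (linear-up/log-down trapezoid plus Clast/λz extrapolation, λz from ≥ 3
declining terminal means) is reported as a cross-check and its
extrapolation is omitted with a warning when the terminal slope is not
estimable.

The synthetic PK generator draws
`C_obs = C_true·(1 + b·ε₁) + a·ε₂`, truncated at zero, with 3 animals per
time point per arm and `CL·θ_CL` in the combination arm; pre-dose samples
are recorded as exactly zero. Defaults emulate the DEX study arm
(5 mg/kg; ka 25 h⁻¹, CL/F 1525 mL/h/kg, V/F 2800 mL/kg, b = 0.15),
chosen to reproduce the reference exposure scale (AUC ≈ 3.3 µg·h/mL,
Cmax ≈ 1.8 µg/mL, early Tmax).

## Pipeline and reproducibility

`run_study` executes the enabled stages of a validated YAML config
(synthesize → in vitro → in vivo → PK → stratification) and writes CSV
tables, JSON summaries and a run manifest (config hash, seed, library
versions). All randomness flows from the config seed; identical
config + seed reproduces byte-identical outputs. Censored values
serialize as ">x" in every report. Schema violations surface with pydantic
field paths; a stage failure aborts with the stage name, preserving
completed outputs.

## Problem sizes and limitations

Simulation-based checks use 100 datasets for clearance recovery, 200 for
the null (type-I) operating characteristic and 100 for power, all at the
reference sampling design; survival-test oracles enumerate cohorts up to
pooled n = 12–16. The synthetic generators emulate design, noise
structure and censoring of the three dataset shapes but not: pharmacologic
linkage between exposure and kill rate (not modeled in the reference
analysis), anti-ASP antibody effects, Michaelis–Menten elimination for
ASP, intra-week dosing structure (kill accrues continuously over the
window), or multi-site (marrow/spleen/liver) burden. Passing recovery
tests therefore demonstrates correctness of the estimators under these
idealized conditions, not robustness to real-data pathologies such as
assay dropouts, batch effects, or model misspecification. The printed CI
table and PK estimates of the reference study are not desk-reproducible
(their raw data are graphical only), so those stages are validated by
construction instead; the bundled summary CSVs carry one internally
inconsistent growth-delay row, flagged `lgd-discrepant` and excluded from
arithmetic checks.
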