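import pytest

from xenosynergy.median_effect import fit_median_effect
from xenosynergy.synthetic_data import (InVitroTruth, InVivoTruth, PKTruth,
                                        gen_dose_response)

THREE_DRUG_RATIO = {"VCR": 0.5, "DEX": 50.0, "ASP": 1.0}


@pytest.fixture(scope="session")
def invitro_truth_equal_slopes():
    """Three drugs, equal slopes, strong potency shift (CI should equal phi)."""
    return InVitroTruth(
        m={d: 1.0 for d in THREE_DRUG_RATIO},
        dm={"VCR": 2.0, "DEX": 150.0, "ASP": 3.0},
        ratio=THREE_DRUG_RATIO,
        phi=0.25, noise_sd=0.0, n_reps=3,
    )


@pytest.fixture(scope="session")
def invitro_truth_mixed_slopes():
    return InVitroTruth(
        m={"VCR": 1.3, "DEX": 0.8, "ASP": 1.0},
        dm={"VCR": 2.0, "DEX": 150.0, "ASP": 3.0},
        ratio=THREE_DRUG_RATIO,
        phi=0.4, noise_sd=0.0, n_reps=3,
    )


def fits_from_points(points):
    """Per-condition median-effect fits (singles dict + combination)."""
    by_cond = {}
    for p in points:
        by_cond.setdefault(p.condition, []).append(p)
    combo = fit_median_effect(by_cond.pop("combination"))
    singles = {c: fit_median_effect(pts) for c, pts in by_cond.items()}
    return singles, combo


@pytest.fixture(scope="session")
def noiseless_plates(invitro_truth_equal_slopes):
    return gen_dose_response(invitro_truth_equal_slopes,
                             [0.5, 1.0, 2.5, 5.0, 10.0], seed=0)


@pytest.fixture(scope="session")
def deterministic_invivo_truth():
    """No noise, no between-mouse variability, kill rates chosen so every
    arm's threshold crossing falls after the dosing window (the regime where
    growth delay equals total log kill / growth rate)."""
    return InVivoTruth(
        g=0.1, f0=1.0,
        kills={"VCR": 0.08, "DEX": 0.07, "ASP": 0.07},
        k_int=0.0, noise_sd=0.0, cv_g=0.0, cv_f0=0.0,
        morbidity_hazard=0.0,
    )


@pytest.fixture(scope="session")
def pk_truth_1cpt():
    return PKTruth(ka=25.0, cl=1525.0, v=2800.0, dose=5.0e6,
                   theta_cl=1.0, prop_sd=0.15)
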