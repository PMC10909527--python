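import warnings

import numpy as np
import pytest

from affectspace.synthetic import GeneratorParams, _var_dict, simulate

# statsmodels emits convergence chatter on tiny designs; results carry an
# explicit converged flag instead
warnings.filterwarnings("ignore", message=".*[Cc]onverge.*")


@pytest.fixture
def tiny_table():
    """Small default-structure trial table (8 participants x 10 stimuli)."""
    _, table = simulate(GeneratorParams(n_participants=8, n_stimuli=10), seed=11)
    return table


@pytest.fixture
def study_table():
    """Full study-sized table (51 x 56) with the default planted structure."""
    _, table = simulate(GeneratorParams(), seed=7)
    return table


@pytest.fixture
def null_table():
    """Table from the calibration null: five mutually independent columns."""
    _, table = simulate(GeneratorParams.null(n_participants=10, n_stimuli=12), seed=3)
    return table


def zero_noise_params(n_participants=4, n_stimuli=6) -> GeneratorParams:
    """Generator parameters whose raw signals are exactly feature-determined."""
    p = GeneratorParams(n_participants=n_participants, n_stimuli=n_stimuli)
    p.signal.pupil_noise_sd = 0.0
    p.signal.scr_noise_sd = 0.0
    p.signal.hr_noise_sd = 0.0
    p.signal.blink_rate = 0.0
    return p


def lmm_recovery_params() -> GeneratorParams:
    """Direct-regression structure with planted pupil slopes.

    Arousal is (up to negligible noise) the shared factor itself and valence
    is an independent unit-variance rating, so the population regression of
    pupil on the observed predictors has exactly the planted coefficients:
    arousal 0.36, valence 0, interaction 0.16, brightness -0.96.
    """
    return GeneratorParams(
        f1_loadings=_var_dict(valence=0.0, arousal=1.0, pupil=0.36, scr=0.0, hr=0.0),
        f2_loadings=_var_dict(),
        interaction={"pupil": 0.16, "scr": 0.0},
        brightness_beta=-0.96,
        participant_sd=_var_dict(0.0, 0.0, 0.3, 0.3, 0.3),
        stimulus_sd=_var_dict(0.0, 0.0, 0.2, 0.2, 0.2),
        residual_sd=_var_dict(1.0, 1e-6, 0.6, 0.6, 0.6),
        valence_arousal_cor=0.0,
        stimulus_affect_share=0.0,
        rating_scale=1.0,
        pupil_scale=1.0,
        pupil_offset=0.0,
        hr_scale=1.0,
        hr_offset=0.0,
    )


def brute_force_mfa(Y: np.ndarray, group_slices):
    """Independent oracle: plain eigendecomposition of the weighted covariance.

    Reimplements the weighting definition directly (standardize, divide each
    group by the square root of its separate first eigenvalue, eigendecompose
    the covariance) without sharing code with the fitted path.
    """
    n = Y.shape[0]
    X = (Y - Y.mean(0)) / Y.std(0)
    for sl in group_slices:
        sub = X[:, sl]
        lam1 = np.max(np.linalg.eigvalsh(sub.T @ sub / n))
        X[:, sl] = sub / np.sqrt(lam1)
    C = X.T @ X / n
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    return evals[order], X @ evecs[:, order], evecs[:, order]
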