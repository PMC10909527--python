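"""Closed-form population moments implied by the generator's latent model.

Every observed variable is a (possibly exponentiated) linear-plus-quadratic
function of one jointly Gaussian latent vector Z: ratings and HR are linear
forms, pupil adds a bilinear valence-by-arousal product, and SCR is the
exponential of such a form.  All first and second moments then have exact
expressions via Gaussian quadratic-form identities: for S = b'Z + Z'AZ and
T = c'Z + Z'BZ with Z ~ N(0, S0),

* E[S] = tr(A S0), cov(S, T) = b'S0 c + 2 tr(A S0 B S0);
* E[e^S] and cross-moments with linear/quadratic forms follow from the
  tilted-Gaussian measure with covariance (S0^-1 - 2A)^-1, which exists iff
  I - 2 S0 A is positive definite (otherwise the parameterization is
  rejected).

These moments give the population covariance of the five observed variables
(plus brightness), against which the planted eigenstructure and the bootstrap
coverage of sample eigenvalues can be checked without simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import ACTIVE_VARS, BRIGHTNESS
from .synthetic import GeneratorParams, ParameterizationError

__all__ = ["implied_covariance", "implied_mean", "population_mfa"]

_VARS = list(ACTIVE_VARS)
# latent layout: f1, f2, residuals (5), participant intercepts (5),
# stimulus intercepts (5), brightness
_NZ = 18
_F1, _F2 = 0, 1
_E0, _U0, _S0, _B = 2, 7, 12, 17


def _latent_cov(p: GeneratorParams) -> np.ndarray:
    S = np.zeros((_NZ, _NZ))
    S[_F1, _F1] = 1.0
    S[_F2, _F2] = 1.0
    for i, v in enumerate(_VARS):
        S[_E0 + i, _E0 + i] = p.residual_sd[v] ** 2
        S[_U0 + i, _U0 + i] = p.participant_sd[v] ** 2
        S[_S0 + i, _S0 + i] = p.stimulus_sd[v] ** 2
    # correlated subjective residuals
    S[_E0, _E0 + 1] = S[_E0 + 1, _E0] = (
        p.valence_arousal_cor * p.residual_sd["valence"] * p.residual_sd["arousal"]
    )
    S[_B, _B] = 1.0
    return S


@dataclass
class _Form:
    """One observed variable as scale * (offset + b'Z + Z'AZ), optionally exp."""

    b: np.ndarray
    A: np.ndarray | None
    scale: float
    offset: float
    exp: bool = False
    log_mean: float = 0.0
    log_scale: float = 1.0


def _forms(p: GeneratorParams) -> dict[str, _Form]:
    def lin(var: str, extra: dict[int, float] | None = None) -> np.ndarray:
        i = _VARS.index(var)
        b = np.zeros(_NZ)
        b[_F1] = p.f1_loadings[var]
        b[_F2] = p.f2_loadings[var]
        b[_E0 + i] = 1.0
        b[_U0 + i] = 1.0
        b[_S0 + i] = 1.0
        for k, v in (extra or {}).items():
            b[k] += v
        return b

    b_val = lin("valence")
    b_aro = lin("arousal")
    sd_v = p.subjective_latent_sd("valence")
    sd_a = p.subjective_latent_sd("arousal")
    bz_v, bz_a = b_val / sd_v, b_aro / sd_a
    A_prod = 0.5 * (np.outer(bz_v, bz_a) + np.outer(bz_a, bz_v))

    forms = {
        "valence": _Form(b_val, None, p.rating_scale, 0.0),
        "arousal": _Form(b_aro, None, p.rating_scale, 0.0),
        "pupil": _Form(
            lin("pupil", {_B: p.brightness_beta}),
            p.interaction["pupil"] * A_prod,
            p.pupil_scale,
            p.pupil_offset,
        ),
        "scr": _Form(
            lin("scr"),
            p.interaction["scr"] * A_prod,
            1.0,
            0.0,
            exp=True,
            log_mean=p.scr_log_mean,
            log_scale=p.scr_log_scale,
        ),
        "hr": _Form(lin("hr"), None, p.hr_scale, p.hr_offset),
        BRIGHTNESS: _Form(np.eye(_NZ)[_B], None, 1.0, 0.0),
    }
    return forms


def _tilt(S: np.ndarray, beta: np.ndarray, C: np.ndarray):
    """Moments of exp(beta'Z + 0.5 Z'C Z) under N(0, S).

    Returns (phi, mu_star, Sigma_star) where phi is the expectation and the
    starred quantities are the mean/covariance of the exponentially tilted
    Gaussian.  Raises if the tilt is not integrable.
    """
    M = np.eye(len(S)) - S @ C
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or np.any(np.linalg.eigvalsh((M + M.T) / 2.0) <= 0):
        raise ParameterizationError(
            "SCR interaction/log-scale too large: the log-normal moments "
            "of the scr block do not exist (implied covariance undefined)"
        )
    Minv = np.linalg.inv(M)
    Sigma_star = Minv @ S
    Sigma_star = (Sigma_star + Sigma_star.T) / 2.0
    mu_star = Sigma_star @ beta
    phi = np.exp(-0.5 * logdet + 0.5 * beta @ mu_star)
    return phi, mu_star, Sigma_star


def _exp_params(f: _Form) -> tuple[float, np.ndarray, np.ndarray]:
    """(m, beta, C) so that the variable equals e^{m + beta'Z + 0.5 Z'C Z}."""
    m = f.log_mean
    beta = f.log_scale * f.b
    C = 2.0 * f.log_scale * (f.A if f.A is not None else np.zeros((_NZ, _NZ)))
    return m, beta, C


def _lin_mean(f: _Form, S: np.ndarray) -> float:
    quad = np.trace(f.A @ S) if f.A is not None else 0.0
    return f.offset + f.scale * quad


def _cov_pair(fi: _Form, fj: _Form, S: np.ndarray) -> float:
    if fi.exp and fj.exp:
        if fi is not fj:
            raise NotImplementedError("only one exponentiated variable supported")
        m, beta, C = _exp_params(fi)
        phi1, _, _ = _tilt(S, beta, C)
        phi2, _, _ = _tilt(S, 2.0 * beta, 2.0 * C)
        return float(np.exp(2 * m) * phi2 - (np.exp(m) * phi1) ** 2)
    if fi.exp or fj.exp:
        fe, fl = (fi, fj) if fi.exp else (fj, fi)
        m, beta, C = _exp_params(fe)
        phi, mu, Sig = _tilt(S, beta, C)
        e_lin = fl.b @ mu
        if fl.A is not None:
            e_lin += np.trace(fl.A @ Sig) + mu @ fl.A @ mu
        e_exp = np.exp(m) * phi
        quad = np.trace(fl.A @ S) if fl.A is not None else 0.0
        return float(fl.scale * (e_exp * e_lin - e_exp * quad))
    c = fi.b @ S @ fj.b
    if fi.A is not None and fj.A is not None:
        c += 2.0 * np.trace(fi.A @ S @ fj.A @ S)
    return float(fi.scale * fj.scale * c)


def implied_covariance(params: GeneratorParams, include_brightness: bool = True) -> pd.DataFrame:
    """Exact population covariance of the observed trial-table variables.

    Rating clipping at the +/-10 slider bounds and norm clipping at [1, 9]
    are ignored; with default scales both affect well under 1% of draws.
    """
    S = _latent_cov(params)
    forms = _forms(params)
    names = _VARS + ([BRIGHTNESS] if include_brightness else [])
    C = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names[: i + 1]):
            C[i, j] = C[j, i] = _cov_pair(forms[a], forms[b], S)
    return pd.DataFrame(C, index=names, columns=names)


def implied_mean(params: GeneratorParams) -> pd.Series:
    S = _latent_cov(params)
    forms = _forms(params)
    out = {}
    for name in _VARS + [BRIGHTNESS]:
        f = forms[name]
        if f.exp:
            m, beta, C = _exp_params(f)
            phi, _, _ = _tilt(S, beta, C)
            out[name] = float(np.exp(m) * phi)
        else:
            out[name] = _lin_mean(f, S)
    return pd.Series(out)


def population_mfa(
    params: GeneratorParams,
    residualize_brightness: bool = True,
    spec=None,
):
    """Population MFA solution implied by the generator parameters.

    Converts the implied covariance to a correlation matrix (optionally after
    removing the linear brightness effect from pupil), applies the group
    weighting and returns the population eigensystem.  Used as the oracle for
    bootstrap-coverage and structure-recovery checks.
    """
    from .mfa import GroupSpec, mfa_from_correlation

    spec = spec or GroupSpec()
    cov = implied_covariance(params, include_brightness=True)
    if residualize_brightness:
        b = cov.loc["pupil", BRIGHTNESS] / cov.loc[BRIGHTNESS, BRIGHTNESS]
        for v in _VARS:
            cov.loc["pupil", v] = cov.loc[v, "pupil"] = (
                cov.loc["pupil", v] - b * cov.loc[BRIGHTNESS, v]
            )
    cov = cov.loc[_VARS, _VARS]
    d = np.sqrt(np.diag(cov.to_numpy()))
    R = cov.to_numpy() / np.outer(d, d)
    R = pd.DataFrame(R, index=_VARS, columns=_VARS)
    return mfa_from_correlation(R, spec)
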