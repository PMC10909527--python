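"""Trial-level coherence regressions with crossed random intercepts.

Each autonomic feature is regressed on the subjective ratings (and their
interaction, plus brightness for pupil), with random intercepts for both
participant and stimulus so that trial-level effects are not confounded with
person- or image-level means.  Cross-signal models test whether the autonomic
channels predict one another.  Estimation is restricted maximum likelihood
via variance components (statsmodels MixedLM with participant and stimulus
dummy blocks); p-values use the large-sample normal approximation, recorded
in the output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .schema import PARTICIPANT, STIMULUS, complete_cases

__all__ = [
    "ModelSpec",
    "CoefficientTable",
    "fit_trial_lmm",
    "coherence_model_suite",
    "simple_slopes",
    "residualize",
]


@dataclass
class ModelSpec:
    """One trial-level regression: response, fixed terms, random factors.

    ``fixed`` uses formula syntax per term (``"valence"``,
    ``"valence:arousal"``).  With ``zscore=True`` (default) every quantitative
    predictor is standardized before the design is built; the response is
    left on its original scale.
    """

    response: str
    fixed: list[str]
    random_factors: list[str] = field(default_factory=lambda: [PARTICIPANT, STIMULUS])
    zscore: bool = True

    def predictor_columns(self) -> list[str]:
        cols: list[str] = []
        for term in self.fixed:
            for part in term.split(":"):
                part = part.strip()
                if part and part not in cols:
                    cols.append(part)
        return cols

    def validate(self, columns) -> None:
        cols = self.predictor_columns()
        if self.response in cols:
            raise ValueError(f"response {self.response!r} appears among fixed terms")
        missing = [c for c in cols + [self.response] + self.random_factors if c not in columns]
        if missing:
            raise ValueError(f"model column(s) not in table: {missing}")


@dataclass
class CoefficientTable:
    """Fixed-effect estimates with variance components and fit metadata."""

    coefficients: pd.DataFrame  # index: term; estimate, se, tvalue, pvalue
    cov_params: pd.DataFrame  # fixed-effects covariance (delta-method input)
    variance_components: dict[str, float]
    residual_variance: float
    n_obs: int
    n_dropped: int
    converged: bool
    df_method: str
    spec: ModelSpec


class RankDeficientError(ValueError):
    pass


def _check_rank(exog: pd.DataFrame) -> None:
    X = exog.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the terms whose removal restores full rank
        collinear = []
        for j, name in enumerate(exog.columns):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                collinear.append(name)
        raise RankDeficientError(f"rank-deficient fixed design; collinear terms: {collinear}")


def fit_trial_lmm(table: pd.DataFrame, spec: ModelSpec) -> CoefficientTable:
    """Fit one crossed-random-intercepts model on the trial table.

    Rows with a missing value in any model column are dropped (and counted).
    Degenerate variance components are reported as zero; non-convergence is
    flagged in the result, never silent.  With ``random_factors=[]`` the fit
    reduces to ordinary least squares (the zero-variance limit).
    """
    spec.validate(table.columns)
    cols = [spec.response] + spec.predictor_columns() + spec.random_factors
    data, n_dropped = complete_cases(table, cols)
    data = data[cols].copy()
    for rf in spec.random_factors:
        if data[rf].nunique() < 2:
            raise ValueError(f"random factor {rf!r} has fewer than 2 levels")
    if spec.zscore:
        for c in spec.predictor_columns():
            sd = data[c].std(ddof=0)
            if sd == 0:
                raise ValueError(f"predictor {c!r} has zero variance")
            data[c] = (data[c] - data[c].mean()) / sd

    formula = f"{spec.response} ~ " + " + ".join(spec.fixed)
    import patsy

    _, exog = patsy.dmatrices(formula, data, return_type="dataframe")
    _check_rank(exog)

    if not spec.random_factors:
        fit = smf.ols(formula, data=data).fit()
        coefs = pd.DataFrame(
            {
                "estimate": fit.params,
                "se": fit.bse,
                "tvalue": fit.tvalues,
                "pvalue": fit.pvalues,
            }
        )
        return CoefficientTable(
            coefficients=coefs,
            cov_params=fit.cov_params(),
            variance_components={},
            residual_variance=float(fit.mse_resid),
            n_obs=int(fit.nobs),
            n_dropped=n_dropped,
            converged=True,
            df_method="ols-t",
            spec=spec,
        )

    vc = {rf: f"0 + C({rf})" for rf in spec.random_factors}
    groups = np.ones(len(data))
    model = sm.MixedLM.from_formula(
        formula, groups=groups, vc_formula=vc, re_formula="0", data=data
    )
    # statsmodels retries failed optimizations internally (warning each
    # time); the converged flag on the result is what matters
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        fit = model.fit(reml=True)
        converged = bool(getattr(fit, "converged", True))
        if not converged:
            refit = model.fit(reml=True, method="powell")
            if bool(getattr(refit, "converged", False)):
                fit, converged = refit, True

    k = len(fit.fe_params)
    from scipy import stats

    est = fit.fe_params
    se = fit.bse[:k]
    if not np.all(np.isfinite(se)):
        converged = False  # singular Hessian: flag, never silently report
    tval = est / se
    pval = 2.0 * stats.norm.sf(np.abs(tval))
    coefs = pd.DataFrame(
        {"estimate": est, "se": se, "tvalue": tval, "pvalue": pval}
    )
    vcomp = {
        rf: max(float(v), 0.0)
        for rf, v in zip(spec.random_factors, np.atleast_1d(fit.vcomp))
    }
    return CoefficientTable(
        coefficients=coefs,
        cov_params=fit.cov_params().iloc[:k, :k],
        variance_components=vcomp,
        residual_variance=float(fit.scale),
        n_obs=int(fit.nobs),
        n_dropped=n_dropped,
        converged=converged,
        df_method="large-sample normal",
        spec=spec,
    )


#: the full suite of coherence models fitted in the analysis
SUITE_SPECS: dict[str, ModelSpec] = {
    "pupil_valence_arousal": ModelSpec("pupil", ["valence", "arousal", "valence:arousal", "brightness"]),
    "scr_valence_arousal": ModelSpec("scr", ["valence", "arousal", "valence:arousal"]),
    "hr_valence": ModelSpec("hr", ["valence"]),
    "hr_arousal": ModelSpec("hr", ["arousal"]),
    "hr_valence_arousal": ModelSpec("hr", ["valence", "arousal"]),
    "scr_on_hr": ModelSpec("scr", ["hr"]),
    "scr_on_pupil": ModelSpec("scr", ["pupil"]),
    "pupil_on_hr": ModelSpec("pupil", ["hr"]),
    "pupil_on_scr": ModelSpec("pupil", ["scr"]),
}


def coherence_model_suite(table: pd.DataFrame) -> dict[str, CoefficientTable]:
    """Fit the full coherence suite; returns a keyed collection of results."""
    return {name: fit_trial_lmm(table, spec) for name, spec in SUITE_SPECS.items()}


def simple_slopes(
    model: CoefficientTable,
    predictor: str,
    moderator: str,
    levels: tuple[float, ...] = (-1.0, 1.0),
) -> pd.DataFrame:
    """Slopes of *predictor* at fixed moderator levels (in moderator SDs).

    slope(m) = b_predictor + m * b_interaction, with delta-method standard
    errors from the fixed-effects covariance.
    """
    terms = model.coefficients.index
    inter = None
    for cand in (f"{predictor}:{moderator}", f"{moderator}:{predictor}"):
        if cand in terms:
            inter = cand
            break
    if inter is None or predictor not in terms:
        raise ValueError(
            f"model lacks the product term {predictor}:{moderator} or the main effect"
        )
    b = model.coefficients["estimate"]
    V = model.cov_params
    rows = []
    for m in levels:
        slope = b[predictor] + m * b[inter]
        var = V.loc[predictor, predictor] + m**2 * V.loc[inter, inter] + 2 * m * V.loc[predictor, inter]
        rows.append({"level": m, "slope": slope, "se": float(np.sqrt(var))})
    return pd.DataFrame(rows).set_index("level")


def residualize(
    table: pd.DataFrame,
    response: str = "pupil",
    covariate: str = "brightness",
    method: str = "lmm",
) -> tuple[pd.DataFrame, float]:
    """Remove the linear effect of a covariate from a response column.

    ``method="lmm"`` estimates the coefficient with crossed random
    intercepts; ``method="ols"`` uses ordinary least squares (same population
    coefficient, faster).  Only the fixed covariate effect is subtracted —
    participant/stimulus structure stays in the residualized column.  Returns
    the modified copy of the table and the estimated coefficient (on raw
    scales).
    """
    if method == "ols":
        x = table[covariate].to_numpy(dtype=float)
        y = table[response].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        beta = float(np.cov(x[ok], y[ok], ddof=0)[0, 1] / np.var(x[ok]))
    elif method == "lmm":
        ct = fit_trial_lmm(table, ModelSpec(response, [covariate], zscore=False))
        beta = float(ct.coefficients.loc[covariate, "estimate"])
    else:
        raise ValueError("method must be 'lmm' or 'ols'")
    out = table.copy()
    out[response] = table[response] - beta * table[covariate]
    return out, beta
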