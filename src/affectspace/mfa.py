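"""Multiple Factor Analysis for grouped quantitative variables.

MFA is a principal-component decomposition of a table whose columns are
partitioned into named groups (here: subjective ratings vs autonomic
responses).  Each column is standardized, then every group's columns are
shrunk by ``1/sqrt(lambda1(g))`` — the first eigenvalue of that group's own
standardized PCA — so that no single group can dominate the common space:
after weighting each group's sub-table has first eigenvalue exactly one.

The global eigensystem of the weighted table yields the common dimensions;
per-variable correlations/cos2/contributions, per-group contributions,
partial row coordinates (a row's position as seen by one group alone, whose
group-mean equals the global coordinate), partial axes (correlations of each
group's separate PCA dimensions with the global dimensions) and barycentric
projections of supplementary categorical variables are all derived from it.

Conventions: row weights are uniform ``1/n``, column standardization uses the
population SD (``ddof=0``), and each dimension's sign is fixed so that the
variable with the largest absolute correlation loads positively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    AROUSAL_CATEGORY,
    AUTONOMIC_VARS,
    PARTICIPANT,
    STIMULUS,
    SUBJECTIVE_VARS,
    VALENCE_CATEGORY,
    complete_cases,
)

__all__ = [
    "GroupSpec",
    "MFAResult",
    "ZeroVarianceError",
    "standardize_and_weight",
    "fit_mfa",
    "mfa_from_correlation",
    "partial_coordinates",
    "partial_axes",
    "project_supplementary",
    "aggregate_table",
]


class ZeroVarianceError(ValueError):
    """An active column has no variance in the (sub)table being decomposed."""


@dataclass
class GroupSpec:
    """Named partition of the active quantitative columns.

    ``supplementary`` columns are categorical variables projected onto the
    fitted space as barycentres but never used in fitting.
    """

    groups: dict[str, list[str]] = field(
        default_factory=lambda: {
            "subjective": list(SUBJECTIVE_VARS),
            "autonomic": list(AUTONOMIC_VARS),
        }
    )
    supplementary: list[str] = field(
        default_factory=lambda: [VALENCE_CATEGORY, AROUSAL_CATEGORY, PARTICIPANT, STIMULUS]
    )

    @property
    def active_columns(self) -> list[str]:
        return [c for cols in self.groups.values() for c in cols]

    def validate(self, columns) -> None:
        cols = self.active_columns
        if len(set(cols)) != len(cols):
            raise ValueError("variable groups must be disjoint")
        if any(len(v) == 0 for v in self.groups.values()):
            raise ValueError("variable groups must be non-empty")
        missing = [c for c in cols if c not in columns]
        if missing:
            raise ValueError(f"active column(s) not in table: {missing}")
        overlap = [c for c in self.supplementary if c in cols]
        if overlap:
            raise ValueError(f"supplementary column(s) also active: {overlap}")

    def slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name, cols in self.groups.items():
            out[name] = slice(start, start + len(cols))
            start += len(cols)
        return out


@dataclass
class MFAResult:
    """Fitted common space; all frames are indexed by variable or row label."""

    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    total_inertia: float
    n_dims: int
    variables: list[str]
    groups: dict[str, list[str]]
    group_first_eigenvalues: dict[str, float]
    group_weights: dict[str, float]
    scores: pd.DataFrame
    correlations: pd.DataFrame
    cos2: pd.DataFrame
    contributions: pd.DataFrame
    group_contributions: pd.DataFrame
    partial_scores: dict[str, pd.DataFrame]
    partial_axes_table: pd.DataFrame
    supplementary_coords: dict[str, pd.DataFrame]
    column_means: pd.Series
    column_sds: pd.Series
    n_rows: int
    n_dropped: int
    aggregation: str | None = None

    def dim_labels(self) -> list[str]:
        return [f"dim{i + 1}" for i in range(self.n_dims)]


# ---------------------------------------------------------------------------
# numerical core (numpy only; reused by the resampling layer)
# ---------------------------------------------------------------------------


def _standardize(Y: np.ndarray, colnames) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [colnames[i] for i in bad]
        raise ZeroVarianceError(f"zero-variance active column(s): {names}")
    return (Y - mu) / sd, mu, sd


def _core_eigensystem(Y: np.ndarray, group_slices: list[slice], colnames) -> dict:
    """Standardize, weight and decompose; returns the raw eigensystem.

    Keys: eigenvalues (descending, >= 0), V (weighted-space eigenvectors,
    sign-fixed), correlations (variables x dims), col_weights, lambda1 (per
    group), X (standardized data), W (weighted data), mu, sd.
    """
    n = Y.shape[0]
    X, mu, sd = _standardize(Y, colnames)
    K = (X.T @ X) / n
    lam1 = np.empty(len(group_slices))
    col_w = np.empty(Y.shape[1])
    for gi, sl in enumerate(group_slices):
        sub = K[sl, sl]
        lam1[gi] = float(np.linalg.eigvalsh(sub)[-1])
        col_w[sl] = 1.0 / lam1[gi]
    sqw = np.sqrt(col_w)
    Kw = K * np.outer(sqw, sqw)
    evals, evecs = np.linalg.eigh(Kw)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    V = evecs[:, order]
    # per-column first group eigenvalue, for the correlation formula
    lam1_col = 1.0 / col_w
    corr = np.sqrt(lam1_col)[:, None] * V * np.sqrt(evals)[None, :]
    # deterministic sign: largest-|correlation| variable loads positively
    for s in range(V.shape[1]):
        j = int(np.argmax(np.abs(corr[:, s])))
        if corr[j, s] < 0:
            V[:, s] = -V[:, s]
            corr[:, s] = -corr[:, s]
    W = X * sqw[None, :]
    return {
        "eigenvalues": evals,
        "V": V,
        "correlations": corr,
        "col_weights": col_w,
        "lambda1": lam1,
        "X": X,
        "W": W,
        "mu": mu,
        "sd": sd,
    }


def mfa_from_correlation(R: pd.DataFrame, spec: GroupSpec) -> dict:
    """MFA eigensystem of a population correlation matrix (no rows).

    Returns a dict with eigenvalues, pct_variance, correlations (DataFrame),
    contributions, group_contributions, group weights.  This is the
    closed-form companion of :func:`fit_mfa` used for population oracles.
    """
    spec.validate(R.columns)
    cols = spec.active_columns
    K = R.loc[cols, cols].to_numpy()
    slices = list(spec.slices().values())
    lam1 = np.empty(len(slices))
    col_w = np.empty(len(cols))
    for gi, sl in enumerate(slices):
        lam1[gi] = float(np.linalg.eigvalsh(K[sl, sl])[-1])
        col_w[sl] = 1.0 / lam1[gi]
    sqw = np.sqrt(col_w)
    Kw = K * np.outer(sqw, sqw)
    evals, evecs = np.linalg.eigh(Kw)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    V = evecs[:, order]
    corr = np.sqrt(1.0 / col_w)[:, None] * V * np.sqrt(evals)[None, :]
    for s in range(V.shape[1]):
        j = int(np.argmax(np.abs(corr[:, s])))
        if corr[j, s] < 0:
            V[:, s] = -V[:, s]
            corr[:, s] = -corr[:, s]
    dims = [f"dim{i + 1}" for i in range(len(cols))]
    contrib = pd.DataFrame(100.0 * V**2, index=cols, columns=dims)
    group_contrib = pd.DataFrame(
        {g: contrib.loc[spec.groups[g]].sum(axis=0) for g in spec.groups}
    ).T
    return {
        "eigenvalues": evals,
        "pct_variance": 100.0 * evals / evals.sum(),
        "correlations": pd.DataFrame(corr, index=cols, columns=dims),
        "contributions": contrib,
        "group_contributions": group_contrib,
        "group_weights": {g: 1.0 / lam1[i] for i, g in enumerate(spec.groups)},
        "group_first_eigenvalues": {g: lam1[i] for i, g in enumerate(spec.groups)},
    }


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def standardize_and_weight(
    table: pd.DataFrame, spec: GroupSpec
) -> tuple[pd.DataFrame, dict[str, float], dict]:
    """Center/scale the active columns and apply the MFA group weighting.

    Returns ``(weighted, weights, info)`` where ``weighted`` holds the
    group-weighted standardized columns (each group's sub-table then has
    first eigenvalue exactly one), ``weights`` maps group name to
    ``1/lambda1(g)``, and ``info`` records dropped-row counts and the first
    separate eigenvalues.
    """
    spec.validate(table.columns)
    cols = spec.active_columns
    kept, n_dropped = complete_cases(table, cols)
    if len(kept) < 3:
        raise ValueError(f"need at least 3 complete rows, got {len(kept)}")
    Y = kept[cols].to_numpy(dtype=float)
    core = _core_eigensystem(Y, list(spec.slices().values()), cols)
    weighted = pd.DataFrame(core["W"], index=kept.index, columns=cols)
    weights = {g: 1.0 / core["lambda1"][i] for i, g in enumerate(spec.groups)}
    info = {
        "n_rows": len(kept),
        "n_dropped": n_dropped,
        "group_first_eigenvalues": {
            g: float(core["lambda1"][i]) for i, g in enumerate(spec.groups)
        },
    }
    return weighted, weights, info


def fit_mfa(
    table: pd.DataFrame,
    spec: GroupSpec | None = None,
    n_dims: int = 2,
    aggregation: str | None = None,
) -> MFAResult:
    """Fit the common autonomic-subjective space on a trial (or aggregate) table."""
    spec = spec or GroupSpec()
    spec.validate(table.columns)
    cols = spec.active_columns
    kept, n_dropped = complete_cases(table, cols)
    if len(kept) < 3:
        raise ValueError(f"need at least 3 complete rows, got {len(kept)}")
    n = len(kept)
    Y = kept[cols].to_numpy(dtype=float)
    slices = list(spec.slices().values())
    core = _core_eigensystem(Y, slices, cols)
    evals = core["eigenvalues"]
    rank = int(np.sum(evals > max(evals[0], 1.0) * 1e-12))
    if n_dims > rank:
        warnings.warn(
            f"n_dims={n_dims} exceeds rank {rank}; truncating", RuntimeWarning, stacklevel=2
        )
        n_dims = rank
    V = core["V"]
    dims = [f"dim{i + 1}" for i in range(n_dims)]
    all_dims = [f"dim{i + 1}" for i in range(len(cols))]

    W = core["W"]
    F = W @ V  # global row scores, all dims
    scores = pd.DataFrame(F[:, :n_dims], index=kept.index, columns=dims)
    corr = pd.DataFrame(core["correlations"], index=cols, columns=all_dims)
    cos2 = corr**2
    contributions = pd.DataFrame(100.0 * V**2, index=cols, columns=all_dims)
    group_contrib = pd.DataFrame(
        {g: contributions.loc[spec.groups[g]].sum(axis=0) for g in spec.groups}
    ).T

    n_groups = len(spec.groups)
    partial_scores: dict[str, pd.DataFrame] = {}
    for g, sl in zip(spec.groups, slices):
        Fg = n_groups * (W[:, sl] @ V[sl, :n_dims])
        partial_scores[g] = pd.DataFrame(Fg, index=kept.index, columns=dims)

    # partial axes: separate PCA per group vs global dimensions
    pa_rows = []
    pa_index = []
    X = core["X"]
    for g, sl in zip(spec.groups, slices):
        Xg = X[:, sl]
        Kg = (Xg.T @ Xg) / n
        gev, gvec = np.linalg.eigh(Kg)
        order = np.argsort(gev)[::-1]
        gvec = gvec[:, order]
        Fg_sep = Xg @ gvec
        for k in range(Xg.shape[1]):
            sep = Fg_sep[:, k]
            if sep.std() == 0:
                row = np.zeros(n_dims)
            else:
                row = [
                    float(np.corrcoef(sep, F[:, s])[0, 1]) if F[:, s].std() > 0 else 0.0
                    for s in range(n_dims)
                ]
            pa_rows.append(row)
            pa_index.append((g, k + 1))
    partial_axes_table = pd.DataFrame(
        pa_rows, index=pd.MultiIndex.from_tuples(pa_index, names=["group", "sep_dim"]), columns=dims
    )

    result = MFAResult(
        eigenvalues=evals,
        pct_variance=100.0 * evals / evals.sum(),
        total_inertia=float(evals.sum()),
        n_dims=n_dims,
        variables=cols,
        groups={g: list(v) for g, v in spec.groups.items()},
        group_first_eigenvalues={
            g: float(core["lambda1"][i]) for i, g in enumerate(spec.groups)
        },
        group_weights={g: float(1.0 / core["lambda1"][i]) for i, g in enumerate(spec.groups)},
        scores=scores,
        correlations=corr,
        cos2=cos2,
        contributions=contributions,
        group_contributions=group_contrib,
        partial_scores=partial_scores,
        partial_axes_table=partial_axes_table,
        supplementary_coords={},
        column_means=pd.Series(core["mu"], index=cols),
        column_sds=pd.Series(core["sd"], index=cols),
        n_rows=n,
        n_dropped=n_dropped,
        aggregation=aggregation,
    )
    for cat in spec.supplementary:
        if cat in kept.columns:
            result.supplementary_coords[cat] = project_supplementary(result, kept[cat])[
                "coordinates"
            ]
    return result


def partial_coordinates(result: MFAResult) -> dict[str, pd.DataFrame]:
    """Per-group partial row coordinates (their group-mean is the global score)."""
    return result.partial_scores


def partial_axes(result: MFAResult) -> pd.DataFrame:
    """Correlations between each group's separate-PCA dimensions and the global ones."""
    return result.partial_axes_table


def project_supplementary(result: MFAResult, categories: pd.Series) -> dict:
    """Barycentric projection of a categorical variable onto the fitted space.

    Returns global category coordinates and, per group, the barycentres of the
    partial coordinates.  Rows with a missing category are an error because a
    barycentre would silently drop them.
    """
    cats = categories.reindex(result.scores.index)
    if cats.isna().any():
        raise ValueError("categorical variable undefined for some retained rows")
    coords = result.scores.groupby(cats, observed=True).mean()
    per_group = {
        g: ps.groupby(cats, observed=True).mean() for g, ps in result.partial_scores.items()
    }
    return {"coordinates": coords, "per_group": per_group}


_AGGREGATIONS = {
    "participant": [PARTICIPANT],
    "stimulus": [STIMULUS],
    "participant_valence": [PARTICIPANT, VALENCE_CATEGORY],
    "participant_arousal": [PARTICIPANT, AROUSAL_CATEGORY],
}


def aggregate_table(table: pd.DataFrame, by: str) -> pd.DataFrame:
    """Cell means of the quantitative variables for a sensitivity variant.

    ``by`` is one of ``participant``, ``stimulus``, ``participant_valence``,
    ``participant_arousal``.  Grouping keys are kept as columns; standardization
    happens downstream, after aggregation, within each variant.
    """
    if by not in _AGGREGATIONS:
        raise ValueError(f"unknown aggregation {by!r}; choose from {sorted(_AGGREGATIONS)}")
    keys = _AGGREGATIONS[by]
    num_cols = [c for c in table.columns if c not in keys and pd.api.types.is_numeric_dtype(table[c])]
    agg = table.groupby(keys, observed=True, dropna=True)[num_cols].mean().reset_index()
    # keep stimulus-level categoricals where they are constant within cells
    if by == "stimulus":
        meta = table.groupby(STIMULUS, observed=True)[[VALENCE_CATEGORY, AROUSAL_CATEGORY]].first()
        agg = agg.merge(meta.reset_index(), on=STIMULUS, how="left")
    return agg
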