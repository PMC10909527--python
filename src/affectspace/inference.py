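"""Hierarchy-respecting resampling inference for the common factor space.

Two complementary procedures quantify the stability and significance of the
fitted space:

* **cluster bootstrap** — participants are resampled with replacement (each
  keeping all their trials, respecting the hierarchical dependence), the MFA
  is refit per replicate, every replicate is aligned to the reference
  solution (dimension reordering and sign flips), and percentile 95%
  confidence intervals are taken from the .025/.975 quantiles of the
  bootstrap distributions of eigenvalues and variable-dimension correlations;
* **stratified permutation null** — each active quantitative column is
  independently reshuffled within strata (by default participant x valence
  category), destroying every cross-variable association while preserving
  marginals and stratum composition; the MFA is refit per replicate and
  one-tailed add-one p-values are computed for eigenvalues and absolute
  correlations.

The retained-dimension count is the number of leading consecutive dimensions
whose eigenvalue permutation p-value falls below alpha.  All procedures are
bit-reproducible under a fixed seed, independent of the parallelism degree
(per-replicate child seeds are spawned deterministically).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .mfa import GroupSpec, MFAResult, ZeroVarianceError, _core_eigensystem, fit_mfa
from .schema import PARTICIPANT, VALENCE_CATEGORY, complete_cases

__all__ = [
    "InferenceReport",
    "cluster_bootstrap",
    "permutation_null",
    "align_solution",
    "retained_dimensions",
    "infer_space",
]


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def greedy_match(ref: np.ndarray, cand: np.ndarray, n_dims: int) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one matching of candidate to reference dimensions.

    ``ref``/``cand`` are (variables x dims) correlation matrices.  Similarity
    is the absolute Pearson correlation between loading vectors; dimensions
    are matched greedily by decreasing similarity and signed so the matched
    correlation is positive.  Returns (perm, signs) such that
    ``cand[:, perm] * signs`` aligns with ``ref[:, :n_dims]``.
    """
    n_cand = cand.shape[1]
    sim = np.zeros((n_dims, n_cand))
    for r in range(n_dims):
        a = ref[:, r] - ref[:, r].mean()
        na = np.linalg.norm(a)
        for c in range(n_cand):
            b = cand[:, c] - cand[:, c].mean()
            nb = np.linalg.norm(b)
            sim[r, c] = 0.0 if na == 0 or nb == 0 else float(a @ b / (na * nb))
    perm = np.full(n_dims, -1)
    signs = np.ones(n_dims)
    absim = np.abs(sim)
    free_r = list(range(n_dims))
    free_c = list(range(n_cand))
    while free_r:
        sub = absim[np.ix_(free_r, free_c)]
        i, j = np.unravel_index(int(np.argmax(sub)), sub.shape)
        r, c = free_r[i], free_c[j]
        perm[r] = c
        signs[r] = 1.0 if sim[r, c] >= 0 else -1.0
        free_r.remove(r)
        free_c.remove(c)
    return perm, signs


def align_solution(reference: MFAResult, candidate: MFAResult, n_dims: int | None = None) -> dict:
    """Align a candidate MFA solution to a reference.

    Dimensions of the candidate are reordered and sign-flipped to maximize the
    summed absolute correlation between matched loading vectors.  Returns a
    dict with the aligned correlation frame, aligned eigenvalues, the
    permutation, the signs, and flags for whether any swap/flip occurred.
    """
    if list(reference.variables) != list(candidate.variables):
        raise ValueError("reference and candidate must share the same variables")
    n_dims = n_dims or reference.n_dims
    ref = reference.correlations.to_numpy()[:, :n_dims]
    cand_full = candidate.correlations.to_numpy()
    if cand_full.shape[1] < n_dims:
        pad = np.full((cand_full.shape[0], n_dims - cand_full.shape[1]), np.nan)
        cand_full = np.hstack([cand_full, pad])
    perm, signs = greedy_match(ref, cand_full, n_dims)
    aligned_corr = cand_full[:, perm] * signs[None, :]
    aligned_eig = candidate.eigenvalues[perm]
    return {
        "correlations": pd.DataFrame(
            aligned_corr, index=reference.variables, columns=[f"dim{i+1}" for i in range(n_dims)]
        ),
        "eigenvalues": aligned_eig,
        "perm": perm,
        "signs": signs,
        "swapped": bool(np.any(perm != np.arange(n_dims))),
        "flipped": bool(np.any(signs < 0)),
    }


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


@dataclass
class InferenceReport:
    """Bootstrap CIs and permutation p-values for the fitted space."""

    eigen_table: pd.DataFrame  # dim, eigenvalue, pct_variance, ci_low, ci_high, p_perm
    loading_tables: dict[str, pd.DataFrame]  # per dim: variable, estimate, ci_low, ci_high, p_perm
    n_boot: int
    n_perm: int
    alpha: float
    n_dims: int
    alignment: dict = field(default_factory=dict)
    n_boot_dropped: int = 0
    retained: int = 0


def retained_dimensions(report: InferenceReport, alpha: float | None = None) -> int:
    """Leading consecutive dimensions with eigenvalue permutation p < alpha."""
    alpha = alpha if alpha is not None else report.alpha
    count = 0
    for p in report.eigen_table["p_perm"]:
        if np.isnan(p) or p >= alpha:
            break
        count += 1
    return count


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _prepare(table: pd.DataFrame, spec: GroupSpec):
    spec.validate(table.columns)
    cols = spec.active_columns
    kept, _ = complete_cases(table, cols)
    Y = kept[cols].to_numpy(dtype=float)
    slices = list(spec.slices().values())
    return kept, Y, slices, cols


def _boot_batch(Y, slices, cols, sampler, seeds, ref_corr, n_dims):
    out_eig, out_corr, flags = [], [], []
    n_drop = 0
    for s in seeds:
        rng = np.random.default_rng(s)
        rows = sampler(rng)
        try:
            core = _core_eigensystem(Y[rows], slices, cols)
        except ZeroVarianceError:
            n_drop += 1
            continue
        perm, signs = greedy_match(ref_corr, core["correlations"], n_dims)
        out_eig.append(core["eigenvalues"][perm])
        out_corr.append(core["correlations"][:, perm] * signs[None, :])
        flags.append(
            (bool(np.any(perm != np.arange(n_dims))), bool(np.any(signs < 0)))
        )
    return out_eig, out_corr, flags, n_drop


def cluster_bootstrap(
    table: pd.DataFrame,
    spec: GroupSpec | None = None,
    n_boot: int = 10_000,
    unit: str = "crossed",
    seed: int | None = None,
    n_dims: int = 2,
    n_jobs: int = 1,
) -> dict:
    """Hierarchy-respecting bootstrap of the MFA eigenstructure.

    ``unit="participant"`` (or ``"stimulus"``) resamples whole clusters with
    replacement, every trial of a drawn unit travelling with it.
    ``unit="crossed"`` is the two-way (pigeonhole) bootstrap: participants
    and stimuli are resampled independently and a replicate consists of all
    cells at sampled-participant x sampled-stimulus combinations — the
    scheme whose variance matches crossed random effects, where one-factor
    cluster resampling understates the sampling variability of the
    eigenstructure.

    The MFA is refit per replicate and aligned to the reference fit.
    Replicates with a zero-variance active column are dropped and counted,
    never silently retained.  Returns a dict with the reference result,
    replicate distributions, percentile CIs and alignment diagnostics.
    """
    spec = spec or GroupSpec()
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    kept, Y, slices, cols = _prepare(table, spec)

    if unit == "crossed":
        from .schema import STIMULUS

        p_lv, p_codes = np.unique(kept[PARTICIPANT].to_numpy(), return_inverse=True)
        s_lv, s_codes = np.unique(kept[STIMULUS].to_numpy(), return_inverse=True)
        if len(p_lv) < 5 or len(s_lv) < 5:
            raise ValueError("need at least 5 participants and 5 stimuli")
        cell = np.full((len(p_lv), len(s_lv)), -1, dtype=np.int64)
        cell[p_codes, s_codes] = np.arange(len(kept))

        def sampler(rng):
            pi = rng.integers(0, len(p_lv), size=len(p_lv))
            si = rng.integers(0, len(s_lv), size=len(s_lv))
            rows = cell[np.ix_(pi, si)].ravel()
            return rows[rows >= 0]

    else:
        units = kept[unit].to_numpy()
        unit_levels, unit_codes = np.unique(units, return_inverse=True)
        if len(unit_levels) < 5:
            raise ValueError(f"need at least 5 resampling units, got {len(unit_levels)}")
        unit_rows = [np.flatnonzero(unit_codes == i) for i in range(len(unit_levels))]

        def sampler(rng):
            pick = rng.integers(0, len(unit_rows), size=len(unit_rows))
            return np.concatenate([unit_rows[i] for i in pick])

    reference = fit_mfa(kept, spec, n_dims=n_dims)
    ref_corr = reference.correlations.to_numpy()[:, :n_dims]

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(n_boot)
    if n_jobs == 1:
        batches = [_boot_batch(Y, slices, cols, sampler, seeds, ref_corr, n_dims)]
    else:
        chunks = np.array_split(np.arange(n_boot), max(1, min(n_jobs * 4, n_boot)))
        batches = Parallel(n_jobs=n_jobs)(
            delayed(_boot_batch)(
                Y, slices, cols, sampler, [seeds[i] for i in ch], ref_corr, n_dims
            )
            for ch in chunks
            if len(ch)
        )
    eig_list, corr_list, flag_list, n_drop = [], [], [], 0
    for be, bc, bf, bd in batches:
        eig_list += be
        corr_list += bc
        flag_list += bf
        n_drop += bd
    if not eig_list:
        raise RuntimeError("every bootstrap replicate was degenerate")
    eig = np.asarray(eig_list)  # (B, n_dims)
    corr = np.asarray(corr_list)  # (B, p, n_dims)
    ci_eig = np.quantile(eig, [0.025, 0.975], axis=0)
    ci_corr = np.quantile(corr, [0.025, 0.975], axis=0)
    flags = np.asarray(flag_list, dtype=bool)
    return {
        "reference": reference,
        "eigenvalues": eig,
        "correlations": corr,
        "eigen_ci": pd.DataFrame(
            {
                "estimate": reference.eigenvalues[:n_dims],
                "ci_low": ci_eig[0],
                "ci_high": ci_eig[1],
            },
            index=[f"dim{i+1}" for i in range(n_dims)],
        ),
        "correlation_ci": {
            f"dim{s+1}": pd.DataFrame(
                {
                    "estimate": ref_corr[:, s],
                    "ci_low": ci_corr[0, :, s],
                    "ci_high": ci_corr[1, :, s],
                },
                index=cols,
            )
            for s in range(n_dims)
        },
        "n_boot": len(eig_list),
        "n_dropped": n_drop,
        "prop_swapped": float(flags[:, 0].mean()),
        "prop_flipped": float(flags[:, 1].mean()),
    }


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


def _stratum_codes(kept: pd.DataFrame, strata: list[str]) -> np.ndarray:
    if not strata:
        return np.zeros(len(kept), dtype=np.int64)
    key = kept[strata[0]].astype(str)
    for s in strata[1:]:
        key = key + "\x1f" + kept[s].astype(str)
    return pd.factorize(key)[0]


def _permute_within(Y: np.ndarray, codes: np.ndarray, order: np.ndarray, rng) -> np.ndarray:
    """Independently permute every column within strata.

    ``order`` is a stable argsort of the stratum codes; each column gets its
    own random within-stratum ordering via a lexsort on (codes, noise).
    """
    out = np.empty_like(Y)
    n = Y.shape[0]
    for j in range(Y.shape[1]):
        idx = np.lexsort((rng.random(n), codes))
        out[order, j] = Y[idx, j]
    return out


def _perm_batch(Y, slices, cols, codes, order, seeds):
    eigs, corrs = [], []
    for s in seeds:
        rng = np.random.default_rng(s)
        Yp = _permute_within(Y, codes, order, rng)
        core = _core_eigensystem(Yp, slices, cols)
        eigs.append(core["eigenvalues"])
        corrs.append(np.abs(core["correlations"]))
    return eigs, corrs


def permutation_null(
    table: pd.DataFrame,
    spec: GroupSpec | None = None,
    strata: list[str] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    n_dims: int = 2,
    n_jobs: int = 1,
) -> dict:
    """Stratified-permutation null distribution of the MFA eigenstructure.

    Every active column is independently reshuffled within strata, the MFA is
    refit, and one-tailed add-one p-values are returned:
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.  For eigenvalues the
    test statistic is the dimension's share of total inertia (raw
    eigenvalues are not comparable across refits because group weights adapt
    to each permuted dataset; raw-eigenvalue p-values are also returned for
    reference); for loadings it is the absolute variable-dimension
    correlation.  Singleton strata are unpermutable and left fixed (with a
    warning).
    """
    spec = spec or GroupSpec()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1 (p-values undefined otherwise)")
    strata = [PARTICIPANT, VALENCE_CATEGORY] if strata is None else strata
    kept, Y, slices, cols = _prepare(table, spec)
    codes = _stratum_codes(kept, strata)
    sizes = np.bincount(codes)
    if (sizes == 1).any():
        warnings.warn(
            f"{int((sizes == 1).sum())} singleton stratum(ta); those rows stay fixed",
            RuntimeWarning,
            stacklevel=2,
        )
    order = np.argsort(codes, kind="stable")

    observed = _core_eigensystem(Y, slices, cols)
    obs_eig = observed["eigenvalues"]
    obs_abs = np.abs(observed["correlations"])

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(n_perm)
    if n_jobs == 1:
        batches = [_perm_batch(Y, slices, cols, codes, order, seeds)]
    else:
        chunks = np.array_split(np.arange(n_perm), max(1, min(n_jobs * 4, n_perm)))
        batches = Parallel(n_jobs=n_jobs)(
            delayed(_perm_batch)(Y, slices, cols, codes, order, [seeds[i] for i in ch])
            for ch in chunks
            if len(ch)
        )
    null_eig = np.asarray([e for be, _ in batches for e in be])  # (R, p)
    null_abs = np.asarray([c for _, bc in batches for c in bc])  # (R, p, p)
    R = null_eig.shape[0]
    # raw eigenvalues are not comparable across refits because the group
    # weights adapt to each permuted dataset (the null's total inertia
    # differs from the observed one); the scale-free statistic is each
    # dimension's share of total inertia
    obs_pct = obs_eig / obs_eig.sum()
    null_pct = null_eig / null_eig.sum(axis=1, keepdims=True)
    p_eig = (1.0 + (null_pct >= obs_pct[None, :]).sum(axis=0)) / (R + 1.0)
    p_eig_raw = (1.0 + (null_eig >= obs_eig[None, :]).sum(axis=0)) / (R + 1.0)
    p_abs = (1.0 + (null_abs >= obs_abs[None, :, :]).sum(axis=0)) / (R + 1.0)
    return {
        "observed_eigenvalues": obs_eig,
        "null_eigenvalues": null_eig,
        "p_eigenvalues": p_eig,
        "p_eigenvalues_raw": p_eig_raw,
        "p_abs_correlations": pd.DataFrame(
            p_abs[:, :n_dims], index=cols, columns=[f"dim{i+1}" for i in range(n_dims)]
        ),
        "n_perm": R,
        "strata": strata,
    }


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------


def infer_space(
    table: pd.DataFrame,
    spec: GroupSpec | None = None,
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    strata: list[str] | None = None,
    unit: str = "crossed",
    seed: int | None = None,
    n_dims: int = 2,
    n_jobs: int = 1,
) -> InferenceReport:
    """Run bootstrap CIs and permutation tests; assemble the joint report."""
    spec = spec or GroupSpec()
    root = np.random.SeedSequence(seed)
    s_boot, s_perm = root.spawn(2)
    boot = cluster_bootstrap(
        table, spec, n_boot=n_boot, unit=unit, seed=s_boot, n_dims=n_dims, n_jobs=n_jobs
    )
    perm = permutation_null(
        table, spec, strata=strata, n_perm=n_perm, seed=s_perm, n_dims=n_dims, n_jobs=n_jobs
    )
    ref: MFAResult = boot["reference"]
    p_all = len(ref.variables)
    eigen_table = pd.DataFrame(
        {
            "eigenvalue": ref.eigenvalues,
            "pct_variance": ref.pct_variance,
            "ci_low": [
                boot["eigen_ci"]["ci_low"].iloc[i] if i < n_dims else np.nan for i in range(p_all)
            ],
            "ci_high": [
                boot["eigen_ci"]["ci_high"].iloc[i] if i < n_dims else np.nan for i in range(p_all)
            ],
            "p_perm": perm["p_eigenvalues"],
        },
        index=[f"dim{i+1}" for i in range(p_all)],
    )
    loading_tables = {}
    for s in range(n_dims):
        dim = f"dim{s+1}"
        lt = boot["correlation_ci"][dim].copy()
        lt["p_perm"] = perm["p_abs_correlations"][dim]
        loading_tables[dim] = lt
    report = InferenceReport(
        eigen_table=eigen_table,
        loading_tables=loading_tables,
        n_boot=boot["n_boot"],
        n_perm=perm["n_perm"],
        alpha=alpha,
        n_dims=n_dims,
        alignment={
            "prop_swapped": boot["prop_swapped"],
            "prop_flipped": boot["prop_flipped"],
        },
        n_boot_dropped=boot["n_dropped"],
    )
    report.retained = retained_dimensions(report, alpha)
    return report
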