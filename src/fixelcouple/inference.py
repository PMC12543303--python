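"""Group inference for coupling statistics.

Permutation nulls for edge-wise and node-wise coupling differences use the
participant as the exchangeable unit: each permutation reassigns subjects
of the two groups to pseudo-groups of the original sizes, keeping every
subject's SC and FC paired, and recomputes the per-key coupling
difference.  Two-tailed p values use the add-one estimator
``(1 + #{|null| >= |obs|}) / (1 + n_perm)``, which is exchangeability-valid
and never zero.  Significance is flagged at p < 0.01 Bonferroni-corrected
over the four SC weightings (0.0025); Benjamini-Hochberg FDR is applied
on top, pooled across all edges of all comparisons when several runs are
combined.

The module also carries the scalar comparisons of the analysis: Fisher
r-to-Z contrast of group-average couplings, ANCOVA (group + age + sex)
with estimated-marginal-means post hocs, the chi-square independence test
with adjusted standardized residuals for demographics, and one-way
ANOVA/Tukey/Wilcoxon tests for cognitive outcomes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import coupling_core
from .coupling_core import (
    MIN_SUBJECTS,
    nan_pearson_columns,
    stack_edges,
    stack_strengths,
)


def bonferroni_threshold(base_p: float = 0.01, n_metrics: int = 4) -> float:
    """Two-tailed significance threshold corrected across SC weightings."""
    if n_metrics < 1:
        raise ValueError("n_metrics must be >= 1")
    return base_p / n_metrics


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1, monotone).

    Invariant to input ordering and idempotent on already-adjusted
    monotone inputs.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int):
    """Compare two independent correlations via Fisher's r-to-Z transform.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-tailed
    normal p.  For group-average couplings, n is the number of edge pairs
    that entered each group's correlation.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1 for the Fisher transform")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("each sample size must exceed 3")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# permutation inference


@dataclass
class PermutationTestResult:
    """Per-key permutation results for one group pair and one level."""

    level: str
    modality: str
    group_a: str
    group_b: str
    n_permutations: int
    table: pd.DataFrame  # key, r_a, r_b, diff, p, bonferroni_pass, q_fdr


def _group_diff(x, y, idx_a, idx_b, min_n):
    r_a = nan_pearson_columns(x[idx_a], y[idx_a], min_n=min_n)
    r_b = nan_pearson_columns(x[idx_b], y[idx_b], min_n=min_n)
    return r_a, r_b, r_a - r_b


def permutation_test(
    subjects: Sequence,
    group_a: str,
    group_b: str,
    level: str = "edge",
    modality: str = "FD",
    n_perm: int = 5000,
    seed: int | None = None,
    alpha_threshold: float | None = None,
    min_subjects: int = MIN_SUBJECTS,
    exhaustive: bool = False,
) -> PermutationTestResult:
    """Permutation test of per-edge or per-node coupling differences.

    The observed statistic per key is r(group_a) - r(group_b).  Nulls come
    from reassigning the pooled subjects to pseudo-groups of the original
    sizes (SC and FC stay paired within a subject).  ``exhaustive=True``
    enumerates every assignment (feasible for small pools) and reports the
    exact proportion-based p; otherwise Monte Carlo with the add-one
    estimator.  Keys undefined in either group (too few subjects, zero
    variance) get NaN p.
    """
    if group_a == group_b:
        raise ValueError("groups must be distinct")
    members = [s for s in subjects if s.group in (group_a, group_b)]
    labels = np.array([s.group for s in members])
    n_a = int((labels == group_a).sum())
    n_b = int((labels == group_b).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be nonempty")
    if not exhaustive and n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small", stacklevel=2)

    if level == "edge":
        x, y = stack_edges(members, modality)
    elif level == "node":
        x, y = stack_strengths(members, modality)
    else:
        raise ValueError("level must be 'edge' or 'node'")

    idx_a0 = np.flatnonzero(labels == group_a)
    idx_b0 = np.flatnonzero(labels == group_b)
    r_a, r_b, observed = _group_diff(x, y, idx_a0, idx_b0, min_subjects)
    abs_obs = np.abs(observed)

    all_idx = np.arange(len(members))
    if exhaustive:
        count_ge = np.zeros(x.shape[1])
        total = 0
        for combo in itertools.combinations(all_idx, n_a):
            ia = np.asarray(combo)
            ib = np.setdiff1d(all_idx, ia, assume_unique=True)
            _, _, diff = _group_diff(x, y, ia, ib, min_subjects)
            count_ge += np.abs(diff) >= abs_obs - 1e-12
            total += 1
        p = count_ge / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count_ge = np.zeros(x.shape[1])
        for _ in range(n_perm):
            perm = rng.permutation(all_idx)
            _, _, diff = _group_diff(x, y, perm[:n_a], perm[n_a:], min_subjects)
            count_ge += np.abs(diff) >= abs_obs - 1e-12
        p = (1.0 + count_ge) / (1.0 + n_perm)
        n_used = n_perm

    p = np.where(np.isfinite(observed), p, np.nan)
    threshold = (
        bonferroni_threshold() if alpha_threshold is None else alpha_threshold
    )
    finite = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if finite.any():
        q[finite] = bh_fdr(p[finite])
    table = pd.DataFrame(
        {
            "key": np.arange(x.shape[1]),
            "r_a": r_a,
            "r_b": r_b,
            "diff": observed,
            "p": p,
            "bonferroni_pass": (p < threshold) & finite,
            "q_fdr": q,
        }
    )
    return PermutationTestResult(
        level=level,
        modality=modality,
        group_a=group_a,
        group_b=group_b,
        n_permutations=n_used,
        table=table,
    )


def pool_fdr(results: Sequence[PermutationTestResult]) -> None:
    """Recompute q_fdr pooled across all keys of all comparisons, in place."""
    frames = [r.table for r in results]
    p_all = np.concatenate([f["p"].to_numpy() for f in frames])
    finite = np.isfinite(p_all)
    q_all = np.full_like(p_all, np.nan)
    if finite.any():
        q_all[finite] = bh_fdr(p_all[finite])
    start = 0
    for f in frames:
        stop = start + len(f)
        f["q_fdr"] = q_all[start:stop]
        start = stop


# ---------------------------------------------------------------------------
# ANCOVA with marginal-means contrasts


@dataclass
class ContrastResult:
    pair: tuple
    estimate: float
    t: float
    df_resid: int
    p: float


@dataclass
class AncovaResult:
    f_stat: float
    df_num: int
    df_resid: int
    p: float
    contrasts: list
    model: object


def ancova_group_effect(
    data: pd.DataFrame,
    response: str,
    group_col: str = "group",
    covariates: Sequence[str] = ("age", "sex"),
) -> AncovaResult:
    """Linear model ``response ~ group + covariates``; group F test and
    covariate-adjusted pairwise group contrasts.

    Marginal means are evaluated at the mean of continuous covariates and
    averaged with equal weight over the levels of categorical covariates
    (sex), reproducing estimated-marginal-means behavior.  Contrast t
    statistics use the model residual df (N - number of parameters:
    387 at the reference N = 392 with 3 groups, age and sex).
    """
    df = data.dropna(subset=[response, group_col, *covariates]).copy()
    terms = [f"C({group_col})"]
    categorical = []
    for cov in covariates:
        if df[cov].dtype == object or str(df[cov].dtype) == "category":
            terms.append(f"C({cov})")
            categorical.append(cov)
        else:
            terms.append(cov)
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    row = anova.loc[f"C({group_col})"]
    df_resid = int(model.df_resid)

    # design rows for marginal means: covariate means, equal weight on
    # categorical covariate levels
    from patsy import dmatrix

    design_info = model.model.data.design_info
    groups = sorted(df[group_col].unique())
    mean_rows = {}
    for g in groups:
        rows = []
        cat_levels = [sorted(df[c].unique()) for c in categorical]
        for combo in itertools.product(*cat_levels) if categorical else [()]:
            point = {group_col: g}
            for cov in covariates:
                if cov in categorical:
                    point[cov] = combo[categorical.index(cov)]
                else:
                    point[cov] = df[cov].mean()
            rows.append(point)
        mat = np.asarray(
            dmatrix(design_info, pd.DataFrame(rows), return_type="matrix")
        )
        mean_rows[g] = mat.mean(axis=0)

    contrasts = []
    cov_beta = model.cov_params().to_numpy()
    beta = model.params.to_numpy()
    for g1, g2 in itertools.combinations(groups, 2):
        L = mean_rows[g1] - mean_rows[g2]
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov_beta @ L))
        t = est / se
        p = 2.0 * sps.t.sf(abs(t), df_resid)
        contrasts.append(
            ContrastResult(pair=(g1, g2), estimate=est, t=float(t),
                           df_resid=df_resid, p=float(p))
        )
    return AncovaResult(
        f_stat=float(row["F"]),
        df_num=int(row["df"]),
        df_resid=df_resid,
        p=float(row["PR(>F)"]),
        contrasts=contrasts,
        model=model,
    )


# ---------------------------------------------------------------------------
# demographics and outcomes


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    expected: np.ndarray
    adjusted_residuals: np.ndarray


def chi_square_independence(table) -> ChiSquareResult:
    """Chi-square independence test with adjusted standardized residuals.

    The adjusted residual for cell (i, j) is
    (O - E) / sqrt(E (1 - row_i/N) (1 - col_j/N)); values beyond ~2 flag
    cells driving the association.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be two-dimensional")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row or column margin")
    expected = row @ col / total
    chi2, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    adj = (obs - expected) / np.sqrt(
        expected * (1.0 - row / total) * (1.0 - col / total)
    )
    return ChiSquareResult(
        chi2=float(chi2), df=int(dof), p=float(p),
        expected=expected, adjusted_residuals=adj,
    )


@dataclass
class OutcomeTestResult:
    f_stat: float
    df_num: int
    df_resid: int
    p_anova: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj
    ranksum: pd.DataFrame  # group1, group2, statistic, p, q_fdr


def outcome_group_tests(
    data: pd.DataFrame, outcome: str, group_col: str = "group"
) -> OutcomeTestResult:
    """One-way ANOVA + Tukey HSD, and Wilcoxon rank-sum pairs with FDR."""
    df = data.dropna(subset=[outcome, group_col])
    groups = sorted(df[group_col].unique())
    samples = [df.loc[df[group_col] == g, outcome].to_numpy() for g in groups]
    if len(groups) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least 2 observations")
    f_stat, p_anova = sps.f_oneway(*samples)
    tk = pairwise_tukeyhsd(df[outcome].to_numpy(), df[group_col].to_numpy())
    pairs = list(itertools.combinations(tk.groupsunique, 2))
    tukey = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": tk.meandiffs,
            "p_adj": tk.pvalues,
        }
    )
    rows = []
    for (g1, s1), (g2, s2) in itertools.combinations(zip(groups, samples), 2):
        stat, p = sps.ranksums(s1, s2)
        rows.append({"group1": g1, "group2": g2, "statistic": stat, "p": p})
    ranksum = pd.DataFrame(rows)
    ranksum["q_fdr"] = bh_fdr(ranksum["p"].to_numpy())
    n = len(df)
    return OutcomeTestResult(
        f_stat=float(f_stat),
        df_num=len(groups) - 1,
        df_resid=n - len(groups),
        p_anova=float(p_anova),
        tukey=tukey,
        ranksum=ranksum,
    )
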