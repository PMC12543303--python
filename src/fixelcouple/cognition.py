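"""Memory composite via one-factor CFA, and coupling-on-cognition models.

The memory composite is a confirmatory factor analysis with a single
latent factor measured by the four RAVLT indicators (learning, immediate
recall, 30-minute delayed recall, recognition), each min-max scaled to
[0, 1] beforehand.  The model is

    x_k = lambda_k * eta + e_k,   eta ~ N(0, 1),  e_k ~ N(0, psi_k),

identified by fixing the latent variance to 1 with all four loadings
free and uncorrelated residuals (10 sample moments - 8 free parameters
= 2 df).  Maximum-likelihood estimation minimizes the discrepancy

    F_ML = log|Sigma(theta)| + tr(S Sigma^{-1}) - log|S| - p

and the fit statistic is chi2 = (n - 1) * F_ML at the optimum, with
CFI against the independence baseline, RMSEA (point estimate and 90%
interval from the noncentral chi-square), and SRMR over standardized
residual moments.  Factor scores use the regression method and are
min-max scaled to [0, 1] to give the composite.

The regression stage relates per-subject DMN coupling (within-DMN edge
coupling and DMN nodal-strength coupling) to MMSE and the memory
composite, controlling for age, sex and intracranial volume, with
standardized betas, collinearity diagnostics (VIF, tolerance, pairwise
predictor correlations) and FDR over the family of coupling coefficients
across the four SC weightings and two outcomes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.optimize import minimize
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from . import coupling_core, inference
from .connectome_model import RAVLT_SCORES, SC_MODALITIES


@dataclass
class CfaFit:
    loadings: np.ndarray
    residual_variances: np.ndarray
    std_loadings: np.ndarray
    chi2: float
    df: int
    p: float
    cfi: float
    rmsea: float
    rmsea_ci90: tuple
    srmr: float
    factor_scores: np.ndarray  # min-max scaled to [0, 1]
    raw_factor_scores: np.ndarray
    n: int
    converged: bool
    heywood: bool
    scale_minima: np.ndarray
    scale_maxima: np.ndarray


def minmax_scale(x: np.ndarray):
    """Column-wise min-max scaling to [0, 1]; returns (scaled, mins, maxs)."""
    x = np.asarray(x, dtype=float)
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    if np.any(span <= 0):
        raise ValueError("constant indicator cannot be min-max scaled")
    return (x - lo) / span, lo, hi


def rmsea_from_fit(chi2: float, df: int, n: int) -> float:
    """Closed-form RMSEA: sqrt(max(0, (chi2 - df) / (df * (n - 1))))."""
    return float(np.sqrt(max(0.0, (chi2 - df) / (df * (n - 1)))))


def _rmsea_interval(chi2: float, df: int, n: int, level: float = 0.90):
    """Confidence interval from the noncentral chi-square distribution."""
    lo_q = (1.0 + level) / 2.0  # 0.95
    hi_q = (1.0 - level) / 2.0  # 0.05

    def _solve(target):
        # find nc with ncx2.cdf(chi2, df, nc) == target
        if sps.chi2.cdf(chi2, df) < target:
            return 0.0
        f = lambda nc: sps.ncx2.cdf(chi2, df, nc) - target
        hi = max(chi2, 1.0)
        while f(hi) > 0:
            hi *= 2.0
        from scipy.optimize import brentq

        return brentq(f, 0.0, hi, xtol=1e-10)

    nc_lo = _solve(lo_q)
    nc_hi = _solve(hi_q)
    denom = df * (n - 1)
    return (float(np.sqrt(nc_lo / denom)), float(np.sqrt(nc_hi / denom)))


def _fml(params, s_cov, sign_logdet_s):
    """ML discrepancy and its analytic gradient w.r.t. (lambda, psi)."""
    p = s_cov.shape[0]
    lam = params[:p]
    psi = params[p:]
    sigma = np.outer(lam, lam) + np.diag(psi)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e6, np.zeros_like(params)
    try:
        inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        return 1e6, np.zeros_like(params)
    f = logdet + float(np.trace(s_cov @ inv)) - sign_logdet_s - p
    g_mat = inv - inv @ s_cov @ inv
    grad = np.concatenate([2.0 * g_mat @ lam, np.diag(g_mat)])
    return f, grad


def fit_one_factor_cfa(indicators, already_scaled: bool = False) -> CfaFit:
    """ML fit of the single-factor RAVLT measurement model.

    ``indicators`` is an n x 4 array/DataFrame; rows with any missing
    value are dropped (complete-case), and columns are min-max scaled to
    [0, 1] unless ``already_scaled``.  Requires at least 50 complete
    cases.  A Heywood case (negative residual variance at the optimum) is
    reported via the ``heywood`` flag, never silently clipped.
    """
    x = np.asarray(
        indicators[list(RAVLT_SCORES)]
        if isinstance(indicators, pd.DataFrame)
        and set(RAVLT_SCORES).issubset(indicators.columns)
        else indicators,
        dtype=float,
    )
    if x.ndim != 2 or x.shape[1] != 4:
        raise ValueError("indicators must be an n x 4 table")
    complete = ~np.isnan(x).any(axis=1)
    x = x[complete]
    n = x.shape[0]
    if n < 50:
        raise ValueError(f"need >= 50 complete cases, got {n}")
    if already_scaled:
        lo, hi = x.min(axis=0), x.max(axis=0)
    else:
        x, lo, hi = minmax_scale(x)
    p = 4
    s_cov = np.cov(x.T, ddof=1)
    sign_s, logdet_s = np.linalg.slogdet(s_cov)
    if sign_s <= 0:
        raise ValueError("sample covariance is singular")

    # F_ML is invariant under diagonal rescaling of the indicators, so fit
    # on the correlation matrix (well-conditioned regardless of the 0-1
    # scaling) and map loadings back to the covariance scale afterwards.
    diag = np.diag(s_cov)
    d_sd = np.sqrt(diag)
    s_corr = s_cov / np.outer(d_sd, d_sd)
    _, logdet_corr = np.linalg.slogdet(s_corr)
    evals, evecs = np.linalg.eigh(s_corr)
    lam0 = evecs[:, -1] * np.sqrt(evals[-1])
    if lam0.sum() < 0:
        lam0 = -lam0
    psi0 = np.clip(1.0 - lam0**2, 1e-4, None)

    # pass 1: psi = exp(theta) keeps Sigma positive definite throughout
    def _fml_logpsi(params):
        lam_ = params[:p]
        psi_ = np.exp(params[p:])
        f, g = _fml(np.concatenate([lam_, psi_]), s_corr, logdet_corr)
        return f, np.concatenate([g[:p], g[p:] * psi_])

    res1 = minimize(
        _fml_logpsi, np.concatenate([lam0, np.log(psi0)]), jac=True,
        method="L-BFGS-B",
        bounds=[(-2.0, 2.0)] * p + [(np.log(1e-10), np.log(4.0))] * p,
        options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10},
    )
    # pass 2: free psi from the barrier optimum, so a Heywood solution
    # (negative residual variance) can be reached and reported
    x1 = np.concatenate([res1.x[:p], np.exp(res1.x[p:])])
    res = minimize(
        _fml, x1, args=(s_corr, logdet_corr), method="L-BFGS-B", jac=True,
        bounds=[(-2.0, 2.0)] * p + [(-0.5, 4.0)] * p,
        options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10},
    )
    if res.fun > res1.fun:  # refinement failed; keep the barrier optimum
        res = res1
        res.x = x1
    lam = res.x[:p] * d_sd
    psi = res.x[p:] * diag
    if lam.sum() < 0:  # sign indeterminacy: orient loadings positive
        lam = -lam
    heywood = bool((psi < 0).any())
    if heywood:
        warnings.warn("Heywood case: negative residual variance", stacklevel=2)

    chi2 = max(0.0, (n - 1) * res.fun)
    df = p * (p + 1) // 2 - 2 * p  # 10 moments - 8 free parameters = 2
    p_chi2 = float(sps.chi2.sf(chi2, df))

    # independence baseline
    f_base = float(np.sum(np.log(diag)) - logdet_s)
    chi2_base = (n - 1) * f_base
    df_base = p * (p - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2 - df, chi2_base - df_base, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den

    rmsea = rmsea_from_fit(chi2, df, n)
    ci = _rmsea_interval(chi2, df, n)

    sigma = np.outer(lam, lam) + np.diag(psi)
    d_s = np.sqrt(diag)
    resid = s_cov / np.outer(d_s, d_s) - sigma / np.outer(d_s, d_s)
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))

    std_load = lam / np.sqrt(lam**2 + psi)
    # regression-method factor scores
    inv_sigma = np.linalg.inv(sigma)
    raw_scores = (x - x.mean(axis=0)) @ inv_sigma @ lam
    span = raw_scores.max() - raw_scores.min()
    scores = (raw_scores - raw_scores.min()) / span

    return CfaFit(
        loadings=lam,
        residual_variances=psi,
        std_loadings=std_load,
        chi2=float(chi2),
        df=df,
        p=p_chi2,
        cfi=float(np.clip(cfi, 0.0, 1.0)),
        rmsea=rmsea,
        rmsea_ci90=ci,
        srmr=srmr,
        factor_scores=scores,
        raw_factor_scores=raw_scores,
        n=n,
        converged=bool(res.success),
        heywood=heywood,
        scale_minima=lo,
        scale_maxima=hi,
    )


# ---------------------------------------------------------------------------
# coupling -> cognition regressions


@dataclass
class RegressionReport:
    modality: str
    outcome: str
    table: pd.DataFrame  # term, beta, ci_low, ci_high, p, (q_fdr)
    vif: Mapping
    tolerance: Mapping
    max_predictor_corr: float
    flags: list
    n: int


_PREDICTORS = ("dmn_edge_coupling", "dmn_node_coupling", "age", "sex", "icv")


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=0)


def coupling_cognition_table(cohort, modality: str) -> pd.DataFrame:
    """Per-subject DMN couplings plus covariates and outcomes."""
    rows = []
    for s in cohort.subjects:
        edge_r, node_r = coupling_core.subject_dmn_coupling(
            s, cohort.atlas, modality
        )
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "dmn_edge_coupling": edge_r,
                "dmn_node_coupling": node_r,
                "age": s.age,
                "sex": 1.0 if s.sex == "F" else 0.0,
                "icv": s.icv,
                "mmse": np.nan if s.mmse is None else s.mmse,
                **{
                    f"ravlt_{k}": (
                        np.nan if s.ravlt is None else s.ravlt.get(k, np.nan)
                    )
                    for k in RAVLT_SCORES
                },
            }
        )
    return pd.DataFrame(rows)


def cognition_regression(
    data: pd.DataFrame, modality: str, outcome: str
) -> RegressionReport:
    """One linear model: outcome ~ DMN edge + DMN node coupling + covariates.

    Response and continuous predictors are z-scored so betas are
    standardized; sex stays 0/1.  Collinearity diagnostics raise flags at
    VIF > 10, tolerance < 0.02, or |pairwise predictor r| > 0.8.
    """
    cols = [outcome, *_PREDICTORS]
    df = data.dropna(subset=cols).copy()
    n = len(df)
    y = _zscore(df[outcome].to_numpy(dtype=float))
    design = pd.DataFrame(index=df.index)
    for term in _PREDICTORS:
        v = df[term].to_numpy(dtype=float)
        design[term] = v if term == "sex" else _zscore(v)
    X = sm.add_constant(design)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "term": _PREDICTORS,
            "beta": [fit.params[t] for t in _PREDICTORS],
            "ci_low": [ci.loc[t, 0] for t in _PREDICTORS],
            "ci_high": [ci.loc[t, 1] for t in _PREDICTORS],
            "p": [fit.pvalues[t] for t in _PREDICTORS],
        }
    )
    Xv = X.to_numpy()
    vif = {
        term: float(variance_inflation_factor(Xv, i + 1))
        for i, term in enumerate(_PREDICTORS)
    }
    tol = {term: 1.0 / v for term, v in vif.items()}
    corr = design.corr().to_numpy()
    iu = np.triu_indices_from(corr, k=1)
    max_corr = float(np.abs(corr[iu]).max())
    flags = []
    for term, v in vif.items():
        if v > 10:
            flags.append(f"VIF>10 for {term}")
        if tol[term] < 0.02:
            flags.append(f"tolerance<0.02 for {term}")
    if max_corr > 0.8:
        flags.append("predictor intercorrelation > 0.8")
    return RegressionReport(
        modality=modality,
        outcome=outcome,
        table=table,
        vif=vif,
        tolerance=tol,
        max_predictor_corr=max_corr,
        flags=flags,
        n=n,
    )


def cognition_report(
    cohort,
    modalities: Sequence[str] = SC_MODALITIES,
    outcomes: Sequence[str] = ("mmse", "memory_composite"),
) -> pd.DataFrame:
    """All coupling-on-cognition models with FDR over coupling coefficients.

    One model per SC weighting and outcome.  The FDR family is the set of
    DMN coupling coefficients across all models (4 weightings x 2 outcomes
    x 2 terms = 16 tests at defaults); covariates are excluded from the
    family.
    """
    reports = []
    for modality in modalities:
        base = coupling_cognition_table(cohort, modality)
        for outcome in outcomes:
            df = base.copy()
            if outcome == "memory_composite":
                ind = df[[f"ravlt_{k}" for k in RAVLT_SCORES]].to_numpy()
                complete = ~np.isnan(ind).any(axis=1)
                fit = fit_one_factor_cfa(ind[complete])
                df = df.loc[complete].copy()
                df["memory_composite"] = fit.factor_scores
            reports.append(cognition_regression(df, modality, outcome))
    rows = []
    for rep in reports:
        for _, r in rep.table.iterrows():
            rows.append(
                {
                    "modality": rep.modality,
                    "outcome": rep.outcome,
                    "term": r["term"],
                    "beta": r["beta"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "p": r["p"],
                    "n": rep.n,
                    "flags": ";".join(rep.flags),
                }
            )
    out = pd.DataFrame(rows)
    family = out["term"].isin(["dmn_edge_coupling", "dmn_node_coupling"])
    q = np.full(len(out), np.nan)
    q[family.to_numpy()] = inference.bh_fdr(out.loc[family, "p"].to_numpy())
    out["q_fdr"] = q
    return out
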