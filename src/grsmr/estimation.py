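"""Causal odds-ratio estimation from the weighted allele score.

The estimator is an allele-score regression: logistic regression of case
status on the relative-25OHD score plus covariates (age band, sex and the
stratum-specific principal components).  The score coefficient is the
causal log-OR per SD increase in log 25OHD.

Because the GWAS weights carry sampling error, the naive information-matrix
SE understates the uncertainty.  A parametric bootstrap propagates the
weight imprecision: replicate weight vectors are drawn
``beta*_jb ~ N(beta_j, SE_j)`` independently across SNPs (no GWAS
covariance is published), the score is rebuilt and the model refit, and the
between-replicate variance of the log-OR is added to the naive variance:

    se_corrected^2 = se_naive^2 + Var_b(theta*_b).

The point estimate remains the original-weight fit; CI and p-value are
recomputed from the corrected SE (Wald / normal throughout).

The in-module Newton (IRLS) solver keeps the ~10^4 bootstrap refits cheap
by warm-starting each replicate at the main fit; it is cross-checked
against statsmodels in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .instrument import RelativeExposure, compute_relative_exposure
from .io_model import CausalEstimate, Cohort, GrsmrError, ValidationError, VariantWeight

logger = logging.getLogger("grsmr")

_Z975 = stats.norm.ppf(0.975)


class FitError(GrsmrError):
    """Logistic fit failed (non-convergence or separation)."""


@dataclass(frozen=True)
class AnalysisSpec:
    """What to fit: site, stratum, covariates, bootstrap settings.

    ``covariates=None`` means age band, sex and every principal component
    present in the cohort (pc1..pcK).  ``site_filter`` keeps oral or
    oropharyngeal cases (always together with all controls, which are
    shared across site analyses) or both ("combined").
    """

    site_filter: str = "combined"
    stratum: str | None = None
    covariates: tuple[str, ...] | None = None
    bootstrap_reps: int = 1000
    seed: int = 0
    missing_dosage: str = "exclude"

    def __post_init__(self):
        if self.site_filter not in ("oral", "oropharyngeal", "combined"):
            raise ValidationError(f"unknown site_filter {self.site_filter!r}")
        if self.bootstrap_reps < 2:
            raise ValidationError("bootstrap correction needs at least 2 replicates")

    def resolve_covariates(self, cohort: Cohort) -> list[str]:
        if self.covariates is not None:
            return list(self.covariates)
        return ["age_band", "sex"] + cohort.pc_columns


# ---------------------------------------------------------------------------
# Newton / IRLS logistic regression
# ---------------------------------------------------------------------------

def _fit_logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    start: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic fit; returns (coef, covariance).

    Newton-Raphson with step-halving on the log-likelihood; convergence on
    the max absolute score.  Raises :class:`FitError` on non-convergence or
    (quasi-)separation, detected as coefficients running away while fitted
    probabilities saturate.
    """
    n, p = X.shape
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()

    def loglik(b):
        eta = X @ b
        # log sigma(eta) for y=1, log(1-sigma) for y=0, numerically stable
        return float(-np.logaddexp(0.0, np.where(y, -eta, eta)).sum())

    ll = loglik(beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol * n:
            break
        w = mu * (1.0 - mu)
        XtWX = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix: {exc}") from exc
        # step-halving
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = ll_new
        if np.max(np.abs(beta)) > 50.0:
            raise FitError("perfect or quasi-perfect separation detected")
    else:
        raise FitError(f"no convergence in {max_iter} Newton iterations")
    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    XtWX = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular information matrix at optimum: {exc}") from exc
    return beta, cov


def _design_matrix(
    cohort: Cohort, score: np.ndarray, covariates: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (X, y, keep-mask); column 1 of X is the score.

    Categorical covariates are dummy-coded against their first level; rows
    with a missing covariate or missing score are dropped.
    """
    ph = cohort.phenotypes
    parts = [np.asarray(score, dtype=float).reshape(-1, 1)]
    keep = ~np.isnan(parts[0][:, 0])
    for cov in covariates:
        if cov not in ph.columns:
            raise ValidationError(f"covariate {cov!r} not in phenotype table")
        col = ph[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            keep &= col.notna().to_numpy()
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            parts.append(dummies.to_numpy())
        else:
            vals = col.to_numpy(dtype=float)
            keep &= ~np.isnan(vals)
            parts.append(vals.reshape(-1, 1))
    X = np.column_stack([np.ones(len(ph))] + parts)
    y = ph["case"].astype(bool).to_numpy()
    return X[keep], y[keep], keep


def _apply_filters(cohort: Cohort, spec: AnalysisSpec) -> Cohort:
    ph = cohort.phenotypes
    mask = np.ones(len(ph), dtype=bool)
    if spec.site_filter != "combined":
        mask &= (ph["site"] == spec.site_filter) | (ph["site"] == "control")
    if spec.stratum is not None:
        mask &= (ph["stratum"] == spec.stratum).to_numpy()
    return cohort.subset(mask)


def _wald(label, log_or, se_naive, se_corrected, n_cases, n_controls) -> CausalEstimate:
    se = se_corrected
    z = log_or / se
    return CausalEstimate(
        label=label, log_or=float(log_or), se_naive=float(se_naive),
        se_corrected=float(se), ci95=(float(np.exp(log_or - _Z975 * se)),
                                      float(np.exp(log_or + _Z975 * se))),
        pvalue=float(2.0 * stats.norm.sf(abs(z))),
        n_cases=int(n_cases), n_controls=int(n_controls))


def fit_causal_logistic(
    cohort: Cohort,
    scores: RelativeExposure,
    spec: AnalysisSpec,
    label: str | None = None,
) -> CausalEstimate:
    """Logistic regression of case status on score + covariates.

    Returns the causal log-OR per SD log 25OHD with its information-matrix
    SE (``se_corrected`` equals ``se_naive`` here; see
    :func:`bootstrap_weight_correction` for the weight-imprecision
    correction).
    """
    sub = _apply_filters(cohort, spec)
    score = scores.as_series().reindex(sub.phenotypes.index).to_numpy()
    X, y, _ = _design_matrix(sub, score, spec.resolve_covariates(sub))
    if y.sum() == 0 or y.sum() == len(y):
        raise FitError("need at least one case and one control after filtering")
    if np.nanstd(X[:, 1]) == 0:
        raise FitError("score has zero variance in the analysis subset")
    stratum_name = spec.stratum or "all"
    try:
        beta, cov = _fit_logistic_irls(X, y)
    except FitError as exc:
        raise FitError(f"stratum {stratum_name!r} ({spec.site_filter}): {exc}") from exc
    log_or, se = beta[1], float(np.sqrt(cov[1, 1]))
    return _wald(label or f"{spec.site_filter}/{stratum_name}", log_or, se, se,
                 y.sum(), len(y) - y.sum())


def bootstrap_weight_correction(
    cohort: Cohort,
    weights: Sequence[VariantWeight],
    spec: AnalysisSpec,
    label: str | None = None,
) -> CausalEstimate:
    """Causal estimate with the weight-imprecision bootstrap correction.

    Replicate weights are drawn from N(beta_j, SE_j); each replicate's
    score is rebuilt and the logistic model refit (warm-started at the main
    fit).  Non-convergent replicates are dropped with a warning; more than
    10% dropped is an error.
    """
    sub = _apply_filters(cohort, spec)
    scores = compute_relative_exposure(sub, weights, missing=spec.missing_dosage)
    score = scores.as_series().reindex(sub.phenotypes.index).to_numpy()
    X, y, keep = _design_matrix(sub, score, spec.resolve_covariates(sub))
    if y.sum() == 0 or y.sum() == len(y):
        raise FitError("need at least one case and one control after filtering")
    if np.nanstd(X[:, 1]) == 0:
        raise FitError("score has zero variance in the analysis subset")
    beta_hat, cov = _fit_logistic_irls(X, y)
    log_or, se_naive = beta_hat[1], float(np.sqrt(cov[1, 1]))

    wmap_rsids = [w.rsid for w in weights if w.rsid in sub.dosages.columns]
    g = sub.dosages[wmap_rsids].to_numpy(dtype=float)
    if spec.missing_dosage == "impute":
        eafs = np.array([w.eaf for w in weights if w.rsid in wmap_rsids])
        g = np.where(np.isnan(g), 2.0 * eafs, g)
    g = g[keep]
    betas = np.array([w.beta for w in weights if w.rsid in wmap_rsids])
    ses = np.array([w.se for w in weights if w.rsid in wmap_rsids])

    rng = np.random.default_rng(spec.seed)
    reps = np.empty(spec.bootstrap_reps)
    n_failed = 0
    Xb = X.copy()
    for b in range(spec.bootstrap_reps):
        beta_star = rng.normal(betas, ses)
        Xb[:, 1] = g @ beta_star
        try:
            coef, _ = _fit_logistic_irls(Xb, y, start=beta_hat)
            reps[b] = coef[1]
        except FitError:
            reps[b] = np.nan
            n_failed += 1
    if n_failed:
        warnings.warn(f"{n_failed} bootstrap replicate(s) dropped for non-convergence",
                      stacklevel=2)
        if n_failed > 0.1 * spec.bootstrap_reps:
            raise FitError(
                f"{n_failed}/{spec.bootstrap_reps} bootstrap replicates failed")
    boot_var = float(np.nanvar(reps, ddof=1))
    se_corr = float(np.sqrt(se_naive ** 2 + boot_var))
    stratum_name = spec.stratum or "all"
    return _wald(label or f"{spec.site_filter}/{stratum_name}", log_or, se_naive,
                 se_corr, y.sum(), len(y) - y.sum())


def bootstrap_sd_only(
    cohort: Cohort, weights: Sequence[VariantWeight], spec: AnalysisSpec,
) -> float:
    """Alternative correction: SE as the SD of replicate estimates alone."""
    est = bootstrap_weight_correction(cohort, weights, spec)
    return float(np.sqrt(max(est.se_corrected ** 2 - est.se_naive ** 2, 0.0)))


def estimate_all_strata(
    cohort: Cohort,
    scores: RelativeExposure,
    spec: AnalysisSpec,
    weights: Sequence[VariantWeight] | None = None,
) -> list[CausalEstimate]:
    """One causal estimate per geographic stratum (MR within each region).

    If ``weights`` is given the bootstrap weight correction is applied per
    stratum; otherwise the naive fits are returned.  Strata with no cases
    (or no controls) after site filtering are skipped with a warning.
    """
    out: list[CausalEstimate] = []
    for stratum in cohort.strata():
        sspec = AnalysisSpec(
            site_filter=spec.site_filter, stratum=stratum,
            covariates=spec.covariates, bootstrap_reps=spec.bootstrap_reps,
            seed=spec.seed, missing_dosage=spec.missing_dosage)
        label = f"{spec.site_filter}/{stratum}"
        try:
            if weights is not None:
                out.append(bootstrap_weight_correction(cohort, weights, sspec, label=label))
            else:
                out.append(fit_causal_logistic(cohort, scores, sspec, label=label))
        except FitError as exc:
            if "at least one case" in str(exc):
                warnings.warn(f"stratum {stratum!r} skipped: {exc}", stacklevel=2)
                continue
            raise
    return out
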