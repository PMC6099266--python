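"""Instrument sensitivity analyses and confounder diagnostics.

Leave-one-out refits flag single SNPs that drive the causal estimate (as a
pleiotropic variant would); the all-subsets analysis refits the model for
every non-empty combination of instrument SNPs, which makes groupings of
estimates containing a suspect SNP visible.  Confounder-balance tests
regress the allele score on each candidate confounder (as a factor) and
report the overall F-test p-value — under valid MR assumptions the
instrument should be independent of confounders, so these have a true
null.  Effect-allele frequencies per geographic stratum expose
population-structure differences directly.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimation import AnalysisSpec, fit_causal_logistic
from .instrument import RelativeExposure, compute_relative_exposure
from .io_model import CausalEstimate, Cohort, ValidationError, VariantWeight, estimates_to_frame


def _refit_with_subset(
    cohort: Cohort, weights: Sequence[VariantWeight], subset: Sequence[str],
    spec: AnalysisSpec, label: str,
) -> CausalEstimate:
    sub_weights = [w for w in weights if w.rsid in subset]
    scores = compute_relative_exposure(cohort, sub_weights, missing=spec.missing_dosage)
    return fit_causal_logistic(cohort, scores, spec, label=label)


def leave_one_out(
    cohort: Cohort, weights: Sequence[VariantWeight], spec: AnalysisSpec,
) -> pd.DataFrame:
    """Refit the causal model k times, each omitting one instrument SNP.

    Returns one row per omitted rsid (column ``omitted``) alongside the
    usual estimate columns.
    """
    if len(weights) < 2:
        raise ValidationError("leave-one-out needs at least 2 instrument SNPs")
    rows = []
    for w in weights:
        keep = [v.rsid for v in weights if v.rsid != w.rsid]
        est = _refit_with_subset(cohort, weights, keep, spec, label=f"omit:{w.rsid}")
        rows.append(est)
    df = estimates_to_frame(rows)
    df.insert(0, "omitted", [w.rsid for w in weights])
    return df


def all_subsets(
    cohort: Cohort, weights: Sequence[VariantWeight], spec: AnalysisSpec,
    flag_rsid: str | None = None,
    include_singletons: bool = True,
) -> pd.DataFrame:
    """Causal estimate for every non-empty subset of the instrument SNPs.

    2^k - 1 rows (k <= 12 guard); ``contains_flagged`` marks subsets
    containing ``flag_rsid``, ready for histogramming.  Singleton
    instruments are included by default.
    """
    k = len(weights)
    if k > 12:
        raise ValidationError(
            f"{k} SNPs give {2 ** k - 1} subsets; pass an explicit subset list instead")
    rsids = [w.rsid for w in weights]
    rows, subsets = [], []
    for size in range(1 if include_singletons else 2, k + 1):
        for combo in itertools.combinations(rsids, size):
            est = _refit_with_subset(cohort, weights, combo, spec,
                                     label="+".join(combo))
            rows.append(est)
            subsets.append(combo)
    df = estimates_to_frame(rows)
    df.insert(0, "subset", ["+".join(c) for c in subsets])
    df.insert(1, "subset_size", [len(c) for c in subsets])
    if flag_rsid is not None:
        df.insert(2, "contains_flagged", [flag_rsid in c for c in subsets])
    return df


def confounder_balance(
    scores: RelativeExposure, covariate: pd.Series,
) -> tuple[float, pd.DataFrame]:
    """Overall p-value for association of the score with a categorical covariate.

    Linear regression of the score on the covariate as a factor; the
    returned p-value is the F test of the factor model against the
    intercept-only model.  Also returns the per-level summaries (n, mean,
    SD, min, max) that a balance boxplot would display.  Missing covariate
    values (and missing scores) are dropped; a single remaining level is an
    error.
    """
    s = scores.as_series()
    cov = covariate.reindex(s.index)
    keep = cov.notna() & s.notna()
    s, cov = s[keep], cov[keep].astype(str)
    levels = sorted(cov.unique())
    if len(levels) < 2:
        raise ValidationError("confounder balance needs >= 2 non-empty levels")
    X = sm.add_constant(pd.get_dummies(cov, drop_first=True, dtype=float))
    fit = sm.OLS(s.to_numpy(), X.to_numpy()).fit()
    pvalue = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
    summary = s.groupby(cov).agg(["size", "mean", "std", "min", "max"])
    summary.columns = ["n", "mean", "sd", "min", "max"]
    return pvalue, summary.reset_index(names="level")


def balance_table(
    scores: RelativeExposure, phenotypes: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "smoking", "alcohol", "stratum"),
) -> pd.DataFrame:
    """Balance p-values across several covariates, raw and Bonferroni-adjusted."""
    rows = []
    for cov in covariates:
        p, _ = confounder_balance(scores, phenotypes[cov])
        rows.append({"covariate": cov, "pvalue": p})
    df = pd.DataFrame(rows)
    df["pvalue_bonferroni"] = np.minimum(df["pvalue"] * len(df), 1.0)
    return df


def eaf_by_group(
    cohort: Cohort, weights: Sequence[VariantWeight], group: str = "stratum",
) -> pd.DataFrame:
    """Realized effect-allele frequency (mean dosage / 2) per rsid and group."""
    rsids = [w.rsid for w in weights if w.rsid in cohort.dosages.columns]
    groups = cohort.phenotypes[group]
    out = cohort.dosages[rsids].groupby(groups).mean() / 2.0
    out.index.name = group
    return out.T
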