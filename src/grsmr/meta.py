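"""DerSimonian-Laird random-effects meta-analysis and heterogeneity.

Used to pool the per-region causal estimates (and, at a second level,
estimates from independent cohorts).  Follows the method-of-moments tau^2
of DerSimonian & Laird with z-based confidence intervals, matching the
defaults of the R 'meta' package, and the Higgins-Thompson test-based
interval for I^2.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .io_model import CausalEstimate, MetaResult, ValidationError

_Z975 = stats.norm.ppf(0.975)


def se_from_ci(or_point: float, ci: tuple[float, float], level: float = 0.95) -> float:
    """Back-derive the log-OR standard error from a printed OR and CI.

    Assumes a symmetric-on-log (Wald) interval:
    ``se = (ln upper - ln lower) / (2 z)``.  Warns if the point estimate
    lies outside the interval.
    """
    lower, upper = ci
    if not 0 < lower < upper:
        raise ValidationError(f"invalid CI ({lower}, {upper})")
    if not lower <= or_point <= upper:
        warnings.warn(f"point estimate {or_point} outside CI ({lower}, {upper})",
                      stacklevel=2)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float((math.log(upper) - math.log(lower)) / (2.0 * z))


def i2_confidence_interval(q: float, k: int, level: float = 0.95) -> tuple[float, float]:
    """Higgins-Thompson test-based CI for I^2 from Cochran's Q and k studies.

    Works on ln H with H = sqrt(Q / (k-1)) (floored at 1), using
    se(ln H) = 0.5 (ln Q - ln(k-1)) / (sqrt(2Q) - sqrt(2k-3))   if Q > k,
    se(ln H) = sqrt( (1/(2(k-2))) (1 - 1/(3(k-2)^2)) )          otherwise,
    then maps H to I^2 = 1 - 1/H^2, truncating to [0, 1].
    """
    if k < 2:
        raise ValidationError("I2 interval needs at least 2 estimates")
    q = max(float(q), 0.0)
    df = k - 1
    ln_h = 0.5 * max(0.0, math.log(q / df)) if q > 0 else 0.0
    if q > k:
        se_ln_h = 0.5 * (math.log(q) - math.log(df)) / (math.sqrt(2 * q) - math.sqrt(2 * k - 3))
    elif k > 2:
        se_ln_h = math.sqrt(1.0 / (2 * (k - 2)) * (1.0 - 1.0 / (3 * (k - 2) ** 2)))
    else:
        # k = 2 with small Q: the large-sample se is undefined; the interval
        # is uninformative
        return (0.0, 1.0)
    z = stats.norm.ppf(0.5 + level / 2.0)
    h_lo = max(1.0, math.exp(ln_h - z * se_ln_h))
    h_hi = max(1.0, math.exp(ln_h + z * se_ln_h))
    to_i2 = lambda h: max(0.0, min(1.0, 1.0 - 1.0 / (h * h)))
    return (to_i2(h_lo), to_i2(h_hi))


def dl_random_effects(
    estimates: Sequence[tuple[float, float] | CausalEstimate],
) -> MetaResult:
    """Pool (log_or, se) pairs by DerSimonian-Laird random effects.

    Fixed-effect weights w_i = 1/se_i^2 give Q and the method-of-moments
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); random-effects
    weights 1/(se_i^2 + tau^2) give the pooled estimate and its SE.
    I^2 = max(0, (Q - (k-1))/Q).  ``CausalEstimate`` inputs use their
    corrected SE.  k = 1 returns the single estimate with a warning.
    """
    pairs = [
        (e.log_or, e.se_corrected) if isinstance(e, CausalEstimate) else (float(e[0]), float(e[1]))
        for e in estimates
    ]
    if not pairs:
        raise ValidationError("no estimates to pool")
    theta = np.array([p[0] for p in pairs])
    se = np.array([p[1] for p in pairs])
    if np.any(se <= 0):
        raise ValidationError("all standard errors must be > 0")
    k = len(pairs)
    if k == 1:
        warnings.warn("single estimate: meta-analysis returns it unchanged", stacklevel=2)
        lo, hi = math.exp(theta[0] - _Z975 * se[0]), math.exp(theta[0] + _Z975 * se[0])
        return MetaResult(
            pooled_log_or=float(theta[0]), pooled_se=float(se[0]), ci95=(lo, hi),
            pvalue=float(2 * stats.norm.sf(abs(theta[0] / se[0]))),
            tau2=0.0, q=0.0, df=0, i2=0.0, i2_ci=(0.0, 1.0), p_het=float("nan"), k=1)

    w = 1.0 / se ** 2
    theta_fe = float(w @ theta / w.sum())
    q = float(w @ (theta - theta_fe) ** 2)
    df = k - 1
    denom = w.sum() - (w ** 2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se ** 2 + tau2)
    pooled = float(w_star @ theta / w_star.sum())
    pooled_se = float(w_star.sum() ** -0.5)
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return MetaResult(
        pooled_log_or=pooled, pooled_se=pooled_se,
        ci95=(math.exp(pooled - _Z975 * pooled_se), math.exp(pooled + _Z975 * pooled_se)),
        pvalue=float(2 * stats.norm.sf(abs(pooled / pooled_se))),
        tau2=float(tau2), q=q, df=df, i2=float(i2),
        i2_ci=i2_confidence_interval(q, k), p_het=float(stats.chi2.sf(q, df)), k=k)
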