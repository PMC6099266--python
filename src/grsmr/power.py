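"""Analytic power for binary-outcome MR with an allele-score instrument.

Uses the normal approximation to the Wald test of the score coefficient in
the case-control logistic regression (the approximation behind the mRnd
calculator): with N = cases + controls, case fraction phi, and instrument
variance explained R^2, the detectable log-OR at significance alpha and
power 1 - beta is

    b = (z_{1-alpha/2} + z_{power}) / sqrt(N * R^2 * phi * (1 - phi)),

reported as the OR pair (exp(-b), exp(+b)); conversely the power to detect
a given OR is Phi(|ln OR| sqrt(N R^2 phi (1-phi)) - z_{1-alpha/2}).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .io_model import ValidationError


@dataclass(frozen=True)
class PowerQuery:
    n_cases: int
    n_controls: int
    r2: float
    alpha: float = 0.05
    target_power: float = 0.8

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValidationError("case and control counts must be positive")
        if not 0 < self.r2 < 1:
            raise ValidationError("r2 must be in (0,1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0,1)")
        if not 0 < self.target_power < 1:
            raise ValidationError("target_power must be in (0,1)")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total

    @property
    def _information(self) -> float:
        phi = self.case_fraction
        return self.n_total * self.r2 * phi * (1.0 - phi)


def detectable_or(query: PowerQuery) -> tuple[float, float]:
    """Smallest detectable (protective OR, risk OR) per SD of exposure."""
    b = (stats.norm.ppf(1.0 - query.alpha / 2.0) + stats.norm.ppf(query.target_power)) \
        / math.sqrt(query._information)
    return (math.exp(-b), math.exp(b))


def power_at_or(query: PowerQuery, or_alt: float) -> float:
    """Power to detect ``or_alt`` at the query's alpha (target_power ignored)."""
    if or_alt <= 0:
        raise ValidationError("alternative OR must be positive")
    z = abs(math.log(or_alt)) * math.sqrt(query._information) \
        - stats.norm.ppf(1.0 - query.alpha / 2.0)
    return float(stats.norm.cdf(z))
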