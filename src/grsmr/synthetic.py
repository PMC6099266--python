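"""Synthetic case-control cohorts with the structure the MR analysis assumes.

The generator emulates a multi-region oral/oropharyngeal cancer consortium:

* genotypes at the five instrument SNPs drawn Binomial(2, EAF) per SNP
  (Hardy-Weinberg, linkage equilibrium);
* a latent standardized log-25OHD exposure
  ``x_i = s_i - E[s] + eps_i`` with ``s_i`` the weighted allele score and
  ``eps`` scaled so Var(x) = 1, which makes the instrument's variance
  explained equal the analytic ``sum beta^2 2p(1-p)`` (~4.4% for the
  packaged weights, inside the 3-5% band reported for these variants);
* a logistic outcome model with a configurable causal log-OR per SD of
  exposure plus covariate effects, sampled *retrospectively*: a large
  population is simulated and the configured numbers of cases and controls
  are drawn per geographic stratum (odds ratios are preserved under
  outcome-dependent sampling);
* covariates (sex, age band, smoking, alcohol, with realistic missingness)
  drawn from the consortium's marginal frequencies, independent of
  genotype by default so instrument-confounder balance tests have a true
  null; principal components drawn standard normal with stratum offsets.

The optional *structure scenario* plants a hidden subpopulation inside one
stratum (default South America) whose allele frequencies are shifted and
whose disease risk is elevated.  Within that stratum the allele score then
correlates with risk even when the causal effect is zero — reproducing,
qualitatively, a spurious stratum-specific odds ratio that disappears when
the stratum is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .instrument import expected_instrument_r2
from .io_model import Cohort, GrsmrError, ValidationError, VariantWeight, packaged_weights


class SimulationError(GrsmrError):
    pass


#: Default per-stratum (n_cases, n_controls), mirroring the consortium's
#: regional sizes: 5,133 cases + 5,984 controls = 11,117 participants.
DEFAULT_STRATA: dict[str, tuple[int, int]] = {
    "Europe": (2323, 2928),
    "North America": (2254, 2329),
    "South America": (556, 727),
}

#: Marginal covariate distributions (all-participants column of the cohort
#: summary table); "" denotes missing-by-questionnaire.
AGE_BANDS = ("<=50", "50-<60", "60-<70", ">=70")
AGE_PROBS = (0.199, 0.310, 0.301, 0.190)
SEX_LEVELS = ("male", "female")
SEX_PROBS = (0.691, 0.309)
SMOKING_LEVELS = ("never", "previous", "current", "")
SMOKING_PROBS = (0.297, 0.329, 0.297, 0.077)
ALCOHOL_LEVELS = ("never", "ever", "")
ALCOHOL_PROBS = (0.164, 0.758, 0.078)

#: Default covariate effects on the outcome (log-OR per level vs reference).
#: Chosen to reflect the dominant smoking/alcohol risk-factor structure of
#: these cancers; independent of genotype, so they do not confound the MR.
DEFAULT_CONFOUNDER_EFFECTS: dict[str, dict[str, float]] = {
    "smoking": {"previous": 0.4, "current": 1.1},
    "alcohol": {"ever": 0.4},
    "sex": {"male": 0.26},
    "age_band": {"50-<60": 0.20, "60-<70": 0.35, ">=70": 0.45},
}

#: Default stratum-average EAF offsets for the structure scenario.  The
#: hidden subgroup carries the shift concentrated by 1/subgroup_fraction so
#: that the *stratum-level* EAF moves by exactly these amounts.  Magnitudes
#: are illustrative user parameters, not calibrated estimates.
DEFAULT_EAF_SHIFT: dict[str, float] = {
    "rs4588": 0.10, "rs116970203": 0.01, "rs4423214": 0.10,
    "rs10741657": 0.125, "rs6013897": 0.075,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator; defaults reproduce the study scale."""

    weights: tuple[VariantWeight, ...] = None  # type: ignore[assignment]
    strata: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_STRATA))
    causal_log_or: float = 0.0
    baseline_case_fraction: float = 0.25
    exposure_noise_sd: float = 1.0
    oral_fraction: float = 0.526
    confounder_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONFOUNDER_EFFECTS.items()})
    pleiotropy_log_or: Mapping[str, float] = field(default_factory=dict)
    structure_scenario: bool = False
    structured_stratum: str = "South America"
    subgroup_fraction: float = 0.5
    eaf_shift: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EAF_SHIFT))
    stratum_log_or: float = 1.4
    n_pcs: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.weights is None:
            object.__setattr__(self, "weights", tuple(packaged_weights()))
        else:
            object.__setattr__(self, "weights", tuple(self.weights))
        for name, (nca, nco) in self.strata.items():
            if nca <= 0 or nco <= 0:
                raise ValidationError(f"stratum {name!r}: case/control counts must be > 0")
        if not 0 < self.baseline_case_fraction < 1:
            raise ValidationError("baseline_case_fraction must be in (0,1)")
        if self.structure_scenario:
            if self.structured_stratum not in self.strata:
                raise ValidationError(
                    f"structured stratum {self.structured_stratum!r} not in strata")
            if not 0 < self.subgroup_fraction < 1:
                raise ValidationError("subgroup_fraction must be in (0,1)")
            for w in self.weights:
                sub_eaf = w.eaf + self.eaf_shift.get(w.rsid, 0.0) / self.subgroup_fraction
                if not 0 < sub_eaf < 1:
                    raise ValidationError(
                        f"{w.rsid}: subgroup EAF {sub_eaf:.3f} outside (0,1)")

    @property
    def n_total(self) -> int:
        return sum(nca + nco for nca, nco in self.strata.values())

    @property
    def n_cases_total(self) -> int:
        return sum(nca for nca, _ in self.strata.values())

    @property
    def n_controls_total(self) -> int:
        return sum(nco for _, nco in self.strata.values())


def _draw_categorical(rng, levels, probs, n):
    p = np.asarray(probs, dtype=float)
    return np.asarray(levels, dtype=object)[rng.choice(len(levels), size=n, p=p / p.sum())]


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept alpha with mean(sigmoid(alpha + lp)) == target."""
    def f(alpha):
        return float(expit(alpha + lp).mean() - target)
    try:
        return brentq(f, -40.0, 40.0, xtol=1e-10)
    except ValueError as exc:
        raise SimulationError(
            "cannot reach baseline_case_fraction "
            f"{target} with the configured effects; adjust baseline_case_fraction "
            "or shrink the covariate/pleiotropy effects") from exc


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate one case-control cohort according to ``config``.

    Per stratum, a population pool ~30% larger than needed at the baseline
    case fraction is simulated, case status is drawn from the logistic
    model, and the configured numbers of cases and controls are sampled
    without replacement.  Raises :class:`SimulationError` with a hint to
    raise ``baseline_case_fraction`` if the pool yields too few cases.

    The returned phenotype table carries the latent standardized exposure
    in an ``exposure`` column (available only in simulation; real cohorts
    have no measured 25OHD) — useful for instrument-strength diagnostics.
    """
    rng = np.random.default_rng(config.seed)
    weights = config.weights
    betas = np.array([w.beta for w in weights])
    eafs = np.array([w.eaf for w in weights])
    rsids = [w.rsid for w in weights]
    r2 = expected_instrument_r2(weights)
    eps_sd = config.exposure_noise_sd * np.sqrt(max(1.0 - r2, 0.0))

    dos_parts, ph_parts = [], []
    offset_step = 0.8  # stratum separation on the leading PCs
    for s_idx, (stratum, (n_cases, n_controls)) in enumerate(config.strata.items()):
        n_target = n_cases + n_controls
        pool = int(np.ceil(1.3 * max(n_cases / config.baseline_case_fraction,
                                     n_controls / (1 - config.baseline_case_fraction))))
        # genotypes: HWE binomials; structure scenario plants a hidden
        # subgroup with shifted EAFs inside the flagged stratum
        p_mat = np.broadcast_to(eafs, (pool, len(weights))).copy()
        subgroup = np.zeros(pool, dtype=bool)
        if config.structure_scenario and stratum == config.structured_stratum:
            subgroup = rng.random(pool) < config.subgroup_fraction
            shift = np.array([config.eaf_shift.get(r, 0.0) for r in rsids])
            p_mat[subgroup] = np.clip(
                eafs + shift / config.subgroup_fraction, 1e-6, 1 - 1e-6)
        g = rng.binomial(2, p_mat).astype(float)

        score = g @ betas
        x = score - float(2.0 * eafs @ betas) + rng.normal(0.0, eps_sd, size=pool)

        sex = _draw_categorical(rng, SEX_LEVELS, SEX_PROBS, pool)
        age = _draw_categorical(rng, AGE_BANDS, AGE_PROBS, pool)
        smoking = _draw_categorical(rng, SMOKING_LEVELS, SMOKING_PROBS, pool)
        alcohol = _draw_categorical(rng, ALCOHOL_LEVELS, ALCOHOL_PROBS, pool)
        cov = {"sex": sex, "age_band": age, "smoking": smoking, "alcohol": alcohol}

        lp = config.causal_log_or * x
        for covariate, effects in config.confounder_effects.items():
            values = cov[covariate]
            for level, eff in effects.items():
                lp = lp + np.where(values == level, eff, 0.0)
        if config.pleiotropy_log_or:
            for j, r in enumerate(rsids):
                eff = config.pleiotropy_log_or.get(r, 0.0)
                if eff:
                    lp = lp + eff * g[:, j]
        if config.structure_scenario and stratum == config.structured_stratum:
            lp = lp + np.where(subgroup, config.stratum_log_or, 0.0)

        alpha = _solve_intercept(lp, config.baseline_case_fraction)
        case = rng.random(pool) < expit(alpha + lp)
        case_idx = np.flatnonzero(case)
        control_idx = np.flatnonzero(~case)
        if len(case_idx) < n_cases or len(control_idx) < n_controls:
            raise SimulationError(
                f"stratum {stratum!r}: pool of {pool} yielded {len(case_idx)} cases / "
                f"{len(control_idx)} controls, need {n_cases}/{n_controls}; "
                "raise baseline_case_fraction (or lower it for controls)")
        keep = np.concatenate([rng.choice(case_idx, n_cases, replace=False),
                               rng.choice(control_idx, n_controls, replace=False)])

        is_case = np.zeros(len(keep), dtype=bool)
        is_case[:n_cases] = True
        site = np.where(
            is_case,
            np.where(rng.random(len(keep)) < config.oral_fraction, "oral", "oropharyngeal"),
            "control")
        pcs = rng.normal(size=(len(keep), config.n_pcs))
        pcs[:, : min(3, config.n_pcs)] += offset_step * s_idx

        ids = [f"{stratum.replace(' ', '')}_{i:06d}" for i in range(len(keep))]
        dos_parts.append(pd.DataFrame(g[keep], index=ids, columns=rsids))
        ph = pd.DataFrame({
            "case": is_case, "site": site, "stratum": stratum,
            "sex": cov["sex"][keep], "age_band": cov["age_band"][keep],
            "smoking": cov["smoking"][keep], "alcohol": cov["alcohol"][keep],
            "exposure": x[keep],
        }, index=ids)
        for k in range(config.n_pcs):
            ph[f"pc{k + 1}"] = pcs[:, k]
        ph_parts.append(ph)

    dosages = pd.concat(dos_parts)
    phenotypes = pd.concat(ph_parts)
    phenotypes[["smoking", "alcohol"]] = phenotypes[["smoking", "alcohol"]].replace("", np.nan)
    dosages.index.name = phenotypes.index.name = "id"
    return Cohort(dosages, phenotypes)


#: Frozen configuration of the packaged test fixture: the default cohort
#: scaled to ~2,000 participants (regional proportions preserved), 5 PCs.
FIXTURE_CONFIG = SimulationConfig(
    strata={"Europe": (420, 529), "North America": (407, 421),
            "South America": (100, 131)},
    n_pcs=5,
    seed=20180730,
)


@lru_cache(maxsize=1)
def _fixture_cohort() -> Cohort:
    return simulate_cohort(FIXTURE_CONFIG)


def packaged_fixture() -> tuple[Cohort, SimulationConfig]:
    """A small (~2,000-sample) deterministic cohort for fast tests.

    Regenerated on first use from :data:`FIXTURE_CONFIG` (fixed seed), so
    it is bit-reproducible without shipping a data file.
    """
    return _fixture_cohort(), FIXTURE_CONFIG
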