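"""Allele harmonization and construction of the weighted 25OHD score.

The instrument weights come from a 25OHD GWAS while the genotypes come from
the outcome cohort (a two-sample design), so each cohort variant must first
be re-oriented to the weight's effect allele: alleles may be reported
swapped, on the opposite strand, or both.  The harmonized dosages are then
combined into a per-individual weighted allele score

    s_i = sum_j beta_j * g_ij ,

whose unit is one standard deviation of log 25OHD ("relative 25OHD"),
because each beta_j is already on the per-allele SD-log scale.  The score
is deliberately *not* re-standardized within the cohort: doing so would
destroy the per-SD interpretation of the downstream causal odds ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_model import Cohort, GrsmrError, ValidationError, VariantWeight

logger = logging.getLogger("grsmr")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

Action = Literal["identity", "swap", "strand-flip", "swap+flip", "dropped"]


class HarmonizationError(GrsmrError):
    """Allele pairs could not be reconciled for a variant."""


@dataclass(frozen=True)
class CohortVariant:
    """A cohort-side variant: which allele the dosage counts, and the dosages."""

    rsid: str
    counted_allele: str
    other_allele: str
    dosages: np.ndarray  # in [0,2], NaN = missing


@dataclass
class HarmonizedDosages:
    """Effect-allele-oriented dosages plus an audit of the action per rsid."""

    rsids: list[str]
    dosages: np.ndarray  # n_samples x n_retained, effect-allele orientation
    actions: dict[str, Action]
    cohort_eaf: dict[str, float]

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rsid": list(self.actions),
            "action": [self.actions[r] for r in self.actions],
            "cohort_eaf": [self.cohort_eaf.get(r, np.nan) for r in self.actions],
        })


def _complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def harmonize(
    weights: Sequence[VariantWeight],
    cohort_variants: Sequence[CohortVariant],
    palindromic_policy: Literal["drop", "infer"] = "drop",
    eaf_warn_threshold: float = 0.2,
) -> HarmonizedDosages:
    """Re-orient cohort dosages to the effect allele of each weight.

    Resolution order per variant: exact allele match (identity), swapped
    alleles (dosage becomes 2-d), strand-complemented match (flip),
    complemented and swapped (2-d).  Palindromic variants (A/T, C/G) are
    ambiguous between swap and flip; the default policy drops them with a
    warning, ``"infer"`` resolves them by comparing cohort allele frequency
    with the weight EAF.  Irreconcilable allele pairs raise
    :class:`HarmonizationError` naming the rsid.
    """
    by_rsid = {v.rsid: v for v in cohort_variants}
    rsids: list[str] = []
    cols: list[np.ndarray] = []
    actions: dict[str, Action] = {}
    cohort_eaf: dict[str, float] = {}
    for w in weights:
        if w.rsid not in by_rsid:
            raise HarmonizationError(f"{w.rsid}: variant absent from cohort")
        v = by_rsid[w.rsid]
        a, b = v.counted_allele.upper(), v.other_allele.upper()
        d = np.asarray(v.dosages, dtype=float)
        freq = float(np.nanmean(d) / 2.0) if np.isfinite(d).any() else np.nan

        weight_set = {w.effect_allele, w.other_allele}
        if {a, b} != weight_set and {_complement(a), _complement(b)} != weight_set:
            raise HarmonizationError(
                f"{w.rsid}: irreconcilable allele pair ({a},{b}) for "
                f"({w.effect_allele},{w.other_allele})")

        if w.is_palindromic:
            if palindromic_policy == "drop":
                warnings.warn(
                    f"{w.rsid}: palindromic variant dropped from the instrument",
                    stacklevel=2)
                actions[w.rsid] = "dropped"
                cohort_eaf[w.rsid] = freq
                continue
            # infer orientation from allele frequency: keep the orientation
            # whose cohort EAF is closer to the weight EAF
            keep = abs(freq - w.eaf) <= abs((1 - freq) - w.eaf)
            action: Action = "identity" if keep else "swap"
            out = d if keep else 2.0 - d
        elif (a, b) == (w.effect_allele, w.other_allele):
            action, out = "identity", d
        elif (a, b) == (w.other_allele, w.effect_allele):
            action, out = "swap", 2.0 - d
        elif (_complement(a), _complement(b)) == (w.effect_allele, w.other_allele):
            action, out = "strand-flip", d
        elif (_complement(a), _complement(b)) == (w.other_allele, w.effect_allele):
            action, out = "swap+flip", 2.0 - d
        else:
            raise HarmonizationError(
                f"{w.rsid}: irreconcilable allele pair ({a},{b}) for "
                f"({w.effect_allele},{w.other_allele})")

        realized = float(np.nanmean(out) / 2.0) if np.isfinite(out).any() else np.nan
        if np.isfinite(realized) and abs(realized - w.eaf) > eaf_warn_threshold:
            warnings.warn(
                f"{w.rsid}: cohort EAF {realized:.3f} differs from weight EAF "
                f"{w.eaf:.3f} by more than {eaf_warn_threshold}", stacklevel=2)
        rsids.append(w.rsid)
        cols.append(out)
        actions[w.rsid] = action
        cohort_eaf[w.rsid] = realized
    dosages = np.column_stack(cols) if cols else np.empty((0, 0))
    return HarmonizedDosages(rsids=rsids, dosages=dosages,
                             actions=actions, cohort_eaf=cohort_eaf)


@dataclass
class RelativeExposure:
    """Per-individual weighted allele score in SD-log-25OHD units."""

    ids: pd.Index
    score: np.ndarray  # NaN = excluded (missing dosage under "exclude" policy)

    def as_series(self) -> pd.Series:
        return pd.Series(self.score, index=self.ids, name="relative_25ohd")


def compute_relative_exposure(
    cohort_or_dosages: Cohort | HarmonizedDosages | pd.DataFrame,
    weights: Sequence[VariantWeight],
    missing: Literal["exclude", "impute"] = "exclude",
) -> RelativeExposure:
    """Weighted allele score s_i = sum_j beta_j g_ij over the retained SNPs.

    ``missing="exclude"`` (default) marks individuals with any missing
    retained dosage as NaN so downstream fits drop them; ``"impute"``
    replaces missing dosages with their Hardy-Weinberg expectation 2*EAF.
    """
    if isinstance(cohort_or_dosages, Cohort):
        frame = cohort_or_dosages.dosages
    elif isinstance(cohort_or_dosages, HarmonizedDosages):
        h = cohort_or_dosages
        frame = pd.DataFrame(h.dosages, columns=h.rsids)
    else:
        frame = cohort_or_dosages
    wmap = {w.rsid: w for w in weights}
    retained = [r for r in frame.columns if r in wmap]
    if not retained:
        raise ValidationError("no retained instrument SNPs to score")
    g = frame[retained].to_numpy(dtype=float)
    betas = np.array([wmap[r].beta for r in retained])
    if missing == "impute":
        eafs = np.array([wmap[r].eaf for r in retained])
        g = np.where(np.isnan(g), 2.0 * eafs, g)
        score = g @ betas
    else:
        score = g @ betas  # NaN propagates -> excluded
        n_excl = int(np.isnan(score).sum())
        if n_excl:
            logger.info("score: %d individuals excluded for missing dosages", n_excl)
    return RelativeExposure(ids=frame.index if hasattr(frame, "index") else
                            pd.RangeIndex(len(score)), score=score)


def expected_instrument_r2(weights: Sequence[VariantWeight]) -> float:
    """Variance in the standardized exposure explained by the instrument.

    Under Hardy-Weinberg and linkage equilibrium, with the exposure scaled
    to unit variance, R^2 = sum_j beta_j^2 * 2 * eaf_j * (1 - eaf_j).
    """
    return float(sum(w.beta ** 2 * 2.0 * w.eaf * (1.0 - w.eaf) for w in weights))
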