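"""Data types and file I/O for the genetic-risk-score MR pipeline.

The pipeline consumes two kinds of input:

* a *variant-weight table* of instrument SNPs — per-allele effects of each
  SNP on standardized log 25-hydroxyvitamin D (25OHD), taken from GWAS
  summary statistics (rsid, alleles, effect-allele frequency, beta, SE, p);
* *individual-level cohort data* — effect-allele dosages per instrument SNP
  (from a VCF or a plain dosage matrix) joined to a phenotype table with
  case status, cancer site, geographic stratum, basic covariates and
  principal components.

All on-disk formats are plain TSV (or VCF); round-tripping through the
writers in this module preserves values to full precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("grsmr")

VALID_ALLELES = frozenset("ACGT")
SITES = ("oral", "oropharyngeal", "control")

#: Column order of the variant-weight TSV dialect.
WEIGHT_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue",
]

#: Fixed (non-PC) columns of the phenotype TSV dialect.  Missing values are
#: coded as the empty string on disk and as NaN/None in memory.
PHENOTYPE_COLUMNS = [
    "id", "case", "site", "stratum", "sex", "age_band", "smoking", "alcohol",
]


class GrsmrError(Exception):
    """Base class for pipeline errors."""


class ValidationError(GrsmrError):
    """An input violated a data-model invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantWeight:
    """One instrument SNP with its per-allele effect on SD log 25OHD.

    ``beta`` is the change in standardized log 25OHD per copy of
    ``effect_allele``; ``eaf`` is the effect-allele frequency in the
    discovery GWAS population.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float

    def __post_init__(self):
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.rsid}: effect allele {self.effect_allele!r} not in A/C/G/T")
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.rsid}: other allele {self.other_allele!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele are equal")
        if not (self.se > 0):
            raise ValidationError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"{self.rsid}: eaf must be in (0,1), got {self.eaf}")
        if self.pos < 1:
            raise ValidationError(f"{self.rsid}: positions are 1-based, got {self.pos}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is ambiguous."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class Cohort:
    """Individual-level case-control data.

    ``dosages`` holds effect-allele dosages in [0, 2] (one column per
    instrument rsid, NaN = missing); ``phenotypes`` holds case status, site,
    stratum, covariates and principal components.  Both frames are indexed
    by the sample identifier and share the same index.
    """

    dosages: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self):
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if not self.dosages.index.equals(self.phenotypes.index):
            raise ValidationError("dosage and phenotype tables index different samples")
        if self.dosages.index.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 2)):
                raise ValidationError("dosages must lie in [0, 2]")
        ph = self.phenotypes
        for col in ("case", "site", "stratum"):
            if col not in ph.columns:
                raise ValidationError(f"phenotype table lacks required column {col!r}")
        bad_site = ~ph["site"].isin(SITES)
        if bad_site.any():
            raise ValidationError(
                f"unknown site labels: {sorted(ph.loc[bad_site, 'site'].unique())}")
        case = ph["case"].astype(bool)
        if ((ph["site"] == "control") != ~case).any():
            raise ValidationError("site == 'control' must coincide with case == False")

    # -- convenience ----------------------------------------------------
    @property
    def rsids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def pc_columns(self) -> list[str]:
        cols = [c for c in self.phenotypes.columns if c.startswith("pc")]
        return sorted(cols, key=lambda c: int(c[2:]))

    @property
    def n_cases(self) -> int:
        return int(self.phenotypes["case"].astype(bool).sum())

    @property
    def n_controls(self) -> int:
        return int((~self.phenotypes["case"].astype(bool)).sum())

    def __len__(self) -> int:
        return len(self.phenotypes)

    def subset(self, mask) -> "Cohort":
        return Cohort(self.dosages.loc[mask].copy(), self.phenotypes.loc[mask].copy())

    def strata(self) -> list[str]:
        return sorted(self.phenotypes["stratum"].unique())


@dataclass(frozen=True)
class CausalEstimate:
    """A causal log-OR per SD increase in log 25OHD from one logistic fit.

    ``se_naive`` comes from the information matrix of the fit;
    ``se_corrected`` additionally carries the imprecision of the instrument
    weights (parametric bootstrap), and is what the CI and p-value use.
    """

    label: str
    log_or: float
    se_naive: float
    se_corrected: float
    ci95: tuple[float, float]  # OR scale
    pvalue: float
    n_cases: int
    n_controls: int

    def __post_init__(self):
        if self.se_corrected < self.se_naive - 1e-12:
            raise ValidationError("corrected SE cannot be below the naive SE")
        lo, hi = self.ci95
        if not lo < hi:
            raise ValidationError("CI lower bound must be below upper bound")
        if not lo <= math.exp(self.log_or) <= hi:
            raise ValidationError("point estimate outside its CI")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)


@dataclass(frozen=True)
class MetaResult:
    """DerSimonian-Laird random-effects pooling of several log-OR estimates."""

    pooled_log_or: float
    pooled_se: float
    ci95: tuple[float, float]  # OR scale
    pvalue: float
    tau2: float
    q: float
    df: int
    i2: float
    i2_ci: tuple[float, float]
    p_het: float
    k: int

    def __post_init__(self):
        if self.tau2 < 0 or self.q < -1e-12:
            raise ValidationError("tau2 and Q must be non-negative")
        if not (self.i2_ci[0] - 1e-12 <= self.i2 <= self.i2_ci[1] + 1e-12):
            raise ValidationError("I2 point estimate outside its CI")

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_log_or)


# ---------------------------------------------------------------------------
# Variant-weight I/O
# ---------------------------------------------------------------------------

def read_variant_weights(path: str | Path) -> list[VariantWeight]:
    """Read a TSV of instrument SNP weights (one row per SNP).

    Requires the header columns ``rsid chrom pos effect_allele other_allele
    eaf beta se pvalue``.  Raises on duplicate rsids, invalid alleles or
    non-positive SEs.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    missing = set(WEIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"weight table lacks columns: {sorted(missing)}")
    if df["rsid"].duplicated().any():
        dups = sorted(df.loc[df["rsid"].duplicated(), "rsid"].unique())
        raise ValidationError(f"duplicate rsid(s) in weight table: {dups}")
    return [
        VariantWeight(
            rsid=row.rsid, chrom=str(row.chrom), pos=int(row.pos),
            effect_allele=str(row.effect_allele), other_allele=str(row.other_allele),
            eaf=float(row.eaf), beta=float(row.beta), se=float(row.se),
            pvalue=float(row.pvalue),
        )
        for row in df.itertuples(index=False)
    ]


def write_variant_weights(weights: Sequence[VariantWeight], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(w, c) for c in WEIGHT_COLUMNS} for w in weights])
    df.to_csv(path, sep="\t", index=False)


def packaged_weights() -> list[VariantWeight]:
    """The five-SNP 25OHD instrument shipped with the package.

    GC rs4588, PDE3B/CYP2R1-region rs116970203, DHCR7 rs4423214, CYP2R1
    rs10741657 and CYP24A1 rs6013897, with per-allele betas on the SD log
    25OHD scale from the 42,274-sample European-ancestry 25OHD GWAS.
    """
    ref = resources.files("grsmr.data") / "weights_25ohd.tsv"
    with resources.as_file(ref) as p:
        return read_variant_weights(p)


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def _read_phenotypes(path: str | Path) -> pd.DataFrame:
    ph = pd.read_csv(path, sep="\t", dtype={"id": str}, keep_default_na=False)
    missing = set(PHENOTYPE_COLUMNS) - set(ph.columns)
    if missing:
        raise ValidationError(f"phenotype table lacks columns: {sorted(missing)}")
    ph = ph.set_index("id")
    # empty string -> missing for categorical covariates
    for col in ("sex", "age_band", "smoking", "alcohol"):
        ph[col] = ph[col].replace("", np.nan)
    truthy = {"1", "true", "True", "TRUE", 1, True}
    falsy = {"0", "false", "False", "FALSE", 0, False}
    bad = ~ph["case"].isin(truthy | falsy)
    if bad.any():
        raise ValidationError(f"unparseable case values: {ph.loc[bad, 'case'].unique()}")
    ph["case"] = ph["case"].isin(truthy)
    for col in ph.columns:
        if col.startswith("pc"):
            ph[col] = pd.to_numeric(ph[col])
    return ph


def _read_dosage_table(path: str | Path) -> pd.DataFrame:
    """TSV dosage matrix: first column = sample id, remaining columns = rsids."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = "id"
    return df.astype(float)


def _read_vcf_dosages(path: str | Path, rsids: Iterable[str]):
    """Extract per-sample dosages for the requested rsids from a VCF.

    Returns ``(samples, dosage frame counting the ALT allele, allele pairs
    {rsid: (ALT, REF)})``.  The DS FORMAT field is used verbatim when
    present; otherwise hard-call GTs are converted to ALT-allele counts.
    Multi-allelic records for instrument sites are rejected.
    """
    from cyvcf2 import VCF

    wanted = set(rsids)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    dosage_cols: dict[str, np.ndarray] = {}
    alleles: dict[str, tuple[str, str]] = {}
    for rec in vcf:
        if rec.ID not in wanted or rec.ID in dosage_cols:
            continue
        if len(rec.ALT) != 1:
            raise ValidationError(f"{rec.ID}: multi-allelic records are not supported")
        ds = None
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
            gt = np.asarray(rec.gt_types, dtype=float)
            d = np.where(gt == 3, np.nan, np.where(gt == 2, 2.0, gt))
        dosage_cols[rec.ID] = d
        alleles[rec.ID] = (rec.ALT[0].upper(), rec.REF.upper())
    vcf.close()
    dos = pd.DataFrame(dosage_cols, index=pd.Index(samples, name="id"))
    return dos, alleles


def read_cohort(
    genotype_path: str | Path,
    phenotype_path: str | Path,
    weights: Sequence[VariantWeight],
    palindromic_policy: str = "infer",
) -> Cohort:
    """Join genotype dosages with phenotypes into a :class:`Cohort`.

    ``genotype_path`` may be a VCF (``.vcf``/``.vcf.gz``; dosages are
    harmonized from the ALT/REF orientation to the effect allele of
    ``weights``) or a TSV dosage matrix whose columns are assumed to
    already count the effect allele.  Individuals present in both sources
    are kept; zero overlap or a missing instrument rsid is an error.

    Palindromic (A/T, C/G) sites in a VCF are oriented by comparing allele
    frequencies by default, which is reliable for instruments whose EAFs
    are far from 0.5 (true of the packaged five-SNP 25OHD instrument,
    which includes the A/T variant rs6013897); pass
    ``palindromic_policy="drop"`` to discard them instead.
    """
    from .instrument import CohortVariant, harmonize

    ph = _read_phenotypes(phenotype_path)
    gp = str(genotype_path)
    rsids = [w.rsid for w in weights]
    if gp.endswith((".vcf", ".vcf.gz", ".vcf.bgz")):
        dos, alleles = _read_vcf_dosages(genotype_path, rsids)
        missing = [r for r in rsids if r not in dos.columns]
        if missing:
            raise ValidationError(f"instrument rsid(s) absent from VCF: {missing}")
        variants = [
            CohortVariant(rsid=r, counted_allele=alleles[r][0],
                          other_allele=alleles[r][1], dosages=dos[r].to_numpy())
            for r in rsids
        ]
        harm = harmonize(weights, variants, palindromic_policy=palindromic_policy)
        dos = pd.DataFrame(harm.dosages, index=dos.index, columns=harm.rsids)
    else:
        dos = _read_dosage_table(genotype_path)
        missing = [r for r in rsids if r not in dos.columns]
        if missing:
            raise ValidationError(f"instrument rsid(s) absent from dosage table: {missing}")
        dos = dos[rsids]
    shared = dos.index.intersection(ph.index)
    if len(shared) == 0:
        raise ValidationError("no overlapping samples between genotype and phenotype sources")
    logger.info(
        "cohort join: %d genotyped, %d phenotyped, %d shared samples",
        len(dos), len(ph), len(shared))
    return Cohort(dos.loc[shared], ph.loc[shared])


def write_cohort(cohort: Cohort, genotype_path: str | Path, phenotype_path: str | Path) -> None:
    """Write a cohort as a dosage TSV + phenotype TSV (the package dialect)."""
    cohort.dosages.to_csv(genotype_path, sep="\t")
    ph = cohort.phenotypes.copy()
    ph["case"] = ph["case"].astype(bool).astype(int)
    ph.to_csv(phenotype_path, sep="\t", na_rep="")


def estimates_to_frame(estimates: Sequence[CausalEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append({
            "label": e.label, "log_or": e.log_or, "or": e.odds_ratio,
            "se_naive": e.se_naive, "se_corrected": e.se_corrected,
            "ci_lower": e.ci95[0], "ci_upper": e.ci95[1], "pvalue": e.pvalue,
            "n_cases": e.n_cases, "n_controls": e.n_controls,
        })
    return pd.DataFrame(rows)


def write_estimates(estimates: Sequence[CausalEstimate], path: str | Path) -> None:
    estimates_to_frame(estimates).to_csv(path, sep="\t", index=False)


def read_estimates(path: str | Path) -> list[CausalEstimate]:
    df = pd.read_csv(path, sep="\t")
    return [
        CausalEstimate(
            label=str(r.label), log_or=r.log_or, se_naive=r.se_naive,
            se_corrected=r.se_corrected, ci95=(r.ci_lower, r.ci_upper),
            pvalue=r.pvalue, n_cases=int(r.n_cases), n_controls=int(r.n_controls),
        )
        for r in df.itertuples(index=False)
    ]
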