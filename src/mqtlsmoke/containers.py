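"""In-memory containers shared across pipeline stages.

All containers are thin wrappers around :class:`pandas.DataFrame` with the
orientation conventions fixed once: samples are rows, loci are columns.
Genotypes are stored as minor-allele counts in {0, 1, 2} with ``NaN`` for
missing calls; methylation is stored as beta-values in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed category levels for the cohort covariates.
SMOKING_LEVELS = ("never", "former", "current")
ALCOHOL_LEVELS = ("abstainer", "low", "intermediate", "high")
BMI_LEVELS = ("normal", "overweight", "obese")
ACTIVITY_LEVELS = ("inactive", "low", "medium_high")


class ValidationError(ValueError):
    """Raised when an input table violates its schema contract."""


class AlignmentError(ValueError):
    """Raised when sample ids do not align across tables."""


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix plus per-SNP annotation.

    Attributes
    ----------
    dosages:
        samples x SNPs, float64; entries in {0, 1, 2} or NaN (missing).
    snps:
        indexed by snp_id; columns ``chrom``, ``pos`` (1-based),
        ``minor_allele``, ``maf`` (within-cohort minor allele frequency).
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.snps.index):
            raise AlignmentError("dosage columns must match SNP annotation index")
        vals = self.dosages.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValidationError("genotype dosages must be in {0,1,2} or missing")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.snps.index

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        snp_ids = pd.Index(snp_ids)
        return GenotypeMatrix(self.dosages[snp_ids], self.snps.loc[snp_ids])

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[sample_ids], self.snps)


@dataclass
class MethylationMatrix:
    """Beta-value matrix plus CpG manifest.

    ``betas`` is samples x CpGs in [0, 1]; ``manifest`` is indexed by cpg_id
    with columns ``chrom``, ``pos`` (1-based), ``gene`` and
    ``reported_frequency`` (number of prior studies reporting the site,
    >= 2 for candidate loci).
    """

    betas: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.betas.columns.equals(self.manifest.index):
            raise AlignmentError("beta columns must match manifest index")
        vals = self.betas.to_numpy(dtype=float)
        if np.nanmin(vals) < 0.0 or np.nanmax(vals) > 1.0:
            raise ValidationError("beta-values must lie in [0, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.betas.index

    @property
    def cpg_ids(self) -> pd.Index:
        return self.manifest.index

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.betas.loc[sample_ids], self.manifest)


@dataclass
class CellReference:
    """Cell-type specific methylation profiles over reference CpGs.

    ``profiles`` is m_ref x K with entries in [0, 1]; columns are cell-type
    labels, the index lists the reference CpG ids.
    """

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.profiles.to_numpy(dtype=float)
        if vals.min() < 0.0 or vals.max() > 1.0:
            raise ValidationError("reference profiles must lie in [0, 1]")
        if np.linalg.matrix_rank(vals) < self.n_cell_types:
            raise ValidationError("reference profile matrix is rank deficient")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def n_cell_types(self) -> int:
        return self.profiles.shape[1]

    @property
    def cpg_ids(self) -> pd.Index:
        return self.profiles.index


#: Required cohort-table columns (cell proportions come as cell_prop_* extras).
COHORT_COLUMNS = (
    "sample_id", "panel", "age", "sex", "smoking_status", "pack_years",
    "smoking_duration", "initiation_age", "cessation_time", "alcohol",
    "bmi_class", "activity", "cvd", "diabetes", "cancer", "batch",
    "followup_time", "dead",
)


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort/covariate table against its schema.

    Returns the table unchanged on success.  Category columns must use the
    canonical level labels; cessation time may only be present for former
    smokers; follow-up times must be positive.
    """
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    if cohort["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in cohort table")
    checks = {
        "smoking_status": SMOKING_LEVELS,
        "alcohol": ALCOHOL_LEVELS,
        "bmi_class": BMI_LEVELS,
        "activity": ACTIVITY_LEVELS,
        "panel": ("discovery", "validation"),
        "sex": ("male", "female"),
    }
    for col, levels in checks.items():
        observed = cohort[col].dropna()
        bad = set(observed) - set(levels)
        if bad:
            raise ValidationError(f"unknown {col} categories: {sorted(bad)}")
    for col in ("cvd", "diabetes", "cancer", "dead"):
        bad = set(cohort[col].dropna().unique()) - {0, 1, True, False}
        if bad:
            raise ValidationError(f"{col} must be binary 0/1, got {sorted(bad)}")
    has_cess = cohort["cessation_time"].notna()
    if (cohort.loc[has_cess, "smoking_status"] != "former").any():
        raise ValidationError("cessation_time present for non-former smokers")
    if (cohort["followup_time"] <= 0).any():
        raise ValidationError("followup_time must be positive")
    pk = cohort["pack_years"]
    if (pk.dropna() < 0).any():
        raise ValidationError("pack_years must be non-negative")
    return cohort


def cell_prop_columns(cohort: pd.DataFrame) -> list[str]:
    """Names of the per-sample cell proportion columns, in order."""
    cols = [c for c in cohort.columns if c.startswith("cell_prop_")]
    return sorted(cols)
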