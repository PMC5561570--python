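"""Synthetic two-panel cohort generator with known genotype-methylation
-phenotype structure.

The generator emulates the study design the pipeline targets: two
independent panels of older adults (defaults 581 and 368 samples), a set
of candidate smoking-related CpG sites, each with a handful of array SNPs
inside the +/-50 kb cis window, whole-blood methylation driven by cell
composition, batch, smoking and (for a subset of CpGs) a single causal
cis-SNP, and Weibull survival with administrative censoring.

Every stochastic draw flows from one seeded :class:`numpy.random.Generator`
derived from ``config.seed``, so a run is fully reproducible.

Model for CpG j, sample i (beta-value scale)::

    beta_ij = clip01( sum_k p_ik w_jk + a_j G_ij + b_j s_i
                      + batch_{B(i)} + eps_ij ),  eps ~ N(0, noise_sd)

where p_ik are Dirichlet cell proportions, w_jk the cell-type-specific
profile of CpG j, G_ij the minor-allele count at the designated causal SNP
(a_j = 0 for CpGs without an mQTL), and s_i the smoking code (current = 1,
former = 0.5, never = 0), so b_j is the current-vs-never effect.

Linkage disequilibrium is produced by a block-autoregressive haplotype
copy scheme: loci within a block share one true MAF and each haplotype
allele copies its left neighbour with probability ``ld_rho``, giving
adjacent-locus allelic correlation ~ ld_rho and geometric decay beyond.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from mqtlsmoke.config import SimulationConfig
from mqtlsmoke.containers import (
    AlignmentError,
    CellReference,
    GenotypeMatrix,
    MethylationMatrix,
)

__all__ = [
    "SimulationTruth",
    "SimulatedStudy",
    "simulate_snp_map",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_cell_reference",
    "simulate_methylation",
    "simulate_reference_betas",
    "simulate_study",
]

#: Distribution of how often a candidate CpG was reported by prior studies
#: (weakly 2-3, moderately 4-5, highly >= 6 times).
_REPORTED_FREQ_LEVELS = (2, 3, 4, 5, 6, 7, 8, 12)
_REPORTED_FREQ_PROBS = (0.36, 0.36, 0.10, 0.08, 0.04, 0.03, 0.02, 0.01)

#: True log-hazard coefficients for all-cause mortality (age is centred
#: at 61 years; smoking contrasts are vs never smokers).
_SURVIVAL_COEFS = {"age": 0.08, "current": 0.7, "former": 0.25}

_SMOKING_CODE = {"never": 0.0, "former": 0.5, "current": 1.0}


def _rng_for(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent child generator for one named stream of the simulation."""
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


@dataclass
class SimulationTruth:
    """Every generative parameter, for recovery tests downstream.

    ``mqtl_effect`` is 0 for CpGs without a planted mQTL and ``causal_snp``
    maps those CpGs to None.
    """

    true_maf: pd.Series
    causal_snp: dict
    mqtl_effect: pd.Series
    smoking_effect: pd.Series
    batch_intercepts: pd.Series
    cell_profiles: pd.DataFrame
    cell_proportions: pd.DataFrame
    survival_coefs: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_maf": self.true_maf.to_dict(),
            "causal_snp": self.causal_snp,
            "mqtl_effect": self.mqtl_effect.to_dict(),
            "smoking_effect": self.smoking_effect.to_dict(),
            "batch_intercepts": self.batch_intercepts.to_dict(),
            "cell_profiles": self.cell_profiles.to_dict(),
            "cell_proportions": self.cell_proportions.to_dict(),
            "survival_coefs": self.survival_coefs,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            true_maf=pd.Series(d["true_maf"]),
            causal_snp=d["causal_snp"],
            mqtl_effect=pd.Series(d["mqtl_effect"]),
            smoking_effect=pd.Series(d["smoking_effect"]),
            batch_intercepts=pd.Series(d["batch_intercepts"]),
            cell_profiles=pd.DataFrame(d["cell_profiles"]),
            cell_proportions=pd.DataFrame(d["cell_proportions"]),
            survival_coefs=d["survival_coefs"],
        )


@dataclass
class SimulatedStudy:
    """Bundle of all simulated tables for a two-panel run."""

    cohort: pd.DataFrame
    genotypes: GenotypeMatrix
    methylation: MethylationMatrix
    reference: CellReference
    reference_betas: pd.DataFrame
    truth: SimulationTruth


def simulate_snp_map(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out candidate CpGs and their regional SNPs on the genome.

    Returns ``(manifest, snp_map)``.  CpGs are spread over chromosomes
    1..22 at 1 Mb spacing so cis windows never overlap; each CpG gets
    ``snps_per_cpg`` SNPs at uniform offsets within +/-50 kb.  Positions
    are 1-based.
    """
    rng = _rng_for(config, 1)
    rows = []
    for j in range(config.n_cpgs):
        chrom = str(1 + j % 22)
        pos = 10_000_000 + (j // 22) * 1_000_000 + j
        gene = f"GENE{j + 1}" if rng.random() < 0.8 else "unassigned"
        freq = int(rng.choice(_REPORTED_FREQ_LEVELS, p=_REPORTED_FREQ_PROBS))
        rows.append((f"cg{j + 1:06d}", chrom, pos, gene, freq))
    manifest = pd.DataFrame(
        rows, columns=["cpg_id", "chrom", "pos", "gene", "reported_frequency"]
    ).set_index("cpg_id")

    snp_rows = []
    for cpg_id, row in manifest.iterrows():
        offsets = rng.choice(
            np.arange(-50_000, 50_001), size=config.snps_per_cpg, replace=False
        )
        offsets = offsets[offsets != 0]
        while len(offsets) < config.snps_per_cpg:
            extra = int(rng.integers(-50_000, 50_001))
            if extra != 0 and extra not in offsets:
                offsets = np.append(offsets, extra)
        for k, off in enumerate(sorted(int(o) for o in offsets)):
            snp_rows.append(
                (f"rs_{cpg_id}_{k + 1}", row["chrom"], row["pos"] + off, cpg_id)
            )
    snp_map = pd.DataFrame(
        snp_rows, columns=["snp_id", "chrom", "pos", "region_cpg"]
    ).set_index("snp_id")
    return manifest, snp_map


def simulate_genotypes(
    config: SimulationConfig,
    n_samples: int,
    *,
    snp_map: pd.DataFrame | None = None,
    true_maf: pd.Series | None = None,
    rng: np.random.Generator | None = None,
    sample_ids: list[str] | None = None,
    apply_missing: bool = True,
) -> tuple[GenotypeMatrix, pd.Series]:
    """Draw unphased genotypes under HWE with block-AR(1) LD.

    Loci within an LD block share one true MAF drawn from
    ``config.maf_range`` and haplotype alleles copy their left neighbour
    with probability ``ld_rho``, so marginal frequencies stay at the true
    MAF while adjacent loci are correlated.  Missing calls are masked in
    at rate ``config.missing_rate`` unless ``apply_missing`` is False.

    Returns the genotype matrix (within-cohort minor-allele counts) and
    the per-SNP true MAFs.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if snp_map is None:
        _, snp_map = simulate_snp_map(config)
    if rng is None:
        rng = _rng_for(config, 2)

    snp_ids = snp_map.index
    m = len(snp_ids)
    if true_maf is None:
        true_maf = _draw_block_mafs(config, snp_map, _rng_for(config, 3))
    hap = np.empty((n_samples, 2, m), dtype=np.int8)

    # blocks never straddle regions: block structure is per region_cpg
    col = 0
    for _, region in snp_map.groupby("region_cpg", sort=False):
        L = len(region)
        for start in range(0, L, config.ld_block_size):
            block = region.index[start : start + config.ld_block_size]
            p = float(true_maf[block[0]])
            prev = (rng.random((n_samples, 2)) < p).astype(np.int8)
            hap[:, :, col] = prev
            col += 1
            for _ in block[1:]:
                copy = rng.random((n_samples, 2)) < config.ld_rho
                fresh = (rng.random((n_samples, 2)) < p).astype(np.int8)
                prev = np.where(copy, prev, fresh)
                hap[:, :, col] = prev
                col += 1
    dosage = hap.sum(axis=1).astype(float)

    if apply_missing and config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    if sample_ids is None:
        sample_ids = [f"S{i + 1:05d}" for i in range(n_samples)]
    dosages = pd.DataFrame(dosage, index=pd.Index(sample_ids, name="sample_id"),
                           columns=snp_ids)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosage, axis=0) / 2.0
    snps = snp_map.copy()
    snps["minor_allele"] = "A"
    snps["maf"] = np.minimum(freq, 1.0 - freq)
    return GenotypeMatrix(dosages, snps), true_maf.loc[snp_ids]


def _draw_block_mafs(
    config: SimulationConfig, snp_map: pd.DataFrame, rng: np.random.Generator
) -> pd.Series:
    lo, hi = config.maf_range
    maf = pd.Series(index=snp_map.index, dtype=float)
    for _, region in snp_map.groupby("region_cpg", sort=False):
        L = len(region)
        for start in range(0, L, config.ld_block_size):
            block = region.index[start : start + config.ld_block_size]
            maf[block] = rng.uniform(lo, hi)
    return maf


def simulate_cohort(
    config: SimulationConfig,
    n_samples: int,
    *,
    panel: str = "discovery",
    rng: np.random.Generator | None = None,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Draw the covariate/phenotype table for one panel.

    Emulates an older-adult screening cohort: ages ~61 +/- 6 years,
    smoking prevalence from ``config.smoking_prevalence``, pack-years for
    ever smokers only, cessation time for former smokers only, lifestyle
    and comorbidity categories at realistic prevalences, round-robin batch
    assignment, Dirichlet cell proportions and Weibull survival with
    administrative censoring at ``followup_horizon`` years.
    """
    if rng is None:
        rng = _rng_for(config, 4 if panel == "discovery" else 5)
    n = int(n_samples)
    if sample_ids is None:
        prefix = "D" if panel == "discovery" else "V"
        sample_ids = [f"{prefix}{i + 1:05d}" for i in range(n)]

    age = np.clip(rng.normal(61.0, 6.3, n), 50.0, 75.0).round(1)
    sex = np.where(rng.random(n) < 0.38, "male", "female")
    status = rng.choice(
        ["current", "former", "never"], size=n, p=list(config.smoking_prevalence)
    )
    current = status == "current"
    former = status == "former"
    ever = current | former

    initiation = np.full(n, np.nan)
    initiation[ever] = np.clip(rng.normal(17.5, 4.0, ever.sum()), 12.0, 35.0).round(1)
    cessation = np.full(n, np.nan)
    # former smokers quit on average ~17 years before recruitment, but not
    # before they started
    max_cess = np.maximum(age - initiation - 1.0, 1.0)
    cessation[former] = np.clip(
        rng.normal(17.0, 11.0, former.sum()), 1.0, max_cess[former]
    ).round(1)
    duration = np.full(n, np.nan)
    duration[current] = (age - initiation)[current].round(1)
    duration[former] = np.maximum((age - initiation - cessation)[former], 1.0).round(1)

    pack_years = np.zeros(n)
    pack_years[current] = np.maximum(rng.normal(34.6, 18.2, current.sum()), 0.5)
    pack_years[former] = np.maximum(rng.normal(21.0, 17.0, former.sum()), 0.5)
    pack_years = pack_years.round(1)

    alcohol = rng.choice(
        ["abstainer", "low", "intermediate", "high"], size=n,
        p=[0.37, 0.56, 0.053, 0.017],
    )
    bmi = rng.choice(["normal", "overweight", "obese"], size=n, p=[0.27, 0.46, 0.27])
    activity = rng.choice(
        ["inactive", "low", "medium_high"], size=n, p=[0.20, 0.45, 0.35]
    )
    cvd = (rng.random(n) < 0.151).astype(int)
    diabetes = (rng.random(n) < 0.156).astype(int)
    cancer = (rng.random(n) < 0.058).astype(int)
    batch = np.array(
        [f"batch{(i % config.n_batches) + 1:02d}" for i in range(n)]
    )
    props = rng.dirichlet(list(config.dirichlet_alpha), size=n)

    c = _SURVIVAL_COEFS
    lp = c["age"] * (age - 61.0) + c["current"] * current + c["former"] * former
    # Weibull proportional hazards: S(t) = exp(-(t/scale)^shape * exp(lp))
    e = rng.exponential(1.0, n)
    t_event = config.survival_scale * (e / np.exp(lp)) ** (1.0 / config.survival_shape)
    dead = (t_event <= config.followup_horizon).astype(int)
    followup = np.minimum(t_event, config.followup_horizon).round(2)
    followup = np.maximum(followup, 0.01)

    cohort = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "panel": panel,
            "age": age,
            "sex": sex,
            "smoking_status": status,
            "pack_years": pack_years,
            "smoking_duration": duration,
            "initiation_age": initiation,
            "cessation_time": cessation,
            "alcohol": alcohol,
            "bmi_class": bmi,
            "activity": activity,
            "cvd": cvd,
            "diabetes": diabetes,
            "cancer": cancer,
            "batch": batch,
            "followup_time": followup,
            "dead": dead,
        }
    )
    for k in range(config.n_cell_types):
        cohort[f"cell_prop_{k + 1}"] = props[:, k]
    return cohort


def simulate_cell_reference(
    config: SimulationConfig, *, rng: np.random.Generator | None = None
) -> CellReference:
    """Cell-type-specific methylation profiles over reference CpGs.

    Columns are well separated (uniform draws over [0.05, 0.95] re-drawn
    until every pairwise column distance exceeds a floor), so the
    constrained projection is identifiable.
    """
    if config.n_cell_types < 2:
        raise ValueError("n_cell_types must be >= 2")
    if rng is None:
        rng = _rng_for(config, 6)
    m, K = config.n_reference_cpgs, config.n_cell_types
    for _ in range(100):
        profiles = rng.uniform(0.05, 0.95, size=(m, K))
        dists = [
            np.linalg.norm(profiles[:, a] - profiles[:, b])
            for a in range(K) for b in range(a + 1, K)
        ]
        if min(dists) > 0.5 * np.sqrt(m / 6.0):
            break
    index = pd.Index([f"refcg{i + 1:05d}" for i in range(m)], name="cpg_id")
    cols = [f"cell{k + 1}" for k in range(K)]
    return CellReference(pd.DataFrame(profiles, index=index, columns=cols))


def _draw_effects(
    config: SimulationConfig,
    manifest: pd.DataFrame,
    snps: pd.DataFrame,
    true_maf: pd.Series,
    rng: np.random.Generator,
) -> tuple[dict, pd.Series, pd.Series, pd.Series, pd.DataFrame]:
    """Draw per-CpG generative coefficients (causal SNP, mQTL and smoking
    effects, batch intercepts, cell-type profiles)."""
    causal: dict = {}
    a = pd.Series(0.0, index=manifest.index)
    b = pd.Series(0.0, index=manifest.index)
    lo_m, hi_m = config.mqtl_effect_range
    lo_s, hi_s = config.smoking_effect_range
    for cpg_id in manifest.index:
        region = snps.index[snps["region_cpg"] == cpg_id]
        if len(region) and rng.random() < config.mqtl_fraction:
            # pick a causal SNP common enough to survive the MAF filter
            common = [s for s in region if true_maf[s] >= 0.15]
            snp = rng.choice(common if common else list(region))
            causal[cpg_id] = str(snp)
            a[cpg_id] = rng.uniform(lo_m, hi_m) * rng.choice([-1.0, 1.0])
        else:
            causal[cpg_id] = None
        # smoking predominantly demethylates the candidate sites
        sign = -1.0 if rng.random() < 0.8 else 1.0
        b[cpg_id] = sign * rng.uniform(lo_s, hi_s)
    batches = pd.Series(
        rng.normal(0.0, config.batch_sd, config.n_batches),
        index=[f"batch{i + 1:02d}" for i in range(config.n_batches)],
    )
    mu = rng.uniform(0.25, 0.75, len(manifest))
    profiles = pd.DataFrame(
        np.clip(mu[:, None] + rng.normal(0.0, 0.05, (len(manifest), config.n_cell_types)),
                0.0, 1.0),
        index=manifest.index,
        columns=[f"cell{k + 1}" for k in range(config.n_cell_types)],
    )
    return causal, a, b, batches, profiles


def simulate_methylation(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    *,
    manifest: pd.DataFrame | None = None,
    truth: SimulationTruth | None = None,
    true_maf: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[MethylationMatrix, SimulationTruth]:
    """Generate beta-values from the additive generative model.

    If ``truth`` is given its coefficients are reused (so discovery and
    validation panels share one set of effects); otherwise effects are
    drawn afresh.  Missing genotype calls contribute their locus mean
    dosage, so masked-in missingness does not shift the generative signal.
    """
    if rng is None:
        rng = _rng_for(config, 7)
    if not genotypes.sample_ids.equals(pd.Index(cohort["sample_id"])):
        raise AlignmentError("cohort and genotype sample ids do not align")
    if manifest is None:
        manifest, _ = simulate_snp_map(config)
    if true_maf is None:
        true_maf = genotypes.snps["maf"]

    if truth is None:
        causal, a, b, batches, profiles = _draw_effects(
            config, manifest, genotypes.snps, true_maf, rng
        )
    else:
        causal, a, b = truth.causal_snp, truth.mqtl_effect, truth.smoking_effect
        batches, profiles = truth.batch_intercepts, truth.cell_profiles

    n = len(cohort)
    prop_cols = [c for c in cohort.columns if c.startswith("cell_prop_")]
    P = cohort[prop_cols].to_numpy()  # n x K
    smoke = cohort["smoking_status"].map(_SMOKING_CODE).to_numpy()
    batch_term = cohort["batch"].map(batches).to_numpy()

    G = genotypes.dosages.to_numpy(dtype=float)
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean, G)
    col_of = {s: i for i, s in enumerate(genotypes.snp_ids)}

    base = P @ profiles.to_numpy().T  # n x n_cpgs
    betas = np.empty((n, len(manifest)))
    for j, cpg_id in enumerate(manifest.index):
        snp = causal.get(cpg_id)
        g = G[:, col_of[snp]] if snp is not None else 0.0
        eps = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
        betas[:, j] = base[:, j] + a[cpg_id] * g + b[cpg_id] * smoke + batch_term + eps
    betas = np.clip(betas, 0.0, 1.0)

    meth = MethylationMatrix(
        pd.DataFrame(betas, index=genotypes.sample_ids, columns=manifest.index),
        manifest,
    )
    if truth is None:
        truth = SimulationTruth(
            true_maf=pd.Series(true_maf, index=genotypes.snp_ids),
            causal_snp=causal,
            mqtl_effect=a,
            smoking_effect=b,
            batch_intercepts=batches,
            cell_profiles=profiles,
            cell_proportions=cohort.set_index("sample_id")[prop_cols],
            survival_coefs=dict(_SURVIVAL_COEFS),
        )
    return meth, truth


def simulate_reference_betas(
    cohort: pd.DataFrame,
    reference: CellReference,
    *,
    noise_sd: float = 0.01,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-sample beta-values at the reference CpGs: R p_i plus noise."""
    if rng is None:
        rng = np.random.default_rng(0)
    prop_cols = [c for c in cohort.columns if c.startswith("cell_prop_")]
    P = cohort[prop_cols].to_numpy()
    R = reference.profiles.to_numpy()
    betas = P @ R.T
    if noise_sd > 0:
        betas = betas + rng.normal(0.0, noise_sd, betas.shape)
    betas = np.clip(betas, 0.0, 1.0)
    return pd.DataFrame(
        betas, index=pd.Index(cohort["sample_id"], name="sample_id"),
        columns=reference.cpg_ids,
    )


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Full two-panel study: shared SNP map and effects, independent samples."""
    manifest, snp_map = simulate_snp_map(config)
    true_maf = _draw_block_mafs(config, snp_map, _rng_for(config, 3))

    parts = []
    for panel, n, stream in (
        ("discovery", config.n_discovery, 10),
        ("validation", config.n_validation, 11),
    ):
        rng = _rng_for(config, stream)
        prefix = "D" if panel == "discovery" else "V"
        ids = [f"{prefix}{i + 1:05d}" for i in range(n)]
        cohort = simulate_cohort(config, n, panel=panel, rng=rng, sample_ids=ids)
        geno_full, _ = simulate_genotypes(
            config, n, snp_map=snp_map, true_maf=true_maf, rng=rng,
            sample_ids=ids, apply_missing=False,
        )
        parts.append((cohort, geno_full, rng))

    truth = None
    meths, cohorts, genos = [], [], []
    mask_rng = _rng_for(config, 12)
    for cohort, geno_full, rng in parts:
        meth, truth = simulate_methylation(
            cohort, geno_full, config, manifest=manifest, truth=truth,
            true_maf=true_maf, rng=rng,
        )
        dosage = geno_full.dosages.to_numpy().copy()
        if config.missing_rate > 0:
            mask = mask_rng.random(dosage.shape) < config.missing_rate
            dosage[mask] = np.nan
        genos.append(pd.DataFrame(dosage, index=geno_full.sample_ids,
                                  columns=geno_full.snp_ids))
        cohorts.append(cohort)
        meths.append(meth.betas)

    cohort_all = pd.concat(cohorts, ignore_index=True)
    dosage_all = pd.concat(genos)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosage_all.to_numpy(), axis=0) / 2.0
    snps = snp_map.copy()
    snps["minor_allele"] = "A"
    snps["maf"] = np.minimum(freq, 1.0 - freq)
    genotypes = GenotypeMatrix(dosage_all, snps)
    methylation = MethylationMatrix(pd.concat(meths), manifest)

    reference = simulate_cell_reference(config)
    ref_betas = simulate_reference_betas(
        cohort_all, reference, rng=_rng_for(config, 13)
    )
    return SimulatedStudy(
        cohort=cohort_all,
        genotypes=genotypes,
        methylation=methylation,
        reference=reference,
        reference_betas=ref_betas,
        truth=truth,
    )
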