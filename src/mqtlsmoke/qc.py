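"""SNP-level quality control: missingness, Hardy-Weinberg exact test,
minor allele frequency, and per-CpG greedy LD pruning.

Filters are applied in the fixed order missingness -> HWE -> MAF -> LD.
Boundaries are inclusive on the exclusion side: a SNP with exactly 1%
missing calls, HWE p exactly below the threshold, or MAF exactly 0.1 is
excluded.  LD pruning is greedy per CpG: the best-ranked SNP is kept and
every remaining candidate with r^2 at or above the threshold against it
is removed, so the retained set is mutually below threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import beta as beta_dist

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "missingness_filter",
    "hwe_exact_test",
    "compute_maf",
    "ld_r2",
    "prune_ld",
    "marginal_pvalue_ranking",
    "run_qc",
    "UndefinedLDError",
]


class UndefinedLDError(ValueError):
    """LD requested for a constant genotype column."""


@dataclass
class QCReport:
    """Per-filter exclusion counts (in application order) and survivors."""

    n_input: int
    excluded_missingness: int = 0
    excluded_hwe: int = 0
    excluded_maf: int = 0
    excluded_ld: dict = field(default_factory=dict)  # cpg_id -> n removed
    survivors_per_cpg: dict = field(default_factory=dict)  # cpg_id -> [snp_id]

    @property
    def n_surviving_snps(self) -> int:
        ids: set = set()
        for s in self.survivors_per_cpg.values():
            ids.update(s)
        return len(ids)

    @property
    def n_surviving_pairs(self) -> int:
        return sum(len(s) for s in self.survivors_per_cpg.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input_snps", self.n_input),
            ("excluded_missingness", self.excluded_missingness),
            ("excluded_hwe", self.excluded_hwe),
            ("excluded_maf", self.excluded_maf),
            ("excluded_ld_pairs", sum(self.excluded_ld.values())),
            ("surviving_snps", self.n_surviving_snps),
            ("surviving_pairs", self.n_surviving_pairs),
        ]
        return pd.DataFrame(rows, columns=["metric", "count"])


def missingness_filter(
    dosages: pd.DataFrame, threshold: float = 0.01
) -> pd.Index:
    """SNP ids whose missing-call fraction is strictly below ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    frac = dosages.isna().mean(axis=0)
    return dosages.columns[frac < threshold]


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditions on the allele counts and sums the probabilities of every
    heterozygote count whose conditional probability does not exceed that
    of the observed count.  A monomorphic site returns p = 1 by
    convention.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped sample is required")
    n_a = 2 * n_aa + n_Aa  # rarer-or-not allele count; symmetric below
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        logger.debug("monomorphic site in HWE test; p = 1 by convention")
        return 1.0

    # log P(n_het = h | allele counts) up to a shared constant
    hets = np.arange(rare % 2, rare + 1, 2)
    n_hom_rare = (rare - hets) // 2
    n_hom_common = (n - hets - n_hom_rare) - 0  # remaining samples
    logp = (
        hets * np.log(2.0)
        - gammaln(n_hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(n_hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def genotype_counts(column: pd.Series | np.ndarray) -> tuple[int, int, int]:
    """(n hom-major, n het, n hom-minor) over non-missing calls."""
    vals = np.asarray(column, dtype=float)
    vals = vals[~np.isnan(vals)]
    return int((vals == 0).sum()), int((vals == 1).sum()), int((vals == 2).sum())


def compute_maf(column: pd.Series | np.ndarray) -> float:
    """Minor allele frequency over non-missing calls."""
    vals = np.asarray(column, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("cannot compute MAF: all calls missing")
    f = vals.sum() / (2.0 * len(vals))
    return float(min(f, 1.0 - f))


def ld_r2(g1: pd.Series | np.ndarray, g2: pd.Series | np.ndarray) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete calls.

    This is the composite-LD estimate available from unphased genotypes.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise UndefinedLDError("need >= 3 pairwise-complete samples")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedLDError("constant genotype column")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def marginal_pvalue_ranking(
    dosages: pd.DataFrame, betas: pd.Series
) -> pd.Series:
    """Per-SNP score for LD-pruning rank: simple-regression p of the CpG's
    beta-values on each dosage column (no covariates); smaller is stronger.

    Computed from the squared sample correlation via the exact Beta
    distribution of r^2 under the null.
    """
    y = betas.to_numpy(dtype=float)
    scores = {}
    for snp in dosages.columns:
        x = dosages[snp].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        xo, yo = x[ok], y[ok]
        n = len(xo)
        if n < 3 or xo.std() == 0 or yo.std() == 0:
            scores[snp] = 1.0
            continue
        r2 = np.corrcoef(xo, yo)[0, 1] ** 2
        # r^2 ~ Beta(1/2, (n-2)/2) under independence
        scores[snp] = float(beta_dist.sf(r2, 0.5, (n - 2) / 2.0))
    return pd.Series(scores)


def prune_ld(
    snp_ids,
    dosages: pd.DataFrame,
    *,
    r2_threshold: float = 0.5,
    ranking: pd.Series,
    positions: pd.Series | None = None,
) -> list[str]:
    """Greedy LD pruning of one CpG's candidate SNPs.

    ``ranking`` scores each SNP (smaller = stronger); ties are broken by
    ascending position, then id.  Returns retained SNP ids in selection
    order; the retained set is mutually below ``r2_threshold``.
    """
    snp_ids = list(snp_ids)
    if positions is None:
        positions = pd.Series(0, index=snp_ids)
    order = sorted(
        snp_ids, key=lambda s: (float(ranking[s]), int(positions[s]), str(s))
    )
    retained: list[str] = []
    remaining = list(order)
    while remaining:
        best = remaining.pop(0)
        retained.append(best)
        keep = []
        for other in remaining:
            if ld_r2(dosages[best], dosages[other]) < r2_threshold:
                keep.append(other)
        remaining = keep
    return retained


def run_qc(
    genotypes,
    pairs: pd.DataFrame,
    discovery_betas: pd.DataFrame,
    *,
    miss_threshold: float = 0.01,
    hwe_p_threshold: float = 1e-4,
    maf_threshold: float = 0.1,
    ld_r2_threshold: float = 0.5,
    ranking: str = "pvalue",
    ranking_dosages: pd.DataFrame | None = None,
) -> QCReport:
    """Apply all four filters to the candidate pairs of each CpG.

    ``pairs`` must carry ``cpg_id`` and ``snp_id`` columns (the output of
    cis pairing).  The marginal p-value ranking for pruning is computed
    on ``ranking_dosages`` (default: the discovery-panel rows of
    ``genotypes``) against ``discovery_betas``.
    """
    dosages = genotypes.dosages
    candidate_snps = pd.Index(pairs["snp_id"].unique())
    report = QCReport(n_input=len(candidate_snps))

    kept = missingness_filter(dosages[candidate_snps], miss_threshold)
    report.excluded_missingness = len(candidate_snps) - len(kept)

    hwe_pass = []
    for snp in kept:
        p = hwe_exact_test(*genotype_counts(dosages[snp]))
        if p >= hwe_p_threshold:
            hwe_pass.append(snp)
    report.excluded_hwe = len(kept) - len(hwe_pass)

    maf_pass = [s for s in hwe_pass if compute_maf(dosages[s]) > maf_threshold]
    report.excluded_maf = len(hwe_pass) - len(maf_pass)
    maf_pass = set(maf_pass)

    if ranking_dosages is None:
        ranking_dosages = dosages.loc[dosages.index.intersection(discovery_betas.index)]
    positions = genotypes.snps["pos"]
    for cpg_id, group in pairs.groupby("cpg_id", sort=False):
        cands = [s for s in group["snp_id"] if s in maf_pass]
        if not cands:
            report.survivors_per_cpg[cpg_id] = []
            continue
        if ranking == "pvalue":
            scores = marginal_pvalue_ranking(
                ranking_dosages[cands], discovery_betas[cpg_id]
            )
        elif ranking == "maf":
            scores = pd.Series({s: -compute_maf(dosages[s]) for s in cands})
        else:
            raise ValueError(f"unknown ranking {ranking!r}")
        retained = prune_ld(
            cands, dosages, r2_threshold=ld_r2_threshold,
            ranking=scores, positions=positions,
        )
        report.survivors_per_cpg[cpg_id] = retained
        report.excluded_ld[cpg_id] = len(cands) - len(retained)
    return report
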