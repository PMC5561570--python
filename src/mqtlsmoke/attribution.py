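"""Attribution of smoking-methylation effects to mQTLs.

For each validated mQTL-CpG pair, the smoking coefficient (current vs
never smoking) is estimated twice in fully adjusted batch-random-effect
models on the identical sample set: once without the mQTL (beta1) and
once including the minor-allele carrier indicator (beta2).  The
percentage change ``|100 * (beta1 - beta2) / beta1|`` measures how much
of the apparent smoking effect the mQTL accounts for; the pair is called
"attenuated" when |beta2| < |beta1| and "strengthened" otherwise.

Percentage changes are categorized by the absolute SNP-CpG distance
(< 10 kb vs >= 10 kb) and by how often the CpG was reported smoking
-related in prior studies (weak 2-3, moderate 4-5, high >= 6), with a
one-way ANOVA across the frequency classes.

The interaction scan mirrors the attribution models but adds genotype
(3-level, major-homozygote reference) x smoking product terms; the
per-pair interaction p-value is the Bonferroni-adjusted minimum contrast
p, corrected across pairs by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from mqtlsmoke.models import PanelData, bh_fdr, build_design, fit_mixed_lm

logger = logging.getLogger(__name__)

__all__ = [
    "recode_dominant",
    "attenuation_pct",
    "frequency_class",
    "distance_class",
    "run_attribution",
    "categorize_and_anova",
    "interaction_scan",
]


def recode_dominant(column: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Collapse minor-allele counts to carrier (1) / non-carrier (0).

    Heterozygotes and minor homozygotes are combined as carriers; missing
    calls stay missing.
    """
    arr = np.asarray(column, dtype=float)
    out = np.where(np.isnan(arr), np.nan, (arr > 0).astype(float))
    if isinstance(column, pd.Series):
        return pd.Series(out, index=column.index, name=column.name)
    return out


def attenuation_pct(beta1: float, beta2: float) -> tuple[float, str]:
    """Percentage change of the smoking coefficient and its direction.

    pct = |100 * (beta1 - beta2) / beta1|; "attenuated" when the adjusted
    coefficient is smaller in magnitude, else "strengthened".
    """
    if beta1 == 0:
        raise ValueError("attenuation undefined for beta1 = 0")
    pct = abs(100.0 * (beta1 - beta2) / beta1)
    direction = "attenuated" if abs(beta2) < abs(beta1) else "strengthened"
    return float(pct), direction


def frequency_class(reported_frequency: int) -> str:
    """weak (reported 2-3 times), moderate (4-5), high (>= 6)."""
    if reported_frequency < 2:
        raise ValueError("candidate CpGs are reported >= 2 times")
    if reported_frequency <= 3:
        return "weak"
    if reported_frequency <= 5:
        return "moderate"
    return "high"


def distance_class(distance: int, breakpoint: int = 10_000) -> str:
    return "<10kb" if abs(distance) < breakpoint else ">=10kb"


def _current_never_subset(panel: PanelData) -> PanelData:
    keep = panel.cohort["smoking_status"].isin(["current", "never"])
    ids = panel.cohort.index[keep]
    return PanelData(
        cohort=panel.cohort.loc[ids],
        betas=panel.betas.loc[ids],
        dosages=panel.dosages.loc[ids],
        cell_props=None if panel.cell_props is None else panel.cell_props.loc[ids],
    )


def run_attribution(
    mqtl_pairs: pd.DataFrame,
    panel: PanelData,
    *,
    manifest: pd.DataFrame,
    distance_breakpoint: int = 10_000,
    flag_alpha: float = 0.05,
) -> pd.DataFrame:
    """Attribution records for every validated mQTL-CpG pair.

    ``panel`` is the pooled two-panel data; the analysis is restricted to
    current + never smokers.  Both fits use the rows complete for the
    carrier-adjusted model, so beta1 and beta2 come from identical
    samples.  Pairs whose unadjusted smoking coefficient is zero or not
    significant at ``flag_alpha`` are flagged and their pct omitted.
    """
    sub = _current_never_subset(panel)
    base = build_design(sub.cohort, cell_props=sub.cell_props,
                        smoking_levels=("current",))
    term = "smoking_status[current]"
    rows = []
    for _, pair in mqtl_pairs.iterrows():
        cpg_id, snp_id = pair["cpg_id"], pair["snp_id"]
        carrier = recode_dominant(sub.dosages[snp_id]).rename("carrier")
        X_with = pd.concat([base, carrier], axis=1)
        complete = X_with.notna().all(axis=1) & sub.betas[cpg_id].notna()
        ids = X_with.index[complete]
        y = sub.betas.loc[ids, cpg_id]
        batch = sub.cohort.loc[ids, "batch"]
        fit1 = fit_mixed_lm(y, base.loc[ids], batch)
        fit2 = fit_mixed_lm(y, X_with.loc[ids], batch)
        beta1 = float(fit1.params[term])
        beta2 = float(fit2.params[term])
        p1 = float(fit1.pvalues[term])
        flagged = (beta1 == 0.0) or (p1 >= flag_alpha)
        if flagged:
            pct, direction = np.nan, None
        else:
            pct, direction = attenuation_pct(beta1, beta2)
        rows.append(
            {
                "cpg_id": cpg_id,
                "snp_id": snp_id,
                "beta1": beta1,
                "beta1_p": p1,
                "beta2": beta2,
                "pct_change": pct,
                "direction": direction,
                "flagged": flagged,
                "n_used": len(ids),
                "distance_class": distance_class(
                    int(pair["distance"]), distance_breakpoint
                ),
                "frequency_class": frequency_class(
                    int(manifest.loc[cpg_id, "reported_frequency"])
                ),
            }
        )
    return pd.DataFrame(rows)


def categorize_and_anova(records: pd.DataFrame) -> dict:
    """Class summaries of pct_change plus one-way ANOVA across frequency
    classes.

    Returns a dict with ``frequency_summary`` and ``distance_summary``
    DataFrames and ``anova_F`` / ``anova_p`` (NaN with a notice when
    fewer than two non-empty frequency classes exist).
    """
    ok = records.dropna(subset=["pct_change"])

    def summarize(by: str) -> pd.DataFrame:
        g = ok.groupby(by)["pct_change"]
        return pd.DataFrame(
            {"n": g.size(), "mean": g.mean(), "sd": g.std(ddof=1)}
        ).reset_index()

    out = {
        "frequency_summary": summarize("frequency_class"),
        "distance_summary": summarize("distance_class"),
    }
    groups = [
        grp["pct_change"].to_numpy()
        for _, grp in ok.groupby("frequency_class")
        if len(grp) >= 2  # singleton classes carry no within-group variance
    ]
    if len(groups) < 2:
        logger.warning("fewer than 2 frequency classes: ANOVA skipped")
        out["anova_F"], out["anova_p"] = np.nan, np.nan
    elif np.ptp(np.concatenate(groups)) == 0:
        out["anova_F"], out["anova_p"] = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*groups)
        out["anova_F"], out["anova_p"] = float(F), float(p)
    return out


def interaction_scan(
    mqtl_pairs: pd.DataFrame,
    panel: PanelData,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """SNP x smoking interaction models for every validated pair.

    Current + never smokers only.  Genotype enters as a 3-level
    categorical with the major homozygote as reference; the interaction
    terms are current-smoking x genotype-group products.  The per-pair
    p-value is the minimum interaction-contrast p, Bonferroni-adjusted
    for the number of contrasts, and BH-FDR is applied across pairs.
    """
    sub = _current_never_subset(panel)
    base = build_design(sub.cohort, cell_props=sub.cell_props,
                        smoking_levels=("current",))
    current = (sub.cohort["smoking_status"] == "current").astype(float)
    rows = []
    for _, pair in mqtl_pairs.iterrows():
        cpg_id, snp_id = pair["cpg_id"], pair["snp_id"]
        dosage = sub.dosages[snp_id]
        terms = {}
        for g in (1, 2):
            if (dosage == g).sum() == 0:
                logger.info("empty genotype cell %s=%d: contrast dropped", snp_id, g)
                continue
            geno = (dosage == g).astype(float)
            geno[dosage.isna()] = np.nan
            terms[f"geno[{g}]"] = geno
            terms[f"current:geno[{g}]"] = geno * current
        if not terms:
            continue
        X = pd.concat([base, pd.DataFrame(terms, index=base.index)], axis=1)
        try:
            fit = fit_mixed_lm(sub.betas[cpg_id], X, sub.cohort["batch"])
        except ValueError:
            continue
        contrasts = [t for t in terms if t.startswith("current:")]
        ps = [float(fit.pvalues[t]) for t in contrasts if t in fit.pvalues.index]
        if not ps:
            continue
        p_pair = min(1.0, min(ps) * len(ps))
        row = {
            "cpg_id": cpg_id,
            "snp_id": snp_id,
            "interaction_p": p_pair,
            "n_used": fit.n_used,
        }
        for t in contrasts:
            tag = t.split("geno")[1].strip("[]")
            row[f"coef_current_x_g{tag}"] = float(fit.params[t])
            row[f"se_current_x_g{tag}"] = float(fit.bse[t])
            row[f"p_current_x_g{tag}"] = float(fit.pvalues[t])
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["interaction_p"])
        out["significant"] = out["fdr"] < alpha
    return out
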