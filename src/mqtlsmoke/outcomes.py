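"""Outcome scans: mQTL carrier status vs smoking indicators and
all-cause mortality.

Six smoking indicators are tested per mQTL: three binary contrasts
(ever vs never, current vs never, current vs former smoking) by logistic
regression and three continuous measures (pack-years, smoking duration,
age of smoking initiation, among ever smokers) by linear regression.
Covariates are age, sex, alcohol, BMI class, physical activity and
prevalent CVD/diabetes/cancer; smoking-derived covariates are excluded
because smoking is the outcome.  FDR correction is applied per indicator
across the mQTL set.

All-cause mortality is tested with a Cox proportional-hazards model
(Breslow tie handling) on the pooled panels, additionally adjusted for
smoking status.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.duration.hazard_regression import PHReg

from mqtlsmoke.attribution import recode_dominant
from mqtlsmoke.models import PanelData, bh_fdr, build_design

logger = logging.getLogger(__name__)

__all__ = ["SMOKING_INDICATORS", "smoking_association_scan", "cox_mortality_scan"]

#: indicator -> (kind, subset rule, outcome builder)
SMOKING_INDICATORS = (
    "ever_vs_never",
    "current_vs_never",
    "current_vs_former",
    "pack_years",
    "duration",
    "initiation_age",
)


def _indicator_outcome(cohort: pd.DataFrame, indicator: str) -> pd.Series:
    s = cohort["smoking_status"]
    if indicator == "ever_vs_never":
        return s.isin(["current", "former"]).astype(float)
    if indicator == "current_vs_never":
        return (
            (s == "current").astype(float)[s.isin(["current", "never"])]
        )
    if indicator == "current_vs_former":
        return (
            (s == "current").astype(float)[s.isin(["current", "former"])]
        )
    if indicator == "pack_years":
        return cohort.loc[s.isin(["current", "former"]), "pack_years"].astype(float)
    if indicator == "duration":
        return cohort.loc[s.isin(["current", "former"]), "smoking_duration"].astype(float)
    if indicator == "initiation_age":
        return cohort.loc[s.isin(["current", "former"]), "initiation_age"].astype(float)
    raise ValueError(f"unknown indicator {indicator!r}")


_BINARY = {"ever_vs_never", "current_vs_never", "current_vs_former"}


def _fit_one(
    y: pd.Series, X: pd.DataFrame, binary: bool, linear_binary: bool
) -> tuple[float, float, float, int, str]:
    df = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    yv, Xv = df["__y__"], df[X.columns]
    n = len(df)
    if Xv["carrier"].nunique() < 2:
        return np.nan, np.nan, np.nan, n, "constant carrier"
    if yv.nunique() < 2:
        return np.nan, np.nan, np.nan, n, "one outcome class"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if binary and not linear_binary:
                res = sm.Logit(yv, Xv).fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", True):
                    return np.nan, np.nan, np.nan, n, "non-convergence"
                if res.bse["carrier"] > 50:
                    return np.nan, np.nan, np.nan, n, "separation"
            else:
                res = sm.OLS(yv, Xv).fit()
    except Exception as exc:  # separation / singular designs
        return np.nan, np.nan, np.nan, n, type(exc).__name__
    return (
        float(res.params["carrier"]),
        float(res.bse["carrier"]),
        float(res.pvalues["carrier"]),
        n,
        "",
    )


def smoking_association_scan(
    mqtl_snps, panel: PanelData, *, alpha: float = 0.05,
    binary_model: str = "logistic",
) -> pd.DataFrame:
    """Test each mQTL (carrier/non-carrier) against the six smoking
    indicators.

    ``binary_model='linear'`` switches the binary contrasts to linear
    probability models (for fidelity comparisons).  Returns one row per
    SNP x indicator with estimate/SE/p/FDR; FDR is computed within each
    indicator family.
    """
    linear_binary = binary_model == "linear"
    base = build_design(panel.cohort, include_smoking=False, cell_props=None)
    base = base.drop(columns=[c for c in base.columns if c.startswith("prop[")])
    rows = []
    for indicator in SMOKING_INDICATORS:
        y = _indicator_outcome(panel.cohort, indicator)
        if y.dropna().nunique() < 2:
            logger.warning("indicator %s has one class only: skipped", indicator)
            continue
        Xb = base.loc[y.index]
        for snp_id in mqtl_snps:
            carrier = recode_dominant(panel.dosages[snp_id]).rename("carrier")
            X = pd.concat([carrier.loc[y.index], Xb], axis=1)
            est, se, p, n, note = _fit_one(
                y, X, indicator in _BINARY, linear_binary
            )
            rows.append(
                {
                    "snp_id": snp_id,
                    "outcome": indicator,
                    "estimate": est,
                    "se": se,
                    "p": p,
                    "n_used": n,
                    "note": note,
                }
            )
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    for indicator in out["outcome"].unique():
        mask = (out["outcome"] == indicator) & out["p"].notna()
        if mask.any():
            out.loc[mask, "fdr"] = bh_fdr(out.loc[mask, "p"])
    out["significant"] = out["fdr"] < alpha
    return out


def cox_mortality_scan(
    mqtl_snps, panel: PanelData, *, alpha: float = 0.05
) -> pd.DataFrame:
    """Cox regression (Breslow ties) of all-cause mortality on carrier
    status, pooled panels, fully adjusted including smoking status."""
    cohort = panel.cohort
    if (cohort["followup_time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if int(cohort["dead"].sum()) == 0:
        raise ValueError("no events: mortality model cannot be fitted")
    base = build_design(cohort, include_smoking=True, cell_props=None)
    base = base.drop(
        columns=["const"] + [c for c in base.columns if c.startswith("prop[")]
    )
    rows = []
    for snp_id in mqtl_snps:
        carrier = recode_dominant(panel.dosages[snp_id]).rename("carrier")
        df = pd.concat(
            [cohort[["followup_time", "dead"]], carrier, base], axis=1
        ).dropna()
        n, n_events = len(df), int(df["dead"].sum())
        note, est, se, p = "", np.nan, np.nan, np.nan
        if df["carrier"].nunique() < 2:
            note = "constant carrier"
        elif n_events == 0:
            note = "no events"
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = PHReg(
                        df["followup_time"],
                        df[["carrier"] + list(base.columns)],
                        status=df["dead"],
                        ties="breslow",
                    ).fit(maxiter=200)
                est = float(res.params[0])
                se = float(res.bse[0])
                p = float(np.asarray(res.pvalues)[0])
                if not np.isfinite(se) or se > 50:
                    note, est, se, p = "non-convergence", np.nan, np.nan, np.nan
            except Exception as exc:
                note = type(exc).__name__
        rows.append(
            {
                "snp_id": snp_id,
                "outcome": "mortality",
                "estimate": est,
                "se": se,
                "p": p,
                "n_used": n,
                "n_events": n_events,
                "note": note,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    mask = out["p"].notna()
    if mask.any():
        out.loc[mask, "fdr"] = bh_fdr(out.loc[mask, "p"])
    out["significant"] = out["fdr"] < alpha
    return out
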