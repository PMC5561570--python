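"""Association models: fully adjusted batch-random-effect fits per
SNP-CpG pair and the two-stage discovery/validation FDR procedure.

The per-pair model regresses the CpG's beta-values on the SNP dosage plus
the full covariate set (age, sex, smoking status, alcohol, BMI class,
physical activity, estimated cell proportions, prevalent CVD, diabetes
and cancer) with methylation batch as a random intercept, fitted by REML.
With a single batch the model degrades to ordinary least squares (the
random intercept is not identifiable) and this is logged.

Stage 1 runs every QC-passing pair in the discovery panel and applies
Benjamini-Hochberg FDR across all SNP-term p-values jointly; stage-1
survivors are refit in the validation panel and a second BH correction is
applied over the survivors only.  Pairs surviving both stages are the
designated mQTLs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from mqtlsmoke.containers import cell_prop_columns

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "PanelData",
    "build_design",
    "fit_mixed_lm",
    "bh_fdr",
    "fit_stage",
    "run_two_stage",
    "RankDeficientError",
]


class RankDeficientError(ValueError):
    pass


@dataclass
class FitResult:
    """One model fit: coefficients, Wald inference, variance components."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    batch_var: float
    resid_var: float
    converged: bool
    n_used: int
    method: str  # "mixedlm" | "ols"


@dataclass
class PanelData:
    """One panel's aligned tables, indexed by sample_id."""

    cohort: pd.DataFrame  # covariates (sample_id index)
    betas: pd.DataFrame  # samples x CpGs
    dosages: pd.DataFrame  # samples x SNPs
    cell_props: pd.DataFrame | None = None  # estimated proportions

    def __post_init__(self) -> None:
        for name, tab in (("betas", self.betas), ("dosages", self.dosages)):
            if not tab.index.equals(self.cohort.index):
                raise ValueError(f"{name} sample ids do not align with cohort")
        if self.cell_props is not None and not self.cell_props.index.equals(
            self.cohort.index
        ):
            raise ValueError("cell_props sample ids do not align with cohort")


#: Dummy coding for the categorical covariates (reference level first).
_CATEGORY_CODING = {
    "sex": ("female", ["male"]),
    "smoking_status": ("never", ["former", "current"]),
    "alcohol": ("abstainer", ["low", "intermediate", "high"]),
    "bmi_class": ("normal", ["overweight", "obese"]),
    "activity": ("inactive", ["low", "medium_high"]),
}


def build_design(
    cohort: pd.DataFrame,
    *,
    include_smoking: bool = True,
    cell_props: pd.DataFrame | None = None,
    smoking_levels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Fully adjusted fixed-effect design matrix (without the SNP term).

    Categorical covariates are dummy-coded against their reference level;
    cell proportions enter as K-1 columns (last type dropped) to avoid
    collinearity with the intercept.  ``smoking_levels`` restricts the
    smoking dummies actually emitted (e.g. only "current" when the data
    are restricted to current + never smokers).
    """
    X = pd.DataFrame(index=cohort.index)
    X["const"] = 1.0
    X["age"] = cohort["age"].astype(float)
    for col, (ref, levels) in _CATEGORY_CODING.items():
        if col == "smoking_status":
            if not include_smoking:
                continue
            if smoking_levels is not None:
                levels = [l for l in levels if l in smoking_levels]
        for level in levels:
            X[f"{col}[{level}]"] = (cohort[col] == level).astype(float)
        X.loc[cohort[col].isna(), [f"{col}[{l}]" for l in levels]] = np.nan
    for col in ("cvd", "diabetes", "cancer"):
        X[col] = cohort[col].astype(float)
    if cell_props is None and cell_prop_columns(cohort):
        cell_props = cohort[cell_prop_columns(cohort)]
    if cell_props is not None:
        cols = [c for c in cell_props.columns if c != "residual"]
        for c in cols[:-1]:  # K-1 proportions
            X[f"prop[{c}]"] = cell_props[c].astype(float)
    # degenerate subsets (a category level absent or universal) yield
    # constant dummies collinear with the intercept: drop them
    for col in list(X.columns):
        if col == "const":
            continue
        vals = X[col].dropna()
        if vals.nunique() <= 1:
            X = X.drop(columns=col)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        _, R = np.linalg.qr(A)
        bad = [X.columns[i] for i in range(A.shape[1]) if abs(R[i, i]) < 1e-8]
        raise RankDeficientError(f"collinear design terms: {bad}")


def fit_mixed_lm(
    y: pd.Series, X: pd.DataFrame, batch: pd.Series
) -> FitResult:
    """REML fit of ``y = X g + u_batch + e`` with Wald tests per term.

    Listwise deletion is applied over ``y``, ``X`` and ``batch``.  With a
    single batch level the random intercept is dropped and the model is
    fitted by OLS (logged).  Non-convergence is flagged, not raised.
    """
    df = pd.concat([y.rename("__y__"), X, batch.rename("__batch__")], axis=1)
    df = df.dropna()
    n_used = len(df)
    if n_used <= X.shape[1] + 1:
        raise ValueError("not enough complete observations to fit the model")
    yv = df["__y__"]
    Xv = df[X.columns]
    _check_rank(Xv)
    groups = df["__batch__"]

    if groups.nunique() < 2:
        logger.info("single methylation batch: fitting OLS instead of mixed model")
        res = sm.OLS(yv, Xv).fit()
        return FitResult(
            params=res.params,
            bse=res.bse,
            pvalues=res.pvalues,
            cov_params=res.cov_params(),
            batch_var=0.0,
            resid_var=float(res.scale),
            converged=True,
            n_used=n_used,
            method="ols",
        )

    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(yv, Xv, groups=groups)
        # bfgs first: lbfgs can report convergence on the sigma_b = 0
        # boundary for small variance ratios
        for method in ("bfgs", "lbfgs", "powell"):
            try:
                cand = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError, OverflowError):
                continue
            res = cand
            if cand.converged:
                break
    if res is None:
        nan = pd.Series(np.nan, index=X.columns)
        return FitResult(
            params=nan, bse=nan, pvalues=nan,
            cov_params=pd.DataFrame(np.nan, index=X.columns, columns=X.columns),
            batch_var=np.nan, resid_var=np.nan,
            converged=False, n_used=n_used, method="mixedlm",
        )
    converged = bool(res.converged)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fe = res.fe_params
        bse = res.bse_fe
        cov = res.cov_params().loc[fe.index, fe.index]
    z = fe / bse
    pvals = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=fe.index)
    return FitResult(
        params=fe,
        bse=bse,
        pvalues=pvals,
        cov_params=cov,
        batch_var=float(np.asarray(res.cov_re)[0, 0]),
        resid_var=float(res.scale),
        converged=converged,
        n_used=n_used,
        method="mixedlm",
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one family of tests."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _snp_terms(dosage: pd.Series, coding: str) -> pd.DataFrame:
    if coding == "additive":
        return dosage.astype(float).rename("snp").to_frame()
    if coding == "categorical":
        out = pd.DataFrame(index=dosage.index)
        out["snp[1]"] = (dosage == 1).astype(float)
        out["snp[2]"] = (dosage == 2).astype(float)
        out.loc[dosage.isna(), :] = np.nan
        return out
    raise ValueError(f"unknown snp coding {coding!r}")


def _fit_pair(
    panel: PanelData,
    base_design: pd.DataFrame,
    cpg_id: str,
    snp_id: str,
    coding: str,
) -> tuple[float, float, float, bool, int]:
    """Fit one pair; returns (coef, se, p, converged, n_used).

    For categorical coding the reported coefficient/SE are for the
    hom-minor contrast and the p-value is the joint Wald test of both
    genotype dummies.
    """
    snp_cols = _snp_terms(panel.dosages[snp_id], coding)
    if snp_cols.dropna().nunique().min() < 2 and coding == "additive":
        return np.nan, np.nan, np.nan, False, 0
    X = pd.concat([snp_cols, base_design], axis=1)
    try:
        fit = fit_mixed_lm(panel.betas[cpg_id], X, panel.cohort["batch"])
    except (RankDeficientError, ValueError):
        return np.nan, np.nan, np.nan, False, 0
    if coding == "additive":
        return (
            float(fit.params["snp"]),
            float(fit.bse["snp"]),
            float(fit.pvalues["snp"]),
            fit.converged,
            fit.n_used,
        )
    terms = [t for t in ("snp[1]", "snp[2]") if t in fit.params.index]
    c = fit.params[terms].to_numpy()
    V = fit.cov_params.loc[terms, terms].to_numpy()
    chi2 = float(c @ np.linalg.solve(V, c))
    p = float(stats.chi2.sf(chi2, df=len(terms)))
    lead = terms[-1]
    return float(fit.params[lead]), float(fit.bse[lead]), p, fit.converged, fit.n_used


def fit_stage(
    pairs: pd.DataFrame,
    panel: PanelData,
    *,
    snp_coding: str = "additive",
) -> pd.DataFrame:
    """Fit the fully adjusted model for every pair in one panel.

    Returns a frame aligned with ``pairs`` holding ``coef``, ``se``,
    ``p`` and ``n`` (NaN for untested / non-converged pairs).
    """
    design = build_design(panel.cohort, cell_props=panel.cell_props)
    out = pd.DataFrame(
        index=pairs.index, columns=["coef", "se", "p"], dtype=float
    )
    out["n"] = 0
    for i, row in pairs.iterrows():
        coef, se, p, conv, n = _fit_pair(
            panel, design, row["cpg_id"], row["snp_id"], snp_coding
        )
        if conv:
            out.loc[i, ["coef", "se", "p"]] = coef, se, p
            out.loc[i, "n"] = n
    return out


def run_two_stage(
    pairs: pd.DataFrame,
    discovery: PanelData,
    validation: PanelData,
    *,
    alpha: float = 0.05,
    snp_coding: str = "additive",
    validation_fdr_scope: str = "survivors",
) -> pd.DataFrame:
    """Two-stage mQTL discovery with BH-FDR at each stage.

    Returns the pair table augmented with ``disc_coef/se/p/fdr``,
    ``valid_coef/se/p/fdr``, ``is_mqtl`` and ``sign_concordant``.  The
    stage-1 FDR family is all tested pairs jointly; the stage-2 family is
    the stage-1 survivors only (or, with ``validation_fdr_scope='joint'``,
    all pairs refit in validation).
    """
    out = pairs.copy().reset_index(drop=True)
    for col in ("disc_coef", "disc_se", "disc_p", "disc_fdr",
                "valid_coef", "valid_se", "valid_p", "valid_fdr"):
        out[col] = np.nan
    out["disc_n"] = 0
    out["valid_n"] = 0
    out["is_mqtl"] = False
    out["sign_concordant"] = pd.array([None] * len(out), dtype="boolean")

    s1 = fit_stage(out, discovery, snp_coding=snp_coding)
    out[["disc_coef", "disc_se", "disc_p"]] = s1[["coef", "se", "p"]].to_numpy()
    out["disc_n"] = s1["n"].to_numpy()

    tested = out["disc_p"].notna()
    if tested.any():
        out.loc[tested, "disc_fdr"] = bh_fdr(out.loc[tested, "disc_p"])
    survivors = tested & (out["disc_fdr"] < alpha)
    if not survivors.any():
        logger.warning("no stage-1 survivors at FDR < %s", alpha)
        return out

    refit = out.index if validation_fdr_scope == "joint" else out.index[survivors]
    s2 = fit_stage(out.loc[refit], validation, snp_coding=snp_coding)
    out.loc[refit, ["valid_coef", "valid_se", "valid_p"]] = (
        s2[["coef", "se", "p"]].to_numpy()
    )
    out.loc[refit, "valid_n"] = s2["n"].to_numpy()

    vtested = out["valid_p"].notna()
    if vtested.any():
        out.loc[vtested, "valid_fdr"] = bh_fdr(out.loc[vtested, "valid_p"])
    out["is_mqtl"] = survivors & vtested & (out["valid_fdr"] < alpha)
    hit = out["is_mqtl"]
    out.loc[hit, "sign_concordant"] = (
        np.sign(out.loc[hit, "disc_coef"]) == np.sign(out.loc[hit, "valid_coef"])
    )
    return out
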