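"""End-to-end orchestration: simulate -> cells -> pair -> qc ->
discover/validate -> attribute -> interact -> outcomes.

Each stage writes its TSV into the run directory as it completes, so a
failed run preserves partial outputs; a stage failure raises
:class:`StageError` tagged with the stage name.  Reruns with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from mqtlsmoke import io as mio
from mqtlsmoke.attribution import categorize_and_anova, interaction_scan, run_attribution
from mqtlsmoke.config import PipelineConfig
from mqtlsmoke.containers import GenotypeMatrix, MethylationMatrix
from mqtlsmoke.deconvolution import estimate_proportions_matrix
from mqtlsmoke.models import PanelData, run_two_stage
from mqtlsmoke.outcomes import cox_mortality_scan, smoking_association_scan
from mqtlsmoke.pairs import build_pairs
from mqtlsmoke.qc import run_qc
from mqtlsmoke.simulate import SimulatedStudy, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["StageError", "PipelineResult", "run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineResult:
    study: SimulatedStudy
    cell_props: pd.DataFrame
    pairs: pd.DataFrame
    dropped_cpgs: list
    qc_report: object
    two_stage: pd.DataFrame
    mqtls: pd.DataFrame
    attribution: pd.DataFrame
    attribution_classes: dict
    interactions: pd.DataFrame
    smoking_outcomes: pd.DataFrame
    mortality: pd.DataFrame
    out_dir: Path


def _panel(study: SimulatedStudy, props: pd.DataFrame, which: str) -> PanelData:
    cohort = study.cohort[study.cohort["panel"] == which].set_index("sample_id")
    ids = cohort.index
    return PanelData(
        cohort=cohort,
        betas=study.methylation.betas.loc[ids],
        dosages=study.genotypes.dosages.loc[ids],
        cell_props=props.loc[ids],
    )


def _pooled(study: SimulatedStudy, props: pd.DataFrame) -> PanelData:
    cohort = study.cohort.set_index("sample_id")
    return PanelData(
        cohort=cohort,
        betas=study.methylation.betas,
        dosages=study.genotypes.dosages,
        cell_props=props.loc[cohort.index],
    )


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    *,
    study: SimulatedStudy | None = None,
    write_inputs: bool = True,
) -> PipelineResult:
    """Run every stage on simulated (or supplied) study data.

    Writes stage TSVs, a QC report, a Manhattan-plot-ready TSV and a JSON
    run-metadata file into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        if study is None:
            sim = config.simulation
            if sim.seed != config.seed:
                sim = type(sim)(**{**sim.to_dict(), "seed": config.seed})
            study = simulate_study(sim)
        if write_inputs:
            mio.write_cohort(study.cohort, out / "cohort.tsv")
            mio.write_methylation(study.methylation.betas, out / "methylation.tsv")
            mio.write_manifest(study.methylation.manifest, out / "manifest.tsv")
            mio.write_genotypes_tsv(
                study.genotypes, out / "genotypes.tsv", out / "snp_annotation.tsv"
            )
            mio.write_methylation(study.reference_betas, out / "reference_betas.tsv")
            mio.write_cell_reference(study.reference, out / "cell_reference.tsv")
            study.truth.to_json(out / "truth.json")
    except Exception as exc:
        raise StageError("simulate", exc)

    try:
        stage("cells")
        cell_props = estimate_proportions_matrix(
            study.reference_betas, study.reference
        )
        cell_props.to_csv(out / "cell_proportions.tsv", sep="\t", float_format="%.12g")
    except Exception as exc:
        raise StageError("cells", exc)

    try:
        stage("pair")
        pairs, dropped = build_pairs(
            study.methylation.manifest, study.genotypes.snps, config.window
        )
        pd.DataFrame({"cpg_id": dropped}).to_csv(
            out / "dropped_cpgs.tsv", sep="\t", index=False
        )
    except Exception as exc:
        raise StageError("pair", exc)

    disc = _panel(study, cell_props, "discovery")
    valid = _panel(study, cell_props, "validation")

    try:
        stage("qc")
        qc_report = run_qc(
            study.genotypes,
            pairs,
            disc.betas,
            miss_threshold=config.miss_threshold,
            hwe_p_threshold=config.hwe_p_threshold,
            maf_threshold=config.maf_threshold,
            ld_r2_threshold=config.ld_r2_threshold,
            ranking=config.ld_ranking,
            ranking_dosages=disc.dosages,
        )
        tables["qc_report"] = qc_report.to_frame().astype({"count": float})
        surv = {
            (c, s)
            for c, lst in qc_report.survivors_per_cpg.items()
            for s in lst
        }
        mask = [
            (c, s) in surv
            for c, s in zip(pairs["cpg_id"], pairs["snp_id"])
        ]
        keep = pairs[mask].reset_index(drop=True)
        tables["pairs"] = keep.astype({"cpg_pos": float, "snp_pos": float,
                                       "distance": float})
    except Exception as exc:
        raise StageError("qc", exc)

    try:
        stage("discover/validate")
        two_stage = run_two_stage(
            keep, disc, valid,
            alpha=config.fdr_alpha,
            snp_coding=config.snp_coding,
            validation_fdr_scope=config.validation_fdr_scope,
        )
        tables["two_stage"] = two_stage.drop(columns=["sign_concordant"]).assign(
            sign_concordant=two_stage["sign_concordant"].astype(object)
        )
        mqtls = two_stage[two_stage["is_mqtl"]].reset_index(drop=True)
        tables["mqtls"] = mqtls.drop(columns=["sign_concordant"]).assign(
            sign_concordant=mqtls["sign_concordant"].astype(object)
        )
        man = two_stage[["cpg_id", "snp_id", "chrom", "snp_pos"]].copy()
        for st in ("disc", "valid"):
            man[f"{st}_p"] = two_stage[f"{st}_p"]
            with np.errstate(divide="ignore"):
                man[f"neglog10_{st}_p"] = -np.log10(two_stage[f"{st}_p"])
        man["fdr_threshold"] = config.fdr_alpha
        man["is_mqtl"] = two_stage["is_mqtl"]
        tables["manhattan"] = man
    except Exception as exc:
        raise StageError("discover/validate", exc)

    pooled = _pooled(study, cell_props)

    try:
        stage("attribute")
        attribution = run_attribution(
            mqtls, pooled,
            manifest=study.methylation.manifest,
            distance_breakpoint=config.distance_breakpoint,
        )
        tables["attribution"] = attribution
        classes = categorize_and_anova(attribution) if len(attribution) else {
            "frequency_summary": pd.DataFrame(), "distance_summary": pd.DataFrame(),
            "anova_F": np.nan, "anova_p": np.nan,
        }
        tables["attribution_by_frequency"] = classes["frequency_summary"]
        tables["attribution_by_distance"] = classes["distance_summary"]
    except Exception as exc:
        raise StageError("attribute", exc)

    try:
        stage("interact")
        interactions = interaction_scan(mqtls, pooled, alpha=config.fdr_alpha)
        tables["interactions"] = interactions
    except Exception as exc:
        raise StageError("interact", exc)

    try:
        stage("outcomes")
        snp_set = list(pd.unique(mqtls["snp_id"]))
        if snp_set:
            smoking = smoking_association_scan(snp_set, pooled, alpha=config.fdr_alpha)
            mortality = cox_mortality_scan(snp_set, pooled, alpha=config.fdr_alpha)
        else:
            smoking = pd.DataFrame()
            mortality = pd.DataFrame()
        tables["smoking_outcomes"] = smoking
        tables["mortality"] = mortality
    except Exception as exc:
        raise StageError("outcomes", exc)

    meta = {
        "seed": config.seed,
        "config": config.to_dict(),
        "anova_F": None if pd.isna(classes["anova_F"]) else classes["anova_F"],
        "anova_p": None if pd.isna(classes["anova_p"]) else classes["anova_p"],
        "n_candidate_pairs": int(len(pairs)),
        "n_qc_pairs": int(len(keep)),
        "n_mqtl_pairs": int(len(mqtls)),
        "n_mqtl_snps": int(mqtls["snp_id"].nunique()) if len(mqtls) else 0,
        "n_mqtl_cpgs": int(mqtls["cpg_id"].nunique()) if len(mqtls) else 0,
        "dropped_cpgs": dropped,
    }
    mio.write_results(tables, out, metadata=meta)

    return PipelineResult(
        study=study,
        cell_props=cell_props,
        pairs=pairs,
        dropped_cpgs=dropped,
        qc_report=qc_report,
        two_stage=two_stage,
        mqtls=mqtls,
        attribution=attribution,
        attribution_classes=classes,
        interactions=interactions,
        smoking_outcomes=smoking,
        mortality=mortality,
        out_dir=out,
    )
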