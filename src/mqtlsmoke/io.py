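"""Readers and writers for the pipeline's on-disk formats.

Formats: a minimal VCF 4.2 subset (CHROM, POS, ID, REF, ALT, GT) read via
cyvcf2, TSV matrices for dosages and beta-values (samples in rows), a
BED-like but 1-based CpG manifest TSV, the cohort covariate TSV, and the
result tables plus a JSON run-metadata sidecar.

Orientation convention: the counted allele is always the minor allele
*within the loaded cohort*.  A VCF whose ALT allele has frequency above
0.5 is flipped at load time (counts become ``2 - g`` and the reported
minor allele becomes REF); ties at exactly 0.5 keep file order (ALT
stays the counted allele).  All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from mqtlsmoke.containers import (
    CellReference,
    GenotypeMatrix,
    MethylationMatrix,
    ValidationError,
    validate_cohort,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "read_methylation",
    "write_methylation",
    "read_manifest",
    "write_manifest",
    "read_cohort",
    "write_cohort",
    "read_cell_reference",
    "write_cell_reference",
    "write_results",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- genotypes

def write_genotypes_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a GT-only VCF 4.2; ALT is the stored minor allele."""
    path = Path(path)
    samples = list(genotypes.sample_ids)
    contigs = sorted(set(str(c) for c in genotypes.snps["chrom"]))
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    order = genotypes.snps.sort_values(["chrom", "pos"]).index
    for snp_id in order:
        snp = genotypes.snps.loc[snp_id]
        minor = snp.get("minor_allele", "A")
        ref = "G" if minor != "G" else "T"
        col = genotypes.dosages[snp_id]
        gts = "\t".join(
            "./." if np.isnan(v) else code[float(v)] for v in col
        )
        lines.append(
            f"{snp['chrom']}\t{int(snp['pos'])}\t{snp_id}\t{ref}\t{minor}"
            f"\t.\t.\t.\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")


def _orient_minor(dosages: pd.DataFrame, alleles: pd.DataFrame) -> GenotypeMatrix:
    """Flip columns so the counted allele is the within-cohort minor one."""
    dosages = dosages.copy()
    snps = alleles.copy()
    minor = []
    maf = []
    for snp_id in dosages.columns:
        col = dosages[snp_id]
        with np.errstate(invalid="ignore"):
            f = np.nanmean(col.to_numpy(dtype=float)) / 2.0
        counted = snps.loc[snp_id, "counted_allele"]
        other = snps.loc[snp_id, "other_allele"]
        if f > 0.5:  # ties keep file order
            dosages[snp_id] = 2.0 - col
            minor.append(other)
            maf.append(1.0 - f)
        else:
            minor.append(counted)
            maf.append(f)
    snps["minor_allele"] = minor
    snps["maf"] = maf
    snps = snps.drop(columns=["counted_allele", "other_allele"])
    return GenotypeMatrix(dosages, snps)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    cols: dict[str, np.ndarray] = {}
    ann = []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            logger.warning(
                "skipping multi-allelic site %s at line-record %d", var.ID, i + 1
            )
            continue
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if snp_id in cols:
            raise ParseError(f"duplicate SNP id {snp_id!r} (record {i + 1})")
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        g = var.gt_types.astype(float)
        g[g == 2] = np.nan
        g[g == 3] = 2.0
        cols[snp_id] = g
        ann.append((snp_id, var.CHROM, var.POS, var.ALT[0], var.REF))
    if not ann:
        raise ParseError(f"no biallelic records in {path}")
    dosages = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
    alleles = pd.DataFrame(
        ann, columns=["snp_id", "chrom", "pos", "counted_allele", "other_allele"]
    ).set_index("snp_id")
    return _orient_minor(dosages, alleles)


def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    *,
    annotation: str | Path | None = None,
) -> GenotypeMatrix:
    """Load genotypes from VCF or dosage TSV as minor-allele counts.

    For ``format='tsv'`` the matrix file has sample_id rows and SNP
    columns (NA = missing); ``annotation`` is a TSV with columns snp_id,
    chrom, pos, counted_allele, other_allele.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format != "tsv":
        raise ValueError(f"unknown genotype format {format!r}")
    dosages = pd.read_csv(path, sep="\t", index_col="sample_id").astype(float)
    if dosages.index.duplicated().any():
        raise ValidationError("duplicate sample_id in genotype matrix")
    vals = dosages.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"invalid dosage {vals[r, c]!r} at line {r + 2}, column {dosages.columns[c]}"
        )
    if annotation is None:
        ann = pd.DataFrame(
            {
                "chrom": "NA",
                "pos": 0,
                "counted_allele": "A",
                "other_allele": "G",
            },
            index=dosages.columns.rename("snp_id"),
        )
    else:
        ann = pd.read_csv(
            annotation, sep="\t", dtype={"chrom": str}
        ).set_index("snp_id")
        ann = ann.loc[dosages.columns]
    return _orient_minor(dosages, ann)


def write_genotypes_tsv(
    genotypes: GenotypeMatrix, path: str | Path, annotation: str | Path | None = None
) -> None:
    genotypes.dosages.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")
    if annotation is not None:
        ann = genotypes.snps.copy()
        ann["counted_allele"] = ann.pop("minor_allele")
        ann["other_allele"] = "G"
        cols = ["chrom", "pos", "counted_allele", "other_allele"]
        ann[cols].to_csv(annotation, sep="\t")


# ------------------------------------------------------------- methylation

def read_methylation(path: str | Path) -> pd.DataFrame:
    """Beta-value matrix (samples x CpGs); strict [0, 1] validation."""
    betas = pd.read_csv(path, sep="\t", index_col="sample_id")
    if betas.index.duplicated().any():
        raise ValidationError("duplicate sample_id in methylation matrix")
    if betas.columns.duplicated().any():
        raise ValidationError("duplicate CpG id in methylation matrix")
    vals = betas.to_numpy(dtype=float)
    if np.nanmin(vals) < 0.0 or np.nanmax(vals) > 1.0:
        raise ValidationError("beta-values outside [0, 1]")
    return betas


def write_methylation(betas: pd.DataFrame, path: str | Path) -> None:
    betas.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """CpG manifest TSV (1-based positions).

    Columns: chrom, pos, cpg_id, gene, reported_frequency.  Candidate
    CpGs must have been reported at least twice.
    """
    man = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "cpg_id", "gene", "reported_frequency"}
    if not required.issubset(man.columns):
        raise ValidationError(f"manifest missing columns {required - set(man.columns)}")
    if man["cpg_id"].duplicated().any():
        raise ValidationError("duplicate cpg_id in manifest")
    if (man["pos"] < 1).any():
        raise ValidationError("manifest positions must be 1-based (>= 1)")
    if (man["reported_frequency"] < 2).any():
        raise ValidationError("candidate CpGs must be reported >= 2 times")
    return man.set_index("cpg_id")[["chrom", "pos", "gene", "reported_frequency"]]


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    out = manifest.reset_index()[["chrom", "pos", "cpg_id", "gene", "reported_frequency"]]
    out.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ cohort

def read_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t", dtype={"batch": str})
    return validate_cohort(cohort)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_cell_reference(path: str | Path) -> CellReference:
    return CellReference(pd.read_csv(path, sep="\t", index_col="cpg_id"))


def write_cell_reference(reference: CellReference, path: str | Path) -> None:
    reference.profiles.to_csv(path, sep="\t", float_format="%.12g")


# ----------------------------------------------------------------- results

def _format_results(table: pd.DataFrame) -> pd.DataFrame:
    """Scientific notation for p/FDR columns, 6 significant digits for
    other floats."""
    out = table.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        name = col.lower()
        if name in ("p", "fdr") or name.endswith(("_p", "_fdr")) or name.startswith(
            ("p_", "fdr_")
        ) or "pvalue" in name or name == "interaction_p":
            out[col] = out[col].map(
                lambda v: "NA" if pd.isna(v) else f"{v:.6e}"
            )
        else:
            out[col] = out[col].map(
                lambda v: "NA" if pd.isna(v) else f"{v:.6g}"
            )
    return out


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    metadata: dict | None = None,
) -> list[Path]:
    """Write result tables as TSVs plus a JSON run-metadata file.

    Column order is preserved as given; empty tables produce header-only
    files; reruns on identical inputs are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        p = out_dir / f"{name}.tsv"
        _format_results(table).to_csv(p, sep="\t", index=False, na_rep="NA")
        written.append(p)
    meta = dict(metadata or {})
    meta.setdefault("versions", _versions())
    if "config" in meta:
        blob = json.dumps(meta["config"], sort_keys=True).encode()
        meta["config_hash"] = hashlib.sha256(blob).hexdigest()
    p = out_dir / "run_metadata.json"
    p.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    written.append(p)
    return written


def _versions() -> dict:
    import scipy
    import statsmodels

    from mqtlsmoke import __version__

    return {
        "mqtlsmoke": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.version.full_version
        if hasattr(statsmodels, "version")
        else statsmodels.__version__,
    }
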