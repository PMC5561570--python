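"""Bundled reference catalogs of published smoking-related cis-mQTLs.

Two small TSVs (GRCh37/hg19 coordinates) ship with the package:

``mqtl_catalog_pairs.tsv``
    Validated SNP-CpG pairs from a published whole-blood cis-mQTL study
    of smoking-related CpG sites, with 1-based positions, the printed
    signed distance (SNP position minus CpG position), the
    validation-panel FDR and the minor allele frequency.  Only rows whose
    printed distance is internally consistent with the printed positions
    are included.

``mqtl_catalog_counts.tsv``
    Per-CpG counts of cis-window SNP candidates and validated mQTLs for
    the 70 smoking-related CpG sites with at least one validated mQTL
    (246 validated pairs in total).

These catalogs serve as ground truth for checking the pairing and
distance conventions, and as realistic position sets for examples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_catalog_pairs", "load_catalog_counts"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("mqtlsmoke.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def load_catalog_pairs() -> pd.DataFrame:
    """Validated SNP-CpG pairs with printed signed distances."""
    return _read("mqtl_catalog_pairs.tsv")


def load_catalog_counts() -> pd.DataFrame:
    """Per-CpG candidate and validated-mQTL counts (70 CpG sites)."""
    return _read("mqtl_catalog_counts.tsv")
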