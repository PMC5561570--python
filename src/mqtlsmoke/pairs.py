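"""cis-window SNP-CpG pairing.

A SNP pairs with a CpG when both sit on the same chromosome and the SNP
position falls inside the inclusive window ``[cpg_pos - window,
cpg_pos + window]``.  The signed distance convention is fixed as
``snp_pos - cpg_pos`` (negative = SNP upstream of the CpG on the plus
strand), matching the convention used in published cis-mQTL tables.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["build_pairs"]


def build_pairs(
    manifest: pd.DataFrame,
    snps: pd.DataFrame,
    window: int = 50_000,
) -> tuple[pd.DataFrame, list[str]]:
    """Emit every SNP-CpG pair inside the cis window.

    Parameters
    ----------
    manifest:
        CpG table indexed by cpg_id with ``chrom`` and ``pos`` (1-based).
    snps:
        SNP table indexed by snp_id with ``chrom`` and ``pos`` (1-based).
    window:
        Half-width of the cis window in bp; bounds are inclusive.

    Returns
    -------
    (pairs, dropped):
        ``pairs`` has columns cpg_id, snp_id, chrom, cpg_pos, snp_pos,
        distance (= snp_pos - cpg_pos), sorted by cpg then position;
        ``dropped`` lists CpG ids with no SNP in their window.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    dropped: list[str] = []
    snps_by_chrom = {
        chrom: grp.sort_values("pos") for chrom, grp in snps.groupby("chrom")
    }
    for cpg_id, cpg in manifest.iterrows():
        chrom_snps = snps_by_chrom.get(cpg["chrom"])
        found = False
        if chrom_snps is not None:
            lo, hi = cpg["pos"] - window, cpg["pos"] + window
            inside = chrom_snps[(chrom_snps["pos"] >= lo) & (chrom_snps["pos"] <= hi)]
            for snp_id, snp in inside.iterrows():
                rows.append(
                    (
                        cpg_id,
                        snp_id,
                        cpg["chrom"],
                        int(cpg["pos"]),
                        int(snp["pos"]),
                        int(snp["pos"] - cpg["pos"]),
                    )
                )
                found = True
        if not found:
            dropped.append(cpg_id)
    pairs = pd.DataFrame(
        rows, columns=["cpg_id", "snp_id", "chrom", "cpg_pos", "snp_pos", "distance"]
    )
    return pairs, dropped
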