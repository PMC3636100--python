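"""Independent-locus reporting: FDR ranking, greedy LD pruning, locus tables.

Significant SNPs are ranked by ascending FDR (ties broken by smaller nominal
p, then chromosome/position) and greedily pruned: a SNP is retained iff its
r² with every higher-ranked retained SNP is at or below the pruning
threshold (default 0.2).  Retained SNPs are grouped into loci by
single-linkage over r² > threshold among all significant SNPs, and loci are
numbered consecutively in genomic order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sumstats import LDTable

DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_R2_THRESHOLD = 0.2


def ld_prune(ranked_snps, ld: LDTable, r2_threshold: float = DEFAULT_R2_THRESHOLD):
    """Greedy LD pruning of a rank-ordered SNP id list.

    Iterates the list in rank order and keeps a SNP iff r² <= threshold with
    every already-kept SNP.  Missing LD pairs count as r² = 0.  Output
    preserves rank order.
    """
    if not 0.0 <= r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in [0, 1]")
    kept: list[str] = []
    kept_set: set[str] = set()
    for snp in ranked_snps:
        neighbors = ld.neighbors(snp)
        if any(r2 > r2_threshold and other in kept_set
               for other, r2 in neighbors.items()):
            continue
        kept.append(snp)
        kept_set.add(snp)
    return kept


def _rank_order(df: pd.DataFrame, fdr_column: str) -> pd.DataFrame:
    """Ascending FDR; ties broken by smaller nominal p, then (chrom, pos)."""
    by = [fdr_column]
    if "P" in df.columns:
        by.append("P")
    if "CHR" in df.columns and "BP" in df.columns:
        by += ["CHR", "BP"]
    return df.sort_values(by=by, kind="mergesort").reset_index(drop=True)


def _connected_components(snps, ld: LDTable, r2_threshold: float) -> dict[str, int]:
    """Single-linkage grouping over r² > threshold among the given SNPs."""
    snp_set = set(snps)
    component: dict[str, int] = {}
    label = 0
    for snp in snps:
        if snp in component:
            continue
        stack = [snp]
        component[snp] = label
        while stack:
            current = stack.pop()
            for other, r2 in ld.neighbors(current).items():
                if r2 > r2_threshold and other in snp_set and other not in component:
                    component[other] = label
                    stack.append(other)
        label += 1
    return component


def _chrom_sort_key(chrom: str):
    try:
        return (0, int(chrom), "")
    except (TypeError, ValueError):
        return (1, 0, str(chrom))


def significant_loci(assignments: pd.DataFrame, ld: LDTable,
                     fdr_column: str = "CONDFDR",
                     fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
                     r2_threshold: float = DEFAULT_R2_THRESHOLD) -> pd.DataFrame:
    """Build an independent-locus table from per-SNP FDR assignments.

    Filters to FDR < threshold, LD-prunes in rank order, groups significant
    SNPs into loci by single-linkage over r² > threshold, and numbers loci
    consecutively in genomic order (falling back to rank order when positions
    are absent).  Rows are the retained (pruned) SNPs; within a locus the
    minimum-FDR SNP is flagged as the representative.  An empty table (no
    significant SNPs) is returned as such, not raised.
    """
    if assignments.empty:
        raise ValueError("no per-SNP FDR assignments supplied")
    sig = assignments.loc[assignments[fdr_column] < fdr_threshold]
    if sig.empty:
        return _empty_locus_table(assignments, fdr_column)

    ranked = _rank_order(sig, fdr_column)
    kept = set(ld_prune(ranked["SNP"].tolist(), ld, r2_threshold))
    component = _connected_components(ranked["SNP"].tolist(), ld, r2_threshold)

    rows = ranked.loc[ranked["SNP"].isin(kept)].copy()
    rows["_component"] = rows["SNP"].map(component)

    # number loci in genomic order of each component's first member
    if "CHR" in rows.columns and "BP" in rows.columns:
        order_key = rows.groupby("_component").apply(
            lambda g: (_chrom_sort_key(g["CHR"].iloc[0]), int(g["BP"].min())),
            include_groups=False,
        )
    else:
        order_key = rows.groupby("_component").apply(
            lambda g: g.index.min(), include_groups=False)
    locus_number = {comp: idx + 1
                    for idx, comp in enumerate(order_key.sort_values().index)}
    rows["LOCUS"] = rows["_component"].map(locus_number)

    rows["REPRESENTATIVE"] = False
    rep_idx = rows.groupby("LOCUS")[fdr_column].idxmin()
    rows.loc[rep_idx, "REPRESENTATIVE"] = True

    rows = rows.drop(columns="_component")
    rows = rows.sort_values(["LOCUS", fdr_column], kind="mergesort")
    return rows.reset_index(drop=True)


def conjunction_loci(assignments: pd.DataFrame, ld: LDTable,
                     fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
                     r2_threshold: float = DEFAULT_R2_THRESHOLD) -> pd.DataFrame:
    """Locus table on the conjunction FDR (max of the two conditional FDRs).

    ``assignments`` must carry ``CONDFDR_12`` and ``CONDFDR_21`` (as produced
    by :func:`condfdr.conditional.assign_conjunction`); a ``CONJFDR`` column
    is (re)computed by the max rule.  Rows retain both phenotypes' z-scores
    when present — opposite-sign effects are reported, not dropped.
    """
    out = assignments.copy()
    out["CONJFDR"] = np.maximum(out["CONDFDR_12"].to_numpy(dtype=float),
                                out["CONDFDR_21"].to_numpy(dtype=float))
    return significant_loci(out, ld, fdr_column="CONJFDR",
                            fdr_threshold=fdr_threshold,
                            r2_threshold=r2_threshold)


def count_loci(locus_table: pd.DataFrame) -> int:
    """Number of independent loci in a locus table."""
    if locus_table.empty:
        return 0
    return int(locus_table["LOCUS"].nunique())


def _empty_locus_table(assignments: pd.DataFrame, fdr_column: str) -> pd.DataFrame:
    cols = list(assignments.columns) + ["LOCUS", "REPRESENTATIVE"]
    return pd.DataFrame(columns=cols)
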