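"""Reading, validating and converting GWAS summary statistics.

Summary statistics are carried as pandas DataFrames with canonical upper-case
columns ``SNP, CHR, BP, A1, A2, P, Z, CATEGORY``.  Only ``SNP`` and ``P`` are
required; ``Z`` is a signed two-sided normal score (sign = direction of effect
of A1) and ``CATEGORY`` is one of ``genic``/``intergenic``/``unknown``.
Positions are 1-based; BED intervals are 0-based half-open, following the two
formats' own conventions.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: Default floor applied to p-values of 0 (or underflow); keeps -log10(p) finite.
P_FLOOR = 1e-300

CANONICAL_COLUMNS = ("SNP", "CHR", "BP", "A1", "A2", "P", "Z", "CATEGORY")
CATEGORIES = ("genic", "intergenic", "unknown")


# ---------------------------------------------------------------------------
# p <-> z conversion


def p_to_z(p, direction=None):
    """Convert two-sided p-values to z-scores.

    |z| is the standard-normal upper quantile of p/2.  ``direction`` may be a
    scalar or array of signs (+1/-1); if absent the magnitude is returned.

    Raises ``ValueError`` for p outside (0, 1].
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p_arr)) or np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    z = norm.isf(p_arr / 2.0)
    # isf(0.5) is ~1e-17 rather than 0; p == 1 must map to z == 0 exactly
    z = np.where(p_arr == 1.0, 0.0, z)
    if direction is not None:
        z = z * np.sign(direction)
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(z)
    return z


def z_to_p(z):
    """Two-sided p-value of a z-score: p = 2(1 - Phi(|z|)).

    Raises ``ValueError`` for non-finite input.  Round-trips :func:`p_to_z`
    to ~1e-10 relative precision for p >= 1e-300.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z_arr)):
        raise ValueError("z-scores must be finite")
    p = 2.0 * norm.sf(np.abs(z_arr))
    if np.isscalar(z) or np.ndim(z) == 0:
        return float(p)
    return p


# ---------------------------------------------------------------------------
# Summary-statistic I/O


def read_sumstats(path, column_map: Mapping[str, str] | None = None,
                  p_floor: float = P_FLOOR) -> pd.DataFrame:
    """Read a delimited summary-statistics file into canonical form.

    ``column_map`` maps canonical names to the file's actual header names,
    e.g. ``{"P": "pval"}``.  Rows with missing/unparseable p are dropped and
    counted in the log; p is clipped into (0, 1] with floor ``p_floor``.
    """
    try:
        raw = pd.read_csv(path, sep=r"\s+")
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty summary-statistics file: {path}") from None
    if raw.empty:
        raise ValueError(f"empty summary-statistics file: {path}")

    column_map = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        actual = column_map.get(canon, canon)
        if actual in raw.columns:
            rename[actual] = canon
    df = raw.rename(columns=rename)

    for required in ("SNP", "P"):
        if required not in df.columns:
            raise KeyError(
                f"required column {required!r} not found in {path} "
                f"(available: {list(raw.columns)}; use column_map to map it)"
            )
    return validate_sumstats(df, p_floor=p_floor)


def validate_sumstats(df: pd.DataFrame, p_floor: float = P_FLOOR) -> pd.DataFrame:
    """Validate and normalize a summary-statistics frame in place rules:

    - drop rows with unparseable/missing p (logged),
    - clip p into (0, 1] (floor at ``p_floor``, logged),
    - drop duplicate SNP ids keeping the first occurrence (logged),
    - check Z/P consistency to 0.5% relative tolerance when Z is present.
    """
    df = df.copy()
    df["SNP"] = df["SNP"].astype(str)
    df["P"] = pd.to_numeric(df["P"], errors="coerce")
    n_bad = int(df["P"].isna().sum())
    if n_bad:
        logger.warning("dropping %d rows with missing/unparseable p", n_bad)
        df = df.dropna(subset=["P"])
    if df.empty:
        raise ValueError("no rows with a valid p-value")

    n_clip = int((df["P"] <= 0).sum() + (df["P"] > 1).sum())
    if n_clip:
        logger.warning("clipping %d p-values into (0, 1] (floor %g)", n_clip, p_floor)
    df["P"] = df["P"].clip(lower=p_floor, upper=1.0)

    n_dup = int(df["SNP"].duplicated().sum())
    if n_dup:
        logger.warning("dropping %d duplicate SNP ids (keeping first)", n_dup)
        df = df.drop_duplicates(subset="SNP", keep="first")

    if "BP" in df.columns:
        df["BP"] = pd.to_numeric(df["BP"], errors="coerce").astype("Int64")
    if "CHR" in df.columns:
        df["CHR"] = df["CHR"].astype(str)
    if "CATEGORY" in df.columns:
        df["CATEGORY"] = df["CATEGORY"].where(
            df["CATEGORY"].isin(CATEGORIES), "unknown"
        )
    else:
        df["CATEGORY"] = "unknown"

    if "Z" in df.columns:
        df["Z"] = pd.to_numeric(df["Z"], errors="coerce")
        have_z = df["Z"].notna()
        if have_z.any():
            implied = z_to_p(df.loc[have_z, "Z"].to_numpy())
            rel = np.abs(implied - df.loc[have_z, "P"].to_numpy()) / df.loc[
                have_z, "P"
            ].to_numpy()
            n_inconsistent = int((rel > 0.005).sum())
            if n_inconsistent:
                logger.warning(
                    "%d rows where two_sided_p(|Z|) deviates from P by >0.5%%",
                    n_inconsistent,
                )
    return df.reset_index(drop=True)


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write canonical columns (those present) as a tab-delimited file."""
    cols = [c for c in CANONICAL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def join_pair(primary: pd.DataFrame, secondary: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two phenotypes' summary statistics by SNP id.

    SNPs present in only one table are dropped (counts logged).  When both
    tables carry alleles, disagreeing A1/A2 pairs are logged as a warning but
    retained — the join is by SNP id only, without allele harmonization.
    Columns from the secondary table get a ``_2`` suffix.
    """
    merged = primary.merge(secondary, on="SNP", how="inner", suffixes=("", "_2"))
    if merged.empty:
        raise ValueError("no SNPs shared between the two summary-statistic sets")
    logger.info(
        "joined %d SNPs (dropped %d primary-only, %d secondary-only)",
        len(merged), len(primary) - len(merged), len(secondary) - len(merged),
    )
    if {"A1", "A2", "A1_2", "A2_2"} <= set(merged.columns):
        mismatch = (merged["A1"].str.upper() != merged["A1_2"].str.upper()) | (
            merged["A2"].str.upper() != merged["A2_2"].str.upper()
        )
        n_mismatch = int(mismatch.fillna(False).sum())
        if n_mismatch:
            logger.warning(
                "%d joined SNPs have disagreeing alleles between phenotypes",
                n_mismatch,
            )
    return merged


# ---------------------------------------------------------------------------
# LD tables


class LDTable:
    """Symmetric pairwise r² lookup; absent pairs have r² = 0."""

    def __init__(self) -> None:
        self._adj: dict[str, dict[str, float]] = {}
        self._n_pairs = 0

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, float]]) -> "LDTable":
        table = cls()
        for a, b, r2 in pairs:
            table.add(str(a), str(b), float(r2))
        return table

    def add(self, a: str, b: str, r2: float) -> None:
        if a == b:
            return  # self-pairs carry no information
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 must lie in [0, 1], got {r2}")
        current = self._adj.get(a, {}).get(b)
        if current is None:
            self._n_pairs += 1
            self._adj.setdefault(a, {})[b] = r2
            self._adj.setdefault(b, {})[a] = r2
        elif r2 > current:  # duplicate pairs keep the maximum
            self._adj[a][b] = r2
            self._adj[b][a] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbors(self, a: str) -> dict[str, float]:
        return self._adj.get(a, {})

    def __len__(self) -> int:
        return self._n_pairs


def read_ld(path) -> LDTable:
    """Read a PLINK ``.ld``-style text file (columns SNP_A, SNP_B, R2).

    Extra columns are ignored; duplicate pairs keep the maximum r²; self-pairs
    are skipped.  R2 outside [0, 1] raises with the offending line number.
    """
    table = LDTable()
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except pd.errors.EmptyDataError:
        return table
    if df.empty:
        return table
    for col in ("SNP_A", "SNP_B", "R2"):
        if col not in df.columns:
            raise KeyError(f"LD file {path} lacks required column {col!r}")
    r2 = pd.to_numeric(df["R2"], errors="coerce")
    bad = r2.isna() | (r2 < 0) | (r2 > 1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(f"invalid R2 value at line {line} of {path}")
    for a, b, val in zip(df["SNP_A"].astype(str), df["SNP_B"].astype(str), r2):
        table.add(a, b, float(val))
    return table


# ---------------------------------------------------------------------------
# Genic / intergenic annotation


def read_bed(path) -> list[tuple[str, int, int]]:
    """Parse a BED3 file into (chrom, start, end) tuples (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"malformed BED line {lineno}: {line!r}") from None
            intervals.append((str(fields[0]), start, end))
    return intervals


def annotate_category(stats: pd.DataFrame,
                      regions: Sequence[tuple[str, int, int]]) -> pd.DataFrame:
    """Label each SNP genic/intergenic against 0-based half-open intervals.

    A SNP at 1-based position x is genic iff x-1 falls inside an interval on
    its chromosome; otherwise intergenic.  Deterministic and independent of
    interval order.
    """
    if "BP" not in stats.columns or "CHR" not in stats.columns:
        raise KeyError("annotation requires CHR and BP columns")
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in regions:
        if end > start:
            trees.setdefault(str(chrom), IntervalTree()).addi(start, end)
    out = stats.copy()
    chroms = out["CHR"].to_numpy()
    pos0 = out["BP"].to_numpy(dtype=np.int64) - 1
    genic = np.fromiter(
        (bool(trees[c][p]) if c in trees else False for c, p in zip(chroms, pos0)),
        dtype=bool, count=len(out),
    )
    out["CATEGORY"] = np.where(genic, "genic", "intergenic")
    return out
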