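"""Genomic inflation control from intergenic SNPs.

The inflation factor lambda_GC is the median squared z-score of a set of
(approximately null) SNPs divided by the median of a chi-square distribution
with one degree of freedom.  Intergenic SNPs are used as the reference set
because they are relatively depleted of true associations; if no annotation
is available the estimate falls back to all SNPs with a warning.

Correction divides each squared statistic by lambda (z <- z / sqrt(lambda))
and recomputes p from the corrected z; this makes the correction idempotent.
Deflation (lambda < 1) is allowed and not floored at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from . import sumstats

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with 1 df (analytic reference).
CHI2_1_MEDIAN = float(chi2.median(1))


@dataclass(frozen=True)
class GcResult:
    """Inflation estimate: lambda_GC and the SNP count it was computed from."""

    lambda_gc: float
    n_snps: int
    reference_median: float = CHI2_1_MEDIAN
    used_fallback: bool = False  # True when estimated from all SNPs


def lambda_gc(z_values, min_n: int = 100) -> GcResult:
    """Estimate lambda_GC = median(z^2) / median(chi^2_1) from z-scores.

    ``z_values`` should be restricted to the intergenic reference set.
    Raises ``ValueError`` when fewer than ``min_n`` values are supplied,
    advising fallback to all SNPs.
    """
    z = np.asarray(z_values, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < min_n:
        raise ValueError(
            f"only {z.size} z-values available (< {min_n}); consider falling "
            "back to all SNPs for genomic control"
        )
    lam = float(np.median(z**2) / CHI2_1_MEDIAN)
    return GcResult(lambda_gc=lam, n_snps=int(z.size))


def lambda_gc_from_sumstats(stats, min_n: int = 100) -> GcResult:
    """Estimate lambda_GC from a summary-statistics frame.

    Uses intergenic SNPs when the CATEGORY annotation identifies any,
    otherwise all SNPs (flagged ``used_fallback``).  z magnitudes are derived
    from p where no Z column is present.
    """
    intergenic = stats[stats["CATEGORY"] == "intergenic"]
    fallback = len(intergenic) < min_n
    subset = stats if fallback else intergenic
    if fallback:
        logger.warning(
            "only %d intergenic SNPs; estimating lambda_GC from all %d SNPs",
            len(intergenic), len(stats),
        )
    z = _z_magnitudes(subset)
    result = lambda_gc(z, min_n=min_n)
    return GcResult(result.lambda_gc, result.n_snps, used_fallback=fallback)


def apply_gc(stats, gc: GcResult):
    """Rescale test statistics by lambda_GC: z^2 <- z^2 / lambda.

    p is recomputed from the corrected z; the original p is retained in a
    ``P_UNCORRECTED`` column (and Z in ``Z_UNCORRECTED`` when present).
    """
    if gc.lambda_gc <= 0:
        raise ValueError(f"lambda_GC must be positive, got {gc.lambda_gc}")
    out = stats.copy()
    out["P_UNCORRECTED"] = out["P"]
    scale = 1.0 / np.sqrt(gc.lambda_gc)
    if "Z" in out.columns and out["Z"].notna().all():
        out["Z_UNCORRECTED"] = out["Z"]
        out["Z"] = out["Z"] * scale
        out["P"] = sumstats.z_to_p(out["Z"].to_numpy())
    else:
        z_mag = sumstats.p_to_z(out["P"].to_numpy()) * scale
        out["P"] = sumstats.z_to_p(z_mag)
        if "Z" in out.columns:
            out["Z_UNCORRECTED"] = out["Z"]
            out["Z"] = np.abs(z_mag) * np.sign(out["Z"].fillna(0.0))
    out["P"] = out["P"].clip(lower=sumstats.P_FLOOR, upper=1.0)
    return out


def _z_magnitudes(stats) -> np.ndarray:
    if "Z" in stats.columns and stats["Z"].notna().all():
        return np.abs(stats["Z"].to_numpy(dtype=float))
    return sumstats.p_to_z(stats["P"].to_numpy())
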