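"""Conditional and conjunction false discovery rate estimation.

The method treats one phenotype's p-values as the primary association signal
and a second, genetically related phenotype's p-values as an auxiliary
conditioning variable.  For a p-value cutoff p and a SNP subset with
empirical cdf q = N_p / N, the conservative Empirical Bayes FDR estimate is
p / q (the null proportion pi0 is set to unity, which biases the estimate
upward).  Conditioning on successively stricter thresholds for the secondary
phenotype enriches the subset for true associations, raising q at fixed p and
thereby lowering the estimated FDR.

Per-SNP conditional FDR values are assigned by building estimates on a grid
of (-log10 p1, -log10 p2) thresholds and interpolating bilinearly in log10
FDR.  The conjunction FDR — evidence a SNP is non-null in *both* phenotypes —
is the maximum of the two directional conditional FDRs, itself a conservative
estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import join_pair

logger = logging.getLogger(__name__)

DEFAULT_GRID = np.round(np.arange(0.0, 10.0 + 1e-9, 0.1), 10)
DEFAULT_MIN_SUBSET = 100


# ---------------------------------------------------------------------------
# Empirical cdf


class EmpiricalCdf:
    """Right-continuous empirical cdf q(p) = #{p_i <= p} / n (ties inclusive)."""

    def __init__(self, pvals) -> None:
        p = np.asarray(pvals, dtype=float)
        if p.size == 0:
            raise ValueError("cannot build an empirical cdf from no p-values")
        self.sorted_p = np.sort(p)
        self.n = int(p.size)

    def evaluate(self, p):
        """Fraction of stored p-values <= p; vectorized."""
        q = np.searchsorted(self.sorted_p, np.asarray(p, dtype=float),
                            side="right") / self.n
        if np.ndim(p) == 0:
            return float(q)
        return q

    __call__ = evaluate


def ecdf(pvals) -> EmpiricalCdf:
    """Build the empirical cdf estimator over a p-value collection."""
    return EmpiricalCdf(pvals)


# ---------------------------------------------------------------------------
# Point estimates


def fdr_estimate(p, q):
    """Conservative Empirical Bayes FDR estimate min(p/q, 1).

    ``q`` is the empirical cdf of the SNP subset evaluated at ``p``.  Cells
    with q = 0 (p below the subset's smallest p-value) return 1, the
    conservative default.
    """
    p_arr = np.asarray(p, dtype=float)
    q_arr = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out = np.where(q_arr > 0, np.minimum(p_arr / np.maximum(q_arr, 1e-320), 1.0), 1.0)
    if np.any(q_arr <= 0):
        logger.warning("FDR requested at p below the subset minimum (q = 0); "
                       "returning 1 (conservative)")
    if np.ndim(p) == 0 and np.ndim(q) == 0:
        return float(out)
    return out


def tdr_estimate(p, q):
    """Conservative true discovery rate estimate 1 - min(p/q, 1)."""
    return 1.0 - fdr_estimate(p, q)


def conjunction_fdr(fdr_1_given_2, fdr_2_given_1):
    """Conjunction FDR: the maximum of the two directional conditional FDRs.

    A conservative estimate of the posterior probability that the SNP is null
    for at least one of the two phenotypes.
    """
    a = np.asarray(fdr_1_given_2, dtype=float)
    b = np.asarray(fdr_2_given_1, dtype=float)
    for name, arr in (("fdr_1_given_2", a), ("fdr_2_given_1", b)):
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
            raise ValueError(f"{name} must lie in (0, 1]")
    out = np.maximum(a, b)
    if np.ndim(fdr_1_given_2) == 0 and np.ndim(fdr_2_given_1) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Conditioning


def conditional_subset(primary: pd.DataFrame, secondary: pd.DataFrame,
                       threshold: float) -> pd.DataFrame:
    """Primary-phenotype records whose secondary p satisfies -log10(p2) >= t.

    Subsets are cumulative (nested), not disjoint strata; the threshold is
    inclusive.  Phenotypes are joined by SNP id.
    """
    joined = join_pair(primary, secondary)
    keep = joined["P_2"] <= 10.0 ** (-threshold) * (1 + 1e-12)
    return joined.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Two-dimensional look-up table


@dataclass
class CondFdrTable:
    """Grid of conditional FDR estimates over (-log10 p1, -log10 p2).

    ``values[i, j]`` is the conservative FDR of the primary phenotype at
    p1 = 10**-grid1[i] within the subset of SNPs with -log10 p2 >= grid2[j].
    ``inherited[:, j]`` flags columns whose conditioning subset was smaller
    than ``min_subset_size`` and was therefore filled from the nearest looser
    threshold; ``q_zero`` flags cells where p1 fell below the subset minimum
    (value 1, conservative).
    """

    grid1: np.ndarray
    grid2: np.ndarray
    values: np.ndarray
    subset_sizes: np.ndarray
    inherited: np.ndarray
    q_zero: np.ndarray
    min_subset_size: int = DEFAULT_MIN_SUBSET
    pi0_assumption: float = field(default=1.0)

    def to_frame(self) -> pd.DataFrame:
        """Serialize as a DataFrame with grid headers."""
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.grid1, name="neglog10_p1"),
            columns=pd.Index(self.grid2, name="neglog10_p2"),
        )


def build_lookup(primary: pd.DataFrame, secondary: pd.DataFrame,
                 grid1=DEFAULT_GRID, grid2=DEFAULT_GRID,
                 min_subset_size: int = DEFAULT_MIN_SUBSET) -> CondFdrTable:
    """Build the two-dimensional conditional FDR look-up table.

    For every conditioning threshold grid2[j], takes the subset of joined
    SNPs with -log10 p2 >= grid2[j] and evaluates min(p1/q, 1) on the grid of
    primary p-value thresholds.  Columns whose subset falls below
    ``min_subset_size`` inherit the nearest looser populated column.
    """
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    if grid1.size < 2 or np.any(np.diff(grid1) <= 0):
        raise ValueError("grid1 must be strictly increasing with >= 2 nodes")
    if grid2.size < 2 or np.any(np.diff(grid2) <= 0):
        raise ValueError("grid2 must be strictly increasing with >= 2 nodes")

    joined = join_pair(primary, secondary)
    p1 = joined["P"].to_numpy(dtype=float)
    neglog_p2 = -np.log10(joined["P_2"].to_numpy(dtype=float))
    p1_thresholds = 10.0 ** (-grid1)

    n1, n2 = grid1.size, grid2.size
    values = np.ones((n1, n2))
    q_zero = np.zeros((n1, n2), dtype=bool)
    inherited = np.zeros(n2, dtype=bool)
    subset_sizes = np.zeros(n2, dtype=int)

    last_good: int | None = None
    tol = 1e-9  # inclusive threshold comparison robust to -log10 rounding
    for j, t2 in enumerate(grid2):
        mask = neglog_p2 >= t2 - tol
        subset_sizes[j] = int(mask.sum())
        if subset_sizes[j] < min_subset_size:
            inherited[j] = True
            continue
        sub_sorted = np.sort(p1[mask])
        q = np.searchsorted(sub_sorted, p1_thresholds, side="right") / subset_sizes[j]
        ratio = np.divide(p1_thresholds, q, out=np.ones_like(q), where=q > 0)
        col = np.minimum(ratio, 1.0)
        values[:, j] = col
        q_zero[:, j] = q == 0
        last_good = j

    if last_good is None:
        raise ValueError(
            "every conditioning cell has fewer SNPs than min_subset_size "
            f"({min_subset_size}); loosen the grid or lower the floor"
        )
    # under-populated columns inherit the nearest looser (smaller-threshold)
    # populated column; a leading run of under-populated columns cannot occur
    # when threshold 0 is populated, but guard by nearest-any fallback
    populated = np.flatnonzero(~inherited)
    for j in np.flatnonzero(inherited):
        looser = populated[populated < j]
        src = looser[-1] if looser.size else populated[0]
        values[:, j] = values[:, src]
        q_zero[:, j] = q_zero[:, src]

    return CondFdrTable(grid1=grid1, grid2=grid2, values=values,
                        subset_sizes=subset_sizes, inherited=inherited,
                        q_zero=q_zero, min_subset_size=min_subset_size)


def lookup_fdr(table: CondFdrTable, p1, p2):
    """Interpolate the look-up table at (p1, p2); vectorized.

    Bilinear in (-log10 p1, -log10 p2) on log10(FDR); queries outside the
    grid are clamped to the boundary.  Exact (bit-identical) at grid nodes.
    """
    scalar = np.ndim(p1) == 0 and np.ndim(p2) == 0
    x = np.clip(-np.log10(np.atleast_1d(np.asarray(p1, dtype=float))),
                table.grid1[0], table.grid1[-1])
    y = np.clip(-np.log10(np.atleast_1d(np.asarray(p2, dtype=float))),
                table.grid2[0], table.grid2[-1])
    # -log10 of a node p-value can miss the node by a few ulp; snap so the
    # exact-at-nodes contract survives the p -> -log10 p round trip
    x = _snap_to_grid(x, table.grid1)
    y = _snap_to_grid(y, table.grid2)
    logv = np.log10(table.values)

    i = np.clip(np.searchsorted(table.grid1, x, side="right") - 1, 0,
                table.grid1.size - 2)
    j = np.clip(np.searchsorted(table.grid2, y, side="right") - 1, 0,
                table.grid2.size - 2)
    tx = (x - table.grid1[i]) / (table.grid1[i + 1] - table.grid1[i])
    ty = (y - table.grid2[j]) / (table.grid2[j + 1] - table.grid2[j])

    interp = (
        (1 - tx) * (1 - ty) * logv[i, j]
        + tx * (1 - ty) * logv[i + 1, j]
        + (1 - tx) * ty * logv[i, j + 1]
        + tx * ty * logv[i + 1, j + 1]
    )
    out = 10.0 ** interp
    # snap exact node queries to the stored value, bit-identically
    at_node = np.isin(tx, (0.0, 1.0)) & np.isin(ty, (0.0, 1.0))
    if np.any(at_node):
        ii = (i + (tx == 1.0))[at_node]
        jj = (j + (ty == 1.0))[at_node]
        out[at_node] = table.values[ii, jj]
    if scalar:
        return float(out[0])
    return out


def _snap_to_grid(v: np.ndarray, grid: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    idx = np.clip(np.searchsorted(grid, v), 0, grid.size - 1)
    for cand in (idx, np.maximum(idx - 1, 0)):
        close = np.abs(v - grid[cand]) < tol
        v = np.where(close, grid[cand], v)
    return v


# ---------------------------------------------------------------------------
# Per-SNP assignment


def assign_condfdr(primary: pd.DataFrame, secondary: pd.DataFrame,
                   grid1=DEFAULT_GRID, grid2=DEFAULT_GRID,
                   min_subset_size: int = DEFAULT_MIN_SUBSET) -> pd.DataFrame:
    """Assign each joined SNP its conditional FDR (primary given secondary).

    Returns the joined frame with a ``CONDFDR`` column obtained by look-up
    table interpolation at the SNP's own (p1, p2).
    """
    table = build_lookup(primary, secondary, grid1=grid1, grid2=grid2,
                         min_subset_size=min_subset_size)
    joined = join_pair(primary, secondary)
    joined["CONDFDR"] = lookup_fdr(table, joined["P"].to_numpy(),
                                   joined["P_2"].to_numpy())
    return joined


def assign_conjunction(primary: pd.DataFrame, secondary: pd.DataFrame,
                       grid1=DEFAULT_GRID, grid2=DEFAULT_GRID,
                       min_subset_size: int = DEFAULT_MIN_SUBSET) -> pd.DataFrame:
    """Assign per-SNP conditional FDRs in both directions plus conjunction FDR.

    Returns the joined frame with ``CONDFDR_12`` (primary given secondary),
    ``CONDFDR_21`` (secondary given primary) and ``CONJFDR`` (max rule).
    """
    fwd = assign_condfdr(primary, secondary, grid1, grid2, min_subset_size)
    rev = assign_condfdr(secondary, primary, grid1, grid2, min_subset_size)
    out = fwd.rename(columns={"CONDFDR": "CONDFDR_12"})
    out = out.merge(rev[["SNP", "CONDFDR"]].rename(columns={"CONDFDR": "CONDFDR_21"}),
                    on="SNP", how="inner")
    out["CONJFDR"] = conjunction_fdr(out["CONDFDR_12"].to_numpy(),
                                     out["CONDFDR_21"].to_numpy())
    return out
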