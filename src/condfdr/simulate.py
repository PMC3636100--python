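"""Synthetic paired GWAS summary statistics with known ground truth.

SNPs are assigned to the four components of the bivariate mixture (null for
both traits, non-null for one, non-null for both) and their z-scores drawn
from the corresponding zero-mean Gaussians; two-sided p-values follow.
Optional features emulate the structure the conditional FDR pipeline must
handle on real data: genomic inflation (z scaled by sqrt(lambda) per trait),
genic/intergenic labels, and LD blocks in which the lead SNP's z-score is
echoed to its block-mates with noise (z_mate = sqrt(r2) z_lead +
sqrt(1-r2) eps), alongside a matching pairwise r² table.

The default scenario is highly polygenic with pleiotropic overlap:
pi = (0.97, 0.009, 0.009, 0.012), unit null variance, effect variance 2.0
per trait (so that roughly 1 in 10^4 SNPs passes local fdr <= 0.05
unconditionally), and uncorrelated pleiotropic effects — shared
non-nullness, not effect correlation, drives the enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import P_FLOOR, LDTable, z_to_p

DEFAULT_PI = (0.97, 0.009, 0.009, 0.012)


@dataclass
class SimulationParams:
    """Generating parameters of the four-groups simulation scenario."""

    n_snps: int = 100_000
    pi: tuple[float, float, float, float] = DEFAULT_PI
    sigma0_sq: tuple[float, float] = (1.0, 1.0)
    sigma1_sq: tuple[float, float] = (2.0, 2.0)
    rho3: float = 0.0
    inflation: tuple[float, float] = (1.0, 1.0)
    ld_block_size: int = 1
    ld_r2: float = 0.8
    genic_fraction: float = 0.5
    n_chromosomes: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.size != 4 or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must be four non-negative proportions summing to 1")
        if min(self.sigma0_sq) <= 0 or min(self.sigma1_sq) < 0:
            raise ValueError("variances must be positive (effect variance >= 0)")
        if not -1.0 < self.rho3 < 1.0:
            raise ValueError("rho3 must lie in (-1, 1)")
        if min(self.inflation) <= 0:
            raise ValueError("inflation factors must be positive")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


def simulate_pair(params: SimulationParams):
    """Draw a pair of summary-statistic tables plus per-SNP truth labels.

    Returns ``(trait1, trait2, truth)`` DataFrames sharing SNP ids; ``truth``
    carries the mixture component and per-trait non-null indicators.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_snps
    s0 = np.sqrt(np.asarray(params.sigma0_sq, dtype=float))
    t = np.asarray(params.sigma1_sq, dtype=float)

    component = rng.choice(4, size=n, p=np.asarray(params.pi, dtype=float))
    noise = rng.standard_normal((n, 2)) * s0

    effects = np.zeros((n, 2))
    c1 = component == 1
    c2 = component == 2
    c3 = component == 3
    effects[c1, 0] = rng.standard_normal(int(c1.sum())) * np.sqrt(t[0])
    effects[c2, 1] = rng.standard_normal(int(c2.sum())) * np.sqrt(t[1])
    if c3.any():
        cov3 = np.array([
            [t[0], params.rho3 * np.sqrt(t[0] * t[1])],
            [params.rho3 * np.sqrt(t[0] * t[1]), t[1]],
        ])
        chol = np.linalg.cholesky(cov3 + 1e-12 * np.eye(2))
        effects[c3] = rng.standard_normal((int(c3.sum()), 2)) @ chol.T

    z = noise + effects

    if params.ld_block_size > 1:
        z, component = _echo_ld_blocks(z, component, params, rng, s0)

    z *= np.sqrt(np.asarray(params.inflation, dtype=float))

    snp = np.array([f"snp{i:07d}" for i in range(n)])
    chrom = (np.arange(n) % params.n_chromosomes + 1).astype(str)
    bp = np.arange(n) // params.n_chromosomes * 10_000 + 1
    category = np.where(rng.random(n) < params.genic_fraction, "genic", "intergenic")

    frames = []
    for trait in range(2):
        p = np.clip(z_to_p(z[:, trait]), P_FLOOR, 1.0)
        frames.append(pd.DataFrame({
            "SNP": snp, "CHR": chrom, "BP": bp,
            "A1": "A", "A2": "G",
            "P": p, "Z": z[:, trait], "CATEGORY": category,
        }))
    truth = pd.DataFrame({
        "SNP": snp,
        "COMPONENT": component,
        "NONNULL_1": np.isin(component, (1, 3)),
        "NONNULL_2": np.isin(component, (2, 3)),
    })
    return frames[0], frames[1], truth


def _echo_ld_blocks(z, component, params, rng, s0):
    """Copy each block lead's z to block-mates, scaled by sqrt(r2) plus noise.

    Block-mates inherit the lead's component label (they tag the same
    underlying signal).
    """
    n = z.shape[0]
    block = np.arange(n) // params.ld_block_size
    lead = block * params.ld_block_size
    r = np.sqrt(params.ld_r2)
    eps = rng.standard_normal((n, 2)) * s0
    z_out = r * z[lead] + np.sqrt(1 - params.ld_r2) * eps
    is_lead = np.arange(n) == lead
    z_out[is_lead] = z[is_lead]
    return z_out, component[lead]


def simulate_ld(params: SimulationParams) -> LDTable:
    """Pairwise r² table matching the simulated LD blocks.

    Consecutive SNPs are grouped into blocks of ``ld_block_size``; all
    within-block pairs get the stated r², across-block pairs are absent
    (r² = 0).  Block size 1 yields an empty table.
    """
    table = LDTable()
    size = params.ld_block_size
    if size <= 1:
        return table
    ids = [f"snp{i:07d}" for i in range(params.n_snps)]
    for start in range(0, params.n_snps, size):
        members = ids[start:start + size]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                table.add(members[i], members[j], params.ld_r2)
    return table


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the truth-label table as tab-delimited text."""
    truth.to_csv(path, sep="\t", index=False)
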