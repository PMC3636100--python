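import numpy as np
import pandas as pd
import pytest

import condfdr as cf


@pytest.fixture(scope="session")
def default_sim():
    """Default pleiotropic scenario at moderate size (shared across tests)."""
    params = cf.SimulationParams(n_snps=50_000, seed=123)
    t1, t2, truth = cf.simulate_pair(params)
    return params, t1, t2, truth


@pytest.fixture(scope="session")
def null_sim():
    """Pure-null paired scenario: no non-null SNPs in either trait."""
    params = cf.SimulationParams(n_snps=50_000, pi=(1.0, 0.0, 0.0, 0.0), seed=7)
    t1, t2, truth = cf.simulate_pair(params)
    return params, t1, t2, truth


@pytest.fixture()
def toy_sumstats(tmp_path):
    """Write a 3-row summary-statistics file and return its path."""
    path = tmp_path / "toy.tsv"
    pd.DataFrame({
        "SNP": ["rs1", "rs2", "rs3"],
        "CHR": ["1", "1", "2"],
        "BP": [100, 200, 300],
        "P": [0.01, 0.5, 0.9],
    }).to_csv(path, sep="\t", index=False)
    return path


def make_sumstats(pvals, start=0, chrom="1", z=None):
    """Minimal canonical frame from a p-value vector."""
    n = len(pvals)
    df = pd.DataFrame({
        "SNP": [f"s{start + i}" for i in range(n)],
        "CHR": chrom,
        "BP": np.arange(start, start + n) * 10 + 1,
        "P": np.asarray(pvals, dtype=float),
        "CATEGORY": "unknown",
    })
    if z is not None:
        df["Z"] = np.asarray(z, dtype=float)
    return df
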