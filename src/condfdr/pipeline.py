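"""End-to-end pipeline: simulate/load -> genomic control -> conditional FDR
-> loci -> mixture fits -> plots, driven by a YAML config.

Every output table starts with provenance header lines (package version,
seed, config echo) as ``#``-prefixed comments, so a run can be reproduced
from its own outputs.  Deterministic stages are bit-identical across reruns
with the same config.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, conditional, genomic_control, loci, mixture, simulate, viz
from . import sumstats as ss

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {"n_snps": 100_000},
    "gc": {"min_intergenic": 100},
    "condfdr": {"grid_step": 0.1, "grid_max": 10.0, "min_cell": 100},
    "loci": {"fdr": 0.05, "r2": 0.2},
    "mixfit": {"enabled": True, "restarts": 5},
    "plot": {"enabled": True},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def _provenance_header(config: dict, stage: str) -> str:
    lines = [f"# condfdr v{__version__} stage={stage} seed={config.get('seed')}"]
    lines += [f"# config.{k}={v!r}" for k, v in sorted(config.items())
              if k not in ("trait1", "trait2")]
    return "\n".join(lines) + "\n"


def _write_table(df: pd.DataFrame, path: Path, config: dict, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(config, stage))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: dict | str | Path, out_dir) -> Path:
    """Run the staged analysis; returns the output directory.

    ``config`` is a dict or a YAML file path.  On a stage failure the error
    names the stage, partial outputs are retained, and a ``FAILED`` marker
    file records the failing stage.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # --- inputs: simulate or load -----------------------------------
        stage = "simulate"
        if "trait1" in config and "trait2" in config:
            t1 = ss.read_sumstats(config["trait1"],
                                  column_map=config.get("column_map"))
            t2 = ss.read_sumstats(config["trait2"],
                                  column_map=config.get("column_map"))
            ld = (ss.read_ld(config["ld"]) if config.get("ld")
                  else ss.LDTable())
            truth = None
        else:
            sim_cfg = dict(config.get("simulate") or {})
            params = simulate.SimulationParams(
                seed=int(config.get("seed", 0)), **sim_cfg)
            t1, t2, truth = simulate.simulate_pair(params)
            ld = simulate.simulate_ld(params)
            _write_table(t1, out / "trait1.tsv", config, stage)
            _write_table(t2, out / "trait2.tsv", config, stage)
            _write_table(truth, out / "truth.tsv", config, stage)

        # --- genomic control --------------------------------------------
        stage = "gc"
        gc_cfg = config.get("gc") or {}
        min_n = int(gc_cfg.get("min_intergenic", 100))
        results = {}
        corrected = []
        for name, t in (("trait1", t1), ("trait2", t2)):
            est = genomic_control.lambda_gc_from_sumstats(t, min_n=min_n)
            logger.info("%s: lambda_GC = %.4f from %d SNPs%s", name,
                        est.lambda_gc, est.n_snps,
                        " (all-SNP fallback)" if est.used_fallback else "")
            results[name] = est
            corrected.append(genomic_control.apply_gc(t, est))
        t1c, t2c = corrected
        pd.DataFrame({
            "trait": ["trait1", "trait2"],
            "lambda_gc": [results["trait1"].lambda_gc, results["trait2"].lambda_gc],
            "n_snps": [results["trait1"].n_snps, results["trait2"].n_snps],
        }).pipe(_write_table, out / "lambda_gc.tsv", config, stage)

        # --- conditional / conjunction FDR ------------------------------
        stage = "condfdr"
        cf = config.get("condfdr") or {}
        import numpy as np
        grid = np.round(np.arange(0.0, float(cf.get("grid_max", 10.0)) + 1e-9,
                                  float(cf.get("grid_step", 0.1))), 10)
        min_cell = int(cf.get("min_cell", 100))
        table12 = conditional.build_lookup(t1c, t2c, grid, grid, min_cell)
        assignments = conditional.assign_conjunction(t1c, t2c, grid, grid, min_cell)
        _write_table(table12.to_frame().reset_index(), out / "lookup_12.tsv",
                     config, stage)
        _write_table(assignments[["SNP", "CHR", "BP", "P", "P_2",
                                  "CONDFDR_12", "CONDFDR_21", "CONJFDR"]],
                     out / "assignments.tsv", config, stage)

        # --- loci --------------------------------------------------------
        stage = "loci"
        lc = config.get("loci") or {}
        fdr_thr = float(lc.get("fdr", 0.05))
        r2_thr = float(lc.get("r2", 0.2))
        cond_loci = loci.significant_loci(assignments, ld,
                                          fdr_column="CONDFDR_12",
                                          fdr_threshold=fdr_thr,
                                          r2_threshold=r2_thr)
        conj_loci = loci.conjunction_loci(assignments, ld,
                                          fdr_threshold=fdr_thr,
                                          r2_threshold=r2_thr)
        _write_table(cond_loci, out / "conditional_loci.tsv", config, stage)
        _write_table(conj_loci, out / "conjunction_loci.tsv", config, stage)

        # --- mixture fits -------------------------------------------------
        stage = "mixfit"
        mf = config.get("mixfit") or {}
        if mf.get("enabled", True):
            seed = int(config.get("seed", 0))
            fit2 = mixture.fit_two_groups(t1c["Z"].to_numpy(), seed=seed,
                                          restarts=int(mf.get("restarts", 5)))
            fit4 = mixture.fit_four_groups(t1c["Z"].to_numpy(),
                                           t2c["Z"].to_numpy(), seed=seed,
                                           restarts=int(mf.get("restarts", 5)))
            _write_table(pd.DataFrame({
                "parameter": ["pi0", "sigma0_sq", "sigma1_sq", "loglik"],
                "value": [fit2.pi0, fit2.sigma0_sq, fit2.sigma1_sq, fit2.loglik],
            }), out / "two_groups_fit.tsv", config, stage)
            _write_table(pd.DataFrame({
                "parameter": ["pi0", "pi1", "pi2", "pi3", "sigma0_sq_1",
                              "sigma0_sq_2", "sigma1_sq", "sigma2_sq", "rho3",
                              "loglik"],
                "value": [*fit4.pi, *fit4.sigma0_sq, fit4.sigma1_sq,
                          fit4.sigma2_sq, fit4.rho3, fit4.loglik],
            }), out / "four_groups_fit.tsv", config, stage)

        # --- plots --------------------------------------------------------
        stage = "plot"
        if (config.get("plot") or {}).get("enabled", True):
            qq = viz.conditional_qq(t1c, t2c)
            viz.plot_qq(qq, out / "conditional_qq.png")
            viz.plot_tdr(viz.tdr_curves(qq), out / "conditional_tdr.png")
            reps = (cond_loci.loc[cond_loci["REPRESENTATIVE"], "SNP"]
                    if not cond_loci.empty else [])
            viz.manhattan(assignments, out / "manhattan_conditional.png",
                          fdr_column="CONDFDR_12", representatives=reps,
                          title="conditional FDR, trait1 | trait2")
            viz.manhattan(assignments, out / "manhattan_conjunction.png",
                          fdr_column="CONJFDR",
                          title="conjunction FDR")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
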