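"""End-to-end orchestration: data -> Re -> REML -> trajectories -> index -> GWAS.

Each stage writes plain delimited tables into the run's output directory;
every file starts with comment lines carrying the config hash and seed so
that two runs with the same config are identical except timestamps in the
log.  The stages can be driven from Python (:func:`run_quantgen`,
:func:`run_gwas`, :func:`run_all`) or from the thin CLI in
:mod:`recurve.cli`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gwas as gwas_mod
from . import legendre, pca_index, phenotypes
from .mixedmodel import (FitResult, fit_repeatability, fit_rrm, genetic_trend,
                         information_criteria, relative_importance,
                         trajectory_table)
from .pedigree import (a_inverse_sparse, inbreeding_classes,
                       inbreeding_meuwissen_luo, read_pedigree, write_pedigree)
from .plinkio import read_plink1, write_plink1
from .simulate import (SimConfig, simulate_genotypes, simulate_ra_dataset,
                       to_calving_records)

logger = logging.getLogger("recurve")


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys in the file are an error."""

    seed: int = 1
    outdir: str = "recurve_run"
    # inputs (optional: when absent the synthetic generator is used)
    pedigree_path: str | None = None
    records_path: str | None = None
    plink_prefix: str | None = None
    gene_table_path: str | None = None
    # model choices
    models: tuple = ("rep", "ra1", "ra2")
    n_fc_classes: int = 15
    fc_class_width: float = 0.02
    max_cn: int = 9
    re_formula: str = "time"
    re_cap: bool = True
    # index / cohort
    n_pcs_index: int = 2
    n_top: int = 212
    n_negative: int = 40
    # gwas knobs
    call_rate_min: float = 0.95
    maf_min: float = 0.05
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.5
    n_strat_pcs: int = 10
    suggestive_p: float = 1e-4
    genomewide_p: float = 1e-5
    gene_flank_bp: int = 500_000
    # synthetic generator overrides
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output path is not part
        of what determines the results)."""
        d = asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, index=False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def _setup_logging(outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)


class _Stage:
    def __init__(self, name):
        self.name = name

    def __enter__(self):
        self.t0 = time.time()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is not None:
            logger.error("stage %s: FAILED (%s)", self.name, exc)
            return False
        logger.info("stage %s: done in %.1fs", self.name, time.time() - self.t0)
        return False


def run_simulate(cfg: RunConfig) -> dict:
    """Generate a full synthetic dataset and write it to the output directory."""
    outdir = Path(cfg.outdir)
    _setup_logging(outdir)
    cfg_echo = outdir / "config_used.yaml"
    cfg_echo.parent.mkdir(parents=True, exist_ok=True)
    cfg_echo.write_text(yaml.safe_dump(asdict(cfg)))
    sim = cfg.sim_config()
    rng = np.random.default_rng(sim.seed + 1)
    with _Stage("simulate"):
        ped, table, truth = simulate_ra_dataset(sim)
        recs, birth = to_calving_records(table, ped, rng)
        geno, y_pseudo, truth_g = simulate_genotypes(sim, np.random.default_rng(sim.seed + 2))
        write_pedigree(ped, outdir / "pedigree.csv")
        recs.to_csv(outdir / "calving_records.csv", index=False)
        birth.rename("birth_date").to_csv(outdir / "birth_dates.csv")
        _write_table(table, outdir / "analysis_table.tsv", cfg)
        write_plink1(outdir / "genotypes", geno)
        truth.write(outdir / "truth")
        truth_g.write(outdir / "truth_genotypes")
    return {"pedigree": ped, "table": table, "truth": truth,
            "genotypes": geno, "pseudo_phenotype": y_pseudo}


def run_quantgen(cfg: RunConfig, data: dict | None = None) -> dict:
    """Quantitative-genetics stage: descriptives, REML fits, trajectories,
    eigen analysis and the composite index; emits the six report tables."""
    outdir = Path(cfg.outdir)
    _setup_logging(outdir)
    if data is None:
        data = _load_or_simulate(cfg)
    ped, table = data["pedigree"], data["table"]

    with _Stage("descriptives"):
        stats_rows = []
        d = phenotypes.descriptive_stats(table["re"])
        stats_rows.append({"parameter": "Reproductive efficiency (%)", **d})
        first = table[table["cn"] == 1]
        if len(first) > 1:
            stats_rows.append({"parameter": "1st calving age (months)",
                               **phenotypes.descriptive_stats(first["age_months"])})
        if "fc" in table:
            stats_rows.append({"parameter": "Inbreeding coefficient (Fc)",
                               **phenotypes.descriptive_stats(table["fc"])})
        descr = pd.DataFrame(stats_rows)
        _write_table(descr, outdir / "table_descriptives.tsv", cfg)

    F = inbreeding_meuwissen_luo(ped)
    ainv = a_inverse_sparse(ped, F)
    fits: dict[str, FitResult] = {}
    with _Stage("reml"):
        for model in cfg.models:
            if model == "rep":
                fits[model] = fit_repeatability(table, ped, ainv=ainv, F=F)
            else:
                r = int(model[-1])
                fits[model] = fit_rrm(table, ped, r=r, ainv=ainv, F=F,
                                      n_fc_classes=cfg.n_fc_classes,
                                      fc_class_width=cfg.fc_class_width)
            logger.info("model %s: logL=%.2f converged=%s iters=%d",
                        model, fits[model].logL, fits[model].converged,
                        fits[model].n_iter)
            hist = pd.DataFrame({"iteration": range(len(fits[model].history)),
                                 "logL": fits[model].history})
            _write_table(hist, outdir / f"reml_{model}_logl.tsv", cfg)

    with _Stage("reports"):
        if "rep" in fits:
            rep = fits["rep"]
            comp = {k: rep.components[k] for k in ("animal", "pe", "hys", "residual")}
            ri = relative_importance(comp)
            comps = pd.DataFrame({"effect": list(comp), "variance": list(comp.values()),
                                  "relative_importance_pct": [ri[k] for k in comp]})
            comps.loc[len(comps)] = ["total", sum(comp.values()), 100.0]
            _write_table(comps, outdir / "table_components_rep.tsv", cfg)

        mc = pd.DataFrame([{
            "model": m, "n_parameters": f.n_params, "logL": f.logL,
            **information_criteria(f.logL, f.n_params, f.n_records),
            "converged": f.converged,
        } for m, f in fits.items()])
        _write_table(mc, outdir / "table_model_comparison.tsv", cfg)

        ra_name = next((m for m in ("ra2", "ra1") if m in fits), None)
        results = {"fits": fits, "pedigree": ped, "table": table, "data": data}
        if ra_name:
            ra = fits[ra_name]
            traj = trajectory_table(ra)
            _write_table(traj, outdir / "table_trajectory.tsv", cfg)
            basis = ra.meta["basis"]
            rg = legendre.genetic_correlation_matrix(ra.components["Ka"], basis.Phi)
            _write_table(pd.DataFrame(rg,
                                      index=[f"cn{i}" for i in range(1, 10)],
                                      columns=[f"cn{i}" for i in range(1, 10)]),
                         outdir / "table_genetic_correlations.tsv", cfg, index=True)

            panel = pca_index.standardize_panel(ra.solutions["egv"])
            pca = pca_index.pca_eigen(panel)
            eig = pd.DataFrame({"variable": [f"ev{i}" for i in range(1, 10)],
                                "PC1": pca.pc1, "PC2": pca.pc2})
            eig.loc[len(eig)] = ["eigenvalue", pca.eigenvalues[0], pca.eigenvalues[1]]
            eig.loc[len(eig)] = ["variance_pct", pca.variance_pct[0], pca.variance_pct[1]]
            _write_table(eig, outdir / "table_eigen.tsv", cfg)

            idx = pca_index.index_table(panel, pca)
            _write_table(idx, outdir / "table_index.tsv", cfg, index=True)
            egv_corr = pd.DataFrame({
                "EGV1": [float(np.corrcoef(ra.solutions["egv"]["cn1"],
                                           ra.solutions["egv"][c])[0, 1])
                         for c in ra.solutions["egv"].columns],
                "IpcT": [float(np.corrcoef(idx.loc[panel.index, "IpcT"],
                                           ra.solutions["egv"].loc[panel.index, c])[0, 1])
                         for c in ra.solutions["egv"].columns],
            }, index=ra.solutions["egv"].columns)
            _write_table(egv_corr, outdir / "table_egv_correlations.tsv", cfg, index=True)

            birth_year = pd.Series(ped.birth_year, index=ped.ids)
            trend = genetic_trend(idx["IpcT"], birth_year)
            _write_table(trend, outdir / "table_genetic_trend.tsv", cfg)
            results.update({"trajectory": traj, "pca": pca, "index": idx,
                            "panel": panel})
        return results


def run_gwas(cfg: RunConfig, data: dict | None = None) -> dict:
    """Association stage: QC, LD pruning, GRM, stratification PCs, LMM scan,
    hits and candidate-gene windows."""
    outdir = Path(cfg.outdir)
    _setup_logging(outdir)
    if data is None:
        data = {}
    geno = data.get("genotypes")
    y = data.get("pseudo_phenotype")
    if geno is None:
        if cfg.plink_prefix:
            with _Stage("read genotypes"):
                geno = read_plink1(cfg.plink_prefix)
                y = data.get("pseudo_phenotype")
                if y is None:
                    y = pd.Series(pd.to_numeric(geno.fam["phenotype"]).to_numpy(),
                                  index=geno.fam["iid"].to_numpy())
        else:
            sim = cfg.sim_config()
            with _Stage("simulate genotypes"):
                geno, y, _ = simulate_genotypes(sim, np.random.default_rng(sim.seed + 2))

    with _Stage("qc"):
        g_qc, rep_qc = gwas_mod.qc_filter(geno, cfg.call_rate_min, cfg.maf_min)
        g_pruned, rep_ld = gwas_mod.ld_prune(g_qc, cfg.ld_window, cfg.ld_step,
                                             cfg.ld_r2_max)
        qc_tab = pd.DataFrame([{"n_input": rep_qc.n_input,
                                "fail_callrate": rep_qc.n_fail_callrate,
                                "fail_maf": rep_qc.n_fail_maf,
                                "pruned_ld": rep_ld.n_pruned_ld,
                                "n_final": rep_ld.n_output}])
        _write_table(qc_tab, outdir / "gwas_qc_report.tsv", cfg)

    with _Stage("scan"):
        yv = np.asarray(y, dtype=float)
        K = gwas_mod.grm_centered(g_pruned)
        W = gwas_mod.stratification_pcs(g_pruned, cfg.n_strat_pcs)
        null = gwas_mod.lmm_null(yv, W, K)
        scan = gwas_mod.wald_scan(g_pruned, yv, W, K, null)
        _write_table(scan, outdir / "gwas_scan.tsv", cfg)
        _write_table(gwas_mod.manhattan_table(scan), outdir / "gwas_manhattan.tsv", cfg)
        logger.info("lambda=%.4g tau_inv=%.4g lambda_GC=%.3f", null.lam,
                    null.tau_inv, gwas_mod.lambda_gc(scan["p_wald"].dropna()))

    with _Stage("hits"):
        hits = gwas_mod.significant_hits(scan, cfg.suggestive_p, cfg.genomewide_p)
        _write_table(hits, outdir / "gwas_hits.tsv", cfg)
        genes = pd.DataFrame()
        if cfg.gene_table_path:
            gene_table = pd.read_csv(cfg.gene_table_path, sep=None, engine="python")
            genes = gwas_mod.candidate_genes(hits, gene_table, cfg.gene_flank_bp)
            _write_table(genes, outdir / "gwas_candidate_genes.tsv", cfg)
    return {"scan": scan, "hits": hits, "genes": genes, "null": null,
            "genotypes": g_pruned, "qc": (rep_qc, rep_ld)}


def run_all(cfg: RunConfig) -> dict:
    """simulate -> quantgen -> gwas, feeding the composite index forward as
    the GWAS pseudo-phenotype on the genotyped cohort."""
    data = run_simulate(cfg)
    qg = run_quantgen(cfg, data)
    idx = qg.get("index")
    if idx is not None:
        cohort = pca_index.select_cohort(idx["IpcT"], cfg.n_top, cfg.n_negative)
        logger.info("cohort: %d animals", len(cohort))
        sim = cfg.sim_config()
        geno, y, _ = simulate_genotypes(
            sim, np.random.default_rng(sim.seed + 2),
            ipct_genetic=idx.loc[cohort, "IpcT"]
            if len(cohort) >= sim.n_samples else idx["IpcT"])
        data["genotypes"], data["pseudo_phenotype"] = geno, y
    g = run_gwas(cfg, data)
    return {**qg, **g}


def _load_or_simulate(cfg: RunConfig) -> dict:
    if cfg.pedigree_path and cfg.records_path:
        ped = read_pedigree(cfg.pedigree_path)
        recs = pd.read_csv(cfg.records_path, dtype={"cow": str, "herd": str})
        birth = None
        bd_path = Path(cfg.records_path).with_name("birth_dates.csv")
        if bd_path.exists():
            bd = pd.read_csv(bd_path, index_col=0)
            birth = bd.iloc[:, 0]
        else:
            birth = pd.Series({a: pd.Timestamp(f"{y}-01-01")
                               for a, y in zip(ped.ids, ped.birth_year)})
        F = inbreeding_meuwissen_luo(ped)
        fc = pd.Series(F, index=ped.ids)
        fc_cls = pd.Series(inbreeding_classes(F), index=ped.ids)
        table, _ = phenotypes.compute_re(recs, birth, formula=cfg.re_formula,
                                         cap=cfg.re_cap, fc=fc, fc_class=fc_cls)
        table, _ = phenotypes.filter_records(table, max_cn=cfg.max_cn)
        return {"pedigree": ped, "table": table}
    sim = cfg.sim_config()
    ped, table, truth = simulate_ra_dataset(sim)
    return {"pedigree": ped, "table": table, "truth": truth}
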