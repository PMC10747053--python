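"""Config-driven end-to-end workflow.

Stage order mirrors the field workflow: site filtering -> LD pruning ->
structure (NJ tree, PCA, admixture with cross-validated K) -> isolation by
distance (Mantel) -> pairwise windowed sweep scans -> genotype-environment
association with SAL merging and gene lookup -> phenotype summary.  Every
output file starts with a provenance header (version, seed, parameters), and
a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import sojapop
from sojapop.errors import ConfigError, SojapopError
from sojapop import gea, geostats, pheno, popstats, structure, sweeps
from sojapop.genotypes import GenotypeMatrix
from sojapop.popstats import ScanParams
from sojapop.sim import SimConfig, simulate, write_outputs
from sojapop.vcfio import FilterSpec, ld_prune, read_vcf

log = logging.getLogger("sojapop")


@dataclass
class RunConfig:
    outdir: str = "sojapop_out"
    seed: int = 0
    log_level: str = "INFO"
    # inputs: either a simulate block or file paths
    simulate: SimConfig | None = None
    vcf: str | None = None
    metadata: str | None = None
    environment: str | None = None
    gff: str | None = None
    phenotypes: str | None = None
    homolog_map: str | None = None
    contig_blocklist: tuple = ()
    # stage parameters (module defaults)
    filter: FilterSpec = field(default_factory=FilterSpec)
    prune_window_snps: int = 50
    prune_step_snps: int = 10
    prune_r2_max: float = 0.1
    scan: ScanParams = field(default_factory=ScanParams)
    fst_tail: float = 0.05
    pi_tail: float = 0.05
    k_min: int = 2
    k_max: int = 10
    cv_folds: int = 5
    mantel_permutations: int = 9999
    n_latent: int | None = None      # default: best K - 1
    sal_flank: int = 100_000
    sal_q_max: float = 0.05
    env_vars: tuple = ("annual_mean_temp", "annual_precip", "latitude")


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config, reporting every violation."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a key-value mapping")
    return build_config(raw, base=Path(path).parent)


def build_config(raw: dict, base=Path(".")) -> RunConfig:
    problems = []
    cfg = RunConfig()
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key, val in raw.items():
        if key not in known:
            problems.append(f"unknown config key {key!r}")
    for key in ("outdir", "seed", "log_level", "prune_window_snps", "prune_step_snps",
                "prune_r2_max", "fst_tail", "pi_tail", "k_min", "k_max", "cv_folds",
                "mantel_permutations", "n_latent", "sal_flank", "sal_q_max"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "env_vars" in raw:
        cfg.env_vars = tuple(raw["env_vars"])
    if "contig_blocklist" in raw:
        cfg.contig_blocklist = tuple(raw["contig_blocklist"])
    if "filter" in raw:
        try:
            cfg.filter = FilterSpec(**(raw["filter"] or {}))
        except (SojapopError, TypeError) as exc:
            problems.append(f"filter: {exc}")
    if "scan" in raw:
        try:
            cfg.scan = ScanParams(**(raw["scan"] or {}))
        except (SojapopError, TypeError) as exc:
            problems.append(f"scan: {exc}")
    if "simulate" in raw and raw["simulate"] is not None:
        try:
            cfg.simulate = SimConfig(**(raw["simulate"] or {}))
            cfg.simulate.validate()
        except (SojapopError, TypeError) as exc:
            problems.append(f"simulate: {exc}")
    for key in ("vcf", "metadata", "environment", "gff", "phenotypes", "homolog_map"):
        if raw.get(key):
            p = (base / raw[key]).resolve() if not Path(raw[key]).is_absolute() else Path(raw[key])
            if not p.exists():
                problems.append(f"{key}: file not found: {raw[key]}")
            setattr(cfg, key, str(p))
    if cfg.simulate is None and cfg.vcf is None:
        problems.append("either a 'simulate' block or a 'vcf' path is required")
    if cfg.simulate is None and cfg.vcf is not None and cfg.metadata is None:
        problems.append("a 'metadata' table is required alongside 'vcf'")
    if cfg.k_min < 1 or cfg.k_max < cfg.k_min:
        problems.append(f"invalid K range [{cfg.k_min}, {cfg.k_max}]")
    if not 0 < cfg.fst_tail < 1 or not 0 < cfg.pi_tail < 1:
        problems.append("fst_tail and pi_tail must lie in (0, 1)")
    if cfg.prune_window_snps < 2:
        problems.append("prune_window_snps must be >= 2")
    if problems:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))
    return cfg


def _provenance(cfg: RunConfig, **extra) -> str:
    bits = [f"sojapop={sojapop.__version__}", f"seed={cfg.seed}"]
    bits += [f"{k}={v}" for k, v in extra.items()]
    return "# " + " ".join(bits) + "\n"


def _write_tsv(df: pd.DataFrame, path, cfg: RunConfig, **extra) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg, **extra))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns a map of artifact names to paths."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    stage = "inputs"
    try:
        if cfg.simulate is not None:
            stage = "simulate"
            sim = simulate(cfg.simulate)
            paths = write_outputs(sim, out / "simulated")
            artifacts.update({f"sim_{k}": v for k, v in paths.items()})
            vcf_path = paths["vcf"]
            metadata = sim.metadata
            environment = sim.environment
            phenotypes = sim.phenotypes
        else:
            vcf_path = cfg.vcf
            metadata = pd.read_csv(cfg.metadata, sep="\t")
            environment = pd.read_csv(cfg.environment, sep="\t") if cfg.environment else None
            phenotypes = pd.read_csv(cfg.phenotypes, sep="\t") if cfg.phenotypes else None

        stage = "filter"
        gm = read_vcf(vcf_path, cfg.filter, cfg.contig_blocklist)
        log.info("filtered matrix: %d samples x %d sites", gm.n_samples, gm.n_sites)
        sites_tsv = out / "filtered_sites.tsv"
        _write_tsv(gm.sites, sites_tsv, cfg, stage="filter",
                   maf_min=cfg.filter.maf_min, max_missing=cfg.filter.max_missing)
        artifacts["filtered_sites"] = str(sites_tsv)

        stage = "prune"
        pruned = ld_prune(gm, cfg.prune_window_snps, cfg.prune_step_snps, cfg.prune_r2_max)
        log.info("LD-pruned matrix: %d sites", pruned.n_sites)
        _write_tsv(pruned.sites, out / "pruned_sites.tsv", cfg, stage="prune",
                   r2_max=cfg.prune_r2_max)
        artifacts["pruned_sites"] = str(out / "pruned_sites.tsv")

        stage = "structure"
        dmat = structure.pdistance(gm)
        tree = structure.nj_tree(structure.pdistance(pruned))
        tree_path = out / "nj_tree.nwk"
        with open(tree_path, "w") as fh:
            fh.write(str(tree))
        artifacts["nj_tree"] = str(tree_path)
        scores, eigvals = structure.pca(pruned)
        pca_df = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
        pca_df.insert(0, "sample", pruned.samples)
        _write_tsv(pca_df, out / "pca_scores.tsv", cfg, stage="pca")
        _write_tsv(pd.DataFrame({"eigenvalue": eigvals}), out / "pca_eigenvalues.tsv",
                   cfg, stage="pca")
        artifacts["pca_scores"] = str(out / "pca_scores.tsv")
        cv = structure.choose_K(pruned, range(cfg.k_min, cfg.k_max + 1),
                                folds=cfg.cv_folds, seed=cfg.seed)
        best_k = min(cv, key=cv.get)
        log.info("cross-validated K errors: %s; best K=%d", cv, best_k)
        _write_tsv(pd.DataFrame({"K": list(cv), "cv_error": list(cv.values())}),
                   out / "choose_k.tsv", cfg, stage="choose_K", folds=cfg.cv_folds)
        fit = structure.admixture_fit(pruned, best_k, seed=cfg.seed)
        structure.write_q_matrix(fit, pruned.samples, out / "admixture_q.tsv")
        artifacts["admixture_q"] = str(out / "admixture_q.tsv")
        artifacts["choose_k"] = str(out / "choose_k.tsv")

        stage = "mantel"
        mantel_row = None
        if metadata is not None and {"location", "latitude", "longitude"} <= set(metadata.columns):
            loc_of = dict(zip(metadata["sample"], metadata["location"]))
            gd = structure.group_mean_distance(dmat, loc_of)
            coords = (metadata.groupby("location", sort=True)
                      .agg(latitude=("latitude", "mean"), longitude=("longitude", "mean"))
                      .reset_index())
            geo = geostats.haversine_matrix(coords)
            geo = geo.filter(gd.ids)
            r, p = geostats.mantel_test(gd, geo, n_perm=cfg.mantel_permutations,
                                        seed=cfg.seed)
            log.info("Mantel r=%.4f p=%.5f", r, p)
            mantel_row = pd.DataFrame([{"r": r, "p": p,
                                        "n_perm": cfg.mantel_permutations,
                                        "seed": cfg.seed}])
            _write_tsv(mantel_row, out / "mantel.tsv", cfg, stage="mantel")
            artifacts["mantel"] = str(out / "mantel.tsv")

        stage = "sweeps"
        groups = {}
        if metadata is not None and "group" in metadata.columns:
            for g, sub in metadata.groupby("group", sort=True):
                groups[g] = [s for s in sub["sample"] if s in set(gm.samples)]
        for ga, gb in itertools.combinations(sorted(groups), 2):
            scan = popstats.scan_pair(gm, groups[ga], groups[gb], cfg.scan)
            name = f"{ga}_vs_{gb}"
            _write_tsv(scan, out / f"scan_{name}.tsv", cfg, stage="scan",
                       window_bp=cfg.scan.window_bp, step_bp=cfg.scan.step_bp)
            regions = sweeps.call_sweeps(scan, cfg.fst_tail, cfg.pi_tail)
            thr = regions.attrs.get("thresholds", {})
            log.info("sweeps %s: %d regions, thresholds %s", name, len(regions), thr)
            bed = out / f"sweeps_{name}.bed"
            with open(bed, "w") as fh:
                fh.write(_provenance(cfg, stage="sweeps", comparison=name, **{
                    k: (f"{v:.6g}" if isinstance(v, float) else v) for k, v in thr.items()}))
                for rrow in regions.itertuples():
                    fh.write(f"{rrow.chrom}\t{rrow.start}\t{rrow.end}\t{rrow.direction}"
                             f"\t{rrow.max_fst:.6g}\t{rrow.extreme_log_pi_ratio:.6g}\n")
            artifacts[f"sweeps_{name}"] = str(bed)

        stage = "gea"
        if environment is not None and metadata is not None:
            env_table = metadata.merge(environment, on="location", how="left")
            env_table = env_table.set_index("sample").loc[gm.samples]
            n_latent = cfg.n_latent if cfg.n_latent is not None else max(1, best_k - 1)
            fac_scores, _ = structure.pca(pruned, n_components=n_latent)
            genes = (gea.read_gff3_genes(cfg.gff, _load_homologs(cfg.homolog_map))
                     if cfg.gff else None)
            for env_name in cfg.env_vars:
                if env_name not in env_table.columns:
                    log.warning("environment variable %r not available; skipped", env_name)
                    continue
                res = gea.associate(gm, env_table[env_name].to_numpy(float),
                                    env_name=env_name, n_latent=n_latent,
                                    factors=fac_scores[:, :n_latent])
                log.info("GEA %s: lambda=%.3f, %d SNPs q<%.2g", env_name,
                         res.attrs["lambda_gc"], int((res["q"] < cfg.sal_q_max).sum()),
                         cfg.sal_q_max)
                _write_tsv(res, out / f"assoc_{env_name}.tsv", cfg, stage="gea",
                           n_latent=n_latent,
                           lambda_gc=f"{res.attrs['lambda_gc']:.6g}")
                sals = gea.build_sals(res, gm.chrom_lengths, cfg.sal_flank, cfg.sal_q_max)
                _write_tsv(sals, out / f"sals_{env_name}.tsv", cfg, stage="sals",
                           flank=cfg.sal_flank, q_max=cfg.sal_q_max)
                artifacts[f"assoc_{env_name}"] = str(out / f"assoc_{env_name}.tsv")
                artifacts[f"sals_{env_name}"] = str(out / f"sals_{env_name}.tsv")
                if genes is not None:
                    hits = gea.genes_in_sals(sals, genes)
                    _write_tsv(hits, out / f"sal_genes_{env_name}.tsv", cfg, stage="sal_genes")
                    artifacts[f"sal_genes_{env_name}"] = str(out / f"sal_genes_{env_name}.tsv")

        stage = "phenosummary"
        if phenotypes is not None:
            summary = pheno.summarize(phenotypes)
            _write_tsv(summary, out / "phenotype_summary.tsv", cfg, stage="phenosummary")
            artifacts["phenotype_summary"] = str(out / "phenotype_summary.tsv")
    except SojapopError as exc:
        raise SojapopError(f"stage {stage!r} failed: {exc}") from exc
    return artifacts


def _load_homologs(path):
    if not path:
        return None
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "homolog"],
                     comment="#")
    return dict(zip(df["gene_id"], df["homolog"]))
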