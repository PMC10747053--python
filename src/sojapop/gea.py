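"""Latent-factor genotype–environment association, FDR, and SAL construction.

Per-SNP tests regress dosage on the environmental variable plus the top
latent factors (principal-component scores of the LD-pruned genotype matrix),
which absorb neutral population structure the way latent-factor mixed models
do.  Test statistics are recalibrated with the genomic-inflation factor
lambda = median(z^2) / median(chi^2_1), and p-values taken from
z^2 / lambda against chi^2_1; Benjamini–Hochberg adjustment controls the FDR.
Significant SNPs are flanked by +/-100 kb and overlapping or touching
neighborhoods merged into significantly associated loci (SALs).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from sojapop.errors import SojapopError
from sojapop.genotypes import MISSING, GenotypeMatrix
from sojapop.structure import pca

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))   # 0.4549...

ASSOC_COLUMNS = ["chrom", "pos", "env_name", "beta", "z", "p_raw", "q", "flag"]
SAL_COLUMNS = ["chrom", "start", "end", "n_snps", "peak_pos", "peak_q", "env_name"]


def fdr_adjust(p_raw) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (empty in, empty out)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise SojapopError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _ols_env_stats(y: np.ndarray, X: np.ndarray):
    """OLS of y (n x m dosages) on X; t-statistic of column 1 (env)."""
    n, p = X.shape
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return None
    if np.linalg.cond(XtX) > 1e10:
        return None
    B = XtX_inv @ (X.T @ y)                       # p x m
    resid = y - X @ B
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    beta = B[1]
    # degenerate fits (monomorphic dosage, perfect fit) carry no evidence
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 1e-8 * (1.0 + np.abs(beta)), beta / np.maximum(se, 1e-300), 0.0)
    return beta, z


def associate(gm: GenotypeMatrix, env, env_name: str = "env", n_latent: int = 2,
              factors: np.ndarray | None = None, gc_recalibrate: bool = True
              ) -> pd.DataFrame:
    """Structure-adjusted per-SNP association between dosage and environment.

    ``factors`` may carry externally computed latent factors (e.g. PC scores
    of the LD-pruned matrix); otherwise the top ``n_latent`` PCs of ``gm``
    itself are used.  ``n_latent <= 0`` falls back to plain per-SNP
    regression with a warning.  Collinear env/factor designs set the affected
    p-values to 1 with ``flag='collinear'``.
    """
    env = np.asarray(env, dtype=float)
    if env.shape != (gm.n_samples,):
        raise SojapopError("env must hold one value per sample")
    if np.std(env) == 0:
        raise SojapopError("environment variable is constant")
    if n_latent >= gm.n_samples:
        raise SojapopError("n_latent must be smaller than the sample count")
    if factors is None:
        if n_latent > 0:
            scores, _ = pca(gm, n_components=n_latent)
            factors = scores[:, :n_latent]
        else:
            warnings.warn("n_latent <= 0: plain per-SNP regression without "
                          "structure correction")
            factors = np.empty((gm.n_samples, 0))
    factors = np.asarray(factors, dtype=float)

    n = gm.n_samples
    X = np.column_stack([np.ones(n), (env - env.mean()) / env.std(), factors])
    d = gm.dosage.astype(float)
    missing = gm.dosage == MISSING
    beta = np.zeros(gm.n_sites)
    z = np.zeros(gm.n_sites)
    flag = np.array([""] * gm.n_sites, dtype=object)

    complete = ~missing.any(axis=0)
    res = _ols_env_stats(d[:, complete], X) if complete.any() else (np.array([]),) * 2
    if res is None:
        flag[:] = "collinear"
    else:
        beta[complete], z[complete] = res
    for j in np.flatnonzero(~complete):
        keep = ~missing[:, j]
        if keep.sum() <= X.shape[1] + 1:
            flag[j] = "collinear"
            continue
        r = _ols_env_stats(d[keep, j][:, None], X[keep])
        if r is None:
            flag[j] = "collinear"
            continue
        beta[j], z[j] = float(r[0][0]), float(r[1][0])

    z2 = z ** 2
    # lambda from polymorphic, cleanly fitted SNPs only; the reference null
    # for a squared t-statistic is F(1, dof), whose tail is noticeably
    # heavier than chi2_1 at these sample sizes
    d_var = np.nanvar(np.where(missing, np.nan, d), axis=0)
    ok = (flag == "") & (d_var > 0)
    dof = np.where(complete, n - X.shape[1],
                   np.maximum((~missing).sum(axis=0) - X.shape[1], 1))
    med_dof = float(np.median(dof[ok])) if ok.any() else float(n - X.shape[1])
    null_median = float(stats.f.ppf(0.5, 1, med_dof))
    lam = 1.0
    if gc_recalibrate and ok.any():
        lam = float(np.median(z2[ok]) / null_median)
        if not np.isfinite(lam) or lam <= 0:
            lam = 1.0
    p_raw = stats.f.sf(z2 / lam, 1, dof)
    p_raw[~ok] = 1.0
    out = pd.DataFrame({
        "chrom": gm.sites["chrom"], "pos": gm.sites["pos"],
        "env_name": env_name, "beta": beta, "z": z,
        "p_raw": p_raw, "q": fdr_adjust(p_raw), "flag": flag,
    })
    out.attrs["lambda_gc"] = lam
    return out


def build_sals(results: pd.DataFrame, chrom_lengths: dict, flank: int = 100_000,
               q_max: float = 0.05) -> pd.DataFrame:
    """Merge +/-``flank`` neighborhoods of significant SNPs into SALs.

    Intervals are 0-based half-open, clipped to [0, L); overlapping or
    touching intervals on one chromosome merge.  The peak is the contained
    significant SNP with the smallest q.
    """
    sig = results.loc[results["q"] < q_max].sort_values(["chrom", "pos"])
    rows = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        if chrom not in chrom_lengths:
            raise SojapopError(f"no chromosome length for contig {chrom!r}")
        L = int(chrom_lengths[chrom])
        cur = None
        for snp in sub.itertuples():
            s = max(0, int(snp.pos) - flank)
            e = min(L, int(snp.pos) + flank)
            if cur is None or s > cur["end"]:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": s, "end": e, "n_snps": 1,
                       "peak_pos": int(snp.pos), "peak_q": float(snp.q),
                       "env_name": snp.env_name}
            else:
                cur["end"] = max(cur["end"], e)
                cur["n_snps"] += 1
                if snp.q < cur["peak_q"]:
                    cur["peak_pos"], cur["peak_q"] = int(snp.pos), float(snp.q)
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(rows, columns=SAL_COLUMNS)


def read_gff3_genes(path, homolog_map: dict | None = None) -> pd.DataFrame:
    """Gene features from a GFF3 file, converted to 0-based half-open.

    ``homolog_map`` optionally maps gene id -> annotation string (e.g. a
    precomputed best-hit homolog table).
    """
    from gffutils.iterators import DataIterator

    rows = []
    for feat in DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        gid = feat.attributes.get("ID", [feat.id or "?"])[0]
        rows.append({"gene_id": gid, "chrom": feat.seqid,
                     "start": int(feat.start) - 1, "end": int(feat.end),
                     "homolog": (homolog_map or {}).get(gid, "")})
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "homolog"])
    if (genes["start"] >= genes["end"]).any():
        raise SojapopError("gene with non-positive length in GFF3")
    return genes


def genes_in_sals(sals: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Genes overlapping each SAL by >= 1 bp (half-open semantics).

    Returns one row per (SAL, gene) pair; SALs on contigs absent from the
    gene table yield a warning and no rows.
    """
    known = set(genes["chrom"])
    rows = []
    for i, sal in sals.iterrows():
        if sal["chrom"] not in known:
            warnings.warn(f"contig {sal['chrom']!r} has SALs but no annotated genes")
            continue
        sub = genes.loc[genes["chrom"] == sal["chrom"]]
        hit = sub.loc[(sub["start"] < sal["end"]) & (sub["end"] > sal["start"])]
        for g in hit.itertuples():
            rows.append({"sal_index": i, "chrom": sal["chrom"],
                         "sal_start": sal["start"], "sal_end": sal["end"],
                         "env_name": sal["env_name"], "gene_id": g.gene_id,
                         "gene_start": g.start, "gene_end": g.end,
                         "homolog": g.homolog})
    return pd.DataFrame(rows, columns=["sal_index", "chrom", "sal_start", "sal_end",
                                       "env_name", "gene_id", "gene_start",
                                       "gene_end", "homolog"])
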