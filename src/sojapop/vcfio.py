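"""VCF reading with site filters, and PLINK-style LD pruning.

Filtering follows common GBS practice for a selfing wild-plant panel:
per-genotype depth/quality masking first (only when the VCF carries the
FORMAT fields), then site-level missingness and minor-allele-frequency
filters.  Boundary rules: a site is kept when MAF >= ``maf_min`` and dropped
when its missing fraction >= ``max_missing``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from sojapop.errors import SojapopError, VcfParseError
from sojapop.genotypes import MISSING, SITE_COLUMNS, GenotypeMatrix


@dataclass
class FilterSpec:
    """Site/genotype filter thresholds.

    ``min_depth`` and ``min_gq`` are applied per genotype only when the VCF
    declares FORMAT/DP resp. FORMAT/GQ.
    """

    maf_min: float = 0.05
    max_missing: float = 0.5
    min_depth: int = 3
    min_gq: int = 20

    def __post_init__(self):
        if not 0.0 <= self.maf_min <= 0.5:
            raise SojapopError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if not 0.0 <= self.max_missing <= 1.0:
            raise SojapopError(f"max_missing must be in [0, 1], got {self.max_missing}")


_SNP_ALLELES = frozenset("ACGT")


def _format_fields(vcf: VCF) -> set:
    fields = set()
    for h in vcf.header_iter():
        try:
            if h["HeaderType"] == "FORMAT":
                fields.add(h["ID"])
        except KeyError:
            continue
    return fields


def read_vcf(path, filt: FilterSpec | None = None, contig_blocklist=()) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are dropped.  Genotypes failing the
    per-sample DP/GQ thresholds are set missing before the site-level
    missingness and MAF filters.  Contigs in ``contig_blocklist`` (e.g.
    organellar genomes) are skipped entirely.  Zero surviving sites yields an
    empty matrix with a warning, not an error.
    """
    filt = filt or FilterSpec()
    blocked = set(contig_blocklist)
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # unreadable / non-VCF file
        raise VcfParseError(f"cannot open {path}: {exc}") from exc
    samples = list(vcf.samples)
    fmt = _format_fields(vcf)
    has_dp = "DP" in fmt
    has_gq = "GQ" in fmt

    chrom_lengths = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens or []):
        if length > 0:
            chrom_lengths[name] = int(length)

    rows, dosages = [], []
    record_no = 0
    it = iter(vcf)
    while True:
        try:
            var = next(it)
        except StopIteration:
            break
        except Exception as exc:
            raise VcfParseError(
                f"malformed VCF record after record {record_no} in {path}: {exc}"
            ) from exc
        record_no += 1
        if var.CHROM in blocked:
            continue
        if len(var.ALT) != 1:
            continue
        ref, alt = var.REF, var.ALT[0]
        if ref not in _SNP_ALLELES or alt not in _SNP_ALLELES:
            continue
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        d = var.gt_types.astype(np.int8)
        d[d == 3] = MISSING
        if has_dp:
            dp = var.format("DP")
            if dp is not None:
                dp = dp.reshape(-1).astype(float)
                d[(dp >= 0) & (dp < filt.min_depth)] = MISSING
        if has_gq:
            gq = var.format("GQ")
            if gq is not None:
                gq = gq.reshape(-1).astype(float)
                d[(gq >= 0) & (gq <= filt.min_gq)] = MISSING
        dosages.append(d)
        rows.append((var.CHROM, var.POS, ref, alt))

    if not rows:
        warnings.warn(f"no biallelic SNP records in {path}; returning empty matrix")
        return GenotypeMatrix(samples, pd.DataFrame(columns=SITE_COLUMNS),
                              np.zeros((len(samples), 0), np.int8), chrom_lengths)

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    dosage = np.array(dosages, dtype=np.int8).T  # samples x sites

    # stable sort keeps input order within equal coordinates
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(sites))):
        sites = sites.iloc[order].reset_index(drop=True)
        dosage = dosage[:, order]
    dup = sites.duplicated(subset=["chrom", "pos"]).to_numpy()
    if dup.any():
        warnings.warn(f"{dup.sum()} duplicate (chrom, pos) records dropped (first kept)")
        sites = sites.loc[~dup].reset_index(drop=True)
        dosage = dosage[:, ~dup]

    gm = GenotypeMatrix(samples, sites, dosage, chrom_lengths)
    keep = (gm.missing_fraction() < filt.max_missing) & (gm.maf() >= filt.maf_min)
    keep &= ~np.isnan(gm.maf())
    if not keep.any():
        warnings.warn("no sites survive the missingness/MAF filters; empty matrix")
    return gm.take_sites(np.flatnonzero(keep))


def _window_r2(dosage_window: np.ndarray) -> np.ndarray:
    """Pairwise squared dosage correlation, missing values pairwise-deleted."""
    masked = np.ma.masked_equal(dosage_window.astype(float), float(MISSING))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = np.ma.corrcoef(masked.T)
    r2 = np.asarray(np.ma.filled(r, 0.0)) ** 2
    np.fill_diagonal(r2, 0.0)
    return np.nan_to_num(r2, nan=0.0)


def ld_prune(gm: GenotypeMatrix, window_snps: int = 50, step_snps: int = 10,
             r2_max: float = 0.1) -> GenotypeMatrix:
    """Thin SNPs so no retained intra-window pair exceeds ``r2_max``.

    Mirrors PLINK ``--indep-pairwise 50 10 0.1``: per chromosome, a window of
    ``window_snps`` sites advances by ``step_snps``; within each window every
    retained pair with r^2 > ``r2_max`` loses one member.  The victim is the
    SNP with lower MAF (ties: the later site), so results are deterministic.
    The sweep repeats over the surviving sites until no further site is
    removed (in structured panels, sites from different original windows can
    exceed the threshold once they become neighbours), which also makes
    pruning idempotent: pruning an already-pruned matrix is the identity.
    """
    if window_snps < 2:
        raise SojapopError("window_snps must be >= 2")
    if gm.n_sites == 0:
        raise SojapopError("cannot LD-prune an empty genotype matrix")
    result = gm
    while True:
        result, removed = _prune_pass(result, window_snps, step_snps, r2_max)
        if not removed:
            return result


def _prune_pass(gm: GenotypeMatrix, window_snps, step_snps, r2_max):
    maf = gm.maf()
    keep = np.ones(gm.n_sites, dtype=bool)
    for _, grp in gm.sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for start in range(0, len(idx), step_snps):
            widx = idx[start:start + window_snps]
            if len(widx) < 2:
                continue
            live = widx[keep[widx]]
            if len(live) < 2:
                continue
            r2 = _window_r2(gm.dosage[:, live])
            alive = np.ones(len(live), dtype=bool)
            for a in range(len(live)):
                if not alive[a]:
                    continue
                for b in range(a + 1, len(live)):
                    if not alive[b] or r2[a, b] <= r2_max:
                        continue
                    if maf[live[a]] < maf[live[b]]:
                        victim = a
                    else:  # equal MAF removes the later site
                        victim = b
                    alive[victim] = False
                    keep[live[victim]] = False
                    if victim == a:
                        break
            if start + window_snps >= len(idx):
                break
    removed = int((~keep).sum())
    return gm.take_sites(np.flatnonzero(keep)), removed
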